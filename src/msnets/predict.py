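"""Connectome-based prediction of a binary long-term outcome.

Implements a prediction framework that embeds NBS-style connected-component
feature selection inside stratified nested cross-validation:

* outer folds give the held-out performance estimate;
* inside each training fold, edges are residualized against confounds with
  coefficients estimated on the training fold only (cross-validated
  deconfounding: no information flows from the test fold), scaled with
  train-only statistics, and filtered to the largest connected component of
  edges passing an edge-wise GLM threshold;
* an inner CV picks the classifier (logistic regression, linear SVM, LDA)
  and its hyperparameters by randomized search under a fixed evaluation
  budget;
* the whole CV structure is repeated with re-randomized folds, and
  significance is assessed by rerunning the pipeline on permuted labels.

Accuracy is the performance metric; sensitivity/specificity are pooled over
held-out predictions; per-edge weights are the fraction of outer folds in
which an edge was selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .core import DesignError
from .netstats import DesignMatrix, EdgeIndex, edgewise_glm, suprathreshold_components

__all__ = [
    "PredictConfig",
    "PredictResult",
    "cv_deconfound",
    "select_component_features",
    "run_nbs_predict",
]


@dataclass
class PredictConfig:
    outer_folds: int = 5
    inner_folds: int = 5
    repeats: int = 10
    p_primary: float = 0.01
    classifiers: tuple[str, ...] = ("logistic", "svm", "lda")
    budget: int = 100                  # hyperparameter evaluations per fold
    n_perm: int = 500
    perm_repeats: int = 1              # reduced budget for permutation reruns
    perm_budget: int | None = 10
    select_all_components: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not self.classifiers:
            raise ValueError("need at least one classifier")


@dataclass
class PredictResult:
    accuracy: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    p_perm: float | None
    weights: np.ndarray                 # per-edge selection frequency in [0, 1]
    repeat_accuracies: np.ndarray
    winning_classifiers: list[str] = field(default_factory=list)
    null_accuracies: np.ndarray | None = None


def cv_deconfound(
    train_edges: np.ndarray,
    train_confounds: np.ndarray,
    test_edges: np.ndarray,
    test_confounds: np.ndarray,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Residualize edges against confounds without test-fold leakage.

    A linear confound model (with intercept) is fitted per edge on the
    training fold only; train and test edges are both residualized with the
    training coefficients, then optionally scaled with train-only mean/SD.
    """
    Ctr = np.column_stack([np.ones(len(train_confounds)), np.atleast_2d(train_confounds)])
    Cte = np.column_stack([np.ones(len(test_confounds)), np.atleast_2d(test_confounds)])
    if np.linalg.matrix_rank(Ctr) < Ctr.shape[1]:
        raise DesignError("confound matrix is rank deficient on the training fold")
    beta = np.linalg.lstsq(Ctr, train_edges, rcond=None)[0]
    rtr = train_edges - Ctr @ beta
    rte = test_edges - Cte @ beta
    if scale:
        mu = rtr.mean(axis=0)
        sd = rtr.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        rtr = (rtr - mu) / sd
        rte = (rte - mu) / sd
    return rtr, rte


def select_component_features(
    train_edges: np.ndarray,
    labels: np.ndarray,
    p_primary: float,
    index: EdgeIndex,
    all_components: bool = False,
) -> np.ndarray:
    """Edge indices of the largest connected suprathreshold component.

    Edge-wise GLM of each edge on the label (with intercept), threshold at
    ``p_primary``, connected components among surviving edges; returns the
    component with the most edges (ties broken by statistic sum), or the
    union of all components when ``all_components``. Empty when nothing
    survives — the caller falls back to a chance-level constant classifier.
    """
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels must contain both classes")
    X = np.column_stack([np.ones(len(labels)), labels])
    design = DesignMatrix(X, np.array([0.0, 1.0]), ["intercept", "label"])
    t, p = edgewise_glm(train_edges, design)
    comps = suprathreshold_components(t, p, p_primary, index, sign="both")
    if not comps:
        return np.array([], dtype=int)
    if all_components:
        return np.sort(np.concatenate([c.edge_indices for c in comps]))
    best = max(comps, key=lambda c: (c.n_edges, c.stat_sum))
    return np.sort(best.edge_indices)


def _candidates(classifiers, budget: int, rng: np.random.Generator):
    """Seeded random search over classifier + hyperparameter space."""
    out = []
    for _ in range(budget):
        kind = classifiers[rng.integers(len(classifiers))]
        if kind == "logistic":
            out.append((kind, {"C": float(10 ** rng.uniform(-3, 3))}))
        elif kind == "svm":
            out.append((kind, {"C": float(10 ** rng.uniform(-3, 3))}))
        elif kind == "lda":
            out.append((kind, {"shrinkage": float(rng.uniform(0, 1))}))
        else:
            raise ValueError(f"unknown classifier: {kind!r}")
    return out


def _build(kind: str, params: dict):
    if kind == "logistic":
        return LogisticRegression(C=params["C"], max_iter=500)
    if kind == "svm":
        return LinearSVC(C=params["C"], max_iter=5000)
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=params["shrinkage"])


class _Majority:
    """Chance-level fallback when no features survive selection."""

    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.label_ = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.label_)


def _run_cv(edges, labels, confounds, cfg: PredictConfig, repeats: int,
            budget: int, rng: np.random.Generator, index: EdgeIndex):
    """One full repeated nested-CV pass; returns per-repeat accuracies,
    pooled predictions, selection counts and winning classifiers."""
    n, n_edges = edges.shape
    sel_counts = np.zeros(n_edges)
    rep_accs = []
    pooled_true, pooled_pred = [], []
    winners = []
    n_folds_total = 0
    for rep in range(repeats):
        skf = StratifiedKFold(cfg.outer_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31 - 1)))
        fold_accs = []
        for tr, te in skf.split(edges, labels):
            if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 1:
                raise ValueError("a class is absent from a fold; reduce folds")
            Etr, Ete = cv_deconfound(edges[tr], confounds[tr], edges[te], confounds[te])
            feat = select_component_features(Etr, labels[tr], cfg.p_primary, index,
                                             cfg.select_all_components)
            n_folds_total += 1
            if len(feat) == 0:
                Xtr, Xte = Etr[:, :1] * 0.0, Ete[:, :1] * 0.0
                model, kind = _Majority().fit(Xtr, labels[tr]), "majority"
            else:
                sel_counts[feat] += 1
                Xtr, Xte = Etr[:, feat], Ete[:, feat]
                cands = _candidates(cfg.classifiers, budget, rng)
                inner = StratifiedKFold(min(cfg.inner_folds, np.bincount(labels[tr].astype(int)).min()),
                                        shuffle=True, random_state=int(rng.integers(2 ** 31 - 1)))
                best_score, best = -np.inf, None
                splits = list(inner.split(Xtr, labels[tr]))
                for kind_c, params in cands:
                    accs = []
                    for itr, ite in splits:
                        m = _build(kind_c, params)
                        m.fit(Xtr[itr], labels[tr][itr])
                        accs.append(np.mean(m.predict(Xtr[ite]) == labels[tr][ite]))
                    score = float(np.mean(accs))
                    if score > best_score:
                        best_score, best = score, (kind_c, params)
                kind, params = best
                model = _build(kind, params).fit(Xtr, labels[tr])
            pred = model.predict(Xte)
            fold_accs.append(float(np.mean(pred == labels[te])))
            pooled_true.append(labels[te])
            pooled_pred.append(pred)
            winners.append(kind)
        rep_accs.append(float(np.mean(fold_accs)))
    return (np.asarray(rep_accs), np.concatenate(pooled_true),
            np.concatenate(pooled_pred), sel_counts / max(n_folds_total, 1), winners)


def run_nbs_predict(
    edges: np.ndarray,
    labels: np.ndarray,
    confounds: np.ndarray,
    cfg: PredictConfig,
    index: EdgeIndex | None = None,
    compute_permutation_p: bool = True,
) -> PredictResult:
    """Repeated stratified nested CV with component feature selection.

    The 95% CI is the 2.5/97.5 percentile of repeat-level mean accuracies.
    The permutation p-value reruns the full pipeline on label permutations
    at a reduced budget (``perm_repeats``/``perm_budget``) and applies the
    add-one rule.
    """
    edges = np.asarray(edges, dtype=float)
    labels = np.asarray(labels).astype(int)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != len(labels):
        confounds = confounds.T
    if index is None:
        # treat edges as a generic feature matrix on an implicit complete graph
        n_nodes = int(np.ceil((1 + np.sqrt(1 + 8 * edges.shape[1])) / 2))
        r, c = np.triu_indices(n_nodes, k=1)
        index = EdgeIndex(r[: edges.shape[1]], c[: edges.shape[1]], n_nodes)
    counts = np.bincount(labels)
    if (counts < cfg.outer_folds).any():
        raise ValueError("each class needs at least outer_folds members")

    rng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), 0)))
    rep_accs, y_true, y_pred, weights, winners = _run_cv(
        edges, labels, confounds, cfg, cfg.repeats, cfg.budget, rng, index)
    acc = float(np.mean(rep_accs))
    lo, hi = np.percentile(rep_accs, [2.5, 97.5]) if len(rep_accs) > 1 else (acc, acc)
    pos = y_true == 1
    sens = float(np.mean(y_pred[pos] == 1)) if pos.any() else np.nan
    spec = float(np.mean(y_pred[~pos] == 0)) if (~pos).any() else np.nan

    p_perm, null_accs = None, None
    if compute_permutation_p and cfg.n_perm > 0:
        budget = cfg.perm_budget or cfg.budget
        null_accs = np.empty(cfg.n_perm)
        for b in range(cfg.n_perm):
            prng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), 1, b)))
            perm_labels = prng.permutation(labels)
            accs_b, *_ = _run_cv(edges, perm_labels, confounds, cfg,
                                 cfg.perm_repeats, budget, prng, index)
            null_accs[b] = float(np.mean(accs_b))
        p_perm = float((1 + np.sum(null_accs >= acc - 1e-12)) / (cfg.n_perm + 1))

    return PredictResult(acc, float(lo), float(hi), sens, spec, p_perm,
                         weights, rep_accs, winners, null_accs)
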