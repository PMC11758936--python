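"""Network-based statistics: edge-wise models, components, permutation FWE.

The network-based statistic (NBS) controls the family-wise error of
edge-wise hypothesis tests by clustering in topological space: (1) the
hypothesis is tested at every edge with a general linear model, (2) edges
are thresholded at a primary p-value, (3) connected graph components are
formed among suprathreshold edges, and (4) each component's summed test
statistic is referred to a permutation null of maximum component sums.

Cross-sectional models use OLS with Freedman-Lane residual permutation to
respect nuisance covariates. Longitudinal models are linear mixed-effects
models with random intercept and slope of follow-up time per subject,
fitted by a profiled-REML engine written for the edge-wise setting (the
criterion is evaluated through per-subject block solves, batched across
subjects, so thousands of permutation refits stay affordable); the
permutation unit is a subject-level sign flip of within-subject
time-centered trajectories. Edge-wise mixed-model p-values use the normal
approximation to the Wald statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.optimize import minimize
from scipy.sparse.csgraph import connected_components as _cc

from .core import ConnMatrix, DesignError, upper_triangle_mask

__all__ = [
    "DesignMatrix",
    "design_from_table",
    "EdgeIndex",
    "vectorize_edges",
    "devectorize_edges",
    "edgewise_glm",
    "Component",
    "NBSResult",
    "suprathreshold_components",
    "nbs_glm",
    "EdgeLMMResult",
    "edgewise_lmm",
    "nbs_lmm",
    "LMMFit",
    "fit_scalar_lmm",
]


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Observation-by-covariate design with a contrast selecting the test.

    Columns are conventionally ``[intercept, variable of interest,
    nuisance...]``; the contrast is any vector of matching length, zero on
    nuisance columns.
    """

    X: np.ndarray
    contrast: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.contrast.shape != (self.X.shape[1],):
            raise DesignError("contrast length must equal the number of design columns")
        if not self.names:
            self.names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def check_rank(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise DesignError("design matrix is rank deficient")

    def drop_zero_columns(self) -> "DesignMatrix":
        """Remove all-zero columns (no-op covariates) from the design."""
        keep = np.flatnonzero(np.any(self.X != 0, axis=0))
        return DesignMatrix(self.X[:, keep], self.contrast[keep], [self.names[j] for j in keep])


def design_from_table(
    table: pd.DataFrame,
    interest: str,
    nuisance: tuple[str, ...] = (),
) -> DesignMatrix:
    """Build ``[intercept, interest, nuisance...]`` from a cohort table."""
    cols = [interest, *nuisance]
    X = np.column_stack([np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in cols])
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X, contrast, ["intercept", *cols])


# ---------------------------------------------------------------------------
# Edge vectorization
# ---------------------------------------------------------------------------

@dataclass
class EdgeIndex:
    """Upper-triangle positions of the analyzed edges of an n-node graph."""

    rows: np.ndarray
    cols: np.ndarray
    n_nodes: int
    node_ids: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return len(self.rows)

    def pairs(self) -> np.ndarray:
        return np.column_stack([self.rows, self.cols])


def vectorize_edges(m, edge_mask: np.ndarray | None = None) -> tuple[np.ndarray, EdgeIndex]:
    """Flatten the analyzed edges of a symmetric matrix into a vector.

    For disconnection matrices the default edge set is the structural mask;
    for similarity matrices it is all off-diagonal pairs. The round trip
    through :func:`devectorize_edges` restores masked entries and zeros
    elsewhere.
    """
    node_ids = None
    if isinstance(m, ConnMatrix):
        vals = m.values
        node_ids = m.node_ids
        if edge_mask is None:
            edge_mask = m.structural_mask if m.kind == "disconnection" and m.structural_mask is not None else None
    else:
        vals = np.asarray(m, dtype=float)
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
    n = vals.shape[0]
    triu = upper_triangle_mask(n)
    if edge_mask is None:
        edge_mask = triu
    else:
        edge_mask = np.asarray(edge_mask, dtype=bool) & triu
    rows, cols = np.nonzero(edge_mask)
    return vals[rows, cols], EdgeIndex(rows, cols, n, node_ids)


def devectorize_edges(vec: np.ndarray, index: EdgeIndex) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; unmasked entries become 0."""
    out = np.zeros((index.n_nodes, index.n_nodes))
    out[index.rows, index.cols] = vec
    out[index.cols, index.rows] = vec
    return out


# ---------------------------------------------------------------------------
# Edge-wise GLM
# ---------------------------------------------------------------------------

def edgewise_glm(Y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """OLS contrast t and two-sided p at every edge.

    ``Y`` is observations x edges. The t statistic has ``n - p`` degrees of
    freedom where ``p`` is the (full) column rank of the design.
    """
    design.check_rank()
    X, c = design.X, design.contrast
    n, p = X.shape
    if n < p + 2:
        raise DesignError(f"need at least {p + 2} observations for {p} design columns")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ne,ne->e", resid, resid) / df
    var_c = float(c @ xtx_inv @ c)
    denom = np.sqrt(np.maximum(sigma2 * var_c, 1e-300))
    t = (c @ beta) / denom
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return t, pvals


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

@dataclass
class Component:
    """A connected suprathreshold subnetwork."""

    edge_indices: np.ndarray          # positions into the edge vector
    node_pairs: np.ndarray            # (n_edges, 2) node positions
    stat_sum: float                   # sum of |t| over member edges
    sign: int                         # +1 / -1 for sign-split, 0 for mixed
    p_fwe: float | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edge_indices)


@dataclass
class NBSResult:
    components: list[Component]
    p_primary: float
    n_perm: int
    null_max: np.ndarray
    edge_index: EdgeIndex

    @property
    def significant(self) -> list[Component]:
        return [c for c in self.components if c.p_fwe is not None and c.p_fwe < 0.05]


def _group_components(sel: np.ndarray, tvals: np.ndarray, index: EdgeIndex, sign: int) -> list[Component]:
    if len(sel) == 0:
        return []
    r, c = index.rows[sel], index.cols[sel]
    nodes, inv = np.unique(np.concatenate([r, c]), return_inverse=True)
    ri, ci = inv[: len(sel)], inv[len(sel):]
    g = sparse.coo_matrix((np.ones(len(sel)), (ri, ci)), shape=(len(nodes), len(nodes)))
    ncomp, labels = _cc(g, directed=False)
    comps = []
    for k in range(ncomp):
        member = labels[ri] == k
        idx = sel[member]
        if len(idx) == 0:
            continue
        comps.append(
            Component(
                edge_indices=idx,
                node_pairs=np.column_stack([index.rows[idx], index.cols[idx]]),
                stat_sum=float(np.abs(tvals[idx]).sum()),
                sign=sign,
            )
        )
    return comps


def suprathreshold_components(
    edge_stats: np.ndarray,
    p_values: np.ndarray,
    p_primary: float,
    index: EdgeIndex,
    sign: str = "split",
) -> list[Component]:
    """Connected components among edges with p strictly below threshold.

    ``sign="split"`` forms components separately among positive- and
    negative-statistic edges so that subnetworks of increase and decrease
    are reported separately; ``"both"`` pools them; ``"positive"`` /
    ``"negative"`` restrict to one direction. The component statistic is
    the sum of absolute edge statistics.
    """
    if not 0 < p_primary < 1:
        raise ValueError("p_primary must lie in (0, 1)")
    supra = np.flatnonzero(p_values < p_primary)
    if sign == "both":
        comps = _group_components(supra, edge_stats, index, 0)
    elif sign == "split":
        comps = _group_components(supra[edge_stats[supra] > 0], edge_stats, index, 1)
        comps += _group_components(supra[edge_stats[supra] < 0], edge_stats, index, -1)
    elif sign == "positive":
        comps = _group_components(supra[edge_stats[supra] > 0], edge_stats, index, 1)
    elif sign == "negative":
        comps = _group_components(supra[edge_stats[supra] < 0], edge_stats, index, -1)
    else:
        raise ValueError(f"unknown sign mode: {sign!r}")
    comps.sort(key=lambda c: -c.stat_sum)
    return comps


def _max_component_sum(tvals: np.ndarray, pvals: np.ndarray, p_primary: float, index: EdgeIndex, sign: str) -> float:
    comps = suprathreshold_components(tvals, pvals, p_primary, index, sign)
    return comps[0].stat_sum if comps else 0.0


def _attach_fwe(comps: list[Component], null_max: np.ndarray) -> None:
    n_perm = len(null_max)
    for comp in comps:
        exceed = int((null_max >= comp.stat_sum - 1e-12).sum())
        comp.p_fwe = (1 + exceed) / (n_perm + 1)


def nbs_glm(
    Y: np.ndarray,
    design: DesignMatrix,
    index: EdgeIndex,
    p_primary: float = 0.01,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    sign: str = "split",
) -> NBSResult:
    """Cross-sectional NBS with Freedman-Lane residual permutation.

    The permutation null permutes the residuals of the nuisance-only fit
    (columns with zero contrast weight), adds back the nuisance fit, and
    refits the full model; the maximum component statistic per permutation
    forms the FWE null. ``p_fwe = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design = design.drop_zero_columns()
    Y = np.asarray(Y, dtype=float)
    t_obs, p_obs = edgewise_glm(Y, design)
    comps = suprathreshold_components(t_obs, p_obs, p_primary, index, sign)

    nuis = np.flatnonzero(design.contrast == 0)
    if len(nuis):
        Z = design.X[:, nuis]
        fitted = Z @ np.linalg.lstsq(Z, Y, rcond=None)[0]
    else:
        fitted = np.zeros_like(Y)
    resid = Y - fitted

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    n = Y.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(n)
        t_b, p_b = edgewise_glm(fitted + resid[perm], design)
        null_max[b] = _max_component_sum(t_b, p_b, p_primary, index, sign)
    _attach_fwe(comps, null_max)
    return NBSResult(comps, p_primary, n_perm, null_max, index)


# ---------------------------------------------------------------------------
# Linear mixed models (random intercept + slope per subject)
# ---------------------------------------------------------------------------

class _LongData:
    """Pre-grouped longitudinal design shared by all edges.

    Rows are reordered so each subject's visits are contiguous; subjects are
    grouped by visit count so the per-subject block algebra can be batched
    with stacked linear solves.
    """

    def __init__(self, subjects, time, nuisance: np.ndarray | None):
        subjects = np.asarray(subjects)
        time = np.asarray(time, dtype=float)
        codes, uniq = pd.factorize(subjects, sort=True)
        order = np.argsort(codes, kind="stable")
        self.order = order
        self.codes = codes[order]
        self.time = time[order]
        cols = [np.ones(len(time)), self.time]
        names = ["intercept", "time"]
        if nuisance is not None and np.size(nuisance):
            nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
            if nuis.shape[0] != len(time):
                nuis = nuis.T
            cols.extend(nuis[order].T)
            names.extend(f"nuis{j}" for j in range(nuis.shape[1]))
        self.X = np.column_stack(cols)
        self.names = names
        self.Z = np.column_stack([np.ones(len(time)), self.time])
        counts = np.bincount(self.codes)
        if (counts >= 2).sum() == 0:
            raise ValueError("all subjects have a single visit; no longitudinal information")
        starts = np.concatenate([[0], np.cumsum(counts)])
        self.groups: dict[int, np.ndarray] = {}
        by_n: dict[int, list[np.ndarray]] = {}
        for s in range(len(uniq)):
            rows = np.arange(starts[s], starts[s + 1])
            by_n.setdefault(len(rows), []).append(rows)
        for n_i, rows in by_n.items():
            self.groups[n_i] = np.vstack(rows)
        self.n_obs, self.p = self.X.shape
        # V-parameter-independent blocks for the Woodbury form of the REML
        # criterion: V_i^{-1} = I - Z_i (I + D Z_i'Z_i)^{-1} D Z_i'
        self.XtX = self.X.T @ self.X
        self.ZtZ = {n_i: np.einsum("sna,snb->sab", self.Z[idx], self.Z[idx])
                    for n_i, idx in self.groups.items()}
        self.XtZ = {n_i: np.einsum("snp,sna->spa", self.X[idx], self.Z[idx])
                    for n_i, idx in self.groups.items()}
        if np.linalg.matrix_rank(self.X) < self.p:
            raise DesignError("longitudinal design matrix is rank deficient")
        self.subject_rows = [np.arange(starts[s], starts[s + 1]) for s in range(len(uniq))]


def _re_cov(theta: np.ndarray, slope: bool) -> np.ndarray:
    th = np.clip(theta, -10.0, 10.0)
    if slope:
        L = np.array([[np.exp(th[0]), 0.0], [th[2], np.exp(th[1])]])
        return L @ L.T
    return np.array([[np.exp(2.0 * th[0])]])


class _PreparedY:
    """Y-dependent, V-parameter-independent blocks for one outcome matrix."""

    def __init__(self, data: _LongData, Yo: np.ndarray):
        self.XtY = data.X.T @ Yo
        self.yty = np.einsum("ne,ne->e", Yo, Yo)
        self.ZtY = {n_i: np.einsum("sna,sne->sae", data.Z[idx], Yo[idx])
                    for n_i, idx in data.groups.items()}
        self.E = Yo.shape[1]


def _batched_inv_det(A: np.ndarray):
    """Inverse and determinant of stacked 1x1 or 2x2 matrices."""
    if A.shape[-1] == 1:
        det = A[:, 0, 0]
        return (1.0 / det)[:, None, None], det
    a, b = A[:, 0, 0], A[:, 0, 1]
    c, d = A[:, 1, 0], A[:, 1, 1]
    det = a * d - b * c
    inv = np.empty_like(A)
    inv[:, 0, 0], inv[:, 0, 1] = d, -b
    inv[:, 1, 0], inv[:, 1, 1] = -c, a
    return inv / det[:, None, None], det


def _reml_eval(theta: np.ndarray, data: _LongData, prep: _PreparedY, slope: bool):
    """Profiled REML criterion (-2 log-lik up to a constant) for all edges.

    Uses the Woodbury identity on the random-effect block, so each
    evaluation costs a handful of small batched matrix products; per-edge
    pieces (quadratic form, criterion) come out vectorized.
    """
    D = _re_cov(theta, slope)
    q = D.shape[0]
    p, E = data.p, prep.E
    logdetV = 0.0
    M = data.XtX.copy()
    U = prep.XtY.copy()
    yVy = prep.yty.copy()
    eye_q = np.eye(q)
    for n_i in data.groups:
        S = data.ZtZ[n_i][:, :q, :q]
        XtZ = data.XtZ[n_i][:, :, :q]
        ZtY = prep.ZtY[n_i][:, :q, :]
        A = eye_q[None] + D @ S
        Ainv, detA = _batched_inv_det(A)
        W = Ainv @ D
        logdetV += float(np.log(detA).sum())
        XtZW = XtZ @ W
        WZtY = W @ ZtY
        M -= (XtZW @ XtZ.transpose(0, 2, 1)).sum(axis=0)
        U -= (XtZ @ WZtY).sum(axis=0)
        yVy -= np.einsum("sae,sae->e", ZtY, WZtY)
    Minv = np.linalg.inv(M)
    MU = Minv @ U
    quad = np.maximum(yVy - np.einsum("pe,pe->e", U, MU), 1e-300)
    crit = logdetV + np.linalg.slogdet(M)[1] + (data.n_obs - p) * np.log(quad)
    return crit, MU, Minv, quad


@dataclass
class EdgeLMMResult:
    """Per-edge mixed-model Wald statistics for the time effect."""

    B: np.ndarray
    SE: np.ndarray
    t: np.ndarray
    p: np.ndarray
    slope_dropped: np.ndarray
    theta: np.ndarray


def _fit_edge(data: _LongData, ye: np.ndarray, x0: np.ndarray, maxiter: int = 200):
    """REML fit of one edge; falls back to random intercept only when the
    slope variance collapses to the boundary."""
    prep = _PreparedY(data, ye)

    def crit(th):
        return float(_reml_eval(th, data, prep, slope=True)[0][0])

    res = minimize(crit, x0, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": maxiter})
    if maxiter >= 100:
        # restart from the first optimum: a fresh simplex escapes premature
        # collapse of Nelder-Mead
        res2 = minimize(crit, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": maxiter // 2})
        if res2.fun < res.fun:
            res = res2
    theta = res.x
    dropped = bool(np.exp(np.clip(theta[1], -10, 10)) < 1e-4)
    if dropped:
        res = minimize(
            lambda th: float(_reml_eval(th, data, prep, slope=False)[0][0]),
            np.array([x0[0]]),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 100},
        )
        theta = np.array([res.x[0], -np.inf, 0.0])
        crit, b, Minv, quad = _reml_eval(res.x, data, prep, slope=False)
    else:
        crit, b, Minv, quad = _reml_eval(theta, data, prep, slope=True)
    sigma2 = quad / (data.n_obs - data.p)
    se = np.sqrt(np.maximum(sigma2[None, :] * np.diag(Minv)[:, None], 1e-300))
    return b[:, 0], se[:, 0], dropped, theta


def edgewise_lmm(
    Y: np.ndarray,
    subjects,
    time,
    nuisance: np.ndarray | None = None,
) -> EdgeLMMResult:
    """Edge-wise LMM: outcome ~ time + nuisance, random intercept + slope.

    Fitted by profiled REML per edge; Wald ``t = B_time / SE`` with normal
    approximation for the two-sided p-value. Edges whose slope variance is
    inestimable (boundary collapse) are refitted with random intercept only
    and flagged in ``slope_dropped``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    data = _LongData(subjects, time, nuisance)
    Yo = Y[data.order]
    E = Y.shape[1]
    B = np.empty(E)
    SE = np.empty(E)
    dropped = np.zeros(E, dtype=bool)
    thetas = np.empty((E, 3))
    x0 = np.array([np.log(0.5), np.log(0.5), 0.0])
    for e in range(E):
        b, se, dr, th = _fit_edge(data, Yo[:, e:e + 1], x0)
        B[e], SE[e] = b[1], se[1]
        dropped[e] = dr
        thetas[e] = th
    t = B / SE
    p = 2.0 * stats.norm.sf(np.abs(t))
    return EdgeLMMResult(B, SE, t, p, dropped, thetas)


def _sign_flip(Yo: np.ndarray, data: _LongData, flips: np.ndarray) -> np.ndarray:
    """Subject-level sign flip of within-subject time-centered trajectories."""
    out = Yo.copy()
    for s, rows in enumerate(data.subject_rows):
        if flips[s] < 0 and len(rows) > 1:
            mean = Yo[rows].mean(axis=0, keepdims=True)
            out[rows] = mean - (Yo[rows] - mean)
    return out


def nbs_lmm(
    Y: np.ndarray,
    subjects,
    time,
    index: EdgeIndex,
    nuisance: np.ndarray | None = None,
    p_primary: float = 0.01,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    sign: str = "split",
) -> NBSResult:
    """Longitudinal NBS on the time effect of edge-wise mixed models.

    Exchangeability under the null of no time effect is preserved by
    flipping the sign of each subject's time-centered trajectory (subject
    means and between-subject covariates are untouched).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    data = _LongData(subjects, time, nuisance)
    Yo = Y[data.order]

    def _stats(Yord: np.ndarray, starts: np.ndarray | None = None, maxiter: int = 200):
        E = Yord.shape[1]
        t = np.empty(E)
        thetas = np.empty((E, 3))
        default = np.array([np.log(0.5), np.log(0.5), 0.0])
        for e in range(E):
            x0 = default if starts is None else starts[e]
            b, se, dropped, th = _fit_edge(data, Yord[:, e:e + 1], x0, maxiter=maxiter)
            t[e] = b[1] / se[1]
            thetas[e] = default if dropped else th
        return t, 2.0 * stats.norm.sf(np.abs(t)), thetas

    t_obs, p_obs, theta_obs = _stats(Yo)
    comps = suprathreshold_components(t_obs, p_obs, p_primary, index, sign)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_subj = len(data.subject_rows)
    null_max = np.empty(n_perm)
    for bperm in range(n_perm):
        flips = rng.choice([-1, 1], size=n_subj)
        # warm-start from the observed variance parameters: sign flips leave
        # the covariance structure unchanged under the null
        t_b, p_b, _ = _stats(_sign_flip(Yo, data, flips), starts=theta_obs, maxiter=60)
        null_max[bperm] = _max_component_sum(t_b, p_b, p_primary, index, sign)
    _attach_fwe(comps, null_max)
    return NBSResult(comps, p_primary, n_perm, null_max, index)


@dataclass
class LMMFit:
    """Fixed effects and variance components of a scalar mixed model."""

    B: dict[str, float]
    SE: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    var_intercept: float
    var_slope: float
    cov_intercept_slope: float
    var_residual: float
    slope_dropped: bool = False


def fit_scalar_lmm(
    outcome,
    time,
    subjects,
    nuisance: np.ndarray | None = None,
    nuisance_names: tuple[str, ...] = (),
) -> LMMFit:
    """Mixed model for a single outcome (EDSS, log1p-TLV, BPF z, ...).

    Uses statsmodels' MixedLM (REML, random intercept + slope of time per
    subject); on degenerate data where that fit fails it falls back to the
    package's own REML engine.
    """
    import warnings

    y = np.asarray(outcome, dtype=float)
    data = _LongData(subjects, time, nuisance)
    names = ["intercept", "time", *nuisance_names]
    names += [f"nuis{j}" for j in range(len(data.names) - len(names))]

    try:
        from statsmodels.regression.mixed_linear_model import MixedLM

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = MixedLM(y[data.order], data.X, groups=data.codes, exog_re=data.Z)
            fit = md.fit(reml=True)
        if not np.isfinite(fit.params[: data.p]).all() or not np.isfinite(fit.bse[: data.p]).all():
            raise ValueError("non-finite mixed-model fit")
        B = dict(zip(names, np.asarray(fit.params)[: data.p]))
        SE = dict(zip(names, np.asarray(fit.bse)[: data.p]))
        tv = {k: B[k] / SE[k] for k in B}
        pv = {k: 2.0 * stats.norm.sf(abs(v)) for k, v in tv.items()}
        cov_re = np.asarray(fit.cov_re)
        return LMMFit(
            B, SE, tv, pv,
            var_intercept=float(cov_re[0, 0]),
            var_slope=float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0,
            cov_intercept_slope=float(cov_re[0, 1]) if cov_re.shape[0] > 1 else 0.0,
            var_residual=float(fit.scale),
        )
    except Exception:
        res = edgewise_lmm(y[:, None], subjects, time, nuisance)
        _, MU, Minv, quad = _reml_eval(
            res.theta[0] if not res.slope_dropped[0] else res.theta[0][:1],
            data, _PreparedY(data, y[data.order][:, None]),
            slope=not res.slope_dropped[0],
        )
        sigma2 = float(quad[0] / (data.n_obs - data.p))
        D = _re_cov(res.theta[0] if not res.slope_dropped[0] else res.theta[0][:1],
                    not res.slope_dropped[0]) * sigma2
        se_all = np.sqrt(np.maximum(sigma2 * np.diag(Minv), 1e-300))
        B = dict(zip(names, MU[:, 0]))
        SE = dict(zip(names, se_all))
        tv = {k: B[k] / SE[k] for k in B}
        pv = {k: 2.0 * stats.norm.sf(abs(v)) for k, v in tv.items()}
        return LMMFit(
            B, SE, tv, pv,
            var_intercept=float(D[0, 0]),
            var_slope=float(D[1, 1]) if D.shape[0] > 1 else 0.0,
            cov_intercept_slope=float(D[0, 1]) if D.shape[0] > 1 else 0.0,
            var_residual=sigma2,
            slope_dropped=bool(res.slope_dropped[0]),
        )
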