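"""Clinical derivations, subnetwork summaries, group statistics, coupling.

Covers the scalar ends of the pipeline: the confirmed-disability-
progression (CDP) rule on the EDSS, brain-parenchymal-fraction z-scores
against a healthy-control normative model, absolute-z subnetwork summaries
referenced to controls, annualized changes and (partial) Spearman
correlations, demographic-table group tests, and the multi-scale coupling
between structural disconnection and morphometric similarity networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConnMatrix, DomainError

__all__ = [
    "cdp_label",
    "invert_sdmt",
    "bpf_z",
    "edge_reference_stats",
    "component_zscore_summary",
    "annualized_change",
    "spearman",
    "partial_spearman",
    "coupling",
    "coupling_by_duration",
    "welch_t_test",
    "welch_t_from_summary",
    "chi_square_2x2",
    "group_compare",
]


# ---------------------------------------------------------------------------
# Clinical derivations
# ---------------------------------------------------------------------------

def _check_edss(x: float, name: str) -> None:
    if not (0.0 <= x <= 10.0) or abs(x * 2 - round(x * 2)) > 1e-9:
        raise DomainError(f"{name}={x} is not on the EDSS 0-10 half-point grid")


def cdp_label(edss_baseline: float, edss_followup: float) -> bool:
    """Confirmed disability progression from an EDSS pair.

    Progression is an EDSS increase >= 1.0 when the baseline EDSS is <= 5.5,
    or >= 0.5 when the baseline EDSS is > 5.5 (inclusive thresholds).
    """
    _check_edss(edss_baseline, "edss_baseline")
    _check_edss(edss_followup, "edss_followup")
    delta = edss_followup - edss_baseline
    required = 1.0 if edss_baseline <= 5.5 else 0.5
    return bool(delta >= required - 1e-9)


def invert_sdmt(z):
    """Flip the sign of an SDMT z-score so that higher = worse cognition."""
    return -np.asarray(z) if np.ndim(z) else -z


def bpf_z(brain_vol, icv, age, sex, hc_reference: pd.DataFrame):
    """Brain parenchymal fraction as z-score vs an age/sex HC model.

    BPF = brain volume / intracranial volume. A linear age + sex model is
    fitted on the healthy-control reference; the z-score is the residual
    from the HC prediction divided by the HC residual SD (computed with
    ``n - 1`` so the HC sample z-distribution has exactly mean 0, SD 1).

    ``hc_reference`` needs columns brain_volume, icv, age, sex.
    """
    hc = hc_reference
    if len(hc) < 10:
        raise ValueError("HC reference needs at least 10 subjects")
    if (np.asarray(hc["icv"]) <= 0).any():
        raise DomainError("intracranial volume must be positive")
    bpf_hc = hc["brain_volume"].to_numpy(dtype=float) / hc["icv"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(hc)), hc["age"].to_numpy(dtype=float),
                         hc["sex"].to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate HC reference (age/sex collinear)")
    beta = np.linalg.lstsq(X, bpf_hc, rcond=None)[0]
    resid = bpf_hc - X @ beta
    sd = float(np.sqrt((resid ** 2).sum() / (len(hc) - 1)))
    if sd <= 0:
        raise ValueError("degenerate HC reference (zero residual variance)")
    icv_arr = np.asarray(icv, dtype=float)
    if (icv_arr <= 0).any() if icv_arr.ndim else icv_arr <= 0:
        raise DomainError("intracranial volume must be positive")
    bpf = np.asarray(brain_vol, dtype=float) / icv_arr
    pred = beta[0] + beta[1] * np.asarray(age, dtype=float) + beta[2] * np.asarray(sex, dtype=float)
    z = (bpf - pred) / sd
    return float(z) if np.ndim(z) == 0 else z


# ---------------------------------------------------------------------------
# Subnetwork z-score summaries
# ---------------------------------------------------------------------------

def edge_reference_stats(matrices: list[ConnMatrix | np.ndarray]):
    """Per-edge mean and SD over a (healthy) reference group."""
    arrs = np.stack([m.values if isinstance(m, ConnMatrix) else np.asarray(m, float)
                     for m in matrices])
    return arrs.mean(axis=0), arrs.std(axis=0, ddof=1)


def component_zscore_summary(
    subject_matrix,
    ref_mean: np.ndarray,
    ref_sd: np.ndarray,
    component_edges,
) -> float:
    """Mean absolute z over a component's edges, referenced to controls.

    Absolute values keep opposite-sign deviations from canceling: the
    summary measures overall deviation from the healthy norm. Edges with a
    zero reference SD are excluded with a warning.
    """
    vals = subject_matrix.values if isinstance(subject_matrix, ConnMatrix) \
        else np.asarray(subject_matrix, dtype=float)
    zs = []
    dropped = 0
    for (i, j) in component_edges:
        sd = ref_sd[i, j]
        if sd <= 0:
            dropped += 1
            continue
        zs.append(abs((vals[i, j] - ref_mean[i, j]) / sd))
    if dropped:
        warnings.warn(f"excluded {dropped} edge(s) with zero reference SD")
    if not zs:
        raise ValueError("no usable edges in component")
    return float(np.mean(zs))


def annualized_change(x_t1: float, x_t2: float, years: float) -> float:
    """Per-year change (x2 - x1) / years."""
    if years <= 0:
        raise DomainError("years must be positive")
    return (x_t2 - x_t1) / years


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """Spearman correlation of x and y controlling linearly for z on ranks.

    All three variables are rank-transformed (average ranks); the ranked
    control variable(s) are regressed out of ranked x and y and the Pearson
    correlation of the rank residuals is returned, with the p-value from a
    t-test on ``n - 2 - k`` degrees of freedom (k control variables).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    if Z.shape[0] != len(x):
        Z = Z.T
    if len(x) < 4 + Z.shape[1]:
        raise ValueError("too few observations for partial correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = np.column_stack([np.ones(len(x))] + [stats.rankdata(Z[:, j]) for j in range(Z.shape[1])])
    ex = rx - rz @ np.linalg.lstsq(rz, rx, rcond=None)[0]
    ey = ry - rz @ np.linalg.lstsq(rz, ry, rcond=None)[0]
    denom = np.sqrt((ex ** 2).sum() * (ey ** 2).sum())
    if denom <= 0:
        raise ValueError("correlation undefined after removing controls")
    rho = float((ex * ey).sum() / denom)
    df = len(x) - 2 - Z.shape[1]
    tstat = rho * np.sqrt(df / max(1e-300, 1.0 - rho ** 2))
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return rho, p


# ---------------------------------------------------------------------------
# Multi-scale coupling
# ---------------------------------------------------------------------------

def _cortical_positions(m: ConnMatrix) -> np.ndarray:
    if m.system_labels is None:
        return np.arange(m.n_nodes)
    return np.flatnonzero(np.asarray(m.system_labels) != "SUBC")


def _align_cortical(disc: ConnMatrix, sim: ConnMatrix):
    """Cortical submatrices of both domains on the shared node set."""
    dpos = _cortical_positions(disc)
    d_ids = disc.node_ids[dpos]
    s_ids = sim.node_ids
    shared = [i for i in d_ids if i in set(s_ids)]
    if not shared:
        raise ValueError("no cortical nodes shared between the two matrices")
    dmap = {n: k for k, n in enumerate(disc.node_ids)}
    smap = {n: k for k, n in enumerate(sim.node_ids)}
    di = np.array([dmap[n] for n in shared])
    si = np.array([smap[n] for n in shared])
    D = disc.values[np.ix_(di, di)]
    S = sim.values[np.ix_(si, si)]
    mask = None
    if disc.structural_mask is not None:
        mask = disc.structural_mask[np.ix_(di, di)]
    return D, S, mask, np.asarray(shared)


def coupling(
    disc_matrices: list[ConnMatrix],
    sim_matrices: list[ConnMatrix],
    level: str = "global",
    exclude_zero_disconnection: bool = False,
):
    """Spearman coupling between disconnection and similarity networks.

    Subcortical rows are dropped from the disconnection matrices so both
    domains live on the shared cortical node set.

    * ``global``: across subjects, correlation of per-subject mean
      disconnection vs mean similarity; returns (rho, p).
    * ``edge``: matrices are averaged across subjects and the vectorized
      group means correlated; returns (rho, p).
    * ``node``: per cortical region, correlation of the paired row profiles
      of the group-mean matrices (self-pairs excluded); returns a per-node
      rho vector aligned with the shared node ids.

    ``exclude_zero_disconnection`` drops edges outside the structural mask
    plus edges whose (mean) disconnection is exactly zero.
    """
    if len(disc_matrices) != len(sim_matrices) or not disc_matrices:
        raise ValueError("need matched, nonempty lists of subject matrices")
    aligned = [_align_cortical(d, s) for d, s in zip(disc_matrices, sim_matrices)]
    n = aligned[0][0].shape[0]
    triu = np.triu_indices(n, k=1)

    if level == "global":
        md, ms = [], []
        for D, S, mask, _ in aligned:
            dv = D[triu]
            sv = S[triu]
            if exclude_zero_disconnection:
                keep = dv > 0
                if mask is not None:
                    keep &= mask[triu]
                dv, sv = dv[keep], sv[keep]
            md.append(dv.mean())
            ms.append(sv.mean())
        return spearman(md, ms)

    Dm = np.mean([a[0] for a in aligned], axis=0)
    Sm = np.mean([a[1] for a in aligned], axis=0)
    mask = aligned[0][2]

    if level == "edge":
        dv, sv = Dm[triu], Sm[triu]
        if exclude_zero_disconnection:
            keep = dv > 0
            if mask is not None:
                keep &= mask[triu]
            dv, sv = dv[keep], sv[keep]
        return spearman(dv, sv)

    if level == "node":
        rhos = np.full(n, np.nan)
        for r in range(n):
            keep = np.ones(n, dtype=bool)
            keep[r] = False
            dv, sv = Dm[r, keep], Sm[r, keep]
            if exclude_zero_disconnection:
                k2 = dv > 0
                if mask is not None:
                    k2 &= mask[r, keep]
                dv, sv = dv[k2], sv[k2]
            if len(dv) >= 4 and np.ptp(dv) > 0 and np.ptp(sv) > 0:
                rhos[r] = stats.spearmanr(dv, sv)[0]
        return rhos

    raise ValueError(f"unknown coupling level: {level!r}")


def coupling_by_duration(
    disc_matrices: list[ConnMatrix],
    sim_matrices: list[ConnMatrix],
    disease_duration,
    level: str = "global",
    **kw,
):
    """Coupling separately in shorter vs longer disease duration.

    The split is at the median; subjects at the median join the "shorter"
    group (<= median).
    """
    dd = np.asarray(disease_duration, dtype=float)
    med = float(np.median(dd))
    short = dd <= med
    out = {}
    for name, sel in (("shorter", short), ("longer", ~short)):
        d = [m for m, s in zip(disc_matrices, sel) if s]
        s = [m for m, ss in zip(sim_matrices, sel) if ss]
        out[name] = coupling(d, s, level=level, **kw) if d else None
        out[f"n_{name}"] = int(sel.sum())
    out["median"] = med
    return out


# ---------------------------------------------------------------------------
# Group comparisons (demographics-table style)
# ---------------------------------------------------------------------------

@dataclass
class GroupTest:
    statistic: float
    p: float
    df: float | None = None
    kind: str = ""


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> GroupTest:
    """Welch t-test from per-group summary statistics.

    Uses the Welch statistic with Satterthwaite degrees of freedom, so a
    printed table row (mean, SD, n per group) is enough to recompute the
    test.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return GroupTest(float(t), p, float(df), "welch")


def welch_t_test(a, b) -> GroupTest:
    """Welch t-test from raw per-group values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    return welch_t_from_summary(a.mean(), a.std(ddof=1), len(a),
                                b.mean(), b.std(ddof=1), len(b))


def chi_square_2x2(table) -> GroupTest:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return GroupTest(float(chi2), float(p), float(df), "chi2")


def group_compare(*args, kind: str | None = None) -> GroupTest:
    """Dispatch: 6 scalars -> Welch from summaries; 2 arrays -> Welch on raw
    values; one 2x2 table -> Pearson chi-square."""
    if kind == "chi2" or (len(args) == 1):
        return chi_square_2x2(args[0])
    if len(args) == 6:
        return welch_t_from_summary(*args)
    if len(args) == 2:
        return welch_t_test(*args)
    raise ValueError("unrecognized group_compare arguments")
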