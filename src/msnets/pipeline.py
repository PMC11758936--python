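"""End-to-end orchestration: simulate -> networks -> statistics -> report.

Runs the whole analysis on a synthetic cohort from a single configuration:
lesion disconnectomes and morphometric similarity matrices, cross-sectional
and longitudinal network-based statistics, scalar mixed models, subnetwork
z-summaries with annualized-change correlations, multi-scale coupling and
(optionally) connectome-based prediction of long-term progression. All
randomness flows from the configuration seed, so two runs into different
directories produce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .core import ConnMatrix
from .mind import mind_matrix
from .netstats import (
    DesignMatrix,
    design_from_table,
    edgewise_lmm,
    fit_scalar_lmm,
    nbs_glm,
    nbs_lmm,
    vectorize_edges,
)
from .predict import PredictConfig, run_nbs_predict
from .summarize import (
    annualized_change,
    bpf_z,
    component_zscore_summary,
    coupling,
    coupling_by_duration,
    edge_reference_stats,
    invert_sdmt,
    partial_spearman,
    spearman,
)
from .synthetic import SimConfig, SyntheticCohort, generate_cohort

__all__ = ["run_pipeline"]


def _nbs_summary(res) -> dict:
    comps = [{"n_edges": int(c.n_edges), "stat_sum": float(c.stat_sum),
              "sign": int(c.sign), "p_fwe": float(c.p_fwe)} for c in res.components]
    return {"n_components": len(comps), "components": comps[:5],
            "p_primary": res.p_primary, "n_perm": res.n_perm}


def _stack_edges(matrices: list[ConnMatrix], mask=None):
    vec0, index = vectorize_edges(matrices[0], mask)
    Y = np.empty((len(matrices), index.n_edges))
    Y[0] = vec0
    for r, m in enumerate(matrices[1:], start=1):
        Y[r] = m.values[index.rows, index.cols]
    return Y, index


def run_pipeline(
    cfg: SimConfig,
    out_dir,
    mind_k: int = 3,
    p_primary: float = 0.01,
    n_perm: int = 200,
    lmm_n_perm: int | None = 60,
    predict_cfg: PredictConfig | None = None,
    write_matrices: bool = True,
) -> dict:
    """Run the full analysis; returns (and writes) the run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort: SyntheticCohort = generate_cohort(cfg)
    tab = cohort.cohort.copy()

    # --- derived clinical columns -------------------------------------------
    hc_rows = tab[tab.group == "HC"]
    tab["bpf_z"] = bpf_z(tab.brain_volume.to_numpy(), tab.icv.to_numpy(),
                         tab.age.to_numpy(), tab.sex.to_numpy(), hc_rows)
    tab["log_tlv"] = np.log1p(tab.TLV.to_numpy())
    tab["sdmt_inv"] = invert_sdmt(tab.sdmt_z.to_numpy())
    base_age = tab.groupby("subject_id").age.transform("first")
    tab["age0"] = base_age
    tab["age0_sq"] = base_age ** 2

    # --- similarity matrices (all visits) -----------------------------------
    ctx = cohort.parcellation.node_table.query("system != 'SUBC'")
    ctx_systems = ctx.system.to_numpy()
    sim: dict[tuple[str, int], ConnMatrix] = {}
    for _, row in tab.iterrows():
        key = (row.subject_id, int(row.visit))
        feats = cohort.vertex_features(*key)
        sim[key] = mind_matrix(feats, k=mind_k, system_labels=ctx_systems)

    # --- write primary artifacts --------------------------------------------
    mio.write_parcellation(cohort.parcellation, out / "parcellation.nii", out / "nodes.tsv")
    mio.write_streamlines_jsonl(cohort.atlas, out / "atlas.jsonl")
    mio.write_table(tab, out / "cohort.tsv")
    mio.write_table(cohort.longterm, out / "longterm.tsv")
    if write_matrices:
        mdir = out / "matrices"
        mdir.mkdir(exist_ok=True)
        for key, m in sorted(cohort.disconnection.items()):
            mio.write_matrix(m, mdir / f"{key[0]}_v{key[1]}_disc.tsv")
        for key, m in sorted(sim.items()):
            mio.write_matrix(m, mdir / f"{key[0]}_v{key[1]}_mind.tsv")

    report: dict = {
        "n_patients": int(cfg.n_patients), "n_controls": int(cfg.n_controls),
        "seed": int(cfg.seed),
    }

    # --- cross-sectional NBS -------------------------------------------------
    base = tab[tab.visit == 0].reset_index(drop=True)
    base_ms = base[base.group == "MS"].reset_index(drop=True)

    sim_base = [sim[(s, 0)] for s in base.subject_id]
    Ys, idx_s = _stack_edges(sim_base)
    d = base.assign(is_ms=(base.group == "MS").astype(float))
    design = design_from_table(d, "is_ms", ("age0", "age0_sq", "sex"))
    nbs_group_sim = nbs_glm(Ys, design, idx_s, p_primary, n_perm, seed=cfg.seed + 11)
    report["nbs_group_similarity"] = _nbs_summary(nbs_group_sim)

    disc_base = [cohort.disconnection[(s, 0)] for s in base_ms.subject_id]
    Yd, idx_d = _stack_edges(disc_base)
    has_edss = base_ms.EDSS.notna().to_numpy()
    design = design_from_table(base_ms[has_edss], "EDSS",
                               ("age0", "age0_sq", "sex", "log_tlv"))
    nbs_edss_disc = nbs_glm(Yd[has_edss], design, idx_d, p_primary, n_perm,
                            seed=cfg.seed + 12)
    report["nbs_edss_disconnection"] = _nbs_summary(nbs_edss_disc)

    design = design_from_table(base_ms, "sdmt_inv", ("age0", "age0_sq", "sex", "log_tlv"))
    nbs_sdmt_disc = nbs_glm(Yd, design, idx_d, p_primary, n_perm, seed=cfg.seed + 13)
    report["nbs_sdmt_disconnection"] = _nbs_summary(nbs_sdmt_disc)

    # --- longitudinal NBS (mixed models) ------------------------------------
    ms = tab[tab.group == "MS"].reset_index(drop=True)
    nuis = ms[["age0", "age0_sq", "sex"]].to_numpy(dtype=float)
    Yd_long = np.stack([cohort.disconnection[(r.subject_id, int(r.visit))]
                        .values[idx_d.rows, idx_d.cols] for r in ms.itertuples()])
    lperm = lmm_n_perm if lmm_n_perm is not None else n_perm
    nbs_long_disc = nbs_lmm(Yd_long, ms.subject_id.to_numpy(), ms.time_years.to_numpy(),
                            idx_d, nuisance=nuis, p_primary=p_primary,
                            n_perm=lperm, seed=cfg.seed + 14)
    report["nbs_longitudinal_disconnection"] = _nbs_summary(nbs_long_disc)

    Ys_long = np.stack([sim[(r.subject_id, int(r.visit))]
                        .values[idx_s.rows, idx_s.cols] for r in ms.itertuples()])
    nbs_long_sim = nbs_lmm(Ys_long, ms.subject_id.to_numpy(), ms.time_years.to_numpy(),
                           idx_s, nuisance=nuis, p_primary=p_primary,
                           n_perm=lperm, seed=cfg.seed + 15)
    report["nbs_longitudinal_similarity"] = _nbs_summary(nbs_long_sim)

    # --- scalar mixed models -------------------------------------------------
    for col, name in (("EDSS", "edss"), ("log_tlv", "log_tlv"), ("bpf_z", "bpf_z")):
        sub = ms[ms[col].notna()]
        fit = fit_scalar_lmm(sub[col].to_numpy(), sub.time_years.to_numpy(),
                             sub.subject_id.to_numpy())
        report[f"lmm_{name}"] = {"B": fit.B["time"], "SE": fit.SE["time"],
                                 "p": fit.p["time"]}

    # --- subnetwork z-summaries and annualized-change correlations ----------
    def _summary_corr(nbs_res, mats_by_key, index, ref_mats, change_col):
        comp = nbs_res.components[0] if nbs_res.components else None
        if comp is None:
            return None
        edges = [tuple(pair) for pair in comp.node_pairs]
        ref_mean, ref_sd = edge_reference_stats(ref_mats)
        rows = []
        for sid, grp in ms.groupby("subject_id"):
            grp = grp.sort_values("time_years")
            if len(grp) < 2:
                continue
            t0, t1 = grp.iloc[0], grp.iloc[-1]
            years = float(t1.time_years - t0.time_years)
            if years <= 0:
                continue
            s0 = component_zscore_summary(mats_by_key[(sid, int(t0.visit))].values,
                                          ref_mean, ref_sd, edges)
            s1 = component_zscore_summary(mats_by_key[(sid, int(t1.visit))].values,
                                          ref_mean, ref_sd, edges)
            rows.append({
                "subject_id": sid,
                "summary_change": annualized_change(s0, s1, years),
                "edss_change": annualized_change(float(t0.EDSS), float(t1.EDSS), years),
                "covar_change": annualized_change(float(t0[change_col]),
                                                  float(t1[change_col]), years),
            })
        df = pd.DataFrame(rows)
        if len(df) < 5:
            return None
        try:
            rho, p = spearman(df.summary_change, df.edss_change)
            prho, pp = partial_spearman(df.summary_change, df.edss_change, df.covar_change)
        except ValueError:        # degenerate (constant) changes in a tiny cohort
            return None
        return {"n": int(len(df)), "rho": rho, "p": p,
                "partial_rho": prho, "partial_p": pp,
                "component_edges": int(comp.n_edges), "component_p_fwe": float(comp.p_fwe)}

    disc_ref = disc_base                       # patients' baseline as reference
    sim_ref = [sim[(s, 0)] for s in hc_rows.subject_id]
    res = _summary_corr(nbs_long_disc, cohort.disconnection, idx_d, disc_ref, "log_tlv")
    report["annualized_disconnection_vs_edss"] = res
    res = _summary_corr(nbs_long_sim, sim, idx_s, sim_ref, "bpf_z")
    report["annualized_similarity_vs_edss"] = res

    # --- coupling -------------------------------------------------------------
    disc_b = [cohort.disconnection[(s, 0)] for s in base_ms.subject_id]
    sim_b = [sim[(s, 0)] for s in base_ms.subject_id]
    g_rho, g_p = coupling(disc_b, sim_b, level="global")
    e_rho, e_p = coupling(disc_b, sim_b, level="edge")
    node_rho = coupling(disc_b, sim_b, level="node")
    e0_rho, e0_p = coupling(disc_b, sim_b, level="edge", exclude_zero_disconnection=True)
    dd_split = coupling_by_duration(disc_b, sim_b, base_ms.disease_duration.to_numpy(),
                                    level="global")
    report["coupling"] = {
        "global": {"rho": g_rho, "p": g_p},
        "edge": {"rho": e_rho, "p": e_p},
        "edge_excluding_zero": {"rho": e0_rho, "p": e0_p},
        "node_mean_rho": float(np.nanmean(node_rho)),
        "duration_split": {k: (None if v is None else
                               {"rho": v[0], "p": v[1]} if isinstance(v, tuple) else v)
                           for k, v in dd_split.items()},
    }

    # --- long-term prediction -------------------------------------------------
    if predict_cfg is not None:
        lt = cohort.longterm.set_index("subject_id")
        keep = [s for s in base_ms.subject_id if s in lt.index]
        rows = base_ms.set_index("subject_id").loc[keep]
        Ydp = np.stack([cohort.disconnection[(s, 0)].values[idx_d.rows, idx_d.cols]
                        for s in keep])
        labels = lt.loc[keep, "CDP"].to_numpy(dtype=int)
        conf = rows[["age0", "age0_sq", "sex", "log_tlv"]].to_numpy(dtype=float)
        pres = run_nbs_predict(Ydp, labels, conf, predict_cfg, index=idx_d)
        report["cdp_prediction"] = {
            "accuracy": pres.accuracy, "ci": [pres.ci_low, pres.ci_high],
            "sensitivity": pres.sensitivity, "specificity": pres.specificity,
            "p_perm": pres.p_perm, "cdp_rate": float(labels.mean()),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
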