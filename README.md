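# msnets

Brain network analysis for multiple sclerosis (MS) cohorts using only
conventional MRI derivatives: binary lesion masks and cortical surface
morphometry. No diffusion or functional imaging is required.

`msnets` is aimed at neuroimaging statisticians who want a tested, scriptable
implementation of four linked analyses:

1. **Structural disconnectomes.** Given a subject's lesion mask and a
   normative streamline atlas on the same grid, the disconnection between
   regions *i* and *j* is the proportion of atlas streamlines connecting
   them that pass through at least one lesioned voxel, filling a symmetric
   node x node matrix (e.g. 114 x 114 for 100 cortical + 14 subcortical
   regions). Group-level lesion and disconnection probability maps are also
   produced.

2. **Morphometric similarity (MIND) networks.** Each cortical region is the
   multivariate distribution of its surface vertices over five features
   (thickness, GM volume, area, mean curvature, sulcal depth). Similarity
   between regions is `s = 1 / (1 + D_sym)` where
   `D_sym = D(P‖Q) + D(Q‖P)` is the symmetrized Kullback–Leibler divergence,
   estimated with a k-nearest-neighbor estimator on the vertex point clouds;
   `s` lies in (0, 1], higher = more similar.

3. **Network-based statistics (NBS).** The hypothesis (group, EDSS, SDMT,
   or time) is tested edge-wise with a GLM, or — longitudinally — with a
   linear mixed model with random intercept and slope of follow-up time per
   subject; edges with p below a primary threshold form connected
   components whose summed |t| is referred to a permutation null of maximum
   component sums (`p_FWE = (1 + #{null ≥ obs}) / (n_perm + 1)`).
   Nuisance covariates (baseline age, age², sex, optionally log(1+TLV) or
   brain-parenchymal-fraction z) are handled by Freedman–Lane residual
   permutation; longitudinal exchangeability uses subject-level sign flips
   of time-centered trajectories.

4. **Connectome-based prediction and coupling.** Long-term confirmed
   disability progression (CDP: EDSS increase ≥ 1 for baseline EDSS ≤ 5.5,
   ≥ 0.5 above) is predicted from baseline connectomes with nested
   stratified cross-validation, cross-validated deconfounding, NBS-style
   connected-component feature selection, and a randomized classifier /
   hyperparameter search; significance comes from label permutations.
   Disconnection–similarity coupling is quantified with Spearman
   correlations at the global, edge and node level.

Because clinical MRI cannot be redistributed, the package ships a
first-class synthetic cohort generator (`msnets.synthetic`) that emulates
every input — parcellation, streamline atlas, per-visit lesion masks with
periventricular predominance, vertex feature tables, longitudinal EDSS/SDMT
and long-term CDP — with *planted*, recoverable subnetwork effects, so the
whole pipeline is testable end to end.

## Worked example

Recover a planted disconnection subnetwork from a synthetic cohort with the
TLV-adjusted EDSS analysis:

```python
import numpy as np
from msnets import SimConfig, generate_cohort, vectorize_edges, nbs_glm, fit_scalar_lmm
from msnets.netstats import design_from_table

cfg = SimConfig(seed=3)            # defaults: 120 patients, 40 controls
cohort = generate_cohort(cfg)

base = cohort.cohort.query("group == 'MS' and visit == 0").reset_index(drop=True)
base["age0"], base["age0_sq"] = base.age, base.age ** 2
base["log_tlv"] = np.log1p(base.TLV)

mats = [cohort.disconnection[(s, 0)] for s in base.subject_id]
_, index = vectorize_edges(mats[0])
Y = np.stack([m.values[index.rows, index.cols] for m in mats])

design = design_from_table(base, "EDSS", ("age0", "age0_sq", "sex", "log_tlv"))
result = nbs_glm(Y, design, index, p_primary=0.01, n_perm=500, seed=11)
top = result.components[0]
print(f"largest component: {top.n_edges} edges, sum|t| = {top.stat_sum:.1f}, "
      f"p_FWE = {top.p_fwe:.3f}")

ms = cohort.cohort.query("group == 'MS'")
fit = fit_scalar_lmm(ms.EDSS.to_numpy(), ms.time_years.to_numpy(),
                     ms.subject_id.to_numpy())
print(f"EDSS worsening: B = {fit.B['time']:.3f}, SE = {fit.SE['time']:.3f}")
```

Output:

```
largest component: 10 edges, sum|t| = 87.9, p_FWE = 0.024
EDSS worsening: B = 0.162, SE = 0.017
```

The detected 10-edge component is exactly the planted clique
(`cohort.truth["planted_disconnection_edges"]`): after adjusting for global
lesion burden, disability is explained by *where* the damage fell. The
mixed-model slope quantifies the cohort's mean EDSS worsening per year.

A thin CLI mirrors the library: `msnets simulate`, `msnets disconnectome`,
`msnets mind`, `msnets nbs`, `msnets predict`, `msnets couple`, and
`msnets pipeline` (the full run from one YAML config into a directory of
TSV/NIfTI/JSON outputs).

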