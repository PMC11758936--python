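"""Synthetic cohort generator for lesion-network analyses.

Emulates every input the pipeline consumes — a parcellation label volume
with functional-system assignments, a labeled streamline atlas, per-visit
binary lesion masks with periventricular predominance, vertex-level
morphometric feature tables, and a longitudinal clinical table with
long-term confirmed disability progression (CDP) labels — on a small voxel
grid, with controllable planted effects:

* a planted *disconnection* component: a chosen edge set shares a deep
  white-matter fascicle, and tiny targeted lesions are placed on fascicle
  voxels hosting no other tract, at a rate driven by a subject
  "vulnerability" factor (independent of the global lesion propensity) that
  also grows with time — so those edges carry focal, progressive
  disconnection beyond the global lesion burden, and clinical scores can
  depend on damage *location* and not just damage amount;
* a planted *similarity* component: patients' vertex feature distributions
  at one endpoint of each chosen edge are shifted/inflated (negative effect,
  similarity decreases) or pulled toward the other endpoint (positive
  effect);
* EDSS trajectories with a configurable mean per-year slope, and long-term
  CDP whose log-odds are coupled to the baseline planted-component
  disconnection score.

Everything is deterministic under a fixed seed: a single global seed feeds
a per-subject, per-stream seed tree, so any subject's data can be
regenerated independently of cohort size.

The geometry is a deliberate abstraction: an ellipsoidal "brain" with a
cortical shell, central subcortical blobs, a ventricle proxy at the grid
center and a white-matter corridor in between. It makes no claim to
anatomical realism; it exists so that every downstream operation is
testable without MRI data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    SYSTEMS,
    CapacityError,
    DomainError,
    LesionMask,
    Parcellation,
    StreamlineAtlas,
)
from .disconnectome import disconnection_matrix, total_lesion_volume

__all__ = [
    "SimConfig",
    "simulate_baseline",
    "SyntheticCohort",
    "make_parcellation",
    "make_streamline_atlas",
    "make_lesions",
    "build_feature_template",
    "make_vertex_features",
    "make_clinical",
    "generate_cohort",
]

# Stream tags for the per-purpose seed tree.
_S_PARC, _S_ATLAS, _S_TEMPLATE, _S_SUBJECT, _S_LESION, _S_TARGET, _S_FEATURE, _S_CLINICAL = range(8)


def _default_disc_edges() -> list[tuple[int, int]]:
    # 10-edge clique over 5 azimuthally neighboring nodes: a compact,
    # connected subnetwork with a small spatial footprint
    return [(i, j) for i in range(1, 6) for j in range(i + 1, 6)]


def _default_sim_edges() -> list[tuple[int, int]]:
    return [(i, j) for i in range(21, 26) for j in range(i + 1, 26)]


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Sizes echo the structure of a conventional-MRI MS cohort (100 cortical
    + 14 subcortical regions on a 2 mm grid); sample sizes are a desk-scale
    cohort. Effect sizes are fixed study conditions, not tuning knobs.
    """

    n_patients: int = 120
    n_controls: int = 40
    n_cortical: int = 100
    n_subcortical: int = 14
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size: float = 2.0
    streamlines_per_pair: int = 5
    connected_pair_fraction: float = 0.3
    vertices_per_region: int = 150
    n_features: int = 5
    lesion_rate: float = 18.0                     # expected lesions at severity 0
    lesion_radius_range: tuple[float, float] = (1.5, 2.5)   # mm
    periventricular_bias: float = 0.04            # per mm of distance to ventricle proxy
    lesion_accrual_rate: float = 0.2              # new lesions / year at severity 0
    planted_disconnection_edges: list[tuple[int, int]] = field(default_factory=_default_disc_edges)
    planted_disconnection_effect: float = 3.0     # targeted lesions / unit vulnerability / edge
    planted_progression_rate: float = 0.15        # targeted lesions / year / edge at vulnerability 1
    planted_similarity_edges: list[tuple[int, int]] = field(default_factory=_default_sim_edges)
    planted_similarity_effect: float = -0.8       # signed, SD units at the endpoint
    similarity_progression_rate: float = 0.3      # per-year inflation of the planted effect
    feature_noise_sd: float = 0.2                 # per-region subject offset
    vertex_noise_sd: float = 0.2                  # per-vertex subject jitter
    visits_per_subject: tuple[int, int] = (2, 5)
    followup_years: tuple[float, float] = (1.0, 6.0)
    longterm_years: tuple[float, float] = (5.0, 17.0)
    edss_slope_mean: float = 0.084                # EDSS points / year
    edss_slope_sd: float = 0.15
    edss_disconnection_effect: float = 1.0        # EDSS points / SD of planted score
    sdmt_disconnection_effect: float = 0.6        # SDMT z (inverted) / SD of planted score
    cdp_effect: float = 1.0                       # log-odds CDP per SD of planted score
    cdp_base_rate: float = 0.446
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_cortical", "streamlines_per_pair",
                     "vertices_per_region"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_cortical < 1:
            raise ValueError("need at least one cortical region")
        if self.n_subcortical < 0:
            raise ValueError("n_subcortical must be nonnegative")
        if not 0.0 <= self.connected_pair_fraction <= 1.0:
            raise ValueError("connected_pair_fraction must lie in [0, 1]")
        if self.n_features != 5:
            raise ValueError("the feature set is fixed at 5 morphometric features")
        if self.vertices_per_region < 2:
            raise ValueError("vertices_per_region must be >= 2")
        if self.lesion_rate < 0 or self.lesion_accrual_rate < 0:
            raise ValueError("lesion rates must be nonnegative")
        if self.periventricular_bias < 0:
            raise ValueError("periventricular_bias must be nonnegative")
        n_nodes = self.n_cortical + self.n_subcortical
        for i, j in list(self.planted_disconnection_edges) + list(self.planted_similarity_edges):
            if not (1 <= i <= n_nodes and 1 <= j <= n_nodes and i != j):
                raise ValueError(f"planted edge ({i}, {j}) references invalid node ids")
        for i, j in self.planted_similarity_edges:
            if i > self.n_cortical or j > self.n_cortical:
                raise ValueError("planted similarity edges must be cortical")

    def rng(self, *key: int) -> np.random.Generator:
        """Named child generator of the global seed tree."""
        return np.random.default_rng(np.random.SeedSequence((int(self.seed),) + tuple(int(k) for k in key)))


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def _radial_field(cfg: SimConfig) -> np.ndarray:
    shape = np.asarray(cfg.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    radii = shape * 0.45
    idx = np.indices(cfg.grid_shape, dtype=float)
    return np.sqrt(sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3)))


def make_parcellation(cfg: SimConfig) -> Parcellation:
    """Label volume + node table: cortical shell Voronoi cells, central
    subcortical blobs, ventricle proxy at the grid center.

    Cortical seeds are drawn without replacement from the shell voxels and
    shell voxels join their nearest seed; each region is then pruned to the
    connected component containing its seed, which guarantees nonempty,
    contiguous regions. Cortical nodes are assigned to the 7 functional
    systems in contiguous blocks; subcortical nodes get system ``SUBC``.
    """
    from scipy.spatial import cKDTree

    rho = _radial_field(cfg)
    ventricle = rho < 0.12
    sub_shell = (rho >= 0.12) & (rho < 0.22)
    ctx_shell = (rho >= 0.58) & (rho <= 0.95)
    rng = cfg.rng(_S_PARC)
    labels = np.zeros(cfg.grid_shape, dtype=np.int32)

    def _assign(shell: np.ndarray, n_regions: int, first_label: int) -> None:
        vox = np.argwhere(shell)
        if len(vox) < 3 * n_regions:
            raise CapacityError(
                f"grid too small: {len(vox)} shell voxels cannot host {n_regions} regions"
            )
        seeds = vox[rng.choice(len(vox), size=n_regions, replace=False)]
        # order seeds by azimuth (then elevation) so that consecutive labels
        # are spatially neighboring, as in anatomically ordered atlases
        ctr = (np.asarray(cfg.grid_shape) - 1) / 2.0
        rel = seeds - ctr
        order = np.lexsort((rel[:, 1], np.arctan2(rel[:, 2], rel[:, 0])))
        seeds = seeds[order]
        tree = cKDTree(seeds)
        _, nearest = tree.query(vox, k=1)
        labels[tuple(vox.T)] = first_label + nearest
        struct = np.ones((3, 3, 3), dtype=bool)
        for r in range(n_regions):
            lab = first_label + r
            mask = labels == lab
            comp, ncomp = ndimage.label(mask, structure=struct)
            if ncomp > 1:
                keep = comp[tuple(seeds[r])]
                labels[mask & (comp != keep)] = 0
            if not (labels == lab).any():
                raise CapacityError(f"region {lab} ended up empty")

    _assign(ctx_shell, cfg.n_cortical, 1)
    if cfg.n_subcortical > 0:
        _assign(sub_shell, cfg.n_subcortical, cfg.n_cortical + 1)

    blocks = np.array_split(np.arange(cfg.n_cortical), 7)
    rows = []
    for sys_idx, block in enumerate(blocks):
        for i in block:
            rows.append({"node_id": int(i + 1), "name": f"CTX_{SYSTEMS[sys_idx]}_{i + 1:03d}",
                         "system": SYSTEMS[sys_idx]})
    for i in range(cfg.n_subcortical):
        nid = cfg.n_cortical + i + 1
        rows.append({"node_id": nid, "name": f"SUBC_{i + 1:02d}", "system": "SUBC"})
    table = pd.DataFrame(rows)
    vs = (cfg.voxel_size,) * 3
    return Parcellation(labels=labels, voxel_size=vs, node_table=table,
                        ventricle_mask=ventricle, space_tag=f"synthetic-{cfg.grid_shape}")


# ---------------------------------------------------------------------------
# Streamline atlas
# ---------------------------------------------------------------------------

def _arc_streamline(p0, p1, center, radii, rho_mid, jitter_sd, rng):
    """Polyline arcing between two points at a controlled radial depth.

    The direction is spherically interpolated (slerp) between the two
    endpoint directions while the normalized radius follows a smooth
    profile dipping to ``rho_mid`` at the middle, so the tract stays within
    its radial band along its whole course instead of cutting through the
    core. Random sinusoidal jitter individualizes streamlines of a pair.
    """
    u0 = (p0 - center) / radii
    u1 = (p1 - center) / radii
    r0, r1 = np.linalg.norm(u0), np.linalg.norm(u1)
    v0, v1 = u0 / r0, u1 / r1
    dot = float(np.clip(v0 @ v1, -1.0, 1.0))
    omega = np.arccos(dot)
    n_pts = max(4, int(np.ceil(omega * 24)) + int(np.ceil(abs(r1 - r0) * 10)) + 4)
    t = np.linspace(0.0, 1.0, n_pts)
    if omega < 1e-6:
        dirs = np.repeat(v0[None, :], n_pts, axis=0)
    else:
        if omega > np.pi - 1e-3:
            # antipodal: route via a random perpendicular waypoint
            w = rng.normal(size=3)
            w -= (w @ v0) * v0
            w /= np.linalg.norm(w)
            half = np.sin((1 - t) * (np.pi / 2))[:, None] * v0 + np.sin(t * (np.pi / 2))[:, None] * w
            # second half rotates from waypoint to v1; compose piecewise
            a = np.where(t <= 0.5, 2 * t, 0.0)
            b = np.where(t > 0.5, 2 * t - 1, 0.0)
            first = (np.sin((1 - a) * (np.pi / 2))[:, None] * v0 + np.sin(a * (np.pi / 2))[:, None] * w)
            second = (np.sin((1 - b) * (np.pi / 2))[:, None] * w + np.sin(b * (np.pi / 2))[:, None] * v1)
            dirs = np.where(t[:, None] <= 0.5, first, second)
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        else:
            s = np.sin(omega)
            dirs = (np.sin((1 - t) * omega)[:, None] * v0 + np.sin(t * omega)[:, None] * v1) / s
    rho = (1 - t) * r0 + t * r1 + np.sin(np.pi * t) * (rho_mid - 0.5 * (r0 + r1))
    pts = center[None, :] + dirs * (rho[:, None] * radii[None, :])
    w = rng.normal(0.0, jitter_sd, 3)
    pts = pts + np.sin(np.pi * t)[:, None] * w[None, :]
    return pts


def make_streamline_atlas(parcellation: Parcellation, cfg: SimConfig) -> StreamlineAtlas:
    """Labeled polylines between a random subset of region pairs.

    Each selected pair carries exactly ``streamlines_per_pair`` polylines
    whose endpoints are random interior points of the two regions. Tracts
    arc through the white matter at a controlled radial depth: background
    tracts ride an outer band (normalized radius ~0.52-0.64, association-
    fiber-like), while pairs of the planted disconnection component share a
    deeper, tighter fascicle band (~0.34-0.40). The spatial segregation is
    what lets targeted lesions on the planted fascicle transect the planted
    edges without collaterally damaging unrelated tracts. Planted pairs are
    always included in the atlas.
    """
    rng = cfg.rng(_S_ATLAS)
    node_ids = [int(n) for n in parcellation.node_ids]
    pairs = list(itertools.combinations(node_ids, 2))
    pick = rng.random(len(pairs)) < cfg.connected_pair_fraction
    selected = {p for p, keep in zip(pairs, pick) if keep}
    planted = {tuple(sorted(e)) for e in cfg.planted_disconnection_edges}
    selected |= planted

    voxels = {n: parcellation.region_voxels(n) for n in node_ids}
    for n, v in voxels.items():
        if len(v) == 0:
            raise ValueError(f"endpoint region {n} is empty")
    shape = np.asarray(cfg.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    radii = shape * 0.45
    eps = 1e-6

    def _rho(p):
        return float(np.linalg.norm((p - center) / radii))

    centroid_dir = {}
    for n in node_ids:
        if n > cfg.n_cortical:
            v = (voxels[n].mean(axis=0) - center) / radii
            centroid_dir[n] = v / np.linalg.norm(v)

    def _dense(a, b, step=1.2):
        k = max(2, int(np.ceil(np.linalg.norm(b - a) / step)) + 1)
        return a[None, :] + np.linspace(0.0, 1.0, k)[:, None] * (b - a)[None, :]

    def _build(i, j, fascicle, push=0.0):
        p0 = voxels[i][rng.integers(len(voxels[i]))] + 0.5 + rng.uniform(-0.45, 0.45, 3)
        p1 = voxels[j][rng.integers(len(voxels[j]))] + 0.5 + rng.uniform(-0.45, 0.45, 3)
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        subc = [n > cfg.n_cortical for n in (i, j)]
        if not any(subc):
            # cortico-cortical: planted pairs share a deep fascicle band,
            # the rest ride the outer association band (lifted further on
            # rerouting attempts)
            rho_mid = rng.uniform(0.34, 0.40) if fascicle else min(rng.uniform(0.52, 0.64) + 0.015 * push, 0.72)
            jit = 0.6 if fascicle else 1.2
            pts = _arc_streamline(p0, p1, center, radii, rho_mid, jit, rng)
        elif all(subc):
            # deep-to-deep: stay below the fascicle band
            pts = _arc_streamline(p0, p1, center, radii,
                                  max(rng.uniform(0.22, 0.27) - 0.01 * push, 0.16), 0.5, rng)
        else:
            # cortico-subcortical: cruise in the outer band, then dive
            # along the blob's centroid axis so deep bands are crossed only
            # inside the blob's own funnel; rerouting attempts displace the
            # dive sideways
            if subc[0]:
                p0, p1 = p1, p0              # cortical end first
                blob = i
            else:
                blob = j
            vb = centroid_dir[blob]
            side = rng.normal(size=3)
            side -= (side @ vb) * vb
            side /= max(np.linalg.norm(side), 1e-9)
            cruise = rng.uniform(0.52, 0.64)
            above = center + vb * (cruise * radii) + rng.normal(0.0, 1.5, 3) + side * push
            knee_b = (center + vb * ((_rho(p1) + 0.04) * radii)
                      + rng.normal(0.0, 1.0, 3) + side * (0.6 * push))
            arc = _arc_streamline(p0, above, center, radii, cruise, 1.0, rng)
            pts = np.vstack([arc, _dense(above, knee_b)[1:], _dense(knee_b, p1)[1:]])
            if subc[0]:
                pts = pts[::-1]
        return np.clip(pts, eps, shape - eps)

    from .disconnectome import voxelize_streamline

    streamlines = []
    if cfg.streamlines_per_pair > 0:
        # planted fascicle first: its dilated voxel tube becomes an
        # exclusion zone that other tracts route around, the way distinct
        # anatomical fascicles do not interpenetrate
        tube = np.zeros(cfg.grid_shape, dtype=bool)
        for (i, j) in sorted(planted & selected):
            for _ in range(cfg.streamlines_per_pair):
                pts = _build(i, j, True)
                vox = np.asarray(voxelize_streamline(pts, cfg.grid_shape), dtype=np.intp)
                tube[tuple(vox.T)] = True
                streamlines.append(((i, j), pts))
        tube = ndimage.binary_dilation(tube, structure=np.ones((3, 3, 3), dtype=bool))
        for (i, j) in sorted(selected - planted):
            for _ in range(cfg.streamlines_per_pair):
                for attempt in range(12):
                    pts = _build(i, j, False, push=float(attempt))
                    vox = np.asarray(voxelize_streamline(pts, cfg.grid_shape), dtype=np.intp)
                    if not tube[tuple(vox.T)].any():
                        break
                streamlines.append(((i, j), pts))
        streamlines.sort(key=lambda sl: sl[0])
    return StreamlineAtlas(streamlines=streamlines, grid_shape=cfg.grid_shape,
                           voxel_size=(cfg.voxel_size,) * 3, space_tag=parcellation.space_tag)


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

def _lesion_fields(parc: Parcellation, bias: float):
    """Allowed (non-GM, non-ventricle) voxels and periventricular sampling
    weights; cached on the parcellation."""
    cache = getattr(parc, "_lesion_cache", None)
    if cache is not None and cache[0] == bias:
        return cache[1], cache[2]
    allowed = (parc.labels == 0)
    # keep background lesions out of the deepest convergence zone, where the
    # radial funnels of all subcortical blobs meet
    shape = np.asarray(parc.labels.shape, dtype=float)
    ctr = (shape - 1) / 2.0
    radii = shape * 0.45
    idxs = np.indices(parc.labels.shape, dtype=float)
    rho = np.sqrt(sum(((idxs[a] - ctr[a]) / radii[a]) ** 2 for a in range(3)))
    allowed &= rho > 0.26
    if parc.ventricle_mask is not None:
        allowed &= ~parc.ventricle_mask
        dist = ndimage.distance_transform_edt(~parc.ventricle_mask, sampling=parc.voxel_size)
    else:
        center = (np.asarray(parc.labels.shape) - 1) / 2.0
        idx = np.indices(parc.labels.shape, dtype=float)
        dist = np.sqrt(sum(((idx[a] - center[a]) * parc.voxel_size[a]) ** 2 for a in range(3)))
    coords = np.argwhere(allowed)
    w = np.exp(-bias * dist[allowed])
    probs = w / w.sum()
    parc._lesion_cache = (bias, coords, probs)
    return coords, probs


def _paint_spheres(mask: np.ndarray, allowed: np.ndarray, centers: np.ndarray,
                   radii: np.ndarray, voxel_size: float) -> None:
    shape = np.asarray(mask.shape)
    for c, r in zip(centers, radii):
        rv = int(np.ceil(r / voxel_size))
        lo = np.maximum(c - rv, 0)
        hi = np.minimum(c + rv + 1, shape)
        sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
        d = np.linalg.norm((sub - c) * voxel_size, axis=1)
        sel = sub[d <= r]
        ok = allowed[tuple(sel.T)]
        sel = sel[ok]
        mask[tuple(sel.T)] = 1


def make_lesions(
    severity: float,
    parcellation: Parcellation,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    rate: float | None = None,
) -> LesionMask:
    """Binary lesion mask with periventricular predominance.

    The lesion count is Poisson with mean ``lesion_rate * (1 + severity)``
    (or an explicit ``rate``); centers are sampled from the non-GM voxels
    with density proportional to ``exp(-bias * distance to the ventricle
    proxy)``, and each lesion is a sphere with radius uniform over
    ``lesion_radius_range``, clipped to non-GM voxels so that disconnection
    acts only through streamline transection.
    """
    if severity < 0:
        raise DomainError("severity must be nonnegative")
    if rng is None:
        rng = cfg.rng(_S_LESION)
    lam = cfg.lesion_rate * (1.0 + severity) if rate is None else rate
    n = int(rng.poisson(lam))
    mask = np.zeros(cfg.grid_shape, dtype=np.uint8)
    if n > 0:
        coords, probs = _lesion_fields(parcellation, cfg.periventricular_bias)
        centers = coords[rng.choice(len(coords), size=n, p=probs)]
        radii = rng.uniform(*cfg.lesion_radius_range, size=n)
        allowed = (parcellation.labels == 0)
        if parcellation.ventricle_mask is not None:
            allowed &= ~parcellation.ventricle_mask
        _paint_spheres(mask, allowed, centers, radii, cfg.voxel_size)
    return LesionMask(mask, (cfg.voxel_size,) * 3, space_tag=parcellation.space_tag)


def _targeted_lesions(
    mask: np.ndarray,
    atlas: StreamlineAtlas,
    parcellation: Parcellation,
    counts: dict[tuple[int, int], int],
    rng: np.random.Generator,
    cfg: SimConfig,
) -> None:
    """Place small lesions directly on the streamlines of planted edges.

    Candidate voxels are restricted to fascicle segments *exclusive* to the
    planted tracts: non-GM voxels at least one voxel away from every
    streamline of any non-planted pair. Targeted damage therefore transects
    only the edges it is meant to disconnect.
    """
    planted = set(counts)
    by_pair: dict[tuple[int, int], list[np.ndarray]] = {}
    for pair, pts in atlas.streamlines:
        by_pair.setdefault(pair, []).append(pts)

    allowed = getattr(atlas, "_target_allowed", None)
    if allowed is None or getattr(atlas, "_target_allowed_key", None) != tuple(sorted(planted)):
        allowed = (parcellation.labels == 0)
        if parcellation.ventricle_mask is not None:
            allowed &= ~parcellation.ventricle_mask
        other = np.zeros(atlas.grid_shape, dtype=bool)
        flat = other.ravel()
        for s, (pair, _) in enumerate(atlas.streamlines):
            if pair not in planted:
                flat[atlas.streamline_voxels()[s]] = True
        other = flat.reshape(atlas.grid_shape)
        allowed &= ~other
        atlas._target_allowed = allowed
        atlas._target_allowed_key = tuple(sorted(planted))

    for pair in sorted(counts):
        n = counts[pair]
        lines = by_pair.get(pair, [])
        if n <= 0 or not lines:
            continue
        centers, radii = [], []
        for _ in range(n):
            for _try in range(10):      # resample until an exclusive voxel
                pts = lines[rng.integers(len(lines))]
                lo = int(len(pts) * 0.30)
                k = rng.integers(lo, max(int(len(pts) * 0.70), lo + 1))
                c = np.floor(pts[k]).astype(int)
                if allowed[tuple(c)]:
                    centers.append(c)
                    radii.append(rng.uniform(0.9, 1.8))
                    break
        if centers:
            _paint_spheres(mask, allowed, np.asarray(centers), np.asarray(radii), cfg.voxel_size)


# ---------------------------------------------------------------------------
# Vertex features
# ---------------------------------------------------------------------------

@dataclass
class FeatureTemplate:
    """Shared regional feature distributions (identical across subjects)."""

    mu: dict[int, np.ndarray]
    sd: dict[int, np.ndarray]
    cloud: dict[int, np.ndarray]


def build_feature_template(cfg: SimConfig) -> FeatureTemplate:
    rng = cfg.rng(_S_TEMPLATE)
    mu, sd, cloud = {}, {}, {}
    for r in range(1, cfg.n_cortical + 1):
        mu[r] = rng.normal(0.0, 1.0, cfg.n_features)
        sd[r] = rng.uniform(0.7, 1.3, cfg.n_features)
        cloud[r] = mu[r] + rng.normal(size=(cfg.vertices_per_region, cfg.n_features)) * sd[r]
    return FeatureTemplate(mu, sd, cloud)


def make_vertex_features(
    cfg: SimConfig,
    template: FeatureTemplate,
    rng: np.random.Generator,
    patient: bool,
    time_years: float = 0.0,
) -> dict[int, np.ndarray]:
    """Per-region vertex feature tables for one subject visit.

    Subjects perturb the shared template cloud with a per-region offset
    (``feature_noise_sd``) and per-vertex jitter (``vertex_noise_sd``); with
    both at zero every subject reproduces the template exactly. For
    patients, each planted similarity edge shifts/inflates the higher-id
    endpoint's distribution along the inter-centroid direction (negative
    effect: away from the partner, similarity drops; positive: toward it);
    the magnitude grows with time by ``similarity_progression_rate``.
    """
    if cfg.vertices_per_region < 2:
        raise ValueError("need at least 2 vertices per region")
    out: dict[int, np.ndarray] = {}
    for r in range(1, cfg.n_cortical + 1):
        X = template.cloud[r].copy()
        if cfg.feature_noise_sd > 0:
            X = X + rng.normal(0.0, cfg.feature_noise_sd, cfg.n_features)
        if cfg.vertex_noise_sd > 0:
            X = X + rng.normal(0.0, cfg.vertex_noise_sd, X.shape)
        out[r] = X
    if patient:
        for (a, b) in cfg.planted_similarity_edges:
            a, b = sorted((a, b))
            eff = cfg.planted_similarity_effect * (1.0 + cfg.similarity_progression_rate * time_years)
            u = template.mu[b] - template.mu[a]
            norm = np.linalg.norm(u)
            u = u / norm if norm > 0 else np.ones(cfg.n_features) / np.sqrt(cfg.n_features)
            X = out[b]
            if eff < 0:
                center = X.mean(axis=0)
                X = center + (X - center) * (1.0 + 0.25 * abs(eff))
                X = X + abs(eff) * u
            else:
                X = X + min(eff, 1.0) * (template.mu[a] - template.mu[b])
            out[b] = X
    return out


# ---------------------------------------------------------------------------
# Clinical trajectories
# ---------------------------------------------------------------------------

def _round_half_up(x):
    """Round to the 0.5 EDSS grid, halves rounding up."""
    return np.floor(np.asarray(x) * 2.0 + 0.5) / 2.0


def make_clinical(
    severity: float,
    slope: float,
    visit_times: Sequence[float],
    cfg: SimConfig,
    rng: np.random.Generator,
    planted_z: Sequence[float] | float = 0.0,
    ztlv: Sequence[float] | float = None,
) -> dict:
    """EDSS/SDMT trajectory plus long-term follow-up and CDP label.

    The latent disability has three parts: a *global* term driven by the
    realized lesion burden (``ztlv``, the cohort-standardized log(1+TLV);
    when absent, latent severity stands in), a *subnetwork-specific* term —
    ``edss_disconnection_effect`` EDSS points per SD of the subject's
    planted-component disconnection over and above global burden
    (``planted_z``) — and a per-year slope with visit noise. Tying the
    global term to TLV itself (rather than to the latent lesion rate) is
    what makes TLV adjustment in downstream models remove the global
    channel exactly, leaving only the planted subnetwork effect: damage
    *location* matters beyond damage amount. The result is rounded half-up
    to the 0.5 EDSS grid and clipped to [0, 10]; SDMT (inverted scale)
    carries analogous global and subnetwork terms. The long-term CDP
    indicator is Bernoulli with log-odds ``logit(cdp_base_rate) +
    cdp_effect * baseline planted_z``; the long-term EDSS is then generated
    to satisfy (or fall short of) the CDP rule, so the label is always
    consistent with its own EDSS pair.
    """
    visit_times = np.asarray(visit_times, dtype=float)
    pz = np.broadcast_to(np.asarray(planted_z, dtype=float), visit_times.shape)
    if ztlv is None:
        gz = np.broadcast_to(np.float64(1.9 * (severity - 1.0)), visit_times.shape)
    else:
        gz = np.broadcast_to(np.asarray(ztlv, dtype=float), visit_times.shape)
    latent0 = 2.5 + rng.normal(0.0, 0.3)
    latent = (latent0 + 1.1 * gz + slope * visit_times
              + cfg.edss_disconnection_effect * pz
              + rng.normal(0.0, 0.2, len(visit_times)))
    edss = np.clip(_round_half_up(latent), 0.0, 10.0)
    sdmt = -(1.1 + 0.8 * gz + cfg.sdmt_disconnection_effect * pz
             + rng.normal(0.0, 0.8, len(visit_times)))

    edss0 = float(edss[0])
    req = 1.0 if edss0 <= 5.5 else 0.5
    logit0 = np.log(cfg.cdp_base_rate / (1.0 - cfg.cdp_base_rate))
    p_prog = 1.0 / (1.0 + np.exp(-(logit0 + cfg.cdp_effect * float(pz[0]))))
    t_lt = float(rng.uniform(*cfg.longterm_years))
    progress = bool(rng.random() < p_prog) and (edss0 + req <= 10.0)
    if progress:
        extra = _round_half_up(abs(rng.normal(0.0, 0.75)))
        edss_lt = min(10.0, edss0 + req + float(extra))
    else:
        delta = float(_round_half_up(rng.normal(0.0, 0.35)))
        delta = min(delta, req - 0.5)
        edss_lt = float(np.clip(edss0 + delta, 0.0, 10.0))
    from .summarize import cdp_label

    return {
        "edss": edss,
        "sdmt_z": sdmt,
        "longterm_years": t_lt,
        "edss_longterm": edss_lt,
        "cdp": cdp_label(edss0, edss_lt),
    }


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Bundle of all synthetic inputs plus generation ground truth.

    ``cohort`` has one row per visit (patients and controls);
    ``longterm`` one row per patient with the long-term EDSS and CDP label.
    Vertex features are regenerated on demand (deterministically) through
    :meth:`vertex_features` to keep memory bounded.
    """

    cfg: SimConfig
    parcellation: Parcellation
    atlas: StreamlineAtlas
    template: FeatureTemplate
    cohort: pd.DataFrame
    longterm: pd.DataFrame
    lesion_masks: dict[tuple[str, int], LesionMask]
    disconnection: dict[tuple[str, int], "object"]
    truth: dict

    def vertex_features(self, subject_id: str, visit: int = 0) -> dict[int, np.ndarray]:
        row = self.cohort[(self.cohort.subject_id == subject_id) & (self.cohort.visit == visit)]
        if len(row) != 1:
            raise KeyError(f"no such visit: {subject_id}/{visit}")
        row = row.iloc[0]
        sidx = int(self.truth["subject_index"][subject_id])
        rng = self.cfg.rng(_S_FEATURE, sidx, visit)
        return make_vertex_features(self.cfg, self.template, rng,
                                    patient=row.group == "MS",
                                    time_years=float(row.time_years))

    @property
    def patient_ids(self) -> list[str]:
        return sorted({s for s in self.cohort.subject_id if s.startswith("MS")})

    @property
    def control_ids(self) -> list[str]:
        return sorted({s for s in self.cohort.subject_id if s.startswith("HC")})


def simulate_baseline(
    cfg: SimConfig,
    parcellation: Parcellation | None = None,
    atlas: StreamlineAtlas | None = None,
    replicate: int = 0,
) -> dict:
    """Baseline-only patient sample for power and calibration studies.

    Regenerates lesions, disconnectomes and clinical scores for
    ``cfg.n_patients`` patients under the same planted-effect machinery as
    :func:`generate_cohort`, but with a single visit per subject and an
    optionally shared parcellation/atlas, so many replicates can be drawn
    cheaply. Returns a dict with the per-patient table, the disconnection
    matrices, and the planted edge list.
    """
    if parcellation is None:
        parcellation = make_parcellation(cfg)
    if atlas is None:
        atlas = make_streamline_atlas(parcellation, cfg)
    planted = [tuple(sorted(e)) for e in cfg.planted_disconnection_edges]

    svox = atlas.streamline_voxels() if atlas.streamlines else []
    planted_lines: dict[tuple[int, int], list[np.ndarray]] = {e: [] for e in planted}
    for s, (pair, _) in enumerate(atlas.streamlines):
        if pair in planted_lines:
            planted_lines[pair].append(svox[s])

    metas, mats, tscores = [], [], []
    for i in range(cfg.n_patients):
        rng = cfg.rng(_S_SUBJECT, replicate, i)
        severity = float(rng.gamma(2.0, 0.5))
        vulnerability = float(rng.gamma(2.0, 0.5))
        age0 = float(np.clip(rng.normal(37.2, 10.6), 18.0, 75.0))
        sex = int(rng.random() < 0.70)
        lrng = cfg.rng(_S_LESION, replicate, i)
        trng = cfg.rng(_S_TARGET, replicate, i)
        mask = make_lesions(severity, parcellation, cfg, rng=lrng).data.copy()
        tmask = np.zeros_like(mask)
        counts = {e: int(trng.poisson(cfg.planted_disconnection_effect * vulnerability))
                  for e in planted}
        _targeted_lesions(tmask, atlas, parcellation, counts, trng, cfg)
        mask |= tmask
        lm = LesionMask(mask, (cfg.voxel_size,) * 3, parcellation.space_tag)
        mats.append(disconnection_matrix(lm, atlas, parcellation=parcellation))
        flat = tmask.ravel()
        fr = [np.mean([bool(flat[lin].any()) for lin in lines])
              for lines in planted_lines.values() if lines]
        tscores.append(float(np.mean(fr)) if fr else 0.0)
        metas.append({"severity": severity, "vulnerability": vulnerability,
                      "age": age0, "sex": sex, "TLV": total_lesion_volume(lm)})

    tscores = np.asarray(tscores)
    sd = tscores.std(ddof=0)
    pz = (tscores - tscores.mean()) / sd if sd > 0 else np.zeros_like(tscores)
    logtlv = np.log1p([m["TLV"] for m in metas])
    lsd = logtlv.std(ddof=0)
    ztlv = (logtlv - logtlv.mean()) / lsd if lsd > 0 else np.zeros_like(logtlv)
    rows = []
    for i, meta in enumerate(metas):
        crng = cfg.rng(_S_CLINICAL, replicate, i)
        clin = make_clinical(meta["severity"], cfg.edss_slope_mean, [0.0], cfg, crng,
                             planted_z=float(pz[i]), ztlv=float(ztlv[i]))
        rows.append({"subject_id": f"MS{i + 1:03d}", "age": meta["age"],
                     "sex": meta["sex"], "TLV": meta["TLV"],
                     "EDSS": float(clin["edss"][0]), "sdmt_z": float(clin["sdmt_z"][0]),
                     "CDP": int(clin["cdp"]), "vulnerability": meta["vulnerability"],
                     "severity": meta["severity"]})
    return {"table": pd.DataFrame(rows), "matrices": mats, "planted_edges": planted,
            "parcellation": parcellation, "atlas": atlas}


def generate_cohort(cfg: SimConfig, compute_disconnection: bool = True) -> SyntheticCohort:
    """Generate the full synthetic cohort.

    Patients accrue lesions over visits (masks are nested across time);
    targeted lesions on the planted disconnection component scale with the
    subject's vulnerability factor at baseline and accrue with time,
    producing both a cross-sectional and a progressive planted
    disconnection signal. The long-term CDP label is coupled to the
    baseline planted-component score with log-odds slope ``cdp_effect``.
    """
    parc = make_parcellation(cfg)
    atlas = make_streamline_atlas(parc, cfg)
    template = build_feature_template(cfg)

    planted = [tuple(sorted(e)) for e in cfg.planted_disconnection_edges]
    rows, lt_rows = [], []
    masks: dict[tuple[str, int], LesionMask] = {}
    tmasks: dict[tuple[str, int], np.ndarray] = {}
    matrices: dict[tuple[str, int], object] = {}
    subject_index: dict[str, int] = {}
    sev_map: dict[str, float] = {}
    vul_map: dict[str, float] = {}
    slope_map: dict[str, float] = {}

    # -- patients: severity, visits, lesions ---------------------------------
    pat_meta = []
    for i in range(cfg.n_patients):
        sid = f"MS{i + 1:03d}"
        subject_index[sid] = i
        rng = cfg.rng(_S_SUBJECT, i)
        severity = float(rng.gamma(2.0, 0.5))
        # vulnerability of the planted subnetwork: independent of the global
        # lesion propensity, so damage *location* carries information that
        # damage *amount* does not
        vulnerability = float(rng.gamma(2.0, 0.5))
        slope = float(rng.normal(cfg.edss_slope_mean, cfg.edss_slope_sd))
        age0 = float(np.clip(rng.normal(37.2, 10.6), 18.0, 75.0))
        sex = int(rng.random() < 0.70)            # 1 = female
        dd = float(rng.gamma(1.33, 6.86))
        icv = float(np.clip(rng.normal(1.45e6, 1.2e5), 1.0e6, 2.0e6))
        n_visits = int(rng.integers(cfg.visits_per_subject[0], cfg.visits_per_subject[1] + 1))
        total_fu = float(rng.uniform(*cfg.followup_years))
        times = np.concatenate([[0.0], np.sort(rng.uniform(0.2, total_fu, n_visits - 1))]) \
            if n_visits > 1 else np.array([0.0])
        sev_map[sid], slope_map[sid] = severity, slope
        vul_map[sid] = vulnerability
        pat_meta.append((sid, i, severity, slope, age0, sex, dd, icv, times))

        lrng = cfg.rng(_S_LESION, i)
        trng = cfg.rng(_S_TARGET, i)
        mask = make_lesions(severity, parc, cfg, rng=lrng).data.copy()
        tmask = np.zeros_like(mask)          # targeted-only lesions, tracked apart
        counts0 = {e: int(trng.poisson(cfg.planted_disconnection_effect * vulnerability)) for e in planted}
        _targeted_lesions(tmask, atlas, parc, counts0, trng, cfg)
        mask |= tmask
        masks[(sid, 0)] = LesionMask(mask.copy(), (cfg.voxel_size,) * 3, parc.space_tag)
        tmasks[(sid, 0)] = tmask.copy()
        for v in range(1, len(times)):
            dt = float(times[v] - times[v - 1])
            new = make_lesions(severity, parc, cfg, rng=lrng,
                               rate=cfg.lesion_accrual_rate * (1.0 + severity) * dt)
            mask |= new.data
            cts = {e: int(trng.poisson(cfg.planted_progression_rate * vulnerability * dt)) for e in planted}
            _targeted_lesions(tmask, atlas, parc, cts, trng, cfg)
            mask |= tmask
            masks[(sid, v)] = LesionMask(mask.copy(), (cfg.voxel_size,) * 3, parc.space_tag)
            tmasks[(sid, v)] = tmask.copy()

    # -- disconnection + planted-component scores ----------------------------
    # The clinical planted score is the fraction of planted-pair streamlines
    # transected by *targeted* lesions only: the subnetwork-specific
    # disability channel is the planted mechanism itself, orthogonal to the
    # background lesion burden by construction.
    if compute_disconnection:
        for (sid, v), m in masks.items():
            matrices[(sid, v)] = disconnection_matrix(m, atlas, parcellation=parc)
    svox = atlas.streamline_voxels() if atlas.streamlines else []
    planted_lines: dict[tuple[int, int], list[np.ndarray]] = {e: [] for e in planted}
    for s, (pair, _) in enumerate(atlas.streamlines):
        if pair in planted_lines:
            planted_lines[pair].append(svox[s])

    def _targeted_score(tm: np.ndarray) -> float:
        flat = tm.ravel()
        fracs = []
        for e, lines in planted_lines.items():
            if lines:
                fracs.append(np.mean([bool(flat[lin].any()) for lin in lines]))
        return float(np.mean(fracs)) if fracs else 0.0

    raw = {key: _targeted_score(tm) for key, tm in tmasks.items()}
    r0 = np.array([raw[(s, 0)] for s, *_ in pat_meta])
    mu0, sd0 = r0.mean(), r0.std(ddof=0)
    score_z = {key: (val - mu0) / sd0 if sd0 > 0 else 0.0 for key, val in raw.items()}

    # -- clinical rows --------------------------------------------------------
    logtlv = {key: float(np.log1p(total_lesion_volume(m))) for key, m in masks.items()}
    lt0 = np.array([logtlv[(s, 0)] for s, *_ in pat_meta])
    lt_mu, lt_sd = lt0.mean(), lt0.std(ddof=0)
    for sid, i, severity, slope, age0, sex, dd, icv, times in pat_meta:
        crng = cfg.rng(_S_CLINICAL, i)
        pz = np.array([score_z[(sid, v)] for v in range(len(times))])
        ztlv = np.array([(logtlv[(sid, v)] - lt_mu) / lt_sd if lt_sd > 0 else 0.0
                         for v in range(len(times))])
        clin = make_clinical(severity, slope, times, cfg, crng, planted_z=pz, ztlv=ztlv)
        for v, t in enumerate(times):
            bpf = float(np.clip(0.85 - 0.0012 * (age0 + t - 40.0) - 0.005 * (1 - sex)
                                - 0.025 * severity - 0.0012 * severity * t
                                + crng.normal(0.0, 0.012), 0.5, 1.0))
            tlv = total_lesion_volume(masks[(sid, v)]) if (sid, v) in masks else 0.0
            rows.append({
                "subject_id": sid, "group": "MS", "visit": v, "time_years": float(t),
                "age": age0 + float(t), "sex": sex, "disease_duration": dd + float(t),
                "EDSS": float(clin["edss"][v]), "sdmt_z": float(clin["sdmt_z"][v]),
                "TLV": tlv, "brain_volume": bpf * icv, "icv": icv,
            })
        lt_rows.append({
            "subject_id": sid, "followup_years": clin["longterm_years"],
            "edss_baseline": float(clin["edss"][0]),
            "edss_longterm": clin["edss_longterm"], "CDP": int(clin["cdp"]),
        })

    # -- controls -------------------------------------------------------------
    for i in range(cfg.n_controls):
        sid = f"HC{i + 1:03d}"
        subject_index[sid] = cfg.n_patients + i
        rng = cfg.rng(_S_SUBJECT, cfg.n_patients + i)
        age = float(np.clip(rng.normal(42.4, 15.7), 18.0, 75.0))
        sex = int(rng.random() < 0.45)
        icv = float(np.clip(rng.normal(1.45e6, 1.2e5), 1.0e6, 2.0e6))
        bpf = float(np.clip(0.85 - 0.0012 * (age - 40.0) - 0.005 * (1 - sex)
                            + rng.normal(0.0, 0.012), 0.5, 1.0))
        rows.append({
            "subject_id": sid, "group": "HC", "visit": 0, "time_years": 0.0,
            "age": age, "sex": sex, "disease_duration": np.nan,
            "EDSS": np.nan, "sdmt_z": float(rng.normal(0.0, 1.0)),
            "TLV": 0.0, "brain_volume": bpf * icv, "icv": icv,
        })

    cohort = pd.DataFrame(rows)
    longterm = pd.DataFrame(lt_rows)
    truth = {
        "severity": sev_map, "vulnerability": vul_map, "edss_slope": slope_map,
        "planted_disconnection_edges": planted,
        "planted_similarity_edges": [tuple(sorted(e)) for e in cfg.planted_similarity_edges],
        "planted_score_z": {sid: score_z.get((sid, 0), 0.0) for sid, *_ in pat_meta},
        "subject_index": subject_index,
    }
    return SyntheticCohort(cfg, parc, atlas, template, cohort, longterm,
                           masks, matrices, truth)
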