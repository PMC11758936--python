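"""Atlas-based structural disconnectomes from binary lesion masks.

A subject's structural disconnection between two gray-matter regions is the
proportion of normative-atlas streamlines connecting them that pass through
at least one lesioned voxel. Region pairs that carry no atlas streamlines
are undefined (``structural_mask`` false) and stored as zero; they are
excluded from edge-wise statistics downstream.
"""

from __future__ import annotations

import numpy as np

from .core import (
    SYSTEMS,
    ConnMatrix,
    DomainError,
    GridMismatchError,
    LesionMask,
    Parcellation,
    StreamlineAtlas,
    check_same_grid,
)

__all__ = [
    "voxelize_streamline",
    "disconnection_matrix",
    "lesion_probability_map",
    "disconnection_probability_map",
    "node_strength",
    "system_block_means",
    "total_lesion_volume",
    "log1p_tlv",
]


def voxelize_streamline(polyline: np.ndarray, grid_shape) -> list[tuple[int, int, int]]:
    """Ordered set of voxels traversed by a polyline.

    Uses exact segment traversal: for every polyline segment, the crossing
    parameters with all integer coordinate planes are collected and the voxel
    of each inter-crossing interval is identified from its midpoint. This is
    deterministic and resolution independent, and by construction contains
    every voxel any segment passes through. A point exactly on a voxel
    boundary belongs to the higher-index voxel.

    Parameters
    ----------
    polyline : (m, 3) array of continuous voxel coordinates.
    grid_shape : tuple of int

    Returns
    -------
    list of (i, j, k) voxel index tuples, in traversal order, without
    repeats.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 1:
        raise ValueError("polyline must be a nonempty (m, 3) array")
    shape = np.asarray(grid_shape, dtype=float)
    if (pts < 0).any() or (pts >= shape).any():
        raise ValueError("polyline point outside grid bounds")

    out: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int, int]] = set()

    def add(v: tuple[int, int, int]) -> None:
        if v not in seen:
            seen.add(v)
            out.append(v)

    add(tuple(int(np.floor(c)) for c in pts[0]))
    hi = np.asarray(grid_shape, dtype=int) - 1
    for p0, p1 in zip(pts[:-1], pts[1:]):
        d = p1 - p0
        ts = [1.0]
        for ax in range(3):
            if d[ax] == 0.0:
                continue
            lo_c, hi_c = sorted((p0[ax], p1[ax]))
            for m in range(int(np.floor(lo_c)) + 1, int(np.floor(hi_c)) + 1):
                t = (m - p0[ax]) / d[ax]
                if 0.0 < t < 1.0:
                    ts.append(t)
        ts = sorted(set(ts))
        prev = 0.0
        for t in ts:
            mid = p0 + 0.5 * (prev + t) * d
            vox = np.minimum(np.floor(mid).astype(int), hi)
            add((int(vox[0]), int(vox[1]), int(vox[2])))
            prev = t
        add(tuple(int(np.floor(c)) for c in p1))
    return out


def _transected(mask: LesionMask, atlas: StreamlineAtlas) -> np.ndarray:
    """Boolean vector: does each atlas streamline cross a lesioned voxel."""
    check_same_grid(mask.data.shape, mask.space_tag, atlas.grid_shape, atlas.space_tag)
    flat = mask.data.ravel()
    return np.fromiter(
        (bool(flat[lin].any()) for lin in atlas.streamline_voxels()),
        dtype=bool,
        count=len(atlas.streamlines),
    )


def disconnection_matrix(
    mask: LesionMask,
    atlas: StreamlineAtlas,
    parcellation: Parcellation | None = None,
    node_ids=None,
    system_labels=None,
) -> ConnMatrix:
    """Subject-level structural disconnection matrix.

    For each region pair connected in the atlas, the entry is the fraction
    of that pair's streamlines with at least one traversed voxel lesioned.
    A streamline counts as transected as soon as one of its voxels is
    lesioned (binary criterion).

    Node identity comes from ``parcellation`` if given, else from explicit
    ``node_ids``/``system_labels``, else from the atlas pair labels.
    """
    if parcellation is not None:
        node_ids = parcellation.node_ids
        system_labels = parcellation.systems
    if node_ids is None:
        present = sorted({i for (i, j), _ in atlas.streamlines} | {j for (i, j), _ in atlas.streamlines})
        node_ids = np.asarray(present if present else [], dtype=int)
    node_ids = np.asarray(node_ids)
    index = {int(n): pos for pos, n in enumerate(node_ids)}
    n = len(node_ids)

    hit = _transected(mask, atlas)
    hits = np.zeros((n, n), dtype=float)
    counts = np.zeros((n, n), dtype=float)
    for s, (pair, _) in enumerate(atlas.streamlines):
        a, b = index[pair[0]], index[pair[1]]
        counts[a, b] += 1
        if hit[s]:
            hits[a, b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(counts > 0, hits / np.where(counts > 0, counts, 1.0), 0.0)
    vals = vals + vals.T
    struct = (counts + counts.T) > 0
    np.fill_diagonal(struct, False)
    return ConnMatrix(
        values=vals,
        node_ids=node_ids,
        kind="disconnection",
        system_labels=None if system_labels is None else np.asarray(system_labels),
        structural_mask=struct,
    )


def lesion_probability_map(masks: list[LesionMask]) -> np.ndarray:
    """Voxel-wise probability of containing a lesion across subjects."""
    if len(masks) == 0:
        raise ValueError("need at least one lesion mask")
    shape, tag = masks[0].data.shape, masks[0].space_tag
    for m in masks[1:]:
        check_same_grid(shape, tag, m.data.shape, m.space_tag)
    return np.mean([m.data for m in masks], axis=0)


def disconnection_probability_map(masks: list[LesionMask], atlas: StreamlineAtlas) -> np.ndarray:
    """Voxel-wise probability of >= 1 streamline intersecting a lesion.

    For each subject, every voxel traversed by any streamline that crosses
    that subject's lesions is marked; the map is the across-subject mean of
    these indicator volumes.
    """
    if len(masks) == 0:
        raise ValueError("need at least one lesion mask")
    total = np.zeros(atlas.grid_shape, dtype=float)
    lin_all = atlas.streamline_voxels()
    for mask in masks:
        hit = _transected(mask, atlas)
        ind = np.zeros(int(np.prod(atlas.grid_shape)), dtype=bool)
        for s in np.flatnonzero(hit):
            ind[lin_all[s]] = True
        total += ind.reshape(atlas.grid_shape)
    return total / len(masks)


def node_strength(m: ConnMatrix) -> np.ndarray:
    """Per-node strength: sum of all edge values attached to each node."""
    return m.values.sum(axis=1) - np.diag(m.values)


def system_block_means(m: ConnMatrix) -> tuple[np.ndarray, list[str]]:
    """Average edge value per ordered pair of functional systems.

    Within-system blocks exclude the diagonal. Returns the symmetric block
    matrix and the system order used (canonical order restricted to systems
    present in the matrix).
    """
    if m.system_labels is None:
        raise ValueError("matrix carries no system labels")
    labels = np.asarray(m.system_labels)
    unknown = set(labels) - set(SYSTEMS)
    if unknown:
        raise ValueError(f"unknown system labels: {sorted(unknown)}")
    present = [s for s in SYSTEMS if s in labels]
    k = len(present)
    out = np.full((k, k), np.nan)
    for a, sa in enumerate(present):
        ia = np.flatnonzero(labels == sa)
        for b, sb in enumerate(present[: a + 1]):
            ib = np.flatnonzero(labels == sb)
            block = m.values[np.ix_(ia, ib)]
            if a == b:
                if len(ia) > 1:
                    off = ~np.eye(len(ia), dtype=bool)
                    out[a, b] = block[off].mean()
            else:
                out[a, b] = out[b, a] = block.mean()
    return out, present


def total_lesion_volume(mask: LesionMask) -> float:
    """Total lesion volume in mm^3: voxel count times voxel volume."""
    return float(mask.data.sum()) * mask.voxel_volume


def log1p_tlv(tlv: float) -> float:
    """log(1 + TLV) transform for the positively skewed lesion volume."""
    if tlv < 0:
        raise DomainError("total lesion volume must be nonnegative")
    return float(np.log1p(tlv))
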