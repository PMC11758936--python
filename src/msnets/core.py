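"""Shared containers and conventions for lesion-network analysis.

All volumes live on a single shared voxel grid (the analogue of a common
template space). Points of streamline polylines are expressed in continuous
voxel coordinates: voxel ``i`` spans the half-open interval ``[i, i + 1)``
along each axis, so a point lying exactly on a voxel boundary belongs to the
higher-index voxel. Voxel centers sit at ``i + 0.5``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of the functional systems used to aggregate edges:
#: seven cortical systems plus one subcortical group.
SYSTEMS = ("VIS", "SM", "DAN", "VAN", "limbic", "CONT", "DMN", "SUBC")

#: Names of the five vertex-level morphometric features, in column order.
FEATURES = ("thickness", "volume", "area", "curvature", "sulcal_depth")


class GridMismatchError(ValueError):
    """Two objects do not share the same voxel grid / space tag."""


class CapacityError(ValueError):
    """The voxel grid is too small to host the requested regions."""


class DesignError(ValueError):
    """A design/confound matrix is rank deficient or otherwise unusable."""


class DomainError(ValueError):
    """An input value lies outside its admissible domain."""


@dataclass
class LesionMask:
    """Binary lesion mask on the shared grid.

    Parameters
    ----------
    data : ndarray
        3-D array with values in {0, 1}.
    voxel_size : tuple of float
        Edge length of a voxel in mm per axis.
    space_tag : str
        Identifier of the shared grid; objects combined in an analysis must
        carry the same tag.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    space_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("lesion mask must be a 3-D volume")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("lesion mask values must be binary")
        self.data = self.data.astype(np.uint8)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class StreamlineAtlas:
    """Labeled streamline polylines on the shared grid.

    ``streamlines`` is a list of ``((i, j), points)`` tuples where ``i < j``
    are node ids of the two endpoint regions and ``points`` is an ``(m, 3)``
    array of continuous voxel coordinates.
    """

    streamlines: list[tuple[tuple[int, int], np.ndarray]]
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    space_tag: str = "synthetic"
    _voxel_cache: list[np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        norm = []
        for (i, j), pts in self.streamlines:
            i, j = int(i), int(j)
            if not i < j:
                raise ValueError(f"streamline pair must satisfy i < j, got ({i}, {j})")
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 1:
                raise ValueError("polyline must be a nonempty (m, 3) array")
            if (pts < 0).any() or (pts >= np.asarray(self.grid_shape)).any():
                raise ValueError("polyline points must lie inside the grid")
            norm.append(((i, j), pts))
        self.streamlines = norm

    @property
    def pair_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for pair, _ in self.streamlines:
            counts[pair] = counts.get(pair, 0) + 1
        return counts

    def streamline_voxels(self) -> list[np.ndarray]:
        """Linear voxel indices traversed by each streamline (cached)."""
        from .disconnectome import voxelize_streamline

        if self._voxel_cache is None:
            cache = []
            for _, pts in self.streamlines:
                vox = voxelize_streamline(pts, self.grid_shape)
                lin = np.ravel_multi_index(np.asarray(vox, dtype=np.intp).T, self.grid_shape)
                cache.append(lin)
            self._voxel_cache = cache
        return self._voxel_cache


@dataclass
class Parcellation:
    """Label volume plus node table on the shared grid.

    The node table has columns ``node_id`` (positive integer label),
    ``name`` and ``system`` (one of :data:`SYSTEMS`). Label 0 is background;
    ``ventricle_mask`` marks the ventricle proxy at the grid center, which is
    part of the background but anchors the periventricular lesion bias.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    node_table: pd.DataFrame
    ventricle_mask: np.ndarray | None = None
    space_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def node_ids(self) -> np.ndarray:
        return self.node_table["node_id"].to_numpy()

    @property
    def systems(self) -> np.ndarray:
        return self.node_table["system"].to_numpy()

    @property
    def n_nodes(self) -> int:
        return len(self.node_table)

    def region_voxels(self, node_id: int) -> np.ndarray:
        """(m, 3) integer voxel coordinates of one region."""
        return np.argwhere(self.labels == node_id)


@dataclass
class ConnMatrix:
    """Symmetric node-by-node connectivity matrix with node metadata.

    ``kind`` is ``"disconnection"`` (values in [0, 1], proportion of atlas
    streamlines between two regions transected by lesions) or
    ``"similarity"`` (morphometric similarity in (0, 1]). The diagonal is
    zero by convention and excluded from all statistics. For disconnection
    matrices ``structural_mask`` flags node pairs that carry atlas
    streamlines; pairs outside the mask are undefined and stored as 0.
    """

    values: np.ndarray
    node_ids: np.ndarray
    kind: str
    system_labels: np.ndarray | None = None
    structural_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind not in ("disconnection", "similarity"):
            raise ValueError(f"unknown matrix kind: {self.kind!r}")
        self.values = v
        self.node_ids = np.asarray(self.node_ids)
        if len(self.node_ids) != v.shape[0]:
            raise ValueError("node_ids length must match matrix size")
        if self.system_labels is not None:
            self.system_labels = np.asarray(self.system_labels)
            if len(self.system_labels) != v.shape[0]:
                raise ValueError("system_labels length must match matrix size")
        if self.kind == "disconnection":
            if (v < -1e-12).any() or (v > 1 + 1e-12).any():
                raise ValueError("disconnection values must lie in [0, 1]")
            if self.structural_mask is not None:
                m = np.asarray(self.structural_mask, dtype=bool)
                if m.shape != v.shape or not (m == m.T).all():
                    raise ValueError("structural_mask must be a symmetric boolean matrix")
                if (v[~m] != 0).any():
                    raise ValueError("values outside the structural mask must be 0")
                self.structural_mask = m

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "ConnMatrix":
        return dataclasses.replace(
            self,
            values=self.values.copy(),
            structural_mask=None if self.structural_mask is None else self.structural_mask.copy(),
        )


def upper_triangle_mask(n: int) -> np.ndarray:
    """Boolean mask of strict upper-triangle entries of an n x n matrix."""
    return np.triu(np.ones((n, n), dtype=bool), k=1)


def check_same_grid(a_shape: Sequence[int], a_tag: str, b_shape: Sequence[int], b_tag: str) -> None:
    if tuple(a_shape) != tuple(b_shape) or a_tag != b_tag:
        raise GridMismatchError(
            f"objects live on different grids: {tuple(a_shape)}/{a_tag} vs {tuple(b_shape)}/{b_tag}"
        )
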