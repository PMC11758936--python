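"""Readers and writers for the pipeline's on-disk formats.

Volumes are NIfTI (via nibabel, affine scaled by the voxel size); matrices
are TSV with node ids in the header; streamlines are JSON-lines (one
``{"pair": [i, j], "points": [[x, y, z], ...]}`` object per line) with an
optional TRK export; tables are TSV; configurations are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import ConnMatrix, LesionMask, Parcellation, StreamlineAtlas
from .synthetic import SimConfig

__all__ = [
    "write_volume", "read_lesion_mask", "write_parcellation", "read_parcellation",
    "write_matrix", "read_matrix", "write_streamlines_jsonl", "read_streamlines_jsonl",
    "write_streamlines_trk", "write_table", "read_table", "load_sim_config",
    "dump_sim_config",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def write_volume(data: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(data).astype(np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def read_lesion_mask(path, space_tag: str = "synthetic") -> LesionMask:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = (np.asanyarray(img.dataobj) > 0.5).astype(np.uint8)
    return LesionMask(data, vs, space_tag)


def write_parcellation(parc: Parcellation, volume_path, table_path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), _affine(parc.voxel_size))
    nib.save(img, str(volume_path))
    parc.node_table.to_csv(table_path, sep="\t", index=False)


def read_parcellation(volume_path, table_path, space_tag: str = "synthetic") -> Parcellation:
    img = nib.load(str(volume_path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(table_path, sep="\t")
    return Parcellation(labels, vs, table, space_tag=space_tag)


def write_matrix(m: ConnMatrix, path) -> None:
    ids = [str(n) for n in m.node_ids]
    df = pd.DataFrame(m.values, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.10g")
    if m.structural_mask is not None:
        mask_path = Path(str(path)).with_suffix(".mask.tsv")
        pd.DataFrame(m.structural_mask.astype(int), index=ids, columns=ids) \
            .to_csv(mask_path, sep="\t")


def read_matrix(path, kind: str, system_labels=None) -> ConnMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    node_ids = np.asarray([int(c) for c in df.columns])
    mask = None
    mask_path = Path(str(path)).with_suffix(".mask.tsv")
    if kind == "disconnection" and mask_path.exists():
        mask = pd.read_csv(mask_path, sep="\t", index_col=0).to_numpy(dtype=bool)
    return ConnMatrix(df.to_numpy(dtype=float), node_ids, kind,
                      system_labels=system_labels, structural_mask=mask)


def write_streamlines_jsonl(atlas: StreamlineAtlas, path) -> None:
    with open(path, "w") as fh:
        header = {"grid_shape": list(atlas.grid_shape),
                  "voxel_size": list(atlas.voxel_size),
                  "space_tag": atlas.space_tag}
        fh.write(json.dumps({"header": header}) + "\n")
        for (i, j), pts in atlas.streamlines:
            fh.write(json.dumps({"pair": [int(i), int(j)],
                                 "points": np.round(pts, 6).tolist()}) + "\n")


def read_streamlines_jsonl(path) -> StreamlineAtlas:
    streamlines = []
    header = None
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            if "header" in obj:
                header = obj["header"]
            else:
                streamlines.append((tuple(obj["pair"]), np.asarray(obj["points"], dtype=float)))
    if header is None:
        raise ValueError("streamline file lacks a header line")
    return StreamlineAtlas(streamlines, tuple(header["grid_shape"]),
                           tuple(header["voxel_size"]), header["space_tag"])


def write_streamlines_trk(atlas: StreamlineAtlas, path) -> None:
    """Optional TRK export (points converted to mm via the voxel size)."""
    from nibabel.streamlines import Tractogram, save as trk_save

    vs = np.asarray(atlas.voxel_size)
    tract = Tractogram([pts * vs for _, pts in atlas.streamlines],
                       affine_to_rasmm=np.eye(4))
    trk_save(tract, str(path))


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("grid_shape", "lesion_radius_range", "visits_per_subject",
                "followup_years", "longterm_years", "classifiers"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    for key in ("planted_disconnection_edges", "planted_similarity_edges"):
        if key in raw:
            raw[key] = [tuple(e) for e in raw[key]]
    return SimConfig(**raw)


def dump_sim_config(cfg: SimConfig, path) -> None:
    import dataclasses

    raw = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
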