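"""Delimited-text and NIfTI input/output.

Time-courses travel as tab-separated text — first row component labels,
one row per retained volume — with an optional JSON sidecar
(``<name>.json``) carrying the sampling interval, neuronal flags and
provenance.  Tables use full-precision floats so a write/read round trip
is lossless.  Spatial components and templates use NIfTI volumes (one
4-D image, last axis = component).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .rsn import SpatialComponentSet, TemplateSet
from .timecourses import TimeCourseSet

__all__ = [
    "read_timecourses",
    "write_timecourses",
    "read_table",
    "write_table",
    "read_motion_trace",
    "write_motion_trace",
    "save_components",
    "load_components",
    "save_templates",
    "load_templates",
]

_FLOAT_FORMAT = "%.17g"  # round-trips IEEE doubles exactly


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timecourses(tcs: TimeCourseSet, path: str | Path) -> Path:
    """Write one subject's time-courses as TSV plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(tcs.data, columns=tcs.labels)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    sidecar = {
        "sampling_interval": tcs.sampling_interval,
        "neuronal": {lab: bool(f) for lab, f in zip(tcs.labels, tcs.neuronal)},
        **{k: v for k, v in tcs.meta.items() if isinstance(v, (str, int, float, bool))},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_timecourses(path: str | Path) -> TimeCourseSet:
    """Read a TSV of labelled time-courses (and its sidecar, if present).

    Raises :class:`SchemaError` on ragged rows, duplicate labels or
    non-numeric cells; :class:`FileNotFoundError` for a missing file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise SchemaError(f"{path}: need a header row and at least one data row")
    labels = lines[0].split("\t")
    if len(set(labels)) != len(labels):
        raise SchemaError(f"{path}: duplicate column labels")
    rows = []
    for k, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(labels):
            raise SchemaError(
                f"{path}: row {k} has {len(cells)} cells, expected {len(labels)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise SchemaError(f"{path}: non-numeric cell in row {k}") from exc
    data = np.asarray(rows)
    sampling_interval, neuronal, meta = 2.0, None, {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        record = json.loads(sidecar.read_text())
        sampling_interval = float(record.pop("sampling_interval", 2.0))
        flags = record.pop("neuronal", None)
        if flags is not None:
            try:
                neuronal = np.array([bool(flags[lab]) for lab in labels])
            except KeyError as exc:
                raise SchemaError(f"{sidecar}: neuronal flags miss label {exc}") from exc
        meta = record
    return TimeCourseSet(
        data=data,
        labels=labels,
        sampling_interval=sampling_interval,
        neuronal=neuronal,
        meta=meta,
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy table as TSV at full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_motion_trace(path: str | Path) -> np.ndarray:
    """Read a 6-column realignment-parameter file (3 translations mm,
    3 rotations rad; whitespace- or tab-delimited)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        trace = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise SchemaError(f"{path}: malformed motion file") from exc
    if trace.shape[1] != 6:
        raise SchemaError(f"{path}: expected 6 columns, found {trace.shape[1]}")
    return trace


def write_motion_trace(trace: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(trace, dtype=float), fmt=_FLOAT_FORMAT, delimiter="\t")
    return path


def _identity_affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_components(components: SpatialComponentSet, path: str | Path) -> Path:
    """Save component maps as one 4-D NIfTI (last axis = component)."""
    path = Path(path)
    vol = np.moveaxis(components.maps, 0, -1)
    nib.save(nib.Nifti1Image(vol, _identity_affine(components.voxel_size)), path)
    return path


def load_components(path: str | Path, ids: list[str] | None = None) -> SpatialComponentSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise SchemaError(f"{path}: expected a 4-D component image")
    maps = np.moveaxis(vol, -1, 0)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if ids is None:
        ids = [f"IC{k + 1:02d}" for k in range(maps.shape[0])]
    return SpatialComponentSet(maps=maps, ids=ids, voxel_size=voxel_size)


def save_templates(templates: TemplateSet, path: str | Path) -> Path:
    """Save template masks as one 4-D NIfTI plus a names sidecar."""
    path = Path(path)
    vol = np.moveaxis(templates.masks.astype(np.uint8), 0, -1)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), path)
    _sidecar_path(path).write_text(json.dumps({"names": templates.names}, indent=2))
    return path


def load_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    vol = np.asarray(img.dataobj)
    if vol.ndim != 4:
        raise SchemaError(f"{path}: expected a 4-D template image")
    masks = np.moveaxis(vol, -1, 0) > 0
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        names = json.loads(sidecar.read_text())["names"]
    else:
        names = [f"template-{k:02d}" for k in range(masks.shape[0])]
    return TemplateSet(names=names, masks=masks)
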