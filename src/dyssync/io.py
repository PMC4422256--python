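"""File formats: NIfTI stacks and fields, PLY meshes, CSV tables, YAML config.

Conventions embedded in every file: world coordinates in mm with an
identity orientation (short-axis slices orthogonal to +z), times in ms,
phase index 0 = end-diastole, displacement fields ED-referenced.
Image stacks are 4D NIfTI ``(x, y, z, phase)``; displacement fields are
5D NIfTI ``(x, y, z, phase, component)`` in mm.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from dyssync.errors import InvalidInputError
from dyssync.mechanics import DeformationField, SegmentCurves
from dyssync.sdi import SDIResult

__all__ = [
    "save_stack",
    "load_stack",
    "save_field",
    "load_field",
    "save_mesh",
    "load_mesh",
    "save_curves",
    "load_curves",
    "save_sdi_result",
    "load_sdi_result",
    "save_cohort",
    "load_cohort",
    "save_config",
    "load_config",
]


def _affine(origin, spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
    aff[:3, 3] = np.asarray(origin, dtype=float)
    return aff


def save_stack(path, stack: np.ndarray, origin, spacing) -> None:
    """Write a phase-indexed image stack as 4D NIfTI (x, y, z, phase)."""
    data = np.moveaxis(np.asarray(stack), 0, -1)  # internal (phase, x, y, z)
    nib.save(nib.Nifti1Image(data, _affine(origin, spacing)), str(path))


def load_stack(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a 4D NIfTI stack; returns (stack[phase, x, y, z], origin, spacing)."""
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    aff = img.affine
    return data, aff[:3, 3].copy(), np.diag(aff)[:3].copy()


def save_field(path, field: DeformationField, times_path=None) -> None:
    """Write a displacement field as 5D NIfTI (x, y, z, phase, component), mm.

    Phase times (and the mask, if present) go to a JSON sidecar next to
    the volume so the field round-trips losslessly.
    """
    data = np.moveaxis(field.disp, 0, 3)  # (x, y, z, phase, 3)
    nib.save(nib.Nifti1Image(data, _affine(field.origin, field.spacing)), str(path))
    sidecar = Path(times_path) if times_path else Path(str(path)).with_suffix("").with_suffix(".json")
    meta = {
        "phase_times_ms": field.phase_times_ms.tolist(),
        "mask_voxels": np.stack(np.nonzero(field.mask)).tolist() if field.mask is not None else None,
        "displacement_reference": "end-diastole (phase 0)",
        "units": "mm",
    }
    sidecar.write_text(json.dumps(meta))


def load_field(path, times_path=None) -> DeformationField:
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), 3, 0)
    aff = img.affine
    sidecar = Path(times_path) if times_path else Path(str(path)).with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    mask = None
    if meta.get("mask_voxels") is not None:
        mask = np.zeros(data.shape[1:4], dtype=bool)
        idx = np.asarray(meta["mask_voxels"])
        mask[idx[0], idx[1], idx[2]] = True
    return DeformationField(
        disp=data,
        origin=aff[:3, 3].copy(),
        spacing=np.diag(aff)[:3].copy(),
        phase_times_ms=np.asarray(meta["phase_times_ms"], dtype=float),
        mask=mask,
    )


def save_mesh(path, mesh, labels: np.ndarray | None = None) -> None:
    """Write a surface as PLY; optional per-face segment labels as a sidecar CSV."""
    mesh.export(str(path))
    if labels is not None:
        pd.DataFrame({"face": np.arange(len(labels)), "segment": labels}).to_csv(
            Path(str(path)).with_suffix(".labels.csv"), index=False
        )


def load_mesh(path):
    import trimesh

    return trimesh.load(str(path), process=False)


_CURVE_COLUMNS = ["measure", "segment", "phase_time_ms", "value", "cycle_length_ms"]


def save_curves(path, curves: SegmentCurves) -> None:
    """Write segment curves as tidy CSV (measure, segment, phase_time_ms, value)."""
    seg, ph = np.meshgrid(np.arange(1, curves.values.shape[0] + 1),
                          np.arange(len(curves.times_ms)), indexing="ij")
    pd.DataFrame(
        {
            "measure": curves.measure,
            "segment": seg.ravel(),
            "phase_time_ms": curves.times_ms[ph.ravel()],
            "value": curves.values.ravel(),
            "cycle_length_ms": curves.cycle_length_ms,
        }
    ).to_csv(path, index=False)


def load_curves(path) -> SegmentCurves:
    df = pd.read_csv(path)
    missing = [c for c in _CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required column(s) {missing}")
    segments = np.sort(df["segment"].unique())
    times = np.sort(df["phase_time_ms"].unique())
    values = (
        df.pivot_table(index="segment", columns="phase_time_ms", values="value", dropna=False)
        .reindex(index=segments, columns=times)
        .to_numpy()
    )
    return SegmentCurves(
        measure=str(df["measure"].iloc[0]),
        values=values,
        times_ms=times,
        cycle_length_ms=float(df["cycle_length_ms"].iloc[0]),
    )


def save_sdi_result(path, result: SDIResult) -> None:
    payload = asdict(result)
    payload["peak_times_ms"] = [None if not np.isfinite(t) else float(t) for t in result.peak_times_ms]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_sdi_result(path) -> SDIResult:
    payload = json.loads(Path(path).read_text())
    payload["peak_times_ms"] = np.array(
        [np.nan if t is None else t for t in payload["peak_times_ms"]], dtype=float
    )
    return SDIResult(**payload)


def save_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


_COHORT_REQUIRED = ["sdi", "qrs_ms", "qrs_morphology", "scar_burden", "esv_pre", "esv_post"]


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required column(s) {missing}")
    return df


def _pyify(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(_pyify(config), sort_keys=False))


def load_config(path) -> dict:
    out = yaml.safe_load(Path(path).read_text())
    if not isinstance(out, dict):
        raise InvalidInputError(f"{path}: config must be a YAML mapping")
    return out
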