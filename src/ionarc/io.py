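"""File formats: NRRD volumes (via SimpleITK), beam-table CSV, JSON metadata."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from ionarc.beam import BeamLibrary, DepthProfileTable


def write_nrrd(path, array: np.ndarray, voxel_size: float) -> None:
    """Write a (nx, ny, nz) grid as NRRD, isocenter at the volume center."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.asarray(array, dtype=np.float32).transpose(2, 1, 0)))
    img.SetSpacing((voxel_size,) * 3)
    extent = np.array(array.shape) * voxel_size
    img.SetOrigin(tuple(-extent / 2 + voxel_size / 2))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_nrrd(path) -> tuple:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, float(img.GetSpacing()[0])


def table_to_frame(table: DepthProfileTable) -> pd.DataFrame:
    """Depth table as a flat CSV-ready frame (per-component columns)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cols = {
            "depth_mm": table.depth,
            "dose_per_primary": table.dose_per_primary,
            "sigma_mm": table.lateral_sigma,
        }
        for c in table.components:
            frac = np.where(table.dose_per_primary > 0,
                            c.dose / np.maximum(table.dose_per_primary, 1e-300), 0.0)
            cols[f"{c.name}_dose_fraction"] = frac
            cols[f"{c.name}_LET_keV_um"] = c.track_let
            cols[f"{c.name}_RQE"] = c.rqe
    return pd.DataFrame(cols)


def write_beam_library(library: BeamLibrary, outdir) -> list:
    """One CSV per (ion, energy) plus a JSON sidecar of generation parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for label, by_e in library.tables.items():
        for e, tab in sorted(by_e.items()):
            p = outdir / f"{label}_{e:.2f}MeVu.csv"
            table_to_frame(tab).to_csv(p, index=False, float_format="%.6g")
            written.append(p)
    sidecar = outdir / "generation_parameters.json"
    sidecar.write_text(json.dumps(library.generation_parameters(), indent=2))
    written.append(sidecar)
    return written


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, paths) -> Path:
    manifest = {str(Path(p).name): sha256_of(p) for p in paths}
    mpath = Path(outdir) / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath
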