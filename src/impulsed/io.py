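"""NIfTI and CSV I/O helpers with validation and reproducibility headers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["read_nifti", "write_nifti", "read_mask", "write_table",
           "read_table", "write_manifest"]

#: unit annotations for known table columns
COLUMN_UNITS = {
    "d_mean": "um", "f_in": "dimensionless", "D_ex": "um^2/ms",
    "cellularity": "um^-1", "b": "s/mm^2", "S_over_S0": "dimensionless",
    "lesion_diameter_mm": "mm",
}


def read_nifti(path: str | Path, expected_acqs: int | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (float data, affine).

    If ``expected_acqs`` is given the image must be 4D with that many
    acquisitions on the last axis (x, y, z, acquisition order).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if expected_acqs is not None:
        if data.ndim != 4:
            raise ValueError(
                f"{path}: expected a 4D volume with {expected_acqs} "
                f"acquisitions, got a {data.ndim}D image")
        if data.shape[-1] != expected_acqs:
            raise ValueError(
                f"{path}: expected {expected_acqs} acquisitions, "
                f"got {data.shape[-1]}")
    return data, img.affine


def write_nifti(volume: np.ndarray, affine: np.ndarray | None,
                path: str | Path) -> None:
    """Write ``volume`` as float32 NIfTI-1; 4D axis order is (x, y, z, acq)."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_intent("estimate", name="axis order x,y,z,acquisition")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary lesion mask; rejects non-{0,1} values."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{path}: mask must contain only 0/1 values, "
                         f"found {vals[:10]}")
    return data.astype(bool), img.affine


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                **meta) -> None:
    """Write a CSV with commented header lines recording seed, units, meta."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    units = {c: COLUMN_UNITS[c] for c in df.columns if c in COLUMN_UNITS}
    units.update({c: "um^2/ms" for c in df.columns if c.startswith("ADC_")})
    if units:
        lines.append("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()))
    for k, v in meta.items():
        lines.append(f"# {k}={v}")
    with open(path, "w") as fh:
        for ln in lines:
            fh.write(ln + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_manifest(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Persist a run manifest: versions, seed and a hash of the config."""
    import scipy

    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
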