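"""NIfTI round-tripping, subject manifests, YAML configs and the canonical
high-res working grid (184 x 202 x 72 voxels of 1 x 1 x 1.5 mm)."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grids import Grid, RigidTransform, Volume, resample

__all__ = [
    "CANONICAL_GRID",
    "read_volume",
    "write_volume",
    "write_mask",
    "to_workspace",
    "read_manifest",
    "write_manifest",
    "load_config",
    "write_run_record",
]

#: The canonical template-aligned working grid for all high-res model I/O.
CANONICAL_GRID = Grid.from_spacing((184, 202, 72), (1.0, 1.0, 1.5))

MANIFEST_COLUMNS = [
    "id", "t1_path", "flair_path", "flair_mask_path", "rigid_path", "split",
    "corrected",
]


def read_volume(path) -> Volume:
    """Read a 3D NIfTI (plain or gzipped) into a Volume."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as e:
        raise IOError(f"cannot read NIfTI volume {path}: {e}") from None
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return Volume(data, Grid(data.shape, img.affine))


def write_volume(vol: Volume, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.grid.affine)
    nib.save(img, str(path))


def write_mask(vol: Volume, path) -> None:
    """Masks go out as unsigned 8-bit."""
    write_volume(Volume((np.asarray(vol.data) > 0.5).astype(np.uint8), vol.grid),
                 path, dtype=np.uint8)


def to_workspace(t1: Volume, transform=None, target: Grid = CANONICAL_GRID) -> Volume:
    """Resample a T1 onto the canonical working grid given a provided
    subject-to-template affine (registration itself is external); None means
    the input is already aligned ("--assume-aligned")."""
    if transform is None and t1.grid == target:
        return t1
    return resample(t1, target, transform=transform, mode="trilinear")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in ("id", "t1_path") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    if df["id"].duplicated().any():
        raise ValueError("manifest ids must be unique")
    if "split" in df.columns:
        bad = set(df["split"].dropna()) - {"train", "test"}
        if bad:
            raise ValueError(f"invalid split values: {sorted(bad)}")
    return df


def write_manifest(rows, path) -> None:
    df = pd.DataFrame(rows)
    for c in MANIFEST_COLUMNS:
        if c not in df.columns:
            df[c] = "" if c != "corrected" else False
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_run_record(out_dir, config: dict, seed: int) -> Path:
    """Reproducibility record written alongside every CLI output."""
    import wmlseg

    record = {
        "config": config,
        "seed": seed,
        "versions": {
            "wmlseg": wmlseg.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "nibabel": nib.__version__,
        },
    }
    out = Path(out_dir) / "run_record.json"
    out.write_text(json.dumps(record, indent=2, default=str))
    return out
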