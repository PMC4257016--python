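"""NIfTI and manifest helpers shared across the pipeline stages."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(data: np.ndarray, voxel_size, path: str | Path,
               dtype=np.float32) -> Path:
    """Write an array as NIfTI-1 with a diagonal affine from the voxel size."""
    path = Path(path)
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    zooms = list(voxel_size[:3]) + ([1.0] * (data.ndim - 3))
    img.header.set_zooms(zooms[:data.ndim])
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a NIfTI file; returns (data, voxel size in mm)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), tuple(float(z) for z in
                                              img.header.get_zooms()[:3])


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict,
                   artifacts: dict[str, str | Path]) -> Path:
    """Record config and content hashes of every written artifact."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "version": __version__,
        "config": config,
        "artifacts": {name: {"path": str(p), "sha256": sha256_of(p)}
                      for name, p in artifacts.items()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
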