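"""NIfTI-1 volume I/O (thin wrappers over nibabel)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["write_volume", "read_volume", "VolumeReadError"]


class VolumeReadError(IOError):
    """Raised when a volume file cannot be parsed as NIfTI-1."""


def write_volume(data, affine, path):
    """Write an array with its affine as NIfTI-1 (.nii or .nii.gz)."""
    data = np.asarray(data)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    img = nib.Nifti1Image(data, np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return Path(path)


def read_volume(path):
    """Read a NIfTI-1 volume; returns ``(data, affine)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        return np.asarray(img.get_fdata()), img.affine
    except Exception as exc:  # nibabel raises several header-specific types
        raise VolumeReadError(f"cannot parse {path} as NIfTI-1: {exc}") from exc
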