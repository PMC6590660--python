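"""Synthetic 3-D brain-like phantom with forward-simulated sequence signals.

The phantom is a nested-ellipsoid layout — CSF surround, gray-matter shell,
white-matter core, and small spherical deep-gray nuclei — with per-tissue
T1/T2*/M0, a smooth low-order-polynomial relative transmit field, and Rician
magnitude noise.  Signals at every voxel come from the same steady-state
Bloch model used for quantification, so a noiseless phantom round-trips the
full pipeline to within grid quantization.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import DEFAULT_TISSUES, ProtocolParams, TissueParams
from .sequence_model import _center_mz, uni_combination

__all__ = ["PhantomConfig", "VolumeSet", "generate_phantom", "make_labels",
           "make_b1_field"]


@dataclass
class PhantomConfig:
    """Configuration of one synthetic acquisition.

    ``snr`` is the magnitude signal-to-noise ratio referenced to the
    white-matter first-echo signal of the second inversion at nominal B1;
    ``snr <= 0`` or ``None`` disables noise.  ``b1_range`` bounds the smooth
    relative transmit field.  ``b1_decimate`` optionally emulates a separately
    acquired low-resolution B1 map by block-averaging with the given integer
    factor.
    """

    grid_shape: tuple = (64, 64, 64)
    voxel_size: float = 0.64                      # mm, isotropic
    tissue_table: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    b1_range: tuple = (0.8, 1.2)
    snr: float | None = 30.0
    seed: int = 0
    b1_decimate: int | None = None


@dataclass
class VolumeSet:
    """Simulated volumes plus ground truth, sharing one affine."""

    uni: np.ndarray                       # noisy UNI image
    inv1_mag: np.ndarray                  # first-inversion magnitude
    inv2_mag: list                        # second-inversion magnitudes per echo
    inv2_phase: list                      # synthetic smooth phase per echo
    b1_map: np.ndarray                    # as "acquired" (possibly low-res)
    b1_true: np.ndarray                   # voxelwise truth on the image grid
    labels: np.ndarray
    t1_true: np.ndarray
    t2star_true: np.ndarray
    m0_true: np.ndarray
    affine: np.ndarray
    tes: tuple
    noise_sd: float


def make_labels(grid_shape) -> np.ndarray:
    """Nested-ellipsoid label volume (labels per ``DEFAULT_TISSUES``)."""
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
                          np.linspace(-1, 1, nz), indexing="ij")
    labels = np.full(grid_shape, 9, dtype=np.int16)       # CSF surround
    r_gm = (x / 0.92) ** 2 + (y / 0.88) ** 2 + (z / 0.85) ** 2
    r_wm = (x / 0.72) ** 2 + (y / 0.68) ** 2 + (z / 0.64) ** 2
    labels[r_gm <= 1] = 2                                 # GM shell
    labels[r_wm <= 1] = 1                                 # WM core
    nuclei = {  # label: (center in normalized coords, radius)
        3: ((0.22, 0.18, 0.10), 0.16),
        4: ((-0.25, 0.15, 0.05), 0.17),
        5: ((0.00, -0.25, 0.12), 0.20),
        6: ((0.18, -0.05, -0.28), 0.14),
        7: ((-0.18, -0.08, -0.28), 0.14),
        8: ((0.00, 0.28, -0.25), 0.13),
    }
    for lab, (c, r) in nuclei.items():
        m = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= r ** 2
        labels[m & (labels == 1)] = lab
    return labels


def make_b1_field(grid_shape, b1_range, seed) -> np.ndarray:
    """Smooth quadratic-polynomial transmit field scaled into ``b1_range``."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
                          np.linspace(-1, 1, nz), indexing="ij")
    coeffs = rng.normal(size=9)
    f = (coeffs[0] * x + coeffs[1] * y + coeffs[2] * z
         + coeffs[3] * x * y + coeffs[4] * y * z + coeffs[5] * x * z
         + coeffs[6] * x * x + coeffs[7] * y * y + coeffs[8] * z * z)
    lo, hi = b1_range
    span = f.max() - f.min()
    if span == 0:
        return np.full(grid_shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (f - f.min()) / span


def _block_mean(vol, factor):
    shape = np.asarray(vol.shape)
    trim = (shape // factor) * factor
    v = vol[:trim[0], :trim[1], :trim[2]]
    v = v.reshape(trim[0] // factor, factor, trim[1] // factor, factor,
                  trim[2] // factor, factor)
    return v.mean(axis=(1, 3, 5))


def generate_phantom(cfg: PhantomConfig, p: ProtocolParams) -> VolumeSet:
    """Forward-simulate a full acquisition of the synthetic phantom.

    Per voxel, the steady-state signals of both inversion blocks are computed
    at the local transmit field, decayed to each echo time, and corrupted by
    complex Gaussian noise (Rician magnitudes).  The UNI image is formed from
    the noisy complex first-echo signals, as a scanner would.
    """
    import warnings

    labels = make_labels(cfg.grid_shape)
    b1 = make_b1_field(cfg.grid_shape, cfg.b1_range, cfg.seed)
    t1 = np.zeros(cfg.grid_shape)
    t2s = np.zeros(cfg.grid_shape)
    m0 = np.zeros(cfg.grid_shape)
    for lab, t in cfg.tissue_table.items():
        m = labels == lab
        t1[m], t2s[m], m0[m] = t.t1, t.t2star, t.m0

    tes = tuple(p.te2) if p.te2 else (p.te1,)
    sin1 = np.sin(np.deg2rad(b1 * p.alpha1))
    sin2 = np.sin(np.deg2rad(b1 * p.alpha2))
    s1 = np.zeros(cfg.grid_shape)
    s2 = np.zeros(cfg.grid_shape + (len(tes),))
    for lab, t in cfg.tissue_table.items():
        m = labels == lab
        if not np.any(m):
            continue
        _, mz1, mz2 = _center_mz(p, t.t1, b1[m], t.m0)
        s1[m] = sin1[m] * mz1 * np.exp(-p.te1 / t.t2star)
        for e, te in enumerate(tes):
            s2[..., e][m] = sin2[m] * mz2 * np.exp(-te / t.t2star)

    wm = cfg.tissue_table.get(1)
    _, _, mz2_wm = _center_mz(p, wm.t1, 1.0, wm.m0)
    ref = float(np.sin(np.deg2rad(p.alpha2)) * mz2_wm
                * np.exp(-tes[0] / wm.t2star))
    if cfg.snr is None or cfg.snr <= 0:
        if cfg.snr is not None and cfg.snr <= 0:
            warnings.warn("snr <= 0: generating a noiseless phantom",
                          RuntimeWarning, stacklevel=2)
        sd = 0.0
    else:
        sd = abs(ref) / cfg.snr

    rng = np.random.default_rng(cfg.seed + 1)
    def noisy(signal):
        if sd == 0.0:
            return signal.astype(complex)
        return (signal + rng.normal(scale=sd, size=signal.shape)
                + 1j * rng.normal(scale=sd, size=signal.shape))

    z1 = noisy(s1)
    z2 = [noisy(s2[..., e]) for e in range(len(tes))]
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.abs(z1) ** 2 + np.abs(z2[0]) ** 2
        uni = np.where(denom > 0, np.real(z1 * np.conj(z2[0])) / denom, 0.0)

    # smooth synthetic phase, linear in TE: format completeness for
    # downstream susceptibility tools only, no susceptibility physics
    nx, ny, nz = cfg.grid_shape
    gx, gy, gz = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
                             np.linspace(-1, 1, nz), indexing="ij")
    base = 0.4 * gx + 0.3 * gy * gy - 0.2 * gz
    phases = [np.angle(np.exp(1j * base * te)) for te in tes]

    b1_map = _block_mean(b1, cfg.b1_decimate) if cfg.b1_decimate else b1.copy()
    affine = np.diag([cfg.voxel_size] * 3 + [1.0])
    return VolumeSet(uni=uni, inv1_mag=np.abs(z1),
                     inv2_mag=[np.abs(z) for z in z2], inv2_phase=phases,
                     b1_map=b1_map, b1_true=b1, labels=labels, t1_true=t1,
                     t2star_true=t2s, m0_true=m0, affine=affine, tes=tes,
                     noise_sd=sd)
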