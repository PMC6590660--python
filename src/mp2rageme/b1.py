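"""Transmit-field (B1+) sensitivity of the T1-weighted UNI contrast.

A relative transmit field ``b1`` scales the achieved excitation flip angles,
shifting the UNI-vs-T1 contrast curve.  Two consequences are studied here:
the spread of UNI intensities a single tissue can take across a plausible B1
range, and the bias in T1 ("apparent T1") incurred when a voxel acquired at
``b1 != 1`` is decoded through the nominal (``b1 = 1``) lookup column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolParams, TissueParams
from .quantification import LookupTable2D
from .sequence_model import steady_state_uni

__all__ = [
    "ContrastCurveSet",
    "contrast_curves",
    "intensity_range",
    "apparent_t1",
    "contrast_metrics",
    "DEFAULT_B1_VALUES",
]

DEFAULT_B1_VALUES = (0.8, 1.0, 1.2)


@dataclass
class ContrastCurveSet:
    """UNI-vs-T1 curves, one per relative-B1 value."""

    t1_axis: np.ndarray             # seconds
    b1_values: tuple
    uni_curves: np.ndarray          # shape (len(b1_values), len(t1_axis))
    protocol_name: str = ""


def contrast_curves(p: ProtocolParams, b1_values=DEFAULT_B1_VALUES,
                    t1_axis=None) -> ContrastCurveSet:
    """Simulate the UNI contrast curve at each relative-B1 value."""
    if t1_axis is None:
        t1_axis = np.arange(0.1, 6.0001, 0.005)
    t1_axis = np.asarray(t1_axis, dtype=float)
    b1_values = tuple(float(b) for b in b1_values)
    curves = np.stack([
        np.atleast_1d(steady_state_uni(p, t1_axis, b)) for b in b1_values
    ])
    return ContrastCurveSet(t1_axis=t1_axis, b1_values=b1_values,
                            uni_curves=curves, protocol_name=p.name)


def intensity_range(curves: ContrastCurveSet, t1_ref: float) -> float:
    """Max minus min UNI intensity at ``t1_ref`` across the B1 values."""
    if not (curves.t1_axis[0] <= t1_ref <= curves.t1_axis[-1]):
        raise ValueError("t1_ref outside the simulated T1 axis")
    vals = [np.interp(t1_ref, curves.t1_axis, c) for c in curves.uni_curves]
    return float(max(vals) - min(vals))


def apparent_t1(p: ProtocolParams, true_t1: float, b1_actual: float,
                lut: LookupTable2D):
    """T1 decoded through the *nominal* lookup for a voxel acquired at
    ``b1_actual``.

    Encodes the UNI intensity at the actual transmit field and inverts it on
    the ``b1 = 1`` column; the mismatch is the transmit-field-induced T1
    bias.  Returns ``(t1_s, valid)``; intensities outside the nominal
    monotone branch clamp to the branch ends with ``valid=False``.
    """
    u = float(steady_state_uni(p, true_t1, b1_actual))
    t1, valid = lut.invert(u, b1=1.0)
    return float(t1), bool(np.all(valid))


def contrast_metrics(p: ProtocolParams, tissue_a: TissueParams,
                     tissue_b: TissueParams) -> float:
    """Absolute UNI contrast between two tissues at nominal transmit field."""
    ua = float(steady_state_uni(p, tissue_a.t1, 1.0))
    ub = float(steady_state_uni(p, tissue_b.t1, 1.0))
    return abs(ua - ub)
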