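"""Protocol and tissue parameter definitions for segmented inversion-recovery GRE sequences.

An MP2RAGE-family cycle consists of an adiabatic inversion followed by two
spoiled-GRE readout blocks and a recovery period, repeated every ``tr_cycle``
seconds.  Inversion times (TI) are defined at the temporal *center* of their
readout block, assuming linear (sequential) phase-encode ordering, which is the
standard convention for this sequence family.  All internal timing arithmetic
is carried out in milliseconds; only the cycle TR is expressed in seconds at
the interface, matching how protocols are conventionally printed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "InvalidProtocolError",
    "ProtocolParams",
    "MeGreParams",
    "TissueParams",
    "block_relaxation_times",
    "timing_audit",
    "load_protocol",
    "SIM_TISSUES",
    "DEFAULT_TISSUES",
]


class InvalidProtocolError(ValueError):
    """Raised when a protocol's timing cannot be realised (a negative gap)."""


@dataclass(frozen=True)
class ProtocolParams:
    """Timing and flip-angle description of one MP2RAGE/MP2RAGEME cycle.

    Parameters
    ----------
    tr_cycle : float
        Time between successive inversion pulses, in seconds.
    tr_block1, tr_block2 : float
        Excitation repetition time within the first / second GRE block (ms).
    te1 : float
        Echo time of the (single-echo) first block (ms).
    te2 : tuple of float
        Echo times of the second block (ms).  A single entry degenerates to a
        plain MP2RAGE; the first entry should match ``te1`` so that T2*
        weighting cancels in the UNI combination.
    ti1, ti2 : float
        Inversion times of the two blocks, measured from the inversion pulse
        to the center excitation of the block (ms).
    alpha1, alpha2 : float
        Nominal excitation flip angles of the two blocks (degrees).
    n_lines : int
        Number of excitations (phase-encode lines) per block.
    n_readouts : int
        Number of outer cycles (e.g. partition encodes).
    inv_efficiency : float
        Inversion efficiency in (0, 1]; the adiabatic pulse maps
        ``Mz -> -inv_efficiency * Mz``.
    """

    tr_cycle: float
    tr_block1: float
    tr_block2: float
    te1: float
    te2: tuple = ()
    ti1: float = 0.0
    ti2: float = 0.0
    alpha1: float = 7.0
    alpha2: float = 6.0
    n_lines: int = 150
    n_readouts: int = 1
    inv_efficiency: float = 0.96
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "te2", tuple(float(t) for t in self.te2))
        ta, tb, tc = _gaps(self)
        for gap, value in (("TA", ta), ("TB", tb), ("TC", tc)):
            if value < -1e-9:
                raise InvalidProtocolError(
                    f"protocol {self.name or '<unnamed>'!s}: gap {gap} = "
                    f"{value:.3f} ms is negative; TI placement does not fit "
                    f"the readout blocks"
                )
        if self.te1 >= self.tr_block1:
            raise InvalidProtocolError("te1 must be shorter than tr_block1")
        if self.te2 and max(self.te2) >= self.tr_block2:
            raise InvalidProtocolError("max(te2) must be shorter than tr_block2")
        if not (0.0 < self.inv_efficiency <= 1.0):
            raise InvalidProtocolError("inv_efficiency must be in (0, 1]")


@dataclass(frozen=True)
class MeGreParams:
    """A plain multi-echo spoiled-GRE (FLASH) protocol."""

    tr: float              # ms
    alpha: float           # degrees
    tes: tuple = ()        # ms
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "tes", tuple(float(t) for t in self.tes))


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one tissue class.

    t1 in seconds, t2star in milliseconds, m0 (equilibrium magnetization /
    effective proton density) in arbitrary units.
    """

    t1: float
    t2star: float
    m0: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.t1 <= 0 or self.t2star <= 0 or self.m0 < 0:
            raise ValueError(f"invalid tissue parameters for {self.label!r}")


def _gaps(p: ProtocolParams):
    half = p.n_lines / 2.0
    ta = p.ti1 - half * p.tr_block1
    tb = (p.ti2 - p.ti1) - half * (p.tr_block1 + p.tr_block2)
    tc = p.tr_cycle * 1000.0 - p.ti2 - half * p.tr_block2
    return ta, tb, tc


def block_relaxation_times(p: ProtocolParams):
    """Free-relaxation gaps (TA, TB, TC) of the cycle, in milliseconds.

    TA precedes the first block, TB separates the blocks, TC follows the
    second block until the next inversion.  The inversion pulse itself is
    modelled as instantaneous, so
    ``TA + n*TR1 + TB + n*TR2 + TC == tr_cycle*1000``.
    """
    return _gaps(p)


def timing_audit(p: ProtocolParams) -> dict:
    """Scan duration and dead-time bookkeeping for one protocol.

    Returns a dict with ``scan_duration`` (seconds, ``n_readouts *
    tr_cycle``) and two dead-time percentages.  Both are reported because
    "dead time" admits two natural readings: ``dead_fraction_total`` counts
    all three free-relaxation gaps TA+TB+TC, while ``dead_fraction_tail``
    counts only the terminal recovery gap TC.
    """
    ta, tb, tc = _gaps(p)
    cycle_ms = p.tr_cycle * 1000.0
    return {
        "scan_duration": p.n_readouts * p.tr_cycle,
        "dead_fraction_total": 100.0 * (ta + tb + tc) / cycle_ms,
        "dead_fraction_tail": 100.0 * tc / cycle_ms,
    }


def load_protocol(source):
    """Load a protocol from a YAML file, mapping, or bundled name.

    ``source`` may be a path, a dict, or the name of one of the bundled
    protocols (``mp2rageme``, ``mp2rage``, ``megre``).  A mapping with key
    ``kind: megre`` yields :class:`MeGreParams`; anything else yields
    :class:`ProtocolParams`.
    """
    if isinstance(source, (ProtocolParams, MeGreParams)):
        return source
    if isinstance(source, dict):
        data = dict(source)
    else:
        path = Path(source)
        if not path.suffix and not path.exists():
            ref = resources.files("mp2rageme").joinpath(f"protocols/{source}.yaml")
            if not ref.is_file():
                raise FileNotFoundError(f"no bundled protocol named {source!r}")
            data = yaml.safe_load(ref.read_text())
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh)
    kind = data.pop("kind", "mp2rage")
    if kind == "megre":
        return MeGreParams(**data)
    known = {f.name for f in dataclasses.fields(ProtocolParams)}
    unknown = set(data) - known
    if unknown:
        raise InvalidProtocolError(f"unknown protocol keys: {sorted(unknown)}")
    return ProtocolParams(**data)


#: Tissue parameters used by the B1-sensitivity and blurring simulations.
SIM_TISSUES = {
    "wm": TissueParams(t1=1.15, t2star=26.7, m0=1.0, label="wm"),
    "gm": TissueParams(t1=1.85, t2star=32.4, m0=1.0, label="gm"),
    "csf": TissueParams(t1=4.00, t2star=200.0, m0=1.0, label="csf"),
}

#: Default per-tissue parameters for the synthetic 3-D phantom (T1 in s,
#: T2* in ms).  Values are typical 7 T results for these structures; CSF T2*
#: and the proton densities are generic literature-style choices.
DEFAULT_TISSUES = {
    1: TissueParams(t1=1.19, t2star=26.7, m0=0.70, label="wm"),
    2: TissueParams(t1=2.00, t2star=32.4, m0=0.82, label="gm"),
    3: TissueParams(t1=1.80, t2star=27.9, m0=0.80, label="caudate"),
    4: TissueParams(t1=1.63, t2star=24.1, m0=0.80, label="putamen"),
    5: TissueParams(t1=1.58, t2star=28.1, m0=0.80, label="thalamus"),
    6: TissueParams(t1=1.33, t2star=16.7, m0=0.80, label="red_nucleus"),
    7: TissueParams(t1=1.38, t2star=14.1, m0=0.80, label="substantia_nigra"),
    8: TissueParams(t1=1.28, t2star=16.4, m0=0.80, label="stn"),
    9: TissueParams(t1=4.00, t2star=200.0, m0=1.00, label="csf"),
}
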