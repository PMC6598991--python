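"""Imaging-protocol phases: named, ordered time windows within an experiment.

A live-cell Zn2+ quantification run is a sequence of treatments — baseline
imaging, a brief depolarizing stimulation, washout, then the in-situ
calibration (chelator to force the sensor to its minimum, ionophore plus
excess Zn2+ to force its maximum).  Every downstream quantity (resting
value, peak search window, calibration endpoints) is defined relative to
these windows, so the phase annotation travels with the trace data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

PHASE_NAMES = frozenset({"baseline", "stimulation", "washout", "chelator", "ionophore"})

__all__ = [
    "ProtocolPhase",
    "PHASE_NAMES",
    "validate_phases",
    "find_phase",
    "stimulation_protocol",
    "calibration_protocol",
]


@dataclass(frozen=True)
class ProtocolPhase:
    """One labeled treatment window, in seconds from experiment start."""

    name: str
    t_start_s: float
    t_end_s: float

    def __post_init__(self) -> None:
        if self.name not in PHASE_NAMES:
            raise ValueError(f"unknown phase name {self.name!r}; expected one of {sorted(PHASE_NAMES)}")
        if not self.t_start_s < self.t_end_s:
            raise ValueError(f"phase {self.name!r}: t_start ({self.t_start_s}) must precede t_end ({self.t_end_s})")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


def validate_phases(phases: Sequence[ProtocolPhase]) -> list[ProtocolPhase]:
    """Check that phases are nonempty, time-ordered, and non-overlapping."""
    phases = list(phases)
    if not phases:
        raise ValueError("phase list is empty")
    for prev, cur in zip(phases, phases[1:]):
        if cur.t_start_s < prev.t_end_s:
            raise ValueError(
                f"phase {cur.name!r} (starts {cur.t_start_s}s) overlaps {prev.name!r} (ends {prev.t_end_s}s)"
            )
    return phases


def find_phase(phases: Iterable[ProtocolPhase], name: str) -> ProtocolPhase:
    """First phase with the given name; KeyError if absent."""
    for p in phases:
        if p.name == name:
            return p
    raise KeyError(f"protocol has no {name!r} phase")


def stimulation_protocol(
    baseline_s: float = 60.0,
    stimulation_s: float = 10.0,
    washout_s: float = 900.0,
    chelator_s: float = 120.0,
    ionophore_s: float = 180.0,
) -> list[ProtocolPhase]:
    """Stimulation-experiment protocol: 1 min baseline, 10 s high-K+
    stimulation, 15 min washout imaging, then the chelator/ionophore
    calibration."""
    t = 0.0
    out = []
    for name, dur in [
        ("baseline", baseline_s),
        ("stimulation", stimulation_s),
        ("washout", washout_s),
        ("chelator", chelator_s),
        ("ionophore", ionophore_s),
    ]:
        out.append(ProtocolPhase(name, t, t + dur))
        t += dur
    return out


def calibration_protocol(
    baseline_s: float = 120.0,
    chelator_s: float = 180.0,
    washout_s: float = 60.0,
    ionophore_s: float = 180.0,
) -> list[ProtocolPhase]:
    """Resting-calibration protocol: baseline, chelator minimum, washout,
    ionophore maximum (no stimulation)."""
    t = 0.0
    out = []
    for name, dur in [
        ("baseline", baseline_s),
        ("chelator", chelator_s),
        ("washout", washout_s),
        ("ionophore", ionophore_s),
    ]:
        out.append(ProtocolPhase(name, t, t + dur))
        t += dur
    return out
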