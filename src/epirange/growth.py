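"""Phenotype calls from serial-passage growth curves.

An epibiotic parasite is added to a host culture at passage 0 and the
coculture is diluted into fresh medium every passage. Host abundance is an
optical-density-like reading; parasite abundance is a 0-1 microscopy score.
Host strains resolve into three responses:

- resistant: the parasite never establishes (score stays low after the
  establishment window);
- permissive: the parasite establishes and the host density crashes
  relative to the uninfected control, then recovers;
- nonpermissive: the parasite establishes but density never crashes.

Crash detection is control-relative: the crash point is the first passage
whose infected/control density ratio drops below ``drop_fraction``, and the
crash lasts while the ratio stays below ``recovery_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pangenome import NONPERMISSIVE, PERMISSIVE, RESISTANT

__all__ = [
    "PassageSeries",
    "PhenotypeCall",
    "detect_crash",
    "classify_host",
    "dose_response",
    "DoseResponseReport",
]


@dataclass
class PassageSeries:
    """Per-strain, per-dose trajectory over serial passages."""

    strain: str
    dose: float  # initial parasite-to-host cell ratio
    passage: np.ndarray  # integer passage indices, strictly increasing from 0
    density: np.ndarray  # OD-like host density, >= 0
    parasite_score: np.ndarray  # microscopy score in [0, 1]
    control_density: np.ndarray  # matched uninfected host-alone series
    total_cfu: np.ndarray | None = None
    irregular_cfu: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.passage = np.asarray(self.passage, dtype=int)
        for name in ("density", "parasite_score", "control_density"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.passage)
        if not (len(self.density) == len(self.parasite_score) == len(self.control_density) == n):
            raise ValueError("all passage columns must have equal length")
        if n and (self.passage[0] != 0 or (np.diff(self.passage) <= 0).any()):
            raise ValueError("passage indices must increase strictly from 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if ((self.parasite_score < 0) | (self.parasite_score > 1)).any():
            raise ValueError("parasite_score must lie in [0, 1]")
        if (self.density < 0).any():
            raise ValueError("density must be >= 0")

    def __len__(self) -> int:
        return len(self.passage)


@dataclass
class PhenotypeCall:
    """Classification of one strain's response at one dose."""

    strain: str
    call: str  # resistant | permissive | nonpermissive
    crash_point: int | None = None  # passage index; present iff permissive
    crash_duration: int | None = None  # consecutive passages below recovery threshold

    def __post_init__(self) -> None:
        if (self.call == PERMISSIVE) != (self.crash_point is not None):
            raise ValueError("crash_point must be present exactly for permissive calls")
        if self.crash_duration is not None and self.crash_duration < 1:
            raise ValueError("crash_duration must be >= 1 when present")


def detect_crash(
    s: PassageSeries,
    drop_fraction: float = 0.5,
    recovery_fraction: float = 0.8,
) -> tuple[int | None, int | None]:
    """Locate a growth crash relative to the uninfected control.

    Returns ``(crash_point, crash_duration)``: the first passage where
    density / control < ``drop_fraction``, and the number of consecutive
    passages (from the crash point) where the ratio stays below
    ``recovery_fraction``. ``(None, None)`` if no passage qualifies.
    """
    if not 0 < drop_fraction < 1 or not 0 < recovery_fraction < 1:
        raise ValueError("drop_fraction and recovery_fraction must lie in (0, 1)")
    if len(s) < 3:
        raise ValueError("need at least 3 passages to call a crash")
    if (s.control_density <= 0).any():
        bad = int(s.passage[np.argmax(s.control_density <= 0)])
        raise ValueError(f"control density is zero at passage {bad}")
    ratio = s.density / s.control_density
    below = np.flatnonzero(ratio < drop_fraction)
    if below.size == 0:
        return None, None
    start = below[0]
    duration = 0
    for r in ratio[start:]:
        if r < recovery_fraction:
            duration += 1
        else:
            break
    return int(s.passage[start]), max(duration, 1)


def classify_host(
    s: PassageSeries,
    establish_score: float = 0.1,
    establish_passages: int = 5,
    drop_fraction: float = 0.5,
    recovery_fraction: float = 0.8,
) -> PhenotypeCall:
    """Call a strain resistant / permissive / nonpermissive from one series.

    Resistance is judged on the parasite score alone: the parasite failed to
    establish if its score stays below ``establish_score`` at every passage
    from ``establish_passages`` on. Otherwise the call is permissive when a
    control-relative crash is found, else nonpermissive.
    """
    if len(s) < establish_passages:
        raise ValueError(
            f"series spans {len(s)} passages; need >= {establish_passages} to judge establishment"
        )
    window = s.parasite_score[s.passage >= establish_passages]
    if window.size and (window < establish_score).all():
        return PhenotypeCall(strain=s.strain, call=RESISTANT)
    crash_point, crash_duration = detect_crash(s, drop_fraction, recovery_fraction)
    if crash_point is not None:
        return PhenotypeCall(
            strain=s.strain, call=PERMISSIVE, crash_point=crash_point, crash_duration=crash_duration
        )
    return PhenotypeCall(strain=s.strain, call=NONPERMISSIVE)


@dataclass
class DoseResponseReport:
    """Monotonicity of crash timing in parasite dose."""

    monotone: bool
    violations: list[tuple[tuple[float, float], tuple[float, float]]]  # ((dose, cp), (dose, cp))
    conflicts: list[float] = field(default_factory=list)  # duplicate doses with unequal crash points


def dose_response(calls: Sequence[tuple[float, int | None]]) -> DoseResponseReport:
    """Check that crash points are non-increasing with dose.

    ``calls`` pairs each dose with its crash point (``None`` = no crash,
    treated as later than any crash). Duplicate doses with conflicting
    crash points are reported but not fatal.
    """
    doses = [d for d, _ in calls]
    if len(set(doses)) < 2:
        raise ValueError("need at least two distinct doses")
    inf = float("inf")
    pts = [(d, inf if cp is None else float(cp)) for d, cp in calls]
    conflicts = sorted(
        {d for d, cp in pts for d2, cp2 in pts if d == d2 and cp != cp2}
    )
    pts.sort()
    violations = [
        (a, b) for a, b in zip(pts, pts[1:]) if b[0] > a[0] and b[1] > a[1]
    ]
    return DoseResponseReport(monotone=not violations, violations=violations, conflicts=conflicts)
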