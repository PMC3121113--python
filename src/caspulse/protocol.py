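"""Piecewise-constant ligand stimulation protocols.

Ligand concentration is an external input held constant on contiguous time
segments (the ligand pool is not depleted by binding); step protocols such as
"0.1 nM for 10 h, then 2.0 nM" are first-class citizens and their
discontinuities become integrator breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InvalidArgumentError

__all__ = ["StimulusProtocol"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, contiguous (t_start, t_end, tnf) segments starting at t = 0."""

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), float(c)) for a, b, c in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise InvalidArgumentError("protocol needs at least one segment")
        if segs[0][0] != 0.0:
            raise InvalidArgumentError("first segment must start at t = 0")
        for (a, b, tnf) in segs:
            if not b > a:
                raise InvalidArgumentError(f"segment ({a}, {b}) must have t_end > t_start")
            if tnf < 0:
                raise InvalidArgumentError("ligand concentration must be >= 0")
        for (_, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if a1 != b0:
                raise InvalidArgumentError("segments must be contiguous and ordered")

    @classmethod
    def constant(cls, tnf: float, t_end: float) -> "StimulusProtocol":
        """Single segment of constant ligand on [0, t_end]."""
        return cls(((0.0, float(t_end), float(tnf)),))

    @classmethod
    def from_steps(cls, steps: Iterable[tuple[float, float]]) -> "StimulusProtocol":
        """Build from (duration, tnf) pairs starting at t = 0."""
        segs, t = [], 0.0
        for duration, tnf in steps:
            segs.append((t, t + float(duration), float(tnf)))
            t += float(duration)
        return cls(tuple(segs))

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def tnf_at(self, t: float) -> float:
        """Ligand concentration at time t; the last segment extends to +inf.

        At interior breakpoints the right-hand (new) segment value is
        returned, matching the convention that a step takes effect at its
        start time.
        """
        if t < 0:
            return 0.0
        for (a, b, tnf) in self.segments:
            if a <= t < b:
                return tnf
        return self.segments[-1][2]

    def breakpoints(self, t_end: float) -> list[float]:
        """Interior segment boundaries strictly inside (0, t_end)."""
        return [a for (a, _, _) in self.segments[1:] if 0.0 < a < t_end]

    def extended(self, t_end: float) -> "StimulusProtocol":
        """Protocol whose last segment is stretched to cover [0, t_end]."""
        if t_end <= self.t_end:
            return self
        *head, (a, _, tnf) = self.segments
        return StimulusProtocol(tuple(head) + ((a, float(t_end), tnf),))
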