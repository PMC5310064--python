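"""Illumination schedules gating growth and division.

Cyanobacteria in time-lapse experiments are grown either under continuous
illumination or under square-wave light-dark (LD) cycles.  Growth and
division arrest completely in the dark, so every time-like quantity in the
pipeline (generation time, growth-curve time axis) is expressed in
*light-time*: cumulative hours spent in the light.  This module provides
the conversion between wall-clock time and light-time.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
import json

__all__ = ["IlluminationSchedule"]

_EPS = 1e-12


@dataclass(frozen=True)
class IlluminationSchedule:
    """Ordered, contiguous light/dark intervals starting at t = 0 h.

    Parameters
    ----------
    intervals
        List of ``(start, end, state)`` with ``state`` in ``{"light",
        "dark"}``.  Intervals must be contiguous, non-overlapping and start
        at 0.
    after
        State assumed after the last listed interval (default ``"light"``),
        so finite schedules extend gracefully.
    """

    intervals: tuple = field(default_factory=tuple)
    after: str = "light"

    def __post_init__(self):
        ivs = tuple((float(s), float(e), str(st)) for s, e, st in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if ivs:
            if abs(ivs[0][0]) > _EPS:
                raise ValueError("schedule must start at t = 0")
            prev_end = ivs[0][0]
            for s, e, st in ivs:
                if st not in ("light", "dark"):
                    raise ValueError(f"unknown state {st!r}")
                if e <= s:
                    raise ValueError("intervals must have positive duration")
                if abs(s - prev_end) > _EPS:
                    raise ValueError("intervals must be contiguous")
                prev_end = e
        if self.after not in ("light", "dark"):
            raise ValueError(f"unknown after-state {self.after!r}")
        if self.after == "dark" and all(st == "dark" for _, _, st in ivs):
            raise ValueError("no growth possible: schedule is all dark")

    # ------------------------------------------------------------------ #
    @classmethod
    def continuous(cls) -> "IlluminationSchedule":
        """All-light schedule (continuous illumination)."""
        return cls(intervals=(), after="light")

    @classmethod
    def light_dark(cls, light_h: float = 12.0, dark_h: float = 12.0,
                   total_h: float = 480.0, start_state: str = "light"
                   ) -> "IlluminationSchedule":
        """Square-wave LD schedule, e.g. the standard 12 h : 12 h cycle."""
        ivs = []
        t = 0.0
        state = start_state
        while t < total_h:
            dur = light_h if state == "light" else dark_h
            ivs.append((t, t + dur, state))
            t += dur
            state = "dark" if state == "light" else "light"
        return cls(intervals=tuple(ivs), after="light")

    # ------------------------------------------------------------------ #
    @property
    def end(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def state_at(self, t: float) -> str:
        """State at wall-clock time ``t``; boundaries belong to the later
        interval."""
        if t >= self.end - _EPS:
            return self.after
        starts = [s for s, _, _ in self.intervals]
        i = max(bisect_right(starts, t + _EPS) - 1, 0)
        return self.intervals[i][2]

    def light_time(self, t0: float, t1: float) -> float:
        """Cumulative light hours in the wall-clock window ``[t0, t1]``."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        total = 0.0
        for s, e, st in self.intervals:
            if st == "light":
                total += max(0.0, min(e, t1) - max(s, t0))
        if self.after == "light" and t1 > self.end:
            total += t1 - max(t0, self.end)
        return total

    def advance_light(self, t0: float, light_hours: float) -> float:
        """Wall-clock time at which ``light_hours`` of light have elapsed
        since ``t0``.

        If the required light is consumed exactly at a light→dark boundary
        the returned instant is the boundary itself, which by the
        boundary convention above belongs to the next interval — i.e.
        events landing exactly on a dark onset are deferred to the next
        light interval by the caller simply re-reading ``state_at``.
        """
        if light_hours < 0:
            raise ValueError("light_hours must be >= 0")
        remaining = float(light_hours)
        t = float(t0)
        for s, e, st in self.intervals:
            if e <= t:
                continue
            seg_start = max(s, t)
            if st == "light":
                seg = e - seg_start
                if remaining <= seg + _EPS:
                    return seg_start + remaining
                remaining -= seg
            t = e
        if self.after != "light":
            raise ValueError("schedule ends in permanent dark; "
                             "light budget cannot be met")
        return max(t0, self.end) + remaining

    # ------------------------------------------------------------------ #
    def to_json(self) -> str:
        return json.dumps({"intervals": list(self.intervals), "after": self.after})

    @classmethod
    def from_json(cls, s: str) -> "IlluminationSchedule":
        d = json.loads(s)
        return cls(intervals=tuple(tuple(iv) for iv in d["intervals"]),
                   after=d.get("after", "light"))
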