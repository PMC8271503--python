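"""Per-frame binary control signals for online crowd advisories.

Two instantaneous signals are derived from each frame's statistics:

* ``c1`` — a non-intrusive audio-visual cue, raised when any inter-pedestrian
  distance is at or below the minimum distance d_c;
* ``c2`` — an entrance-modulation (overcrowding) advisory, raised when the
  social density exceeds the critical density rho_c.

The cue trigger is deliberately *inclusive* (d <= d_c) while violation
counting elsewhere is strict (d < d_c): a pair at exactly the minimum
distance earns a warning but not a counted violation.  Both comparisons are
configurable.  Signals are pure per-frame outputs with no latching; actuator
integration (speakers, signage, gates) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import FrameStats

__all__ = ["ControlSignals", "control_signals"]


@dataclass(frozen=True)
class ControlSignals:
    """Binary cue (c1) and entrance-advisory (c2) signals for one frame."""

    c1: int
    c2: int


def control_signals(
    stats: FrameStats,
    rho_c: float,
    d_c: float,
    cue_comparison: str = "inclusive",
    density_comparison: str = "strict",
) -> ControlSignals:
    """Evaluate the control policy on one frame's statistics.

    ``c1 = 1`` iff some pairwise distance satisfies d <= d_c (or d < d_c
    under ``cue_comparison="strict"``); with fewer than two pedestrians
    there is no pair and c1 = 0.  ``c2 = 1`` iff rho > rho_c (strictly, by
    default): a density exactly at the critical value is still advised safe.
    """
    if rho_c < 0.0:
        raise ValueError("rho_c must be non-negative")
    if d_c <= 0.0:
        raise ValueError("d_c must be positive")

    if stats.distances.size == 0:
        c1 = 0
    else:
        d_min = stats.distances.min()
        if cue_comparison == "inclusive":
            c1 = int(d_min <= d_c)
        elif cue_comparison == "strict":
            c1 = int(d_min < d_c)
        else:
            raise ValueError(f"unknown cue_comparison {cue_comparison!r}")

    if density_comparison == "strict":
        c2 = int(stats.rho > rho_c)
    elif density_comparison == "inclusive":
        c2 = int(stats.rho >= rho_c)
    else:
        raise ValueError(f"unknown density_comparison {density_comparison!r}")

    return ControlSignals(c1=c1, c2=c2)
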