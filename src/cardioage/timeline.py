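"""Human-equivalent age conversion and ordered event timelines.

Collects point events (pathway tipping points, morphometric vertices) and
window events (staining accumulation phases) on the baboon age axis,
converts each age to its human equivalent via a fixed ratio (default 4.0 —
the ratio implied by the published pairs 7.5 -> 30, 13.0 -> 52,
22.1 -> ~88), and orders them ascending to form the aging-event timeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["Event", "human_equivalent_age", "order_events", "timeline_table"]

SOURCES = ("pathway_tipping", "staining_window", "morphometry")


def human_equivalent_age(baboon_age: float, factor: float = 4.0) -> int:
    """Convert a baboon age (years) to an integer human-equivalent age.

    ``factor * age`` rounded half away from zero.
    """
    if baboon_age <= 0:
        raise ValueError("age must be positive")
    x = factor * baboon_age
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Event:
    label: str
    baboon_age: float | tuple[float, float]  # point, or (start, end) window
    source: str
    sd: float | None = None  # years, for pathway tipping points

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown event source {self.source!r}")
        if isinstance(self.baboon_age, tuple):
            if not self.baboon_age[0] < self.baboon_age[1]:
                raise ValueError("window events need start < end")

    @property
    def start_age(self) -> float:
        return self.baboon_age[0] if isinstance(self.baboon_age, tuple) else self.baboon_age


def order_events(events: list[Event]) -> list[Event]:
    """Sort events ascending by (point or window-start) age, ties broken
    alphabetically by label."""
    if not events:
        raise ValueError("need at least one event")
    return sorted(events, key=lambda e: (e.start_age, e.label))


def timeline_table(events: list[Event], factor: float = 4.0) -> pd.DataFrame:
    """Ordered timeline with baboon and human-equivalent ages."""
    rows = []
    for e in order_events(events):
        if isinstance(e.baboon_age, tuple):
            lo, hi = e.baboon_age
            rows.append(
                {
                    "label": e.label,
                    "source": e.source,
                    "baboon_age_start": lo,
                    "baboon_age_end": hi,
                    "sd_years": e.sd,
                    "human_age_start": human_equivalent_age(lo, factor),
                    "human_age_end": human_equivalent_age(hi, factor),
                }
            )
        else:
            rows.append(
                {
                    "label": e.label,
                    "source": e.source,
                    "baboon_age_start": e.baboon_age,
                    "baboon_age_end": None,
                    "sd_years": e.sd,
                    "human_age_start": human_equivalent_age(e.baboon_age, factor),
                    "human_age_end": None,
                }
            )
    return pd.DataFrame(rows)
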