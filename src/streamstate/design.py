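"""Factorial space-state experimental design.

Builds the sampling-unit layout of the flow-disturbance experiment: rows of
artificial substrates per stream (one control row plus the three disturbance
frequencies), destructive-sampling columns forming the occasions, and the
whole layout repeated once per disturbance-intensity battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import FREQUENCY_LEVELS

__all__ = ["DesignSpec", "build_design", "sampling_days", "disturbance_schedule"]


@dataclass(frozen=True)
class DesignSpec:
    """Dimensions and calendar of the factorial disturbance experiment.

    Defaults reproduce the field layout: 5 streams, 4 rows (control, F1, F2,
    F3), 5 destructive-sampling columns at days 23, 27, 31, 35, 39, run twice
    at pump intensities of 30 and 60 m3/h.
    """

    n_streams: int = 5
    rows: tuple[str, ...] = FREQUENCY_LEVELS
    n_columns: int = 5
    n_batteries: int = 2
    start_day: int = 23
    interval_days: int = 4
    intensities: tuple[int, ...] = (30, 60)

    def __post_init__(self) -> None:
        if self.n_streams < 1 or self.n_columns < 1 or len(self.rows) < 1:
            raise ValueError("streams, rows and columns must all be non-empty")
        if self.n_batteries < 1:
            raise ValueError("need at least one intensity battery")
        if list(self.rows).count("C") != 1:
            raise ValueError("exactly one control row is required")
        unknown = set(self.rows) - set(FREQUENCY_LEVELS)
        if unknown:
            raise ValueError(f"unknown row labels: {sorted(unknown)}")
        if len(self.intensities) < self.n_batteries:
            raise ValueError("need an intensity label per battery")

    @property
    def horizon_day(self) -> int:
        """Calendar day of the last sampling occasion."""
        return self.start_day + (self.n_columns - 1) * self.interval_days

    @property
    def n_units(self) -> int:
        return self.n_streams * len(self.rows) * self.n_columns * self.n_batteries

    def occasion_days(self) -> list[int]:
        return sampling_days(self.start_day, self.interval_days, self.n_columns)


def sampling_days(start: int, interval: int, n: int) -> list[int]:
    """Calendar days of the n destructive-sampling occasions."""
    if n < 1:
        raise ValueError("need at least one occasion")
    if interval < 1:
        raise ValueError("sampling interval must be positive")
    return [start + k * interval for k in range(n)]


def disturbance_schedule(frequency: str, horizon: int, rng_seed: int | None = None) -> list[int]:
    """Days on which a row of substrates is disturbed, up to the horizon.

    F1 disturbs every 6 days and F2 every 3 days.  F3 is a random schedule:
    the number of events is drawn uniformly between the F1 and F2 event
    counts and the event days are distinct days in (0, horizon].  The control
    row has no events.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if frequency == "C":
        return []
    if frequency == "F1":
        return list(range(6, horizon + 1, 6))
    if frequency == "F2":
        return list(range(3, horizon + 1, 3))
    if frequency == "F3":
        rng = np.random.default_rng(rng_seed)
        lo = len(range(6, horizon + 1, 6))
        hi = len(range(3, horizon + 1, 3))
        n_events = int(rng.integers(lo, hi + 1))
        days = rng.choice(np.arange(1, horizon + 1), size=n_events, replace=False)
        return sorted(int(d) for d in days)
    raise ValueError(f"unknown frequency level {frequency!r}")


def build_design(spec: DesignSpec | None = None) -> pd.DataFrame:
    """One sampling unit per (battery, stream, row, column).

    Returns a table with the treatment-cell label of each unit ('C' for the
    control row, else e.g. 'I2F1') and the calendar day its column is
    collected.
    """
    spec = spec or DesignSpec()
    days = spec.occasion_days()
    records = []
    for b in range(1, spec.n_batteries + 1):
        for s in range(1, spec.n_streams + 1):
            for row in spec.rows:
                cell = "C" if row == "C" else f"I{b}{row}"
                for c in range(1, spec.n_columns + 1):
                    records.append(
                        {
                            "battery": b,
                            "intensity_m3h": spec.intensities[b - 1],
                            "stream": s,
                            "frequency": row,
                            "column": c,
                            "occasion": c,
                            "day": days[c - 1],
                            "cell": cell,
                        }
                    )
    df = pd.DataFrame.from_records(records)
    assert len(df) == spec.n_units
    return df
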