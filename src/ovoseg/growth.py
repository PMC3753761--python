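"""In ovo long-bone growth analysis from repeated measurements.

A growth record is one bone's eigen-box length on one incubation day.
Growth rates are day-to-day differences of cross-specimen mean lengths
(left and right bones of an embryo both contribute to the mean), one
rate per bone class per consecutive-day interval, in mm/day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["GrowthRecord", "records_frame", "growth_rates", "length_summary"]


@dataclass
class GrowthRecord:
    """One bone length measurement."""

    specimen_id: str
    bone_class: str
    day: int
    length_mm: float

    def __post_init__(self) -> None:
        if not 13 <= self.day <= 19:
            raise ValueError("day of incubation must lie in [13, 19]")
        if self.length_mm <= 0:
            raise ValueError("length must be > 0")


def records_frame(records) -> pd.DataFrame:
    """Normalize records (dataclasses or a DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        required = {"specimen_id", "bone_class", "day", "length_mm"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"growth table is missing columns: {sorted(missing)}")
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records])


def growth_rates(records) -> pd.DataFrame:
    """Per-bone, per-interval growth rates in mm/day.

    ``rate(d -> d+1)`` is the mean length over all specimens at day d+1
    minus the mean at day d.  Intervals with a missing endpoint are
    skipped with a warning.  Returns columns ``bone_class, day_from,
    day_to, rate_mm_per_day``.
    """
    table = records_frame(records)
    if table.empty:
        raise ValueError("no growth records")
    means = (table.groupby(["bone_class", "day"])["length_mm"]
             .mean().reset_index())
    rows = []
    for bone, sub in means.groupby("bone_class"):
        by_day = dict(zip(sub["day"], sub["length_mm"]))
        days = sorted(by_day)
        for d in range(min(days), max(days)):
            if d not in by_day or d + 1 not in by_day:
                warnings.warn(f"{bone}: no data for interval d{d}->d{d + 1}; skipped")
                continue
            rows.append({
                "bone_class": bone,
                "day_from": d,
                "day_to": d + 1,
                "rate_mm_per_day": by_day[d + 1] - by_day[d],
            })
    if not rows:
        raise ValueError("no bone class has two consecutive days of data")
    return pd.DataFrame(rows)


def length_summary(records) -> pd.DataFrame:
    """Five-number summary plus mean per (bone class, day).

    Quartiles use linear interpolation; the summary feeds box-and-whisker
    style reporting of in ovo bone lengths.
    """
    table = records_frame(records)
    if table.empty:
        raise ValueError("no growth records")

    def _summary(x: pd.Series) -> pd.Series:
        return pd.Series({
            "n": len(x),
            "mean": x.mean(),
            "min": x.min(),
            "q1": x.quantile(0.25),
            "median": x.quantile(0.5),
            "q3": x.quantile(0.75),
            "max": x.max(),
        })

    out = (table.groupby(["bone_class", "day"])["length_mm"]
           .apply(_summary).unstack())
    return out.reset_index()
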