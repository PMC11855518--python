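"""Cohort inclusion filter and descriptive summary.

The analysis cohort is restricted to complete records of non-traumatic
arrests in adults (>= 18 y) with an ambulance on scene within 20 min
(<= 1200 s); longer response times are treated as coverage gaps or data
entry errors and excluded.  Continuous variables are summarised as median
and interquartile range (linear-interpolation quartiles), categorical ones
as absolute and relative frequencies, and response times additionally as
counts in the 0-5 / 5-10 / >10 min bins used to judge defibrillation
timeliness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synth_city import EventRecord

#: Left-closed response-time bin edges in seconds (0-5, 5-10, >10 min).
RESPONSE_BINS = ((0.0, 300.0), (300.0, 600.0), (600.0, 1200.0 + 1e-9))
RESPONSE_BIN_LABELS = ("0-5 min", "5-10 min", ">10 min")

MAX_RESPONSE_S = 1200.0
MIN_AGE_Y = 18.0


def filter_events(events: list[EventRecord]) -> list[EventRecord]:
    """Apply the inclusion criteria, preserving order.

    Retains records that are complete, non-traumatic, age >= 18 and with
    response time <= 1200 s (the 20-min cut-off read inclusively).
    Idempotent by construction.
    """
    return [
        e
        for e in events
        if e.complete
        and not e.traumatic
        and e.age >= MIN_AGE_Y
        and e.response_time_s <= MAX_RESPONSE_S
    ]


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def _freq(levels: list, order: list) -> dict[str, tuple[int, float]]:
    n = len(levels)
    out = {}
    for lv in order:
        c = sum(1 for x in levels if x == lv)
        out[str(lv)] = (c, 100.0 * c / n)
    return out


def response_bin_index(response_time_s: float) -> int:
    """Index of the left-closed bin containing the response time."""
    for i, (lo, hi) in enumerate(RESPONSE_BINS):
        if lo <= response_time_s < hi:
            return i
    raise ValueError(f"response time {response_time_s} outside binned range")


@dataclass
class CohortSummary:
    """Descriptive surface of the filtered cohort."""

    n_total_calls: int
    n_complete: int
    medians_iqr: dict[str, tuple[float, float, float]]  # (median, q1, q3)
    frequencies: dict[str, dict[str, tuple[int, float]]]
    response_bins: dict[str, tuple[int, float]]
    shockable_by_bin: dict[str, tuple[int, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total_calls": self.n_total_calls,
            "n_complete": self.n_complete,
            "medians_iqr": {
                k: {"median": m, "q1": q1, "q3": q3}
                for k, (m, q1, q3) in self.medians_iqr.items()
            },
            "frequencies": {
                var: {lv: {"count": c, "percent": round(p, 2)} for lv, (c, p) in d.items()}
                for var, d in self.frequencies.items()
            },
            "response_bins": {
                lv: {"count": c, "percent": round(p, 2)}
                for lv, (c, p) in self.response_bins.items()
            },
            "shockable_by_bin": {
                lv: {"count": c, "percent": round(p, 2)}
                for lv, (c, p) in self.shockable_by_bin.items()
            },
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def summarize(events: list[EventRecord], n_total_calls: int | None = None) -> CohortSummary:
    """Descriptive statistics of an (already filtered) cohort.

    Percents are computed against the cohort size, except the
    shockable-by-bin breakdown, whose denominator is the number of
    shockable cases.
    """
    if not events:
        raise ValueError("cannot summarise an empty cohort")
    n = len(events)

    resp = np.array([e.response_time_s for e in events])
    medians = {
        "age": _median_iqr(np.array([e.age for e in events])),
        "response_time_s": _median_iqr(resp),
        "dispatch_time_s": _median_iqr(np.array([e.dispatch_time_s for e in events])),
        "cpr_duration_s": _median_iqr(np.array([e.cpr_duration_s for e in events])),
    }

    frequencies = {
        "bystander_cpr": _freq([e.bystander_cpr for e in events], ["yes", "no", "unknown"]),
        "sex": _freq([e.sex for e in events], ["male", "female"]),
        "death": _freq(["yes" if e.death else "no" for e in events], ["yes", "no"]),
        "shockable": _freq(["yes" if e.shockable else "no" for e in events], ["yes", "no"]),
    }

    bins = [response_bin_index(t) for t in resp]
    response_bins = {
        lab: (c := bins.count(i), 100.0 * c / n)
        for i, lab in enumerate(RESPONSE_BIN_LABELS)
    }

    shock_bins = [b for e, b in zip(events, bins) if e.shockable]
    n_shock = len(shock_bins)
    shockable_by_bin = {}
    if n_shock:
        shockable_by_bin = {
            lab: (c := shock_bins.count(i), 100.0 * c / n_shock)
            for i, lab in enumerate(RESPONSE_BIN_LABELS)
        }

    return CohortSummary(
        n_total_calls=n_total_calls if n_total_calls is not None else n,
        n_complete=n,
        medians_iqr=medians,
        frequencies=frequencies,
        response_bins=response_bins,
        shockable_by_bin=shockable_by_bin,
    )
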