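"""Tumor-response classification and native survival statistics.

Preclinical therapy studies here use tumor-size surrogates for survival: the
event is the first day the tumor doubles its baseline volume (or reaches a
10-mm diameter for the PDX model), with deaths from any other cause counted
as events at the death time and animals that never reach the endpoint
censored at last follow-up.  Complete response (CR) is a *final* tumor
volume at or below 4.2 mm^3 — a dip-and-regrow trajectory is not a CR.

The Kaplan–Meier product-limit estimator, median survival, and the
Mantel–Cox (log-rank) test are implemented natively (and cross-checked
against lifelines in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "CR_THRESHOLD_MM3",
    "TumorSeries",
    "SurvivalRecord",
    "SurvivalCurve",
    "MedianSurvival",
    "classify_response",
    "endpoint_time",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "read_tumor_series",
    "survival_table",
]

#: complete-response threshold: final tumor volume at or below this is a CR
CR_THRESHOLD_MM3 = 4.2


@dataclass(frozen=True)
class TumorSeries:
    """Per-animal tumor size measurements.

    ``kind`` is ``"volume"`` (mm^3) or ``"diameter"`` (mm).  ``baseline`` is
    the day-0 (treatment-start) measurement; it defaults to the first
    recorded value.  ``death_day`` records death from a cause other than the
    size endpoint, which counts as an event at that day.
    """

    animal_id: str
    group: str
    days: tuple[float, ...]
    values: tuple[float, ...]
    kind: str = "volume"
    baseline: float | None = None
    death_day: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.size == 0:
            raise ValueError("series needs at least one measurement")
        if d.size != v.size:
            raise ValueError("days and values must have equal length")
        if d.size > 1 and np.any(np.diff(d) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("sizes must be >= 0")
        if self.kind not in ("volume", "diameter"):
            raise ValueError(f"unknown measurement kind {self.kind!r}")

    @property
    def baseline_value(self) -> float:
        return self.values[0] if self.baseline is None else self.baseline


@dataclass(frozen=True)
class SurvivalRecord:
    """One animal's endpoint time and event flag (event=False means censored)."""

    animal_id: str
    group: str
    time_d: float
    event: bool
    censored_reason: str = ""

    def __post_init__(self) -> None:
        if not (self.time_d > 0):
            raise ValueError("survival time must be positive")


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier step function with risk-set bookkeeping.

    ``times`` are the distinct event times; ``survival[i]`` is S(t) just
    after ``times[i]``; ``at_risk``/``events`` the risk set and event count
    at each time.  S(0)=1 implicitly; ``last_followup`` is the largest
    observed time (event or censoring).
    """

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]
    last_followup: float

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("S(t) must lie in [0, 1]")
        if s.size > 1 and np.any(np.diff(s) > 1e-12):
            raise ValueError("S(t) must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass(frozen=True)
class MedianSurvival:
    """Median survival time; ``value`` is None when S never reaches 0.5."""

    value: float | None
    last_followup: float

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __str__(self) -> str:
        if self.defined:
            return f"{self.value:g} d"
        return f">{self.last_followup:g} d"


def classify_response(series: TumorSeries, threshold: float = CR_THRESHOLD_MM3) -> str:
    """``"complete_response"`` iff the final recorded volume is <= threshold (inclusive)."""
    if series.kind != "volume":
        raise ValueError("complete response is defined on volume series only")
    return (
        "complete_response"
        if series.values[-1] <= threshold
        else "no_complete_response"
    )


def _first_crossing(
    days: np.ndarray, values: np.ndarray, threshold: float, interpolate: bool
) -> float | None:
    """First day the series reaches ``threshold``, linearly interpolated."""
    above = values >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0 or not interpolate or values[i] == threshold:
        return float(days[i])
    d0, d1 = days[i - 1], days[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:  # flat segment at threshold
        return float(d1)
    return float(d0 + (threshold - v0) / (v1 - v0) * (d1 - d0))


def endpoint_time(
    series: TumorSeries, rule: str = "doubling", interpolate: bool = True
) -> tuple[float, bool]:
    """Endpoint time and event flag for one animal.

    ``rule="doubling"`` (volume series): first day the volume reaches twice
    baseline.  ``rule="diameter_10mm"`` (diameter series): first day the
    diameter reaches 10 mm.  Crossings between measurement days are linearly
    interpolated by default.  If the endpoint is never reached the animal is
    censored at its last observation — unless it died of another cause
    first, which is an event at the death day.
    """
    if rule == "doubling":
        if series.kind != "volume":
            raise ValueError("doubling rule requires a volume series")
        threshold = 2.0 * series.baseline_value
        if threshold <= 0:
            raise ValueError("baseline volume must be positive for doubling rule")
    elif rule == "diameter_10mm":
        if series.kind != "diameter":
            raise ValueError("diameter rule requires a diameter series")
        threshold = 10.0
    else:
        raise ValueError(f"unknown endpoint rule {rule!r}")

    days = np.asarray(series.days, dtype=float)
    values = np.asarray(series.values, dtype=float)
    cross = _first_crossing(days, values, threshold, interpolate)

    if series.death_day is not None and (cross is None or series.death_day < cross):
        return float(series.death_day), True
    if cross is None:
        return float(days[-1]), False
    return cross, True


def km_estimate(records: list[SurvivalRecord]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate.

    Censored observations leave the risk set without producing a step; a
    censoring tied with an event time is conventionally at risk for that
    event (censored "just after").
    """
    if not records:
        raise ValueError("KM needs at least one record")
    times = np.array([r.time_d for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)

    event_times = np.unique(times[events])
    s = 1.0
    out_t, out_s, out_n, out_d = [], [], [], []
    for t in event_times:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / n_at_risk
        out_t.append(float(t))
        out_s.append(s)
        out_n.append(n_at_risk)
        out_d.append(d)
    return SurvivalCurve(
        times=tuple(out_t),
        survival=tuple(out_s),
        at_risk=tuple(out_n),
        events=tuple(out_d),
        last_followup=float(times.max()),
    )


def median_survival(curve: SurvivalCurve) -> MedianSurvival:
    """Smallest time with S(t) <= 0.5; undefined when S never reaches 0.5."""
    for t, s in zip(curve.times, curve.survival):
        if s <= 0.5:
            return MedianSurvival(value=t, last_followup=curve.last_followup)
    return MedianSurvival(value=None, last_followup=curve.last_followup)


def logrank_test(
    a: list[SurvivalRecord], b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel–Cox (log-rank) test between two groups.

    At each distinct event time a 2x2 table of events vs at-risk contributes
    an observed-minus-expected increment and a hypergeometric variance; the
    statistic ``(sum(O-E))^2 / sum(V)`` is referred to chi-square with 1 df.
    Symmetric under group swap.

    Returns ``(chi_square, p_value)``; with no events in either group the
    statistic is undefined and ``(nan, nan)`` is returned.
    """
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    t_a = np.array([r.time_d for r in a])
    e_a = np.array([r.event for r in a], dtype=bool)
    t_b = np.array([r.time_d for r in b])
    e_b = np.array([r.event for r in b], dtype=bool)

    event_times = np.unique(np.concatenate([t_a[e_a], t_b[e_b]]))
    if event_times.size == 0:
        return float("nan"), float("nan")

    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int(np.sum(t_a >= t))
        n2 = int(np.sum(t_b >= t))
        d1 = int(np.sum(e_a & (t_a == t)))
        d2 = int(np.sum(e_b & (t_b == t)))
        n = n1 + n2
        d = d1 + d2
        if n < 1:
            continue
        expected1 = d * n1 / n
        o_minus_e += d1 - expected1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return float("nan"), float("nan")
    chi_sq = o_minus_e**2 / var
    p = float(chi2.sf(chi_sq, df=1))
    return float(chi_sq), p


def read_tumor_series(path: str | Path) -> list[TumorSeries]:
    """Read per-animal tumor measurements from CSV.

    Columns: ``animal_id, group, day`` and either ``volume_mm3`` or
    ``diameter_mm``; optional ``death_day`` (constant per animal).
    """
    df = pd.read_csv(path)
    required = {"animal_id", "group", "day"}
    if not required.issubset(df.columns):
        raise ValueError(f"tumor file {path} missing columns: {sorted(required - set(df.columns))}")
    if "volume_mm3" in df.columns:
        value_col, kind = "volume_mm3", "volume"
    elif "diameter_mm" in df.columns:
        value_col, kind = "diameter_mm", "diameter"
    else:
        raise ValueError(f"tumor file {path} needs a volume_mm3 or diameter_mm column")
    series = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        sub = sub.sort_values("day")
        death = None
        if "death_day" in sub.columns and sub["death_day"].notna().any():
            death = float(sub["death_day"].dropna().iloc[0])
        series.append(
            TumorSeries(
                animal_id=str(animal),
                group=str(group),
                days=tuple(sub["day"].astype(float)),
                values=tuple(sub[value_col].astype(float)),
                kind=kind,
                death_day=death,
            )
        )
    return series


def survival_table(
    series: list[TumorSeries], rule: str = "doubling", interpolate: bool = True
) -> pd.DataFrame:
    """Derive the survival export table from tumor series.

    Columns: ``animal_id, group, time_d, event, reason``.
    """
    rows = []
    for s in series:
        t, event = endpoint_time(s, rule=rule, interpolate=interpolate)
        if event and s.death_day is not None and t == s.death_day:
            reason = "death_other_cause"
        elif event:
            reason = rule
        else:
            reason = "no_endpoint_by_last_followup"
        rows.append(
            {"animal_id": s.animal_id, "group": s.group, "time_d": t, "event": event, "reason": reason}
        )
    return pd.DataFrame(rows)
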