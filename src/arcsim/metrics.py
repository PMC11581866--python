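"""Controller-performance metrics for resuscitation events.

Twelve metrics scored per resuscitation event, following the Varvel
convention for the performance-error family: the performance error at each
sample is PE = 100 * (MAP - target) / target, with the *instantaneous*
active target as denominator (safety-rule target reductions change the
denominator from the reduction time onward).

* MDPE    - median PE (signed bias, %)
* MDAPE   - median |PE| (error magnitude, %)
* wobble  - median |PE - MDPE| (oscillation, %)
* effectiveness                 - % of samples with |MAP - target| <= band
* resuscitation effectiveness   - % of samples with MAP >= target - band
  (undershoot-only penalty; overshoot is not penalised during hemorrhagic
  shock resuscitation)
* target overshoot - max positive excursion above target, % of target
* area above / below target - trapezoidal integrals (mmHg*min); the area
  below is reported non-positive
* rise time - minutes from event start until MAP first reaches target
* median / mean infusion rate and infusion-rate variability (sample SD)

All band boundaries are inclusive and even-length medians are averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

#: Order of metric fields, used for reports and the ratio table.
METRIC_FIELDS = (
    ("mdpe", "MDPE (%)"),
    ("mdape", "MDAPE (%)"),
    ("wobble", "Wobble (%)"),
    ("effectiveness", "Effectiveness (%)"),
    ("resuscitation_effectiveness", "Resuscitation effectiveness (%)"),
    ("target_overshoot", "Target overshoot (%)"),
    ("area_above", "Area above the target MAP (mmHg*min)"),
    ("area_below", "Area below the target MAP (mmHg*min)"),
    ("rise_time", "Rise time efficiency (min)"),
    ("median_infusion", "Median infusion (mL/min)"),
    ("mean_infusion", "Mean infusion (mL/min)"),
    ("infusion_variability", "Variable infusion rate (mL/min)"),
)


@dataclass
class MetricsReport:
    """Twelve-metric scorecard for one resuscitation event."""

    mdpe: float
    mdape: float
    wobble: float
    effectiveness: float
    resuscitation_effectiveness: float
    target_overshoot: float
    area_above: float
    area_below: float
    rise_time: float        # NaN if the target was never attained
    median_infusion: float
    mean_infusion: float
    infusion_variability: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def performance_error(map_mmHg, target_mmHg) -> np.ndarray:
    """Per-sample performance error (%) against the instantaneous target."""
    m = np.asarray(map_mmHg, dtype=float)
    t = np.asarray(target_mmHg, dtype=float)
    t = np.broadcast_to(t, m.shape)
    if np.any(t <= 0):
        raise ValueError("target must be positive at all samples")
    return 100.0 * (m - t) / t


def varvel_metrics(pe) -> tuple[float, float, float]:
    """(MDPE, MDAPE, wobble) in percent from a performance-error series."""
    arr = np.asarray(pe, dtype=float)
    if arr.size == 0:
        raise ValueError("performance-error series must be non-empty")
    mdpe = float(np.median(arr))
    mdape = float(np.median(np.abs(arr)))
    wobble = float(np.median(np.abs(arr - mdpe)))
    return mdpe, mdape, wobble


def band_metrics(map_mmHg, target_mmHg, band: float = 5.0) -> tuple[float, float]:
    """(effectiveness %, resuscitation effectiveness %), boundaries inclusive."""
    m = np.asarray(map_mmHg, dtype=float)
    t = np.broadcast_to(np.asarray(target_mmHg, dtype=float), m.shape)
    if m.size == 0:
        raise ValueError("trace must be non-empty")
    eff = 100.0 * np.mean(np.abs(m - t) <= band)
    resus = 100.0 * np.mean(m >= t - band)
    return float(eff), float(resus)


def transient_metrics(
    time_min,
    map_mmHg,
    target_mmHg,
    start: float,
) -> tuple[float, float, float, float]:
    """(rise_time min, overshoot %, area_above, area_below mmHg*min).

    Rise time is the first sample time with MAP >= target, minus ``start``
    (NaN if never attained).  Overshoot uses the largest single positive
    excursion relative to the instantaneous target.  Areas are trapezoidal
    integrals of the positive and negative parts of (MAP - target); the
    area below the target is returned as a non-positive number.
    """
    t = np.asarray(time_min, dtype=float)
    m = np.asarray(map_mmHg, dtype=float)
    tgt = np.broadcast_to(np.asarray(target_mmHg, dtype=float), m.shape)
    if t.size == 0:
        raise ValueError("trace must be non-empty")

    attained = np.nonzero(m >= tgt)[0]
    rise_time = float(t[attained[0]] - start) if attained.size else math.nan

    overshoot = float(max(0.0, np.max((m - tgt) / tgt)) * 100.0)
    above = np.maximum(m - tgt, 0.0)
    below = np.maximum(tgt - m, 0.0)
    area_above = float(np.trapezoid(above, t))
    area_below = -float(np.trapezoid(below, t))
    return rise_time, overshoot, area_above, area_below


def infusion_stats(rates) -> tuple[float, float, float]:
    """(median, mean, sample-SD) of the infusion-rate series, zeros included."""
    arr = np.asarray(rates, dtype=float)
    if arr.size == 0:
        raise ValueError("infusion-rate series must be non-empty")
    median = float(np.median(arr))
    mean = float(np.mean(arr))
    variability = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return median, mean, variability


def compute_report(
    trace: pd.DataFrame,
    target: float | None = None,
    band: float = 5.0,
    start: float | None = None,
) -> MetricsReport:
    """Score one event trace.

    ``trace`` needs columns ``time_min``, ``map_mmHg``, ``infusion_mL_min``
    and either a ``target_mmHg`` column (piecewise-constant active target)
    or an explicit scalar ``target``.  ``start`` defaults to the first
    sample time.  The window is the caller's choice; the protocol runner
    scores the full event from resuscitation start through maintenance end.
    """
    t = trace["time_min"].to_numpy(dtype=float)
    m = trace["map_mmHg"].to_numpy(dtype=float)
    rates = trace["infusion_mL_min"].to_numpy(dtype=float)
    if target is not None:
        tgt = np.full_like(m, float(target))
    elif "target_mmHg" in trace.columns:
        tgt = trace["target_mmHg"].to_numpy(dtype=float)
    else:
        raise ValueError("trace has no target_mmHg column and no target was given")
    if start is None:
        start = float(t[0]) if t.size else 0.0

    pe = performance_error(m, tgt)
    mdpe, mdape, wobble = varvel_metrics(pe)
    eff, resus = band_metrics(m, tgt, band)
    rise, overshoot, above, below = transient_metrics(t, m, tgt, start)
    median_q, mean_q, var_q = infusion_stats(rates)
    return MetricsReport(
        mdpe=mdpe,
        mdape=mdape,
        wobble=wobble,
        effectiveness=eff,
        resuscitation_effectiveness=resus,
        target_overshoot=overshoot,
        area_above=above,
        area_below=below,
        rise_time=rise,
        median_infusion=median_q,
        mean_infusion=mean_q,
        infusion_variability=var_q,
    )


def _arrow(ratio: float) -> str:
    if not math.isfinite(ratio):
        return "n/a"
    if ratio >= 1.5:
        return "↑"   # large increase
    if ratio > 1.0:
        return "↗"   # mild increase
    if ratio == 1.0:
        return "→"
    if ratio >= 0.5:
        return "↘"   # mild decrease
    return "↓"       # large decrease / sign flip


def ratio_table(
    report_event1: MetricsReport,
    report_event2: MetricsReport,
) -> pd.DataFrame:
    """Two-event comparison: per-metric event1/event2 ratio with trend arrow.

    Ratios are rounded to two decimals; a zero denominator flags the cell
    (NaN ratio, ``n/a`` arrow) rather than raising.
    """
    rows = []
    for name, label in METRIC_FIELDS:
        v1 = getattr(report_event1, name)
        v2 = getattr(report_event2, name)
        if v2 == 0 or not (math.isfinite(v1) and math.isfinite(v2)):
            ratio = math.nan
        else:
            ratio = round(v1 / v2, 2)
        rows.append(
            {
                "metric": label,
                "event1": v1,
                "event2": v2,
                "ratio": ratio,
                "trend": _arrow(ratio),
            }
        )
    return pd.DataFrame(rows)


def format_report(report: MetricsReport) -> str:
    """Tab-separated metric/value lines (parseable by :func:`parse_report`)."""
    lines = [f"{name}\t{getattr(report, name):.10g}" for name, _ in METRIC_FIELDS]
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> MetricsReport:
    """Inverse of :func:`format_report`."""
    values = {}
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        name, raw = line.split("\t")
        values[name] = float(raw)
    missing = [name for name, _ in METRIC_FIELDS if name not in values]
    if missing:
        raise ValueError(f"report is missing metric(s): {', '.join(missing)}")
    return MetricsReport(**values)


def format_ratio_table(table: pd.DataFrame) -> str:
    """Tab-separated rendering of :func:`ratio_table` output."""
    lines = ["metric\tevent1\tevent2\tratio\ttrend"]
    for _, row in table.iterrows():
        ratio = "n/a" if not math.isfinite(row["ratio"]) else f"{row['ratio']:.2f}"
        lines.append(
            f"{row['metric']}\t{row['event1']:.4g}\t{row['event2']:.4g}"
            f"\t{ratio}\t{row['trend']}"
        )
    return "\n".join(lines) + "\n"
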