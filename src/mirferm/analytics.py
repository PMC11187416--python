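"""Control-quality and soft-sensor analytics.

Quantities derived from a RunLog (or any measurement series):

* **Cumulative deviation from setpoint** — the absolute-value integral of the
  measured concentration around its setpoint over a window (default the first
  48 h of the series), accumulated by the rectangle rule: each sample carries
  its deviation forward until the next sample, the last until the window end.
  This is the single number used to compare control regimes; smaller is
  better, and the manual/automated ratio is the "fold reduction" headline.
* **Consumption-rate soft sensor** — C_t = (G_{t−1}·V_{t−1} − G_t·V_t + F·S)/I
  in g/h, a mass balance over one measurement interval: what disappeared from
  the broth plus what was pumped in, per hour. F is the pumped feed volume in
  mL over the interval and S the stock concentration in g/mL so F·S is grams.
* **Yield summary** — group means/SDs plus a two-sided two-sample t test
  (Welch by default) for end-of-run product yields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError


@dataclass(frozen=True)
class DeviationSeries:
    """Running cumulative |measured − setpoint| integral, g·h/L."""

    times: np.ndarray  # h, sample times inside the window
    running_total: np.ndarray  # g·h/L after each sample's rectangle
    total: float  # g·h/L over the full window
    setpoint: float
    window: float  # h
    t0: float  # h, window start


def cumulative_deviation(
    times,
    values,
    setpoint: float,
    window: float = 48.0,
    t0: float | None = None,
) -> DeviationSeries:
    """Rectangle-rule cumulative absolute deviation from setpoint.

    ``times`` must be nondecreasing. The window spans [t0, t0 + window] with
    ``t0`` defaulting to the first sample time; each sample's |value −
    setpoint| is weighted by the gap to the next sample, the last sample
    carrying to the window end. Duplicated time points contribute zero width,
    and the total is additive over contiguous sub-windows.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError("times and values must be 1-D of equal length")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be nondecreasing")
    if not window > 0:
        raise ValueError("window must be > 0")
    if t0 is None:
        t0 = float(times[0]) if len(times) else 0.0
    t_end = t0 + window
    mask = (times >= t0) & (times <= t_end)
    t_in, v_in = times[mask], values[mask]
    if len(t_in) < 2:
        raise InsufficientDataError(
            f"need >= 2 measurements inside [{t0}, {t_end}] h, got {len(t_in)}"
        )
    bounds = np.append(t_in[1:], t_end)
    widths = np.clip(bounds - t_in, 0.0, None)
    areas = np.abs(v_in - setpoint) * widths
    running = np.cumsum(areas)
    return DeviationSeries(
        times=t_in, running_total=running, total=float(running[-1]),
        setpoint=setpoint, window=window, t0=t0,
    )


def fold_reduction(manual_total: float, auto_total: float) -> float:
    """Ratio of two cumulative-deviation totals (e.g. manual / automated).

    A zero denominator is reported as ``inf`` (perfect control) rather than an
    error so regime tables stay rectangular.
    """
    if manual_total < 0 or auto_total < 0:
        raise ValueError("deviation totals must be >= 0")
    if auto_total == 0.0:
        return math.inf
    return manual_total / auto_total


def consumption_rate(
    G_prev: float, V_prev: float, G_now: float, V_now: float,
    F: float, S: float, I: float,
) -> float:
    """Soft-sensor consumption rate, g/h, over one measurement interval.

    C = (G_prev·V_prev − G_now·V_now + F·S) / I with concentrations in g/L,
    volumes in L, pumped feed volume F in mL, stock S in g/mL and interval I
    in hours. No smoothing is applied here; see
    :func:`soft_sensor_series` for an optional moving average.
    """
    if not I > 0:
        raise ValueError(f"interval I must be > 0, got {I}")
    if F < 0:
        raise ValueError(f"pumped volume F must be >= 0, got {F}")
    return (G_prev * V_prev - G_now * V_now + F * S) / I


def soft_sensor_series(
    runlog: pd.DataFrame,
    analyte: str,
    stock: float,
    source: str = "inline",
    smooth: int = 1,
) -> pd.DataFrame:
    """Consumption-rate series recomputed from a RunLog alone.

    Uses consecutive measurement events of the given source for G and V, and
    integrates the logged per-tick pump rates for the pumped volume F between
    them. ``smooth`` > 1 applies a centred moving average of that many points
    (optional post-filter; default off). Columns: t_h, C_g_per_h, G_prev,
    G_now, V_prev, V_now, F_mL, I_h.
    """
    meas = runlog[(runlog.event == "measurement") & (runlog.analyte == analyte)
                  & (runlog.source == source)]
    if len(meas) < 2:
        raise InsufficientDataError("need >= 2 measurement events")
    ticks = runlog[(runlog.event == "tick") & (runlog.analyte == analyte)]
    t_tick = ticks.time_h.to_numpy()
    rate = ticks.pump_rate_mL_per_h.to_numpy()
    # pumped volume up to each tick time: rate i holds over [t_i, t_{i+1}),
    # so the cumulative volume is piecewise linear through the tick times
    vol_at_tick = np.concatenate([[0.0], np.cumsum(rate[:-1] * np.diff(t_tick))])

    def pumped_until(t: float) -> float:
        return float(np.interp(t, t_tick, vol_at_tick))

    t_m = meas.time_h.to_numpy()
    g_m = meas.measured_g_per_L.to_numpy()
    v_m = meas.V_L.to_numpy()
    recs = []
    for k in range(1, len(t_m)):
        interval = t_m[k] - t_m[k - 1]
        if interval <= 0:
            continue
        F = pumped_until(t_m[k]) - pumped_until(t_m[k - 1])
        recs.append({
            "t_h": t_m[k],
            "C_g_per_h": consumption_rate(g_m[k - 1], v_m[k - 1], g_m[k],
                                          v_m[k], F, stock, interval),
            "G_prev": g_m[k - 1], "G_now": g_m[k],
            "V_prev": v_m[k - 1], "V_now": v_m[k],
            "F_mL": F, "I_h": interval,
        })
    out = pd.DataFrame.from_records(recs)
    if smooth > 1:
        out["C_g_per_h"] = (
            out["C_g_per_h"].rolling(smooth, center=True, min_periods=1).mean()
        )
    return out


def yield_summary(groups: dict[str, list], pooled: bool = False) -> dict:
    """Group means/SDs and an unpaired two-tailed t test on run yields.

    ``groups`` maps group name (e.g. "manual", "automated") to per-run yields
    in mg per L of culture. Welch's t test by default; set ``pooled`` for the
    equal-variance version. Exactly two groups are compared.
    """
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise InsufficientDataError(f"group {name!r} has < 2 runs")
    (name_a, a), (name_b, b) = groups.items()
    a, b = np.asarray(a, float), np.asarray(b, float)
    t_stat, p = stats.ttest_ind(a, b, equal_var=pooled)
    return {
        "groups": {
            name_a: {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
            name_b: {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
        },
        "mean_difference": float(a.mean() - b.mean()),
        "t_statistic": float(t_stat),
        "p_value": float(p),
        "test": "pooled t" if pooled else "Welch t",
    }
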