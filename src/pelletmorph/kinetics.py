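"""Growth and substrate-uptake kinetics from batch cultivation time series.

From cell dry weight (CDW) and glucose concentration series this module
derives the standard batch physiology parameters:

* µ — specific growth rate (h⁻¹), least-squares slope of ln(CDW) vs time
  over a stated growth window,
* R_s — volumetric substrate uptake rate (g L⁻¹ h⁻¹), endpoint difference
  over the glucose-uptake window,
* q_s — specific uptake rate R_s / X̄ with X̄ the trapezoidal time-average
  CDW over that window (g g⁻¹ h⁻¹),
* Y_x/s — biomass yield ΔCDW_max / consumed glucose (g g⁻¹),
* ΔCDW_max — maximum CDW increase over the run (g L⁻¹).

The talcum carried over from the seed culture is part of the measured CDW
and is not subtracted (it cannot be separated quantitatively and its share
is small).  A `GrowthKineticsModel` wraps the series statsmodels-style: its
``fit()`` returns a `KineticsResult` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthSeries",
    "KineticsResult",
    "GrowthKineticsModel",
    "specific_growth_rate",
    "substrate_rates",
    "yield_and_deltas",
    "detect_uptake_window",
]


@dataclass
class GrowthSeries:
    """CDW and glucose time series of one cultivation replicate."""

    times: np.ndarray  # h
    cdw: np.ndarray  # g/L
    glucose: np.ndarray  # g/L
    replicate: str = "A"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cdw = np.asarray(self.cdw, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if not (len(self.times) == len(self.cdw) == len(self.glucose)):
            raise ValueError("times, cdw and glucose must have equal length")
        if len(self.times) < 2:
            raise ValueError("need at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cdw < 0) or np.any(self.glucose < 0):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, replicate: str | None = None):
        req = {"time_h", "cdw_g_per_L", "glucose_g_per_L"}
        missing = req - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if replicate is not None and "replicate" in df.columns:
            df = df[df["replicate"] == replicate]
        rep = replicate or (
            str(df["replicate"].iloc[0]) if "replicate" in df.columns else "A"
        )
        df = df.sort_values("time_h")
        return cls(
            df["time_h"].to_numpy(),
            df["cdw_g_per_L"].to_numpy(),
            df["glucose_g_per_L"].to_numpy(),
            rep,
        )

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        t0, t1 = window
        if t0 >= t1:
            raise ValueError("window must satisfy t0 < t1")
        if t0 < self.times[0] or t1 > self.times[-1]:
            raise ValueError("window outside the series range")
        return (self.times >= t0) & (self.times <= t1)


@dataclass
class KineticsResult:
    """Derived physiology parameters of one growth series."""

    mu: float  # h⁻¹
    r_s: float  # g L⁻¹ h⁻¹
    q_s: float  # g g⁻¹ h⁻¹
    y_xs: float  # g g⁻¹
    delta_cdw_max: float  # g L⁻¹
    mu_window: tuple[float, float]
    uptake_window: tuple[float, float]
    replicate: str = "A"
    mu_method: str = "log-linear least-squares regression"
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        rows = [
            ("Specific growth rate mu [1/h]", f"{self.mu:.4f}",
             f"window {self.mu_window[0]:g}-{self.mu_window[1]:g} h"),
            ("Substrate uptake rate R_s [g/L/h]", f"{self.r_s:.4f}",
             f"window {self.uptake_window[0]:g}-{self.uptake_window[1]:g} h"),
            ("Specific uptake rate q_s [g/g/h]", f"{self.q_s:.4f}", ""),
            ("Biomass yield Y_x/s [g/g]", f"{self.y_xs:.4f}", ""),
            ("Max CDW increase dCDW_max [g/L]", f"{self.delta_cdw_max:.4f}", ""),
        ]
        width = max(len(r[0]) for r in rows)
        lines = [f"Growth kinetics (replicate {self.replicate})",
                 f"mu estimator: {self.mu_method}", "-" * (width + 22)]
        for name, val, note in rows:
            lines.append(f"{name:<{width}}  {val:>8}  {note}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mu_per_h": self.mu,
            "r_s_g_per_L_h": self.r_s,
            "q_s_g_per_g_h": self.q_s,
            "y_xs_g_per_g": self.y_xs,
            "delta_cdw_max_g_per_L": self.delta_cdw_max,
            "mu_window_h": list(self.mu_window),
            "uptake_window_h": list(self.uptake_window),
            "replicate": self.replicate,
            "mu_method": self.mu_method,
        }


def specific_growth_rate(s: GrowthSeries, window: tuple[float, float]) -> float:
    """Least-squares slope of ln(CDW) vs time over the window (h⁻¹)."""
    mask = s.window_mask(window)
    if mask.sum() < 2:
        raise ValueError("need at least two samples in the window")
    x = s.cdw[mask]
    if np.any(x <= 0):
        raise ValueError("CDW must be positive throughout the growth window")
    slope = np.polyfit(s.times[mask], np.log(x), 1)[0]
    return float(slope)


def detect_uptake_window(
    s: GrowthSeries, depletion_threshold: float = 0.1
) -> tuple[float, float]:
    """Glucose-uptake window: first sample to first sample below threshold.

    When glucose never falls below ``depletion_threshold`` g/L the window
    runs to the glucose minimum.  Raises when glucose does not decrease.
    """
    g = s.glucose
    if g[0] <= g.min() + 1e-12:
        raise ValueError("glucose does not decrease over the series")
    below = np.flatnonzero(g < depletion_threshold)
    end_idx = below[0] if len(below) else int(np.argmin(g))
    if end_idx == 0:
        end_idx = int(np.argmin(g))
    return float(s.times[0]), float(s.times[end_idx])


def substrate_rates(
    s: GrowthSeries, uptake_window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """(R_s, q_s): average uptake rates over the glucose-uptake period.

    R_s is the endpoint glucose difference divided by the window length;
    q_s divides R_s by the trapezoidal time-average CDW over the window.
    """
    window = uptake_window or detect_uptake_window(s)
    mask = s.window_mask(window)
    t = s.times[mask]
    g = s.glucose[mask]
    if len(t) < 2:
        raise ValueError("uptake window contains fewer than two samples")
    if g[-1] >= g[0]:
        raise ValueError("glucose not decreasing over the uptake window")
    r_s = (g[0] - g[-1]) / (t[-1] - t[0])
    x_mean = np.trapezoid(s.cdw[mask], t) / (t[-1] - t[0])
    return float(r_s), float(r_s / x_mean)


def yield_and_deltas(s: GrowthSeries) -> tuple[float, float]:
    """(Y_x/s, ΔCDW_max) over the whole series.

    ΔCDW_max = max(CDW) − CDW(0); Y_x/s = ΔCDW_max / (S(0) − min(S)).
    """
    delta = float(s.cdw.max() - s.cdw[0])
    consumed = float(s.glucose[0] - s.glucose.min())
    if delta <= 0:
        return 0.0, 0.0
    if consumed <= 0:
        raise ValueError("no substrate consumed; yield undefined")
    return delta / consumed, delta


class GrowthKineticsModel:
    """Batch growth kinetics, statsmodels-style.

    Parameters
    ----------
    series : GrowthSeries
        The CDW/glucose time series to analyse.

    ``fit`` accepts explicit µ and uptake windows (h); when omitted the
    uptake window is auto-detected (start to glucose depletion) and the µ
    window defaults to the uptake window, mirroring the convention that the
    growth phase coincides with the period of glucose consumption.
    """

    def __init__(self, series: GrowthSeries):
        self.series = series

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, replicate: str | None = None):
        return cls(GrowthSeries.from_dataframe(df, replicate))

    def fit(
        self,
        mu_window: tuple[float, float] | None = None,
        uptake_window: tuple[float, float] | None = None,
    ) -> KineticsResult:
        s = self.series
        uw = uptake_window or detect_uptake_window(s)
        mw = mu_window or uw
        mu = specific_growth_rate(s, mw)
        r_s, q_s = substrate_rates(s, uw)
        y_xs, delta = yield_and_deltas(s)
        mask = s.window_mask(uw)
        x_mean = np.trapezoid(s.cdw[mask], s.times[mask]) / (uw[1] - uw[0])
        return KineticsResult(
            mu=mu,
            r_s=r_s,
            q_s=q_s,
            y_xs=y_xs,
            delta_cdw_max=delta,
            mu_window=(float(mw[0]), float(mw[1])),
            uptake_window=(float(uw[0]), float(uw[1])),
            replicate=s.replicate,
            diagnostics={"mean_cdw_uptake_window": float(x_mean)},
        )
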