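"""Bioluminescence preprocessing and circadian period estimation.

Plate-reader timeseries (e.g. a per3:luciferase reporter read in
counts-per-second every ~10 min) are background-subtracted against blank
wells, detrended (moving-average baseline subtraction and division by a
moving-average amplitude envelope) and mean-normalised.  The circadian
period is then estimated per well by nonlinear least squares: a cosine
``A cos(2 pi t / T + phi)`` (plus an optional residual linear term) is
fitted to the free-running portion of the trace, initialised from the
dominant periodogram peak inside a user-defined window of plausible
circadian periods (e.g. 18-32 h for untreated fish, 28-42 h under a
period-lengthening drug).  Estimates whose period hits the window boundary
or whose relative period standard error exceeds a threshold are flagged
equivocal for manual review; wells with no spectral peak in the window or
a failed fit are flagged failed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LuminescencePlate",
    "PeriodEstimate",
    "preprocess",
    "crop_free_running",
    "fit_period",
    "fit_plate",
]

DEFAULT_WINDOW = (18.0, 32.0)


@dataclass
class LuminescencePlate:
    """Per-well luminescence timeseries with blank annotations.

    ``data`` is timepoints x wells (counts-per-second); time advances by
    ``interval_minutes`` per row, starting at circadian time ``ct_start``
    hours (hours since the last Zeitgeber).
    """

    data: pd.DataFrame
    interval_minutes: float = 9.92
    blank_wells: tuple[str, ...] = ()
    conditions: Mapping[str, str] = field(default_factory=dict)
    ct_start: float = 0.0

    def __post_init__(self) -> None:
        missing = [w for w in self.blank_wells if w not in self.data.columns]
        if missing:
            raise ValueError(f"blank wells absent from plate: {missing}")

    @property
    def times_hours(self) -> np.ndarray:
        """Circadian-time axis in hours."""
        n = len(self.data)
        return self.ct_start + np.arange(n) * self.interval_minutes / 60.0

    @property
    def sample_wells(self) -> list[str]:
        return [w for w in self.data.columns if w not in self.blank_wells]


@dataclass(frozen=True)
class PeriodEstimate:
    period: float
    amplitude: float
    phase: float
    rel_se: float
    gof: float  # fraction of variance explained by the fit
    window: tuple[float, float]
    flag: str  # "ok" | "equivocal" | "failed"


def _rolling_mean(x: np.ndarray, window_pts: int) -> np.ndarray:
    """Centred moving average with reflected ends (a shrinking edge window
    would bend the baseline at the record boundaries and bias the fit)."""
    window_pts = min(window_pts, 2 * x.size - 1)
    half = window_pts // 2
    padded = np.concatenate([x[half:0:-1], x, x[-2 : -half - 2 : -1]])
    kernel = np.full(window_pts, 1.0 / window_pts)
    smoothed = np.convolve(padded, kernel, mode="valid")
    return smoothed[: x.size]


def preprocess(
    plate: LuminescencePlate,
    baseline_window_hours: float = 48.0,
    envelope_window_hours: float = 48.0,
) -> pd.DataFrame:
    """Background-subtract, detrend and normalise every sample well.

    Steps: (1) subtract the mean blank signal per timepoint (skipped with a
    warning if the plate has no blanks); (2) subtract a centred
    moving-average baseline; (3) divide by a moving-average amplitude
    envelope (of the absolute detrended signal), making the output
    invariant to rescaling the raw counts; (4) centre on the mean.

    The default 48 h windows deliberately exceed the longest plausible
    circadian period: a moving average shorter than the rhythm partially
    tracks the oscillation and biases the downstream period fit.
    """
    data = plate.data[plate.sample_wells].astype(float)
    if plate.blank_wells:
        background = plate.data[list(plate.blank_wells)].astype(float).mean(axis=1)
        data = data.sub(background, axis=0)
    else:
        warnings.warn("plate has no blank wells; background subtraction skipped", stacklevel=2)
    pts_per_hour = 60.0 / plate.interval_minutes
    b_win = max(3, int(round(baseline_window_hours * pts_per_hour)))
    e_win = max(3, int(round(envelope_window_hours * pts_per_hour)))
    out = {}
    for well in data.columns:
        x = data[well].to_numpy()
        detr = x - _rolling_mean(x, b_win)
        envelope = _rolling_mean(np.abs(detr), e_win)
        floor = np.nanmax(envelope) * 1e-6
        if not np.isfinite(floor) or floor == 0:
            out[well] = np.zeros_like(detr)
            continue
        norm = detr / np.maximum(envelope, floor)
        out[well] = norm - norm.mean()
    return pd.DataFrame(out, index=plate.data.index)


def crop_free_running(
    series: pd.Series | pd.DataFrame | np.ndarray,
    times_hours: np.ndarray,
    crop_ct: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop samples before ``crop_ct`` (hours of circadian time).

    Used to restrict period analysis to free-running conditions, e.g. 24 h
    after the end of the last partial light:dark cycle.
    """
    times_hours = np.asarray(times_hours, dtype=float)
    values = np.asarray(series, dtype=float)
    if crop_ct > times_hours[-1]:
        raise ValueError("crop point lies beyond the end of the series")
    keep = times_hours >= crop_ct
    return values[keep], times_hours[keep]


def _periodogram_peak(
    values: np.ndarray, times: np.ndarray, window: tuple[float, float], n_grid: int = 400
) -> float | None:
    """Period (hours) of the dominant spectral peak inside the window.

    The discrete Fourier spectrum is evaluated on a fine period grid
    restricted to the window (the record is short relative to circadian
    periods, so the natural FFT bins are too coarse to seed the fit)."""
    detrended = values - values.mean()
    periods = np.linspace(window[0], window[1], n_grid)
    phase = np.exp(-2j * np.pi * np.outer(1.0 / periods, times))
    power = np.abs(phase @ detrended) ** 2
    if power.max() <= 0:
        return None
    return float(periods[np.argmax(power)])


def _cosine(t, amplitude, period, phase, offset, slope):
    return amplitude * np.cos(2.0 * np.pi * t / period + phase) + offset + slope * t


def fit_period(
    series: np.ndarray,
    times_hours: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
    linear_term: bool = True,
    equivocal_rel_se: float = 0.10,
    min_gof: float = 0.2,
) -> PeriodEstimate:
    """Cosine NLLS period estimate within a bounded window of periods.

    The fit is seeded from the dominant periodogram peak inside ``window``
    and bounded to it; a single cosine component (plus offset and optional
    residual linear term) is fitted by least squares.  Flags: ``failed`` if
    no in-window spectral peak exists or the fit does not converge;
    ``equivocal`` if the relative period standard error exceeds
    ``equivocal_rel_se``, the cosine explains less than ``min_gof`` of the
    variance (e.g. the true rhythm lies outside the window), or the period
    sticks to a window boundary (manual review); ``ok`` otherwise, in
    which case the period lies strictly inside the window.
    """
    values = np.asarray(series, dtype=float)
    times = np.asarray(times_hours, dtype=float)
    if values.size != times.size or values.size < 8:
        raise ValueError("series and time axis must match and hold >= 8 samples")
    low, high = window
    if not (0 < low < high):
        raise ValueError("window must satisfy 0 < low < high")
    nan_est = PeriodEstimate(float("nan"), float("nan"), float("nan"), float("nan"), 0.0, window, "failed")
    p0_period = _periodogram_peak(values, times, window)
    if p0_period is None:
        return nan_est
    amp0 = float(np.std(values)) * float(np.sqrt(2.0))
    p0 = [amp0, p0_period, 0.0, float(values.mean()), 0.0]
    bounds_lo = [0.0, low, -2 * np.pi, -np.inf, -np.inf]
    bounds_hi = [np.inf, high, 2 * np.pi, np.inf, np.inf]
    if not linear_term:
        p0 = p0[:4]
        bounds_lo, bounds_hi = bounds_lo[:4], bounds_hi[:4]
        model = lambda t, a, T, ph, c: _cosine(t, a, T, ph, c, 0.0)  # noqa: E731
    else:
        model = _cosine
    try:
        popt, pcov = curve_fit(
            model, times, values, p0=p0, bounds=(bounds_lo, bounds_hi), maxfev=20000
        )
    except (RuntimeError, ValueError):
        return nan_est
    amplitude, period, phase = float(popt[0]), float(popt[1]), float(popt[2])
    residuals = values - model(times, *popt)
    total_var = float(np.sum((values - values.mean()) ** 2))
    gof = 1.0 - float(np.sum(residuals**2)) / total_var if total_var > 0 else 0.0
    period_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("inf")
    rel_se = period_se / period if period > 0 else float("inf")
    edge = 0.01 * (high - low)
    flag = "ok"
    if (
        rel_se > equivocal_rel_se
        or gof < min_gof
        or period <= low + edge
        or period >= high - edge
    ):
        flag = "equivocal"
    phase_hours = -phase * period / (2.0 * np.pi)
    return PeriodEstimate(period, abs(amplitude), phase_hours, rel_se, gof, window, flag)


def fit_plate(
    plate: LuminescencePlate,
    windows: Mapping[str, tuple[float, float]] | tuple[float, float] = DEFAULT_WINDOW,
    crop_ct: float | None = None,
    baseline_window_hours: float = 48.0,
    envelope_window_hours: float = 48.0,
    equivocal_rel_se: float = 0.10,
    min_gof: float = 0.2,
) -> pd.DataFrame:
    """Preprocess, crop and fit every sample well of a plate.

    ``windows`` may be a single (low, high) window or a per-condition
    mapping (separate groups get separate windows of plausible periods).
    Returns one row per well: condition, period, amplitude, phase, rel_se,
    gof and flag.
    """
    processed = preprocess(plate, baseline_window_hours, envelope_window_hours)
    times = plate.times_hours
    rows = []
    for well in processed.columns:
        condition = plate.conditions.get(well, "")
        if isinstance(windows, Mapping):
            window = windows.get(condition, DEFAULT_WINDOW)
        else:
            window = windows
        values = processed[well].to_numpy()
        t = times
        if crop_ct is not None:
            values, t = crop_free_running(values, times, crop_ct)
        est = fit_period(
            values, t, window=window, equivocal_rel_se=equivocal_rel_se, min_gof=min_gof
        )
        rows.append(
            {
                "well": well,
                "condition": condition,
                "period_hours": est.period,
                "amplitude": est.amplitude,
                "phase_hours": est.phase,
                "rel_se": est.rel_se,
                "gof": est.gof,
                "window_low": window[0],
                "window_high": window[1],
                "flag": est.flag,
            }
        )
    return pd.DataFrame(rows).set_index("well")
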