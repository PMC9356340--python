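"""Minute-level summary measures of raw tri-axial acceleration.

Four open-source epoch measures are computed per calendar minute:

* ENMO — mean over samples of max(‖a‖ − 1, 0), in g, on autocalibrated data;
* MAD — mean absolute deviation of ‖a‖ from its minute mean, in g;
* AI — per 1-s sub-epoch, sqrt of the mean per-axis variance in excess of a
  systematic noise variance σ̄², floored at 0; the minute value is the sum
  over sub-epochs;
* MIMS — per axis: resample to a common rate, extrapolate dynamic-range
  clipping, band-pass filter (zero-phase Butterworth), rectify, integrate
  over the minute, truncate near-zero values; the minute value is the sum
  of the three axis integrals.

Autocalibration estimates per-axis gain and offset so that still-window
accelerations lie on the unit gravity sphere; only ENMO uses it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_formats import RawSignal


@dataclass
class MIMSParams:
    """Constants of the MIMS pipeline (all surfaced, none hard-coded)."""

    resample_hz: float = 100.0
    band_low_hz: float = 0.2
    band_high_hz: float = 5.0
    filter_order: int = 4
    truncation_threshold: float = 1e-4  # per axis-minute integral, g·s
    extrapolate_clipped: bool = True
    extrapolation_cap_factor: float = 1.5  # × dynamic range
    clip_tol_g: float = 0.05

    def validate(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz < self.resample_hz / 2:
            raise ValueError("need 0 < band_low < band_high < resample_hz/2")


@dataclass
class AIParams:
    noise_variance_g2: float = 0.0  # σ̄², systematic device noise variance
    sub_epoch_s: float = 1.0


@dataclass
class CalibrationModel:
    """Per-axis affine correction a ↦ gain·a + offset onto the unit sphere."""

    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_still_windows: int = 0
    residual_before: float = float("nan")
    residual_after: float = float("nan")

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls()

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz * self.gain + self.offset


@dataclass
class MeasureParams:
    mims: MIMSParams = field(default_factory=MIMSParams)
    ai: AIParams = field(default_factory=AIParams)
    calibration: CalibrationModel = field(default_factory=CalibrationModel.identity)
    still_sd_g: float = 0.013
    still_win_s: float = 10.0
    sphere_coverage_g: float = 0.3


def vector_magnitude(x, y, z):
    """Euclidean norm ‖(x, y, z)‖ in g; accepts scalars or arrays."""
    return np.sqrt(np.square(x) + np.square(y) + np.square(z))


def compute_enmo(minute: RawSignal, calib: CalibrationModel | None = None) -> float:
    """Euclidean norm minus one: mean over samples of max(r − 1, 0), in g."""
    if minute.n_samples == 0:
        return float("nan")
    xyz = minute.xyz if calib is None else calib.apply(minute.xyz)
    r = np.sqrt(np.sum(xyz**2, axis=1))
    return float(np.mean(np.maximum(r - 1.0, 0.0)))


def compute_mad(minute: RawSignal) -> float:
    """Mean amplitude deviation: (1/n) Σ |r_i − r̄|, in g. NaN below 2 samples."""
    if minute.n_samples < 2:
        return float("nan")
    r = minute.magnitude()
    return float(np.mean(np.abs(r - r.mean())))


def compute_ai(minute: RawSignal, params: AIParams | None = None) -> float:
    """Activity intensity: Σ over sub-epochs of sqrt(max(mean_m(σ²_m − σ̄²), 0)).

    Per-axis variances use the unbiased (n−1) estimator. A sub-epoch with
    fewer than 2 samples contributes 0 with a warning.
    """
    params = params or AIParams()
    fs = minute.sample_rate_hz
    n_per = int(round(params.sub_epoch_s * fs))
    if n_per < 1:
        raise ValueError("sub-epoch shorter than one sample")
    xyz = minute.xyz
    total = 0.0
    n_sub = int(np.ceil(minute.n_samples / n_per))
    for j in range(n_sub):
        seg = xyz[j * n_per:(j + 1) * n_per]
        if len(seg) < 2:
            warnings.warn("sub-epoch with <2 samples contributes 0 to AI")
            continue
        var = seg.var(axis=0, ddof=1)
        total += float(np.sqrt(max(np.mean(var - params.noise_variance_g2), 0.0)))
    return total


def _still_window_means(signals, still_sd_g, win_s):
    means = []
    for sig in signals:
        n_win = int(round(win_s * sig.sample_rate_hz))
        if n_win < 2:
            continue
        xyz = sig.xyz
        n_full = len(xyz) // n_win
        if n_full == 0:
            continue
        blocks = xyz[: n_full * n_win].reshape(n_full, n_win, 3)
        sd = blocks.std(axis=1, ddof=1)
        still = np.all(sd < still_sd_g, axis=1)
        if still.any():
            means.append(blocks[still].mean(axis=1))
    if not means:
        return np.empty((0, 3))
    return np.vstack(means)


def autocalibrate(
    signals: list[RawSignal] | RawSignal,
    still_sd_g: float = 0.013,
    win_s: float = 10.0,
    sphere_coverage_g: float = 0.3,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CalibrationModel:
    """Estimate per-axis gain/offset from still windows (unit-sphere fit).

    Non-overlapping windows of ``win_s`` seconds whose per-axis SD is below
    ``still_sd_g`` are treated as still; their mean vectors should lie on the
    unit gravity sphere. Gains and offsets are found by iteratively
    regressing each axis onto the closest sphere point. If no still windows
    exist, or the window means do not reach ±``sphere_coverage_g`` on every
    axis (insufficient orientation variety), the identity model is returned
    with a warning.
    """
    if isinstance(signals, RawSignal):
        signals = [signals]
    pts = _still_window_means(signals, still_sd_g, win_s)
    if len(pts) == 0:
        warnings.warn("no still windows found; using identity calibration")
        return CalibrationModel.identity()
    covered = np.all((pts.min(axis=0) < -sphere_coverage_g)
                     & (pts.max(axis=0) > sphere_coverage_g))
    if not covered:
        warnings.warn("insufficient sphere coverage of still windows; "
                      "using identity calibration")
        m = CalibrationModel.identity()
        m.n_still_windows = len(pts)
        return m

    gain = np.ones(3)
    offset = np.zeros(3)
    res0 = float(np.mean(np.abs(np.linalg.norm(pts, axis=1) - 1.0)))
    prev = np.inf
    for _ in range(max_iter):
        cur = pts * gain + offset
        norms = np.linalg.norm(cur, axis=1)
        target = cur / norms[:, None]
        for m in range(3):
            A = np.column_stack([np.ones(len(cur)), cur[:, m]])
            (a, b), *_ = np.linalg.lstsq(A, target[:, m], rcond=None)
            gain[m] *= b
            offset[m] = offset[m] * b + a
        res = float(np.mean(np.abs(np.linalg.norm(pts * gain + offset, axis=1) - 1.0)))
        if abs(prev - res) < tol:
            break
        prev = res
    return CalibrationModel(gain, offset, len(pts), res0, res)


def _extrapolate_clipped(a: np.ndarray, t: np.ndarray, range_g: float,
                         tol_g: float, cap_factor: float) -> np.ndarray:
    """Replace dynamic-range-clipped runs with a local quadratic through the
    neighboring samples, capped in magnitude at cap_factor × range."""
    out = a.copy()
    clipped = np.abs(a) >= range_g - tol_g
    if not clipped.any():
        return out
    padded = np.concatenate([[False], clipped, [False]])
    d = np.diff(padded.astype(np.int8))
    starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    k = 3  # neighbors per side for the quadratic fit
    for s, e in zip(starts, ends):
        lo, hi = max(s - k, 0), min(e + k, len(a))
        nb = np.r_[np.arange(lo, s), np.arange(e, hi)]
        if len(nb) < 3:
            continue
        coef = np.polyfit(t[nb] - t[s], a[nb], 2)
        fit = np.polyval(coef, t[s:e] - t[s])
        cap = cap_factor * range_g
        out[s:e] = np.clip(fit, -cap, cap)
        # never shrink below the recorded clipped magnitude
        sign = np.sign(a[s:e])
        out[s:e] = np.where(np.abs(out[s:e]) < np.abs(a[s:e]), a[s:e], out[s:e])
        out[s:e] = np.where(sign * out[s:e] < 0, a[s:e], out[s:e])
    return out


def compute_mims(minute: RawSignal, params: MIMSParams | None = None) -> float:
    """Monitor-independent movement summary for one minute (unitless).

    Pipeline: linear resample → clipped-run extrapolation → zero-phase
    Butterworth band-pass → rectify → per-axis trapezoidal integration over
    the minute (time in seconds) → per-axis truncation to 0 below the
    threshold → sum of the three axes.
    """
    params = params or MIMSParams()
    params.validate()
    if minute.n_samples < 2:
        return float("nan")
    fs_in = minute.sample_rate_hz
    t_in = np.arange(minute.n_samples) / fs_in
    dur = minute.n_samples / fs_in
    n_out = int(round(dur * params.resample_hz))
    t_out = np.arange(n_out) / params.resample_hz
    sos = sps.butter(params.filter_order,
                     [params.band_low_hz, params.band_high_hz],
                     btype="bandpass", fs=params.resample_hz, output="sos")
    total = 0.0
    for a in (minute.x, minute.y, minute.z):
        if params.extrapolate_clipped:
            a = _extrapolate_clipped(a, t_in, minute.dynamic_range_g,
                                     params.clip_tol_g,
                                     params.extrapolation_cap_factor)
        res = np.interp(t_out, t_in, a)
        filt = sps.sosfiltfilt(sos, res)
        integ = float(np.trapezoid(np.abs(filt), dx=1.0 / params.resample_hz))
        if integ < params.truncation_threshold:
            integ = 0.0
        total += integ
    return total


def summarize_minutes(signal: RawSignal,
                      params: MeasureParams | None = None) -> pd.DataFrame:
    """All four measures for every complete calendar minute of a raw signal.

    Returns a DataFrame indexed by minute start with columns
    ``mims, enmo, mad, ai``. Partial boundary minutes are omitted.
    """
    params = params or MeasureParams()
    fs = signal.sample_rate_hz
    start = signal.start_time
    first_minute = start.ceil("min") if start != start.floor("min") else start
    end = start + pd.Timedelta(seconds=signal.n_samples / fs)
    rows, idx = [], []
    minute = first_minute
    while minute + pd.Timedelta(minutes=1) <= end:
        i0 = int(round((minute - start).total_seconds() * fs))
        i1 = i0 + int(round(60 * fs))
        sl = signal.slice(i0, min(i1, signal.n_samples))
        rows.append({
            "mims": compute_mims(sl, params.mims),
            "enmo": compute_enmo(sl, params.calibration),
            "mad": compute_mad(sl),
            "ai": compute_ai(sl, params.ai),
        })
        idx.append(minute)
        minute += pd.Timedelta(minutes=1)
    return pd.DataFrame(rows, index=pd.DatetimeIndex(idx))
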