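"""Seeded generators for raw signals and minute-level cohorts.

Real wrist-accelerometry studies of the kind this pipeline targets are not
publicly deposited, so every module is exercised against simulated data with
known ground truth:

* raw 80 Hz tri-axial signals: a slowly drifting gravity unit vector, a
  bout-dependent band-limited (0.5–3 Hz) movement oscillation, white sensor
  noise, and scheduled artifacts (dynamic-range clipping runs, stuck-value
  runs, spikes);
* minute-level cohorts: counts from a zero-inflated gamma intensity process
  whose zero-inflation varies by hour of day (producing realistic diurnal
  median curves), nonwear blocks as long all-zero runs, and each measure
  linked to the count by a known strictly increasing power law
  g(ac) = a·ac^p plus heteroscedastic noise (SD proportional to level).

Truth tables (the mapping g, scheduled wear, QC-clean flags) are returned
alongside, so preprocessing and harmonization can be scored exactly.
All randomness flows from ``SimProfile.seed`` through per-(participant, day)
spawned generator streams (numpy PCG64), so outputs are reproducible
bit-for-bit for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_formats import MINUTES_PER_DAY, MinuteSeries, ParticipantData, RawSignal

# power-law truths a·ac^p per measure, chosen as smooth concave monotone
# shapes whose translated cut-offs and daily sums sit in realistic ranges
DEFAULT_MAPPING_TRUTH = {
    "mims": (0.012, 0.88),
    "enmo": (2.0e-5, 0.93),
    "mad": (3.5e-5, 0.93),
    "ai": (0.004, 0.90),
}


@dataclass
class ArtifactSchedule:
    """Raw-signal artifact injections, in seconds from signal start."""

    clip_runs: list = field(default_factory=list)   # (start_s, duration_s, axis)
    stuck_runs: list = field(default_factory=list)  # (start_s, duration_s)
    spikes: list = field(default_factory=list)      # start_s


@dataclass
class SimProfile:
    """Study-condition parameters for the generators."""

    seed: int = 0
    n_participants: int = 100
    days_per_participant: int = 6
    sample_rate_hz: float = 80.0
    dynamic_range_g: float = 8.0
    # raw-signal bouts: (label, minutes, oscillation amplitude g)
    bout_schedule: list = field(default_factory=lambda: [
        ("sedentary", 20, 0.005), ("light", 6, 0.05), ("mvpa", 4, 0.2),
    ])
    osc_band_hz: tuple = (0.5, 3.0)
    noise_sd_g: float = 0.01
    gravity_drift_rad_per_min: float = 0.02
    artifacts: ArtifactSchedule = field(default_factory=ArtifactSchedule)
    # minute-level cohort
    mapping_truth: dict = field(default_factory=lambda: dict(DEFAULT_MAPPING_TRUTH))
    measure_noise_cv: float = 0.15
    zero_measure_noise_sd: float = 0.002  # measure noise at AC = 0, × g(1000)
    ac_gamma_shape: float = 1.6
    ac_day_mean: float = 2500.0           # mean nonzero count at the diurnal peak
    nonwear_block_prob: float = 0.15      # per participant-day
    nonwear_len_minutes: tuple = (90, 240)
    short_zero_block_prob: float = 0.1    # sub-threshold zero runs (stay wear)
    short_zero_len_minutes: tuple = (30, 85)
    qc_invalid_prob: float = 0.002
    age_range: tuple = (40.0, 92.0)
    bmi_mean_sd: tuple = (27.3, 5.0)

    def truth_fn(self, measure: str):
        a, p = self.mapping_truth[measure]
        return lambda ac: a * np.power(np.maximum(ac, 0.0), p)


def _rng_for(profile: SimProfile, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([profile.seed, *key]))


def _bandlimited_noise(rng, n, fs, band, amp):
    """White noise band-passed to ``band`` and rescaled to RMS ``amp``."""
    w = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    f = sps.sosfiltfilt(sos, w)
    rms = np.sqrt(np.mean(f**2))
    return f * (amp / rms) if rms > 0 else f


def generate_raw_day(profile: SimProfile, participant: int = 0, day: int = 0,
                     duration_s: float = 86400.0,
                     start_time: str | pd.Timestamp | None = None) -> RawSignal:
    """One raw tri-axial signal, deterministic given (seed, participant, day)."""
    rng = _rng_for(profile, 1, participant, day)
    fs = profile.sample_rate_hz
    n = int(round(duration_s * fs))
    t_min = np.arange(n) / fs / 60.0

    # gravity: unit vector with a slow random orientation drift
    theta0, phi0 = rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi)
    theta = theta0 + profile.gravity_drift_rad_per_min * np.cumsum(
        np.interp(t_min, np.arange(int(t_min[-1]) + 2),
                  rng.standard_normal(int(t_min[-1]) + 2)) / 60 / fs * 60)
    phi = phi0 + profile.gravity_drift_rad_per_min * np.cumsum(
        np.interp(t_min, np.arange(int(t_min[-1]) + 2),
                  rng.standard_normal(int(t_min[-1]) + 2)) / 60 / fs * 60)
    grav = np.column_stack([np.sin(theta) * np.cos(phi),
                            np.sin(theta) * np.sin(phi), np.cos(theta)])

    # bout-dependent oscillation amplitude per sample
    amp = np.zeros(n)
    cycle = profile.bout_schedule
    cyc_len = sum(m for _, m, _ in cycle)
    pos = 0.0
    while pos * 60 * fs < n:
        for _, minutes, a in cycle:
            i0 = int(round(pos * 60 * fs))
            i1 = min(int(round((pos + minutes) * 60 * fs)), n)
            if i0 >= n:
                break
            amp[i0:i1] = a
            pos += minutes
    xyz = grav.copy()
    for m in range(3):
        osc = _bandlimited_noise(rng, n, fs, profile.osc_band_hz, 1.0)
        xyz[:, m] += amp * osc * rng.uniform(0.7, 1.3)
        xyz[:, m] += rng.standard_normal(n) * profile.noise_sd_g

    rg = profile.dynamic_range_g
    for (s, d, ax) in profile.artifacts.clip_runs:
        i0, i1 = int(s * fs), min(int((s + d) * fs), n)
        xyz[i0:i1, ax] = rg
    for (s, d) in profile.artifacts.stuck_runs:
        i0, i1 = int(s * fs), min(int((s + d) * fs), n)
        if i1 > i0:
            xyz[i0:i1] = xyz[i0]
    for s in profile.artifacts.spikes:
        # rail-to-rail swing across consecutive samples (jump of 2×range)
        i = min(int(s * fs), n - 2)
        xyz[i], xyz[i + 1] = rg, -rg

    xyz = np.clip(xyz, -rg, rg)
    start = pd.Timestamp(start_time) if start_time is not None else (
        pd.Timestamp("2020-01-01") + pd.Timedelta(days=day))
    return RawSignal(start, fs, xyz[:, 0], xyz[:, 1], xyz[:, 2], rg)


def _diurnal_activity_prob(minute_of_day: np.ndarray) -> np.ndarray:
    """Probability a minute is active (nonzero count), by time of day."""
    h = minute_of_day / 60.0
    base = 0.06 + 0.62 * np.exp(-0.5 * ((h - 11.0) / 3.2) ** 2) \
        + 0.38 * np.exp(-0.5 * ((h - 17.5) / 2.2) ** 2)
    return np.clip(base, 0.02, 0.9)


def generate_minute_cohort(profile: SimProfile):
    """Minute-level cohort with known truth.

    Returns ``(cohort, truth)``: a list of :class:`ParticipantData` (counts,
    measures and QC flags populated; wear/valid flags left to the
    preprocessing stage) and a truth dict with the mapping functions and
    per-participant DataFrames of the scheduled wear and valid states.
    """
    cohort, truth_wear = [], {}
    mod = np.arange(MINUTES_PER_DAY)
    p_active_base = _diurnal_activity_prob(mod)
    for i in range(profile.n_participants):
        rng = _rng_for(profile, 2, i)
        pid = f"P{i:04d}"
        age = float(rng.uniform(*profile.age_range))
        sex = "female" if rng.random() < 0.55 else "male"
        bmi = float(rng.normal(*profile.bmi_mean_sd))
        level = float(np.exp(rng.normal(0.0, 0.25)))  # participant activity level

        n_days = profile.days_per_participant
        n_min = n_days * MINUTES_PER_DAY
        p_act = np.tile(p_active_base, n_days) * level
        active = rng.random(n_min) < np.clip(p_act, 0, 0.95)
        intensity = np.tile(0.4 + 0.6 * p_active_base / p_active_base.max(), n_days)
        scale = profile.ac_day_mean * level * intensity / profile.ac_gamma_shape
        ac = np.where(active,
                      rng.gamma(profile.ac_gamma_shape, 1.0, n_min) * scale, 0.0)
        ac = np.round(ac)

        wear_true = np.ones(n_min, dtype=bool)
        for d in range(n_days):
            if rng.random() < profile.nonwear_block_prob:
                length = int(rng.integers(*profile.nonwear_len_minutes))
                start = int(rng.integers(0, MINUTES_PER_DAY - length))
                sl = slice(d * MINUTES_PER_DAY + start,
                           d * MINUTES_PER_DAY + start + length)
                ac[sl] = 0.0
                wear_true[sl] = False
            if rng.random() < profile.short_zero_block_prob:
                length = int(rng.integers(*profile.short_zero_len_minutes))
                start = int(rng.integers(0, MINUTES_PER_DAY - length))
                sl = slice(d * MINUTES_PER_DAY + start,
                           d * MINUTES_PER_DAY + start + length)
                ac[sl] = 0.0

        qc_invalid = rng.random(n_min) < profile.qc_invalid_prob
        data = {"ac": ac}
        for m, (a, pw) in profile.mapping_truth.items():
            g = profile.truth_fn(m)(ac)
            noise = rng.standard_normal(n_min) * profile.measure_noise_cv * g
            vals = np.maximum(g + noise, 0.0)
            base = profile.zero_measure_noise_sd * profile.truth_fn(m)(1000.0)
            vals[ac == 0] = np.abs(rng.standard_normal(int((ac == 0).sum()))) * base
            data[m] = vals
        idx = pd.date_range("2020-03-02", periods=n_min, freq="min")
        df = pd.DataFrame(data, index=idx)
        df["qc_invalid"] = pd.array(qc_invalid, dtype="boolean")
        series = MinuteSeries(pid, df)
        cohort.append(ParticipantData(pid, age, sex, bmi, series))
        truth_wear[pid] = pd.DataFrame({"wear_true": wear_true,
                                        "qc_invalid_true": qc_invalid}, index=idx)
    truth = {
        "mapping": {m: profile.truth_fn(m) for m in profile.mapping_truth},
        "mapping_params": dict(profile.mapping_truth),
        "wear": truth_wear,
    }
    return cohort, truth


def generate_mapping_pairs(profile: SimProfile, n_pairs: int,
                           measure: str = "mims", seed_key: int = 3):
    """(ac, measure) pairs from the mapping truth with heteroscedastic noise.

    Counts are drawn log-uniformly over a realistic span so the low-count
    curvature is well represented. Returns (ac, values, truth function).
    """
    rng = _rng_for(profile, seed_key)
    ac = np.exp(rng.uniform(np.log(1.0), np.log(12000.0), n_pairs))
    g = profile.truth_fn(measure)
    vals = g(ac) * (1.0 + profile.measure_noise_cv * rng.standard_normal(n_pairs))
    return ac, np.maximum(vals, 0.0), g
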