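"""Raw-data quality-control flags.

Three per-minute flags mark signal patterns unlikely to result from human
movement (they are deliberately not a nonwear detector):

* clipped-sustained — any axis pinned at the dynamic range (within a
  tolerance) for a sustained run;
* stuck values — the identical (x, y, z) triplet repeated for a run;
* spike — an implausibly large sample-to-sample jump on any axis.

A minute is flagged when any sample within it triggers the condition;
``qc_invalid`` is the OR of the three flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import RawSignal


@dataclass
class QCParams:
    """Thresholds for the three flags.

    clip_run_s : minimum duration of a sustained at-range run (seconds).
    stuck_run_s : minimum duration of an identical-triplet run (seconds).
    spike_g : sample-to-sample change on any axis above this is a spike (g).
    clip_tol_g : how close to the dynamic range counts as clipped (g).
    """

    clip_run_s: float = 2.0
    stuck_run_s: float = 1.0
    spike_g: float = 11.0
    clip_tol_g: float = 0.05

    def validate(self) -> None:
        if min(self.clip_run_s, self.stuck_run_s, self.spike_g, self.clip_tol_g) <= 0:
            raise ValueError("all QC thresholds must be positive")


def _samples_in_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """True for samples belonging to a run of True of length >= min_len."""
    out = np.zeros(len(mask), dtype=bool)
    if len(mask) == 0 or min_len <= 0:
        return out
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            out[s:e] = True
    return out


def qc_flag_minutes(signal: RawSignal, params: QCParams | None = None) -> pd.DataFrame:
    """Per-calendar-minute QC flags for a raw signal.

    Returns a DataFrame indexed by minute start with boolean columns
    ``flag_clipped_sustained``, ``flag_stuck_values``, ``flag_spike`` and
    ``qc_invalid`` (their OR). Raises if the signal spans less than one minute.
    """
    params = params or QCParams()
    params.validate()
    if signal.duration_s < 60:
        raise ValueError("signal must cover at least one full minute")
    fs = signal.sample_rate_hz
    xyz = signal.xyz
    n = signal.n_samples

    clip_len = max(int(round(params.clip_run_s * fs)), 1)
    at_range = np.abs(xyz) >= (signal.dynamic_range_g - params.clip_tol_g)
    clipped = np.zeros(n, dtype=bool)
    for m in range(3):
        clipped |= _samples_in_runs(at_range[:, m], clip_len)

    # a run of k equal consecutive-pair indicators spans k+1 identical samples
    stuck_len = max(int(round(params.stuck_run_s * fs)), 1)
    eq_next = np.all(np.diff(xyz, axis=0) == 0.0, axis=1)
    stuck_pairs = _samples_in_runs(eq_next, max(stuck_len - 1, 1))
    stuck = np.zeros(n, dtype=bool)
    stuck[:-1] |= stuck_pairs
    stuck[1:] |= stuck_pairs

    jump = np.abs(np.diff(xyz, axis=0)) > params.spike_g
    spike_pairs = jump.any(axis=1)
    spike = np.zeros(n, dtype=bool)
    spike[:-1] |= spike_pairs
    spike[1:] |= spike_pairs

    minute_codes = (signal.sample_times().asi8 // 60_000_000_000)
    uniq, inv = np.unique(minute_codes, return_inverse=True)
    agg = lambda flags: np.bincount(inv, weights=flags, minlength=len(uniq)) > 0
    idx = pd.to_datetime(uniq * 60_000_000_000)
    out = pd.DataFrame({
        "flag_clipped_sustained": agg(clipped),
        "flag_stuck_values": agg(stuck),
        "flag_spike": agg(spike),
    }, index=idx)
    out["qc_invalid"] = out.any(axis=1)
    return out


def write_qc_report(flags: pd.DataFrame, path) -> None:
    """Serialize the per-minute QC flags as 0/1 CSV."""
    flags.astype(int).rename_axis("timestamp").to_csv(path)
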