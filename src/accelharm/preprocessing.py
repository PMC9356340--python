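"""Minute-level preprocessing: wear detection, validity flags, winsorization.

The rules, in pipeline order:

* a minute is nonwear iff it lies in a maximal run of consecutive
  zero-count minutes at least 90 minutes long (run length configurable);
* a minute is valid iff it is wear and no raw-data QC flag fired in it;
* a calendar day (12:00 AM–11:59 PM, 1440 minutes) is valid iff it has at
  most 10% (144) invalid minutes;
* participants with fewer than 3 valid days are dropped, and invalid days
  are dropped from retained participants;
* each measure is winsorized at the cohort-wide 0.999 quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (MEASURE_COLUMNS, MINUTES_PER_DAY, MinuteSeries,
                         ParticipantData)

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    nonwear_run_minutes: int = 90
    max_invalid_per_day: int = 144
    min_valid_days: int = 3
    winsor_quantile: float = 0.999
    # isolated nonzero "artifactual" runs up to this length inside a zero run
    # are tolerated when joining zero runs; 0 = the literal rule
    artifact_tolerance_minutes: int = 0

    def validate(self) -> None:
        if min(self.nonwear_run_minutes, self.max_invalid_per_day,
               self.min_valid_days) <= 0:
            raise ValueError("run/threshold parameters must be positive")
        if not 0 < self.winsor_quantile < 1:
            raise ValueError("winsor_quantile must be in (0, 1)")
        if self.artifact_tolerance_minutes < 0:
            raise ValueError("artifact_tolerance_minutes must be >= 0")


def detect_nonwear(ac: np.ndarray | pd.Series,
                   run_minutes: int = 90,
                   artifact_tolerance_minutes: int = 0) -> np.ndarray:
    """Wear flags from minute counts: True = wear, False = nonwear.

    A minute is nonwear iff it belongs to a maximal run of consecutive
    zero-count minutes of length >= ``run_minutes``. Missing counts are
    treated as zero for run detection (and logged). With a positive
    ``artifact_tolerance_minutes``, nonzero runs no longer than that,
    flanked by zeros, are treated as zero when measuring run lengths.
    """
    ac = np.asarray(pd.Series(ac, dtype=float))
    n_missing = int(np.isnan(ac).sum())
    if n_missing:
        log.info("detect_nonwear: %d missing counts treated as 0", n_missing)
    zero = np.nan_to_num(ac, nan=0.0) == 0.0
    effective = zero.copy()
    if artifact_tolerance_minutes > 0:
        padded = np.concatenate([[True], zero, [True]])
        d = np.diff(padded.astype(np.int8))
        nz_starts, nz_ends = np.flatnonzero(d == -1), np.flatnonzero(d == 1)
        for s, e in zip(nz_starts, nz_ends):
            interior = s > 0 and e < len(zero)
            if interior and e - s <= artifact_tolerance_minutes:
                effective[s:e] = True
    wear = np.ones(len(ac), dtype=bool)
    padded = np.concatenate([[False], effective, [False]])
    d = np.diff(padded.astype(np.int8))
    for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if e - s >= run_minutes:
            wear[s:e] = np.where(effective[s:e], False, wear[s:e])
    return wear


def flag_valid(series: MinuteSeries) -> MinuteSeries:
    """valid = wear AND NOT qc_invalid, minute-wise (missing flags → invalid)."""
    df = series.data
    wear = df["wear"].fillna(False)
    qc = df["qc_invalid"].fillna(True)
    df["valid"] = (wear & ~qc).astype("boolean")
    return series


def flag_valid_days(series: MinuteSeries,
                    max_invalid_per_day: int = 144) -> pd.Series:
    """Per-calendar-day validity: at most ``max_invalid_per_day`` invalid minutes.

    Minutes with a missing valid flag count as invalid. The grid completion
    in :class:`MinuteSeries` guarantees 1440 slots per day, so partial
    first/last days are automatically penalized for their absent minutes.
    """
    valid = series.data["valid"].fillna(False).astype(bool)
    invalid_per_day = (~valid).groupby(series.data.index.normalize()).sum()
    if (invalid_per_day.index.to_series().diff().dropna() != pd.Timedelta(days=1)).any():
        log.info("flag_valid_days: non-contiguous days for %s", series.participant_id)
    return invalid_per_day <= max_invalid_per_day


def preprocess_participant(p: ParticipantData,
                           params: PreprocessParams | None = None) -> ParticipantData:
    """Wear → valid → valid-day flags for one participant, in place."""
    params = params or PreprocessParams()
    params.validate()
    df = p.minutes.data
    wear = detect_nonwear(df["ac"], params.nonwear_run_minutes,
                          params.artifact_tolerance_minutes)
    df["wear"] = pd.array(wear, dtype="boolean")
    if df["qc_invalid"].isna().all():
        # minute-level-only runs carry no raw QC; treat as not flagged
        df["qc_invalid"] = df["qc_invalid"].fillna(False)
    flag_valid(p.minutes)
    p.valid_day_flags = flag_valid_days(p.minutes, params.max_invalid_per_day)
    return p


def select_participants(cohort: list[ParticipantData],
                        min_valid_days: int = 3) -> list[ParticipantData]:
    """Keep participants with >= ``min_valid_days`` valid days; drop their
    invalid days."""
    kept = []
    for p in cohort:
        if p.valid_day_flags is None:
            raise ValueError(f"{p.participant_id}: valid-day flags not computed")
        if int(p.valid_day_flags.sum()) < min_valid_days:
            log.info("dropping %s: %d valid days", p.participant_id,
                     int(p.valid_day_flags.sum()))
            continue
        good_days = p.valid_day_flags[p.valid_day_flags].index
        keep_mask = p.minutes.data.index.normalize().isin(good_days)
        df = p.minutes.data[keep_mask]
        kept.append(ParticipantData(
            p.participant_id, p.age_years, p.sex, p.bmi_kg_m2,
            MinuteSeries(p.participant_id, df.copy()),
            p.valid_day_flags[p.valid_day_flags],
        ))
    return kept


def winsorize(values: np.ndarray | pd.Series, q: float = 0.999) -> tuple[np.ndarray, float]:
    """Cap values above the empirical ``q`` quantile at that quantile.

    The cap is the order statistic at the ceiling index (numpy's "higher"
    quantile method): an interpolated quantile would drift downward when the
    capped data are winsorized again, whereas an order-statistic cap makes
    the operation exactly idempotent. At q = 0.999 on cohort-sized samples
    the two conventions are indistinguishable. Missing values are untouched;
    an all-missing input is an error. Returns (capped, cap). Never increases
    any value.
    """
    v = np.asarray(pd.Series(values, dtype=float))
    if np.all(np.isnan(v)):
        raise ValueError("winsorize: all values missing")
    cap = float(np.nanquantile(v, q, method="higher"))
    out = v.copy()
    out[out > cap] = cap
    return out, cap


def winsorize_cohort(cohort: list[ParticipantData],
                     q: float = 0.999,
                     measures: list[str] = MEASURE_COLUMNS) -> dict[str, float]:
    """Winsorize each measure with a single cohort-wide cap, pooling all
    retained participant-minutes. Returns the caps per measure."""
    caps = {}
    for m in measures:
        pooled = np.concatenate([p.minutes.data[m].to_numpy(dtype=float)
                                 for p in cohort])
        _, cap = winsorize(pooled, q)
        caps[m] = cap
        for p in cohort:
            col = p.minutes.data[m]
            p.minutes.data[m] = col.where(~(col > cap), cap)
    return caps


def validity_report(cohort: list[ParticipantData]) -> pd.DataFrame:
    """Per participant-day validity summary (for the report CSV)."""
    rows = []
    for p in cohort:
        valid = p.minutes.data["valid"].fillna(False).astype(bool)
        by_day = valid.groupby(p.minutes.data.index.normalize())
        for day, g in by_day:
            rows.append({
                "participant": p.participant_id,
                "date": day.date().isoformat(),
                "valid_minutes": int(g.sum()),
                "invalid_minutes": int((~g).sum()),
                "day_valid": bool(p.valid_day_flags.get(day, False))
                if p.valid_day_flags is not None else None,
            })
    return pd.DataFrame(rows)
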