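"""Core data types and the CSV dialects the pipeline reads and writes.

Three kinds of table move through the pipeline:

* raw tri-axial acceleration (``timestamp,X,Y,Z`` in g, nominally 80 Hz,
  optionally preceded by a vendor preamble which is autodetected and skipped);
* minute-level series (``timestamp,AC[,MIMS,ENMO,MAD,AI,qc_invalid,wear,valid]``),
  always completed to full 1440-minute calendar days (12:00 AM–11:59 PM);
* participant metadata (``id,age,sex,bmi``).

Timestamps are local clock time with no timezone arithmetic: a "day" is a
calendar day. Missing values are serialized as empty fields; flags as 0/1.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASURE_COLUMNS = ["ac", "mims", "enmo", "mad", "ai"]
FLAG_COLUMNS = ["qc_invalid", "wear", "valid"]
MINUTES_PER_DAY = 1440


class RawCsvParseError(ValueError):
    """A raw accelerometry CSV row could not be parsed."""


class SampleRateError(ValueError):
    """Observed sampling rate disagrees with the expected rate by more than 1%."""


class DuplicateMinuteError(ValueError):
    """Two rows claim the same calendar minute."""


@dataclass
class RawSignal:
    """Contiguous tri-axial acceleration at a fixed sampling rate, in g."""

    start_time: pd.Timestamp
    sample_rate_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    dynamic_range_g: float = 8.0

    def __post_init__(self):
        self.start_time = pd.Timestamp(self.start_time)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z) >= 1):
            raise ValueError("x, y, z must be equal-length and nonempty")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        for a in (self.x, self.y, self.z):
            if not np.all(np.isfinite(a)):
                raise ValueError("acceleration values must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) sample matrix."""
        return np.column_stack([self.x, self.y, self.z])

    def sample_times(self) -> pd.DatetimeIndex:
        offsets = np.arange(self.n_samples) / self.sample_rate_hz
        return self.start_time + pd.to_timedelta(np.round(offsets * 1e6), unit="us")

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)

    def slice(self, i0: int, i1: int) -> "RawSignal":
        return RawSignal(
            self.start_time + pd.Timedelta(seconds=i0 / self.sample_rate_hz),
            self.sample_rate_hz,
            self.x[i0:i1], self.y[i0:i1], self.z[i0:i1],
            self.dynamic_range_g,
        )


def _sniff_preamble(path) -> int:
    """Number of leading lines before the header row naming the timestamp column."""
    with open(path, "r", newline="") as fh:
        for i, line in enumerate(fh):
            if line.strip().lower().startswith("timestamp"):
                return i
            if i > 50:
                break
    raise RawCsvParseError(f"{path}: no header line starting with 'timestamp' found")


def read_raw_csv(path, expected_hz: float, dynamic_range_g: float = 8.0) -> RawSignal:
    """Read a raw accelerometry CSV, tolerating a vendor preamble.

    The median inter-sample gap must match ``expected_hz`` within 1%,
    otherwise :class:`SampleRateError` is raised.
    """
    skip = _sniff_preamble(path)
    df = pd.read_csv(path, skiprows=skip, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("timestamp", "x", "y", "z"):
        if col not in df.columns:
            raise RawCsvParseError(f"{path}: missing column {col!r}")
    vals = {}
    for col in ("x", "y", "z"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.isna() | ~np.isfinite(v)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: 1 for the header line, 1 for 1-based numbering
            raise RawCsvParseError(
                f"{path}: unparseable value {df[col].iloc[row]!r} in column "
                f"{col!r} at line {skip + row + 2}"
            )
        vals[col] = v.to_numpy()
    ts = pd.to_datetime(df["timestamp"], format="mixed")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise RawCsvParseError(f"{path}: unparseable timestamp at line {skip + row + 2}")
    if ts.dt.tz is not None:
        ts = ts.dt.tz_localize(None)
    gaps = ts.diff().dropna().dt.total_seconds().to_numpy()
    if len(gaps) == 0:
        rate = expected_hz
    else:
        med = float(np.median(gaps))
        if med <= 0:
            raise RawCsvParseError(f"{path}: non-increasing timestamps")
        rate = 1.0 / med
    if abs(rate - expected_hz) > 0.01 * expected_hz:
        raise SampleRateError(
            f"{path}: observed rate {rate:.3f} Hz differs from expected "
            f"{expected_hz:g} Hz by more than 1%"
        )
    return RawSignal(ts.iloc[0], expected_hz, vals["x"], vals["y"], vals["z"],
                     dynamic_range_g)


def write_raw_csv(signal: RawSignal, path) -> None:
    """Write ``timestamp,X,Y,Z`` with 6-decimal values (round-trip safe)."""
    df = pd.DataFrame({
        "timestamp": signal.sample_times().strftime("%Y-%m-%d %H:%M:%S.%f"),
        "X": signal.x, "Y": signal.y, "Z": signal.z,
    })
    df.to_csv(path, index=False, float_format="%.6f")


@dataclass
class MinuteSeries:
    """One participant's minute-level record on a complete 1440-minute/day grid.

    ``data`` is indexed by minute start (aligned to :00 seconds) and carries
    the activity count, the four raw-data measures, and the QC/wear/valid
    flags (pandas nullable booleans; NA until the corresponding stage runs).
    """

    participant_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("data must be indexed by minute-start timestamps")
        if (df.index.second != 0).any():
            raise ValueError("minute starts must align to :00 seconds")
        for col in MEASURE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = df[col].astype(float)
        for col in FLAG_COLUMNS:
            if col not in df.columns:
                df[col] = pd.array([pd.NA] * len(df), dtype="boolean")
            df[col] = df[col].astype("boolean")
        self.data = complete_minute_grid(df)
        # strictly increasing by 60 s within each day; days may be
        # non-adjacent once invalid days have been dropped
        steps = np.diff(self.data.index.asi8)
        same_day = np.diff(self.data.index.normalize().asi8) == 0
        if len(steps) and not np.all(steps[same_day] == 60_000_000_000):
            raise ValueError("minutes must increase strictly by 60 s within a day")
        if len(steps) and np.any(steps <= 0):
            raise ValueError("minutes must be strictly increasing")

    @property
    def n_minutes(self) -> int:
        return len(self.data)

    @property
    def n_days(self) -> int:
        return len(self.data) // MINUTES_PER_DAY

    def day_dates(self) -> list:
        return sorted(set(self.data.index.normalize()))

    def day_frame(self, date) -> pd.DataFrame:
        date = pd.Timestamp(date).normalize()
        return self.data.loc[date:date + pd.Timedelta(days=1) - pd.Timedelta(minutes=1)]

    def copy(self) -> "MinuteSeries":
        return MinuteSeries(self.participant_id, self.data.copy())


def complete_minute_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Expand to full calendar days; inserted slots are missing-valued.

    Never alters observed values: only inserts rows for absent minutes.
    """
    if len(df) == 0:
        return df
    df = df.sort_index()
    days = df.index.normalize().unique()
    grid = pd.DatetimeIndex(np.concatenate(
        [pd.date_range(d, periods=MINUTES_PER_DAY, freq="min").values for d in days]))
    out = df.reindex(grid)
    for col in FLAG_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype("boolean")
    return out


@dataclass
class ParticipantData:
    """A participant: demographics plus their ordered minute-level days."""

    participant_id: str
    age_years: float
    sex: str  # "female" (reference level) or "male"
    bmi_kg_m2: float
    minutes: MinuteSeries
    valid_day_flags: pd.Series | None = None  # indexed by normalized date

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")

    @property
    def n_valid_days(self) -> int:
        if self.valid_day_flags is None:
            raise ValueError("valid_day_flags not computed yet")
        return int(self.valid_day_flags.sum())


def read_minute_ac_csv(path, participant_id: str = "") -> MinuteSeries:
    """Read a minute-level activity-count CSV (``timestamp,count`` per row).

    The minute grid is completed so every day has 1440 slots; absent minutes
    get a missing count. Duplicate minute timestamps raise
    :class:`DuplicateMinuteError`.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    tcol = "timestamp" if "timestamp" in df.columns else df.columns[0]
    ccol = "count" if "count" in df.columns else ("ac" if "ac" in df.columns else df.columns[1])
    ts = pd.to_datetime(df[tcol]).dt.floor("min")
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise DuplicateMinuteError(f"{path}: duplicate minute {dup}")
    out = pd.DataFrame({"ac": pd.to_numeric(df[ccol], errors="coerce").to_numpy()},
                       index=pd.DatetimeIndex(ts))
    return MinuteSeries(participant_id or str(path), out)


def write_minute_summary(series: MinuteSeries, path) -> None:
    """Write one row per minute: timestamp, AC, four measures, three flags.

    Column order is fixed: ``timestamp,ac,mims,enmo,mad,ai,qc_invalid,wear,valid``.
    Values carry 6 decimals; flags are 0/1; missing values are empty fields.
    An empty series produces a header-only file (with a warning).
    """
    if series.n_minutes == 0:
        warnings.warn(f"empty minute series for {series.participant_id}; header-only file")
    df = series.data.copy()
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype("Int64")
    df.index.name = "timestamp"
    df.to_csv(path, float_format="%.6f",
              columns=MEASURE_COLUMNS + FLAG_COLUMNS)


def read_minute_summary(path, participant_id: str = "") -> MinuteSeries:
    """Read back a file written by :func:`write_minute_summary`."""
    df = pd.read_csv(path, index_col="timestamp", parse_dates=True)
    for col in FLAG_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("Int64").astype("boolean")
    return MinuteSeries(participant_id or str(path), df)


def read_metadata_csv(path) -> pd.DataFrame:
    """Participant metadata: id, age (years), sex (female/male), bmi (kg/m²)."""
    df = pd.read_csv(path, dtype={"id": str})
    df.columns = [c.strip().lower() for c in df.columns]
    need = {"id", "age", "sex", "bmi"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: metadata must have columns {sorted(need)}")
    df["sex"] = df["sex"].str.lower()
    if not df["sex"].isin(["female", "male"]).all():
        raise ValueError(f"{path}: sex must be female/male")
    return df.set_index("id")


def write_metadata_csv(cohort: list[ParticipantData], path) -> None:
    pd.DataFrame({
        "id": [p.participant_id for p in cohort],
        "age": [p.age_years for p in cohort],
        "sex": [p.sex for p in cohort],
        "bmi": [p.bmi_kg_m2 for p in cohort],
    }).to_csv(path, index=False)


def write_long_csv(cohort: list[ParticipantData], path) -> None:
    """Tidy long format keyed by (participant, minute, variable)."""
    frames = []
    for p in cohort:
        df = p.minutes.data[MEASURE_COLUMNS].copy()
        df.index.name = "minute"
        long = df.reset_index().melt(id_vars="minute", var_name="variable",
                                     value_name="value")
        long.insert(0, "participant", p.participant_id)
        frames.append(long)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
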