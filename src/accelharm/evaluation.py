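"""Comparison statistics between activity counts and the mapped measures.

Four families of summary, computed per participant and aggregated across
the cohort as mean (SD):

* Pearson correlations between minute-level counts and each measure, with
  intercept-only and demographics-adjusted (age, BMI, sex; female reference)
  linear regressions of the participant-specific correlations;
* percentage errors of estimating daily total counts through the inverse
  mapping: MPE, MAPE, MdPE, MdAPE — defined per day, averaged within
  participant;
* classification of minutes against a count cut-off: accuracy, sensitivity
  and specificity of predicting (AC > cut-off) from (ÂC > cut-off), strict
  inequality, positive class = above the cut-off;
* smoothed 24-hour median count curves per age group, and the curve-level
  MAPE 100·Σ|â − a| / Σa pooled over minutes and groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._spline import fit_penalized_spline
from .harmonization import HarmonizationModel, invert_to_ac
from .io_formats import MINUTES_PER_DAY, ParticipantData

log = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (1853.0, 2860.0, 3940.0)
DEFAULT_AGE_BREAKS = (60.0, 68.0, 75.0)


def _valid_mask(df: pd.DataFrame) -> np.ndarray:
    return df["valid"].fillna(False).to_numpy(dtype=bool)


def participant_correlations(cohort: list[ParticipantData],
                             measure: str) -> pd.DataFrame:
    """Participant-specific Pearson r between counts and one measure.

    Computed over the participant's valid minutes only; participants whose
    series has zero variance (or < 2 valid minutes) get a missing r.
    Returns columns ``participant, r, age, bmi, sex``.
    """
    rows = []
    for p in cohort:
        df = p.minutes.data
        mask = _valid_mask(df)
        a = df["ac"].to_numpy(dtype=float)[mask]
        b = df[measure].to_numpy(dtype=float)[mask]
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if len(a) < 2 or a.std() == 0 or b.std() == 0:
            log.info("%s: degenerate series for correlation (%s)",
                     p.participant_id, measure)
            r = np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"participant": p.participant_id, "r": r,
                     "age": p.age_years, "bmi": p.bmi_kg_m2, "sex": p.sex})
    return pd.DataFrame(rows)


def correlation_regression(records: pd.DataFrame,
                           adjusted: bool = False) -> pd.DataFrame:
    """OLS of participant correlations on an intercept (and demographics).

    The adjusted model regresses r on age, BMI, and sex (female as the
    reference level). Returns estimate, SE, p-value and an α=.05
    significance flag per term.
    """
    rec = records.dropna(subset=["r"])
    if len(rec) < 10:
        raise ValueError(f"need >= 10 correlation records, got {len(rec)}")
    y = rec["r"].to_numpy()
    if adjusted:
        X = pd.DataFrame({
            "age": rec["age"].to_numpy(dtype=float),
            "bmi": rec["bmi"].to_numpy(dtype=float),
            "sex_male": (rec["sex"] == "male").astype(float).to_numpy(),
        })
        X = sm.add_constant(X)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValueError("collinear covariates in adjusted model")
    else:
        X = pd.DataFrame({"const": np.ones(len(y))})
    res = sm.OLS(y, X).fit()
    out = pd.DataFrame({
        "term": X.columns,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "p_value": res.pvalues.to_numpy(),
    })
    out["significant"] = out["p_value"] < 0.05
    return out


def _daily_totals(df: pd.DataFrame, model: HarmonizationModel,
                  measure: str) -> pd.DataFrame:
    day = df.index.normalize()
    ac = df["ac"].to_numpy(dtype=float)
    ac_hat = invert_to_ac(model, np.nan_to_num(df[measure].to_numpy(dtype=float),
                                               nan=0.0))
    g = pd.DataFrame({"day": day, "T": np.nan_to_num(ac, nan=0.0),
                      "That": ac_hat}).groupby("day").sum()
    return g


def total_ac_errors(cohort: list[ParticipantData], model: HarmonizationModel,
                    measure: str, per_day: bool = True) -> pd.DataFrame:
    """Percentage errors of daily-total count estimation, per participant.

    Per day d: e_d = 100 · (T̂_d − T_d) / T_d with T̂_d the sum of inverse-
    mapped measure values. Per participant: MPE = mean(e_d),
    MAPE = mean(|e_d|), MdPE = median(e_d), MdAPE = median(|e_d|).
    Days with T_d = 0 are excluded (logged). With ``per_day=False`` the
    errors are computed on participant-total counts instead.
    """
    rows = []
    for p in cohort:
        g = _daily_totals(p.minutes.data, model, measure)
        nz = g["T"] > 0
        if (~nz).any():
            log.info("%s: %d zero-total days excluded", p.participant_id,
                     int((~nz).sum()))
        g = g[nz]
        if len(g) == 0:
            continue
        if per_day:
            e = 100.0 * (g["That"] - g["T"]) / g["T"]
            rows.append({"participant": p.participant_id,
                         "mpe": float(e.mean()), "mape": float(e.abs().mean()),
                         "mdpe": float(e.median()),
                         "mdape": float(e.abs().median()),
                         "n_days": len(g)})
        else:
            e = 100.0 * (g["That"].sum() - g["T"].sum()) / g["T"].sum()
            rows.append({"participant": p.participant_id, "mpe": e,
                         "mape": abs(e), "mdpe": e, "mdape": abs(e),
                         "n_days": len(g)})
    return pd.DataFrame(rows)


def classification_from_table(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Accuracy, sensitivity, specificity from a 2×2 table (positive = above)."""
    pos, neg = tp + fn, fp + tn
    return {
        "accuracy": (tp + tn) / (pos + neg) if pos + neg else np.nan,
        "sensitivity": tp / pos if pos else np.nan,
        "specificity": tn / neg if neg else np.nan,
    }


def cutoff_classification(cohort: list[ParticipantData],
                          model: HarmonizationModel, measure: str,
                          ac_cutoff: float) -> pd.DataFrame:
    """Per-participant classification of minutes against a count cut-off.

    Truth is (AC > cut-off); prediction is (ÂC > cut-off) with ÂC the
    inverse-mapped measure. Strict inequalities; valid minutes only.
    Participants with no positive minutes get a missing sensitivity.
    """
    rows = []
    for p in cohort:
        df = p.minutes.data
        mask = _valid_mask(df)
        ac = df["ac"].to_numpy(dtype=float)[mask]
        mv = df[measure].to_numpy(dtype=float)[mask]
        ok = np.isfinite(ac) & np.isfinite(mv)
        ac, mv = ac[ok], mv[ok]
        ac_hat = invert_to_ac(model, mv)
        truth, pred = ac > ac_cutoff, ac_hat > ac_cutoff
        tp = int(np.sum(truth & pred)); fn = int(np.sum(truth & ~pred))
        fp = int(np.sum(~truth & pred)); tn = int(np.sum(~truth & ~pred))
        stats = classification_from_table(tp, fn, fp, tn)
        if tp + fn == 0:
            log.info("%s: no minutes above cut-off %g", p.participant_id, ac_cutoff)
        rows.append({"participant": p.participant_id, "cutoff": ac_cutoff,
                     **stats, "tp": tp, "fn": fn, "fp": fp, "tn": tn})
    return pd.DataFrame(rows)


def cohort_mean_sd(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Cohort aggregation: mean and SD of per-participant statistics."""
    return pd.DataFrame({"mean": df[cols].mean(), "sd": df[cols].std(ddof=1)})


def daily_median_curves(cohort: list[ParticipantData],
                        model: HarmonizationModel | None = None,
                        measure: str | None = None,
                        age_breaks=DEFAULT_AGE_BREAKS,
                        smooth: bool = True) -> tuple[pd.DataFrame, float]:
    """Smoothed 24-hour median count curves per age group, plus curve MAPE.

    Per minute-of-day, the median is taken across all participant-days in
    the age group, for counts and (when a model is given) inverse-mapped
    counts. Smoothing is a penalized cubic spline over minute-of-day with
    GCV. The curve MAPE is 100 · Σ|â − a| / Σa pooled over all minutes and
    groups (NaN when no model is given). Empty groups are excluded.
    """
    edges = [-np.inf, *age_breaks, np.inf]
    labels = [f"<{age_breaks[0]:g}"] + [
        f"{age_breaks[i]:g}-{age_breaks[i+1]:g}" for i in range(len(age_breaks) - 1)
    ] + [f">={age_breaks[-1]:g}"]
    t = np.arange(MINUTES_PER_DAY, dtype=float)
    frames = []
    num = den = 0.0
    for lo, hi, lab in zip(edges[:-1], edges[1:], labels):
        members = [p for p in cohort if lo <= p.age_years < hi]
        if not members:
            log.info("age group %s empty; excluded", lab)
            continue
        ac_stack, hat_stack = [], []
        for p in members:
            df = p.minutes.data
            n_days = len(df) // MINUTES_PER_DAY
            ac = np.nan_to_num(df["ac"].to_numpy(dtype=float), nan=0.0)
            ac_stack.append(ac[: n_days * MINUTES_PER_DAY].reshape(n_days, -1))
            if model is not None:
                mv = np.nan_to_num(df[measure].to_numpy(dtype=float), nan=0.0)
                hat = invert_to_ac(model, mv)
                hat_stack.append(hat[: n_days * MINUTES_PER_DAY].reshape(n_days, -1))
        med_ac = np.median(np.vstack(ac_stack), axis=0)
        a = fit_penalized_spline(t, med_ac, n_basis=30)(t) if smooth else med_ac
        row = pd.DataFrame({"group": lab, "minute": t.astype(int), "ac_curve": a})
        if model is not None:
            med_hat = np.median(np.vstack(hat_stack), axis=0)
            ahat = fit_penalized_spline(t, med_hat, n_basis=30)(t) if smooth else med_hat
            row["mapped_curve"] = ahat
            num += float(np.sum(np.abs(ahat - a)))
            den += float(np.sum(a))
        frames.append(row)
    curves = pd.concat(frames, ignore_index=True)
    mape = 100.0 * num / den if (model is not None and den > 0) else float("nan")
    return curves, mape
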