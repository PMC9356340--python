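"""Imputation of invalid minutes from FPCA-smoothed diurnal profiles.

Each participant's days form a day × 1440 matrix per measure, with missing
entries at invalid minutes. Functional principal component analysis gives a
smooth mean-of-day curve plus eigenfunctions; each day is reconstructed as
mean + Σ_k score_k · φ_k, with scores estimated from that day's observed
minutes only. Invalid minutes are then replaced by the reconstruction
(floored at 0); valid minutes are never touched.

The FPCA is the basis-projection variant: every day is projected onto a
penalized cubic spline basis over minute-of-day, and the eigenproblem is
solved for the covariance of those coefficients in function space. This
keeps the eigenfunctions smooth by construction and handles missing entries
row-wise. The minute-of-day grid is treated as non-periodic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._spline import (design_matrix, fit_penalized_spline, quantile_knots,
                      second_derivative_penalty)
from .io_formats import MINUTES_PER_DAY, MinuteSeries, ParticipantData

log = logging.getLogger(__name__)


@dataclass
class FPCAResult:
    """Smoothed day×minute surface with its functional components."""

    mean: np.ndarray            # (1440,) smooth mean-of-day curve
    eigenfunctions: np.ndarray  # (K, 1440), orthonormal on the grid
    eigenvalues: np.ndarray     # (K,)
    scores: np.ndarray          # (n_days, K)
    smooth: np.ndarray          # (n_days, 1440) reconstruction
    row_labels: list
    excluded_rows: list         # rows with <50% observed, fit-excluded

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[0]


def day_by_minute_matrix(series: MinuteSeries, measure: str,
                         valid_only: bool = True) -> tuple[np.ndarray, list]:
    """Rows = participant-days, columns = 1440 minutes of day.

    With ``valid_only`` (the normal mode), entries at invalid minutes are
    missing, so the FPCA smooth is driven by valid data only.
    """
    df = series.data
    vals = df[measure].to_numpy(dtype=float).copy()
    if valid_only and "valid" in df.columns:
        invalid = ~df["valid"].fillna(False).to_numpy(dtype=bool)
        vals[invalid] = np.nan
    n_days = len(vals) // MINUTES_PER_DAY
    mat = vals[: n_days * MINUTES_PER_DAY].reshape(n_days, MINUTES_PER_DAY)
    labels = [(series.participant_id, d.date().isoformat())
              for d in series.day_dates()[:n_days]]
    return mat, labels


def fpca_smooth(matrix: np.ndarray, k_max: int = 10, pve: float = 0.95,
                n_basis: int = 30, row_labels: list | None = None,
                min_observed_frac: float = 0.5) -> FPCAResult:
    """FPCA of a day×1440 matrix with missing entries.

    The number of components is the smallest K ≤ ``k_max`` whose
    eigenvalues explain at least ``pve`` of the (basis-projected) variance.
    Rows with less than ``min_observed_frac`` observed are excluded from
    fitting and reconstructed afterwards from mean + projected scores.
    """
    mat = np.asarray(matrix, dtype=float)
    n_rows, n_t = mat.shape
    if n_rows < 2:
        raise ValueError("FPCA needs at least 2 rows")
    row_labels = row_labels or list(range(n_rows))
    t = np.linspace(0.0, 1.0, n_t)
    obs_frac = np.mean(np.isfinite(mat), axis=1)
    fit_rows = np.flatnonzero(obs_frac >= min_observed_frac)
    excluded = [row_labels[i] for i in np.flatnonzero(obs_frac < min_observed_frac)]
    if excluded:
        log.info("fpca_smooth: %d rows below %.0f%% observed excluded from fitting",
                 len(excluded), 100 * min_observed_frac)
    if len(fit_rows) < 2:
        raise ValueError("fewer than 2 rows with enough observed entries")

    # smooth mean from the pooled observed entries
    obs = np.isfinite(mat)
    t_all = np.tile(t, n_rows)[obs.ravel()]
    y_all = mat.ravel()[obs.ravel()]
    mean_fit = fit_penalized_spline(t_all, y_all, n_basis=n_basis)
    mean = mean_fit(t)

    # per-row spline coefficients of the centered curves
    knots = quantile_knots(t, n_basis)
    P = second_derivative_penalty(knots)
    B = design_matrix(t, knots).toarray()
    nb = B.shape[1]
    coefs = np.full((n_rows, nb), np.nan)
    for i in range(n_rows):
        oi = obs[i]
        if oi.sum() < 5:
            continue
        fit_i = fit_penalized_spline(t[oi], mat[i, oi] - mean[oi], n_basis=n_basis)
        # row fits share the common knot vector by construction only when the
        # observed support matches; re-solve on the shared basis at the row's λ
        Bi = B[oi]
        yi = mat[i, oi] - mean[oi]
        A = Bi.T @ Bi + fit_i.lam * P
        coefs[i] = np.linalg.solve(A + 1e-10 * np.eye(nb), Bi.T @ yi)

    ok = np.array([i for i in fit_rows if np.all(np.isfinite(coefs[i]))])
    C = np.cov(coefs[ok], rowvar=False, ddof=1)
    G = (B.T @ B) / n_t  # Gram of the basis on the grid
    evalG, evecG = np.linalg.eigh(G)
    evalG = np.maximum(evalG, 1e-12)
    Gh = evecG @ np.diag(np.sqrt(evalG)) @ evecG.T
    Ghi = evecG @ np.diag(1.0 / np.sqrt(evalG)) @ evecG.T
    M = Gh @ C @ Gh
    w, V = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w, V = np.maximum(w[order], 0.0), V[:, order]

    total = w.sum()
    if total <= max(1e-12, 1e-10 * abs(mean).max() ** 2):
        K = 0
    else:
        cum = np.cumsum(w) / total
        K = int(np.searchsorted(cum, pve) + 1)
        K = min(K, k_max)
    phi = np.zeros((K, n_t))
    for k in range(K):
        f = B @ (Ghi @ V[:, k])
        nrm = np.sqrt(np.mean(f**2))
        phi[k] = f / nrm if nrm > 0 else f

    # scores from each row's observed entries
    scores = np.zeros((n_rows, K))
    if K > 0:
        for i in range(n_rows):
            oi = obs[i]
            if oi.sum() == 0:
                continue
            Phi = phi[:, oi].T
            yi = mat[i, oi] - mean[oi]
            scores[i] = np.linalg.lstsq(Phi, yi, rcond=None)[0]
    smooth = mean[None, :] + scores @ phi if K > 0 else np.tile(mean, (n_rows, 1))
    return FPCAResult(mean, phi, w[:K], scores, smooth, row_labels, excluded)


def impute_invalid(series: MinuteSeries, measure: str,
                   fpca: FPCAResult) -> MinuteSeries:
    """Replace invalid minutes of one measure by the smoothed surface, ≥ 0.

    Valid minutes are left untouched (imputation is the identity on them).
    """
    df = series.data
    invalid = ~df["valid"].fillna(False).to_numpy(dtype=bool)
    n_days = len(df) // MINUTES_PER_DAY
    vals = df[measure].to_numpy(dtype=float).copy()
    surface = np.maximum(fpca.smooth[:n_days], 0.0).ravel()
    take = invalid[: n_days * MINUTES_PER_DAY]
    vals[: n_days * MINUTES_PER_DAY][take] = surface[take]
    df[measure] = vals
    return series


def impute_participant(p: ParticipantData, measures: list[str],
                       k_max: int = 10, pve: float = 0.95,
                       n_basis: int = 30) -> ParticipantData:
    """FPCA-impute every listed measure for one participant, in place.

    Performed separately per measure. Participants with a single day (FPCA
    needs ≥ 2 rows) fall back to filling invalid minutes with the day's
    smooth mean curve fitted on observed minutes.
    """
    for m in measures:
        mat, labels = day_by_minute_matrix(p.minutes, m)
        if not np.isfinite(mat).any():
            log.warning("%s: measure %s entirely missing; skipped", p.participant_id, m)
            continue
        if mat.shape[0] >= 2:
            fpca = fpca_smooth(mat, k_max=k_max, pve=pve, n_basis=n_basis,
                               row_labels=labels)
        else:
            t = np.linspace(0, 1, mat.shape[1])
            oi = np.isfinite(mat[0])
            fit = fit_penalized_spline(t[oi], mat[0, oi], n_basis=n_basis)
            sm = fit(t)[None, :]
            fpca = FPCAResult(sm[0], np.zeros((0, mat.shape[1])), np.zeros(0),
                              np.zeros((1, 0)), sm, labels, [])
        impute_invalid(p.minutes, m, fpca)
    return p
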