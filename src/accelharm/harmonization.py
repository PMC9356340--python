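"""Harmonization mapping between activity counts and each raw-data measure.

The mapping measure = f(AC) is fitted by penalized least squares on a cubic
regression-spline basis of dimension 30 in AC, with a second-derivative
roughness penalty and the penalty weight chosen by cross-validation (GCV by
default). Minutes with AC = 0 are excluded from fitting — zeros are so
frequent that they would dominate the fit near the origin — but zero counts
are still mapped at prediction time.

Monotonicity is not enforced during fitting; for inversion, the fitted
values on a dense evaluation grid are projected onto the nondecreasing cone
(isotonic regression) and the inverse is a linear-interpolation table lookup
on that monotone grid. Count cut-offs translate to measure cut-offs by
evaluating f at the cut-off.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from ._spline import DEFAULT_LAMBDA_GRID, PenalizedSplineFit, fit_penalized_spline


class ExtrapolationWarning(UserWarning):
    """A query fell outside the fitted count range and was clamped."""


@dataclass
class HarmonizeParams:
    n_basis: int = 30
    cv: str = "gcv"               # "gcv" or "kfold"
    n_folds: int = 5
    lam: float | None = None      # fixed penalty weight, overrides cv
    lam_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID)
    grid_size: int = 2000
    subsample_cap: int | None = None  # optional seeded uniform subsample
    seed: int = 0
    min_pairs: int = 100


@dataclass
class HarmonizationModel:
    """Fitted smooth map measure = f(count), with grid and monotone inverse."""

    measure_name: str
    fit: PenalizedSplineFit
    grid: np.ndarray          # strictly increasing count grid g_1..g_M
    fitted: np.ndarray        # f̂(g_j)
    fitted_mono: np.ndarray   # isotonic projection of f̂ on the grid
    n_fit: int                # pairs used (AC=0 excluded)
    ac_range: tuple[float, float]
    nonmono_magnitude: float  # max |f̂ − monotonized| corrected

    def grid_step_at(self, ac: float) -> float:
        j = int(np.clip(np.searchsorted(self.grid, ac), 1, len(self.grid) - 1))
        return float(self.grid[j] - self.grid[j - 1])

    def to_json(self, path) -> None:
        obj = {
            "measure_name": self.measure_name,
            "knots": self.fit.knots.tolist(),
            "degree": self.fit.degree,
            "coef": self.fit.coef.tolist(),
            "lam": self.fit.lam,
            "edf": self.fit.edf,
            "gcv": self.fit.gcv,
            "n_obs": self.fit.n_obs,
            "grid": self.grid.tolist(),
            "fitted": self.fitted.tolist(),
            "fitted_mono": self.fitted_mono.tolist(),
            "n_fit": self.n_fit,
            "ac_range": list(self.ac_range),
            "nonmono_magnitude": self.nonmono_magnitude,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "HarmonizationModel":
        with open(path) as fh:
            o = json.load(fh)
        fit = PenalizedSplineFit(np.array(o["knots"]), o["degree"],
                                 np.array(o["coef"]), o["lam"], o["edf"],
                                 o["gcv"], o["n_obs"])
        return cls(o["measure_name"], fit, np.array(o["grid"]),
                   np.array(o["fitted"]), np.array(o["fitted_mono"]),
                   o["n_fit"], tuple(o["ac_range"]), o["nonmono_magnitude"])


def fit_mapping(ac: np.ndarray, measure: np.ndarray,
                params: HarmonizeParams | None = None,
                measure_name: str = "measure") -> HarmonizationModel:
    """Fit the count→measure mapping on minute-level pairs.

    Pairs with missing values or AC = 0 are dropped before fitting; at least
    ``params.min_pairs`` must remain. The evaluation grid is log-spaced from
    the smallest positive fitted count to the largest (resolving the strong
    curvature at low counts).
    """
    params = params or HarmonizeParams()
    ac = np.asarray(ac, dtype=float)
    measure = np.asarray(measure, dtype=float)
    keep = np.isfinite(ac) & np.isfinite(measure) & (ac > 0)
    ac, measure = ac[keep], measure[keep]
    if len(ac) < params.min_pairs:
        raise ValueError(f"insufficient pairs after AC=0 exclusion: {len(ac)}")
    if np.all(ac == ac[0]):
        raise ValueError("degenerate (constant) count predictor")
    if params.subsample_cap is not None and len(ac) > params.subsample_cap:
        rng = np.random.default_rng(params.seed)
        idx = rng.choice(len(ac), params.subsample_cap, replace=False)
        ac, measure = ac[idx], measure[idx]

    fit = fit_penalized_spline(ac, measure, n_basis=params.n_basis,
                               lam=params.lam, lam_grid=params.lam_grid,
                               cv=params.cv, n_folds=params.n_folds,
                               rng=np.random.default_rng(params.seed))
    lo, hi = float(ac.min()), float(ac.max())
    grid = np.unique(np.geomspace(lo, hi, params.grid_size))
    fitted = fit(grid)
    iso = IsotonicRegression(increasing=True)
    fitted_mono = iso.fit_transform(grid, fitted)
    nonmono = float(np.max(np.abs(fitted - fitted_mono)))
    scale = max(float(np.max(np.abs(fitted))), 1e-12)
    if nonmono > 1e-6 * scale:
        warnings.warn(f"{measure_name}: non-monotone fit corrected by isotonic "
                      f"projection (max correction {nonmono:.3g})")
    return HarmonizationModel(measure_name, fit, grid, fitted, fitted_mono,
                              len(ac), (lo, hi), nonmono)


def predict_measure(model: HarmonizationModel, ac,
                    return_flags: bool = False):
    """Evaluate f̂ at counts; out-of-range counts clamp to the endpoints.

    Negative counts are an error. With ``return_flags`` the second return is
    a boolean mask of clamped (extrapolated) queries.
    """
    ac = np.asarray(ac, dtype=float)
    scalar = ac.ndim == 0
    ac = np.atleast_1d(ac)
    if np.any(ac < 0):
        raise ValueError("negative activity count")
    lo, hi = model.ac_range
    flagged = (ac < lo) | (ac > hi)
    vals = model.fit(np.clip(ac, lo, hi))
    if scalar:
        vals = float(vals[0])
        flagged = bool(flagged[0])
    return (vals, flagged) if return_flags else vals


def invert_to_ac(model: HarmonizationModel, x, return_flags: bool = False):
    """Estimated count for a measure value, via the monotone inverse table.

    Values below f̂(g_1) map to 0; values above f̂(g_M) clamp to g_M and are
    flagged. Negative measure values are an error.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("negative measure value")
    # break exact ties in the monotone table so interpolation is well posed
    mono = model.fitted_mono + 1e-12 * np.arange(len(model.grid))
    ac_hat = np.interp(x, mono, model.grid)
    ac_hat[x < mono[0]] = 0.0
    over = x > mono[-1]
    ac_hat[over] = model.grid[-1]
    if scalar:
        ac_hat = float(ac_hat[0])
        over = bool(over[0])
    return (ac_hat, over) if return_flags else ac_hat


def translate_cutoff(model: HarmonizationModel, ac_cutoff: float) -> float:
    """Measure-scale threshold equivalent to a count threshold: f̂(cut-off)."""
    lo, hi = model.ac_range
    if not lo <= ac_cutoff <= hi:
        raise ValueError(f"cut-off {ac_cutoff} outside fitted count range "
                         f"[{lo:g}, {hi:g}]")
    return float(model.fit(np.array([ac_cutoff]))[0])
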