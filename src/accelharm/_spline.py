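"""Penalized regression splines with a second-derivative penalty.

Shared numerical core for the count↔measure harmonization fit, the FPCA
mean/row smooths, and the 24-hour median-curve smoother.  A cubic B-spline
basis with interior knots at data quantiles plays the role of a cubic
regression spline; the roughness penalty is the integrated squared second
derivative, whose null space is the linear functions (so λ→∞ recovers the
least-squares line).  λ is selected by generalized cross-validation by
default, or by K-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

DEFAULT_LAMBDA_GRID = np.logspace(-7, 7, 43)


def quantile_knots(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Full knot vector for ``n_basis`` B-splines of the given degree.

    Interior knots sit at quantiles of ``x`` (deduplicated; the basis shrinks
    if the data cannot support ``n_basis`` distinct knots), boundary knots at
    the data range, repeated ``degree + 1`` times.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("degenerate predictor: all values identical")
    n_interior = n_basis - degree - 1
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.unique(np.quantile(x, probs))
        interior = interior[(interior > lo) & (interior < hi)]
    else:
        interior = np.array([])
    return np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])


def design_matrix(x: np.ndarray, knots: np.ndarray, degree: int = 3):
    """Sparse B-spline design matrix; x is clipped to the knot span."""
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree)


def second_derivative_penalty(knots: np.ndarray, degree: int = 3, n_quad: int = 2001) -> np.ndarray:
    """P[i,j] = ∫ B_i''(t) B_j''(t) dt over the knot span, by trapezoid rule."""
    lo, hi = knots[degree], knots[-degree - 1]
    t = np.linspace(lo, hi, n_quad)
    n_b = len(knots) - degree - 1
    coef = np.eye(n_b)
    d2 = np.empty((n_quad, n_b))
    for j in range(n_b):
        d2[:, j] = BSpline(knots, coef[j], degree).derivative(2)(t)
    w = np.full(n_quad, (hi - lo) / (n_quad - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    return (d2 * w[:, None]).T @ d2


@dataclass
class PenalizedSplineFit:
    """A fitted penalized spline y ≈ f(x)."""

    knots: np.ndarray
    degree: int
    coef: np.ndarray
    lam: float
    edf: float
    gcv: float
    n_obs: int
    x_range: tuple[float, float] = field(default=(0.0, 1.0))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the fit; inputs outside the fitted range clamp to the ends."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        return BSpline(self.knots, self.coef, self.degree)(np.clip(x, lo, hi))


def _solve_path(XtX, Xty, yty, n, P, lam_grid):
    """Coefficients, RSS and effective df along the λ path."""
    out = []
    for lam in lam_grid:
        A = XtX + lam * P
        try:
            c, low = cho_factor(A + 1e-12 * np.trace(A) / A.shape[0] * np.eye(A.shape[0]))
            beta = cho_solve((c, low), Xty)
            edf = float(np.trace(cho_solve((c, low), XtX)))
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, Xty, rcond=None)[0]
            edf = float(np.trace(np.linalg.lstsq(A, XtX, rcond=None)[0]))
        rss = float(yty - 2 * beta @ Xty + beta @ XtX @ beta)
        rss = max(rss, 0.0)
        out.append((lam, beta, rss, edf))
    return out


def fit_penalized_spline(
    x: np.ndarray,
    y: np.ndarray,
    n_basis: int = 30,
    degree: int = 3,
    lam: float | None = None,
    lam_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    cv: str = "gcv",
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> PenalizedSplineFit:
    """Fit a penalized cubic regression spline of y on x.

    Parameters
    ----------
    lam : fixed penalty weight; when None it is selected on ``lam_grid`` by
        the criterion named in ``cv`` ("gcv" or "kfold").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"too few observations ({n}) for a spline fit")
    knots = quantile_knots(x, n_basis, degree)
    X = design_matrix(x, knots, degree)
    P = second_derivative_penalty(knots, degree)
    XtX = (X.T @ X).toarray()
    Xty = X.T @ y
    yty = float(y @ y)

    if lam is not None:
        (_, beta, rss, edf), = _solve_path(XtX, Xty, yty, n, P, [lam])
        gcv = n * rss / max(n - edf, 1e-9) ** 2
        return PenalizedSplineFit(knots, degree, beta, float(lam), edf, gcv, n,
                                  (float(x.min()), float(x.max())))

    if cv == "gcv":
        path = _solve_path(XtX, Xty, yty, n, P, lam_grid)
        scores = [n * rss / max(n - edf, 1e-9) ** 2 for (_, _, rss, edf) in path]
        i = int(np.argmin(scores))
        lam_best, beta, rss, edf = path[i]
        return PenalizedSplineFit(knots, degree, beta, float(lam_best), edf,
                                  float(scores[i]), n, (float(x.min()), float(x.max())))
    if cv == "kfold":
        rng = rng or np.random.default_rng(0)
        folds = rng.permutation(n) % n_folds
        cv_err = np.zeros(len(lam_grid))
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            Xtr, Xte = X[tr], X[te]
            XtXf = (Xtr.T @ Xtr).toarray()
            Xtyf = Xtr.T @ y[tr]
            for j, lam_j in enumerate(lam_grid):
                beta = np.linalg.solve(XtXf + lam_j * P, Xtyf)
                cv_err[j] += float(np.sum((y[te] - Xte @ beta) ** 2))
        i = int(np.argmin(cv_err))
        (_, beta, rss, edf), = _solve_path(XtX, Xty, yty, n, P, [lam_grid[i]])
        gcv = n * rss / max(n - edf, 1e-9) ** 2
        return PenalizedSplineFit(knots, degree, beta, float(lam_grid[i]), edf, gcv, n,
                                  (float(x.min()), float(x.max())))
    raise ValueError(f"unknown cv method {cv!r}")
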