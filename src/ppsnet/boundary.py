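"""Sigmoid boundary fitting for reaction-time curves.

The peripersonal-space boundary is operationalized as the central point
``xc`` of a four-parameter sigmoid fitted to reaction times against
sound distance (simulation, cm) or touch-delivery time (behavior, ms):

``y(x) = ymin + ymax * exp((x - xc)/b) / (1 + exp((x - xc)/b))``

At ``x = xc`` the curve passes through ``ymin + ymax/2``.  (Under the
alternative "halfway between the asymptotes" convention the midpoint
ordinate would be ``(ymin + ymax)/2``, which coincides with the above
only for ``ymin = 0``; the fit report carries the abscissa of that
convention as well.)  The 95% CI of ``xc`` is t-based, from the
Jacobian covariance at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class DegenerateFitError(ValueError):
    """The response has no usable range (flat y)."""


def sigmoid(x, ymin, ymax, xc, b):
    """Evaluate the boundary sigmoid; ``b`` sets slope and orientation."""
    x = np.asarray(x, dtype=float)
    if b == 0:
        raise ValueError("b must be nonzero")
    t = (x - xc) / b
    # numerically stable logistic
    out = np.where(t >= 0, 1.0 / (1.0 + np.exp(-np.clip(t, -700, 700))),
                   np.exp(np.clip(t, -700, 700))
                   / (1.0 + np.exp(np.clip(t, -700, 700))))
    return ymin + ymax * out


@dataclass
class BoundaryFit:
    """Fitted sigmoid parameters, covariance and boundary CI."""

    ymin: float
    ymax: float
    xc: float
    b: float
    cov: np.ndarray | None
    ci95_xc: tuple[float, float]
    rss: float
    n_points: int
    converged: bool
    #: abscissa where y = (ymin + ymax)/2 (midpoint-between-asymptotes
    #: convention); NaN when that level is not crossed
    xc_halfway_convention: float = float("nan")

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.ymin, self.ymax, self.xc, self.b)

    def predict(self, x):
        return sigmoid(x, *self.params)

    def to_dict(self) -> dict:
        return {
            "ymin": self.ymin, "ymax": self.ymax, "xc": self.xc, "b": self.b,
            "ci95_xc": list(self.ci95_xc), "rss": self.rss,
            "n_points": self.n_points, "converged": self.converged,
            "xc_halfway_convention": self.xc_halfway_convention,
            "cov": None if self.cov is None else self.cov.tolist(),
        }


def _initial_guess(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spec'd heuristic start: extremes from the data, xc at the steepest
    local slope of a 3-point moving average, |b| = x-range / 10."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.zeros(len(ux))
    np.add.at(uy, inv, ys)
    uy /= np.bincount(inv)
    if len(ux) >= 3:
        smooth = np.convolve(uy, np.ones(3) / 3.0, mode="valid")
        sx = ux[1:-1]
        if len(smooth) >= 2:
            slopes = np.diff(smooth) / np.diff(sx)
            k = int(np.argmax(np.abs(slopes)))
            xc0 = 0.5 * (sx[k] + sx[k + 1])
        else:
            xc0 = float(np.median(ux))
    else:
        xc0 = float(np.median(ux))
    b0 = (ux[-1] - ux[0]) / 10.0
    rising = uy[-1] >= uy[0]
    if not rising:
        b0 = -b0
    return np.array([float(np.min(uy)), float(np.ptp(uy)), xc0, b0])


def fit_sigmoid(x, y, weights=None, n_starts: int = 5,
                ci_level: float = 0.95) -> BoundaryFit:
    """Least-squares sigmoid fit with a t-based CI on the central point.

    ``x`` may contain repeated values (repetition-level data pooled);
    at least four distinct x values are required.  ``weights`` are
    per-point standard deviations passed to the least-squares criterion.
    On failure of the default start, up to ``n_starts`` deterministic
    jittered restarts are tried; a fit that never converges is returned
    flagged rather than raised.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct x values")
    if np.ptp(y) <= max(1e-12, 1e-10 * np.abs(y).max()):
        raise DegenerateFitError("flat response: no range to fit")

    p0 = _initial_guess(x, y)
    sigma = None if weights is None else np.asarray(weights, dtype=float)
    jitter_rng = np.random.default_rng(12345)  # deterministic restarts
    attempts = [p0]
    for _ in range(n_starts - 1):
        fac = jitter_rng.uniform(0.5, 1.5, size=4)
        shift = jitter_rng.uniform(-0.2, 0.2) * np.ptp(x)
        attempts.append(p0 * fac + np.array([0.0, 0.0, shift, 0.0]))

    best = None
    for start in attempts:
        if start[3] == 0:
            start[3] = np.ptp(x) / 10.0
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    sigmoid, x, y, p0=start, sigma=sigma, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        if not np.all(np.isfinite(popt)):
            continue
        rss = float(np.sum((y - sigmoid(x, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)

    n = len(x)
    if best is None:
        return BoundaryFit(*p0, cov=None, ci95_xc=(np.nan, np.nan),
                           rss=float("nan"), n_points=n, converged=False)

    popt, pcov, rss = best
    dof = max(n - 4, 1)
    if np.all(np.isfinite(pcov)):
        se_xc = float(np.sqrt(pcov[2, 2]))
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, dof)
        ci = (popt[2] - tcrit * se_xc, popt[2] + tcrit * se_xc)
        cov = pcov
    else:
        ci = (np.nan, np.nan)
        cov = None

    ymin, ymax, xc, b = (float(v) for v in popt)
    # abscissa of the "(ymin+ymax)/2" midpoint convention, where defined
    xc_half = float("nan")
    if ymax != 0:
        level = (ymax - ymin) / (2.0 * ymax)
        if 0.0 < level < 1.0:
            xc_half = xc + b * float(np.log(level / (1.0 - level)))

    return BoundaryFit(ymin=ymin, ymax=ymax, xc=xc, b=b, cov=cov,
                       ci95_xc=(float(ci[0]), float(ci[1])), rss=rss,
                       n_points=n, converged=True,
                       xc_halfway_convention=xc_half)


def bootstrap_ci_xc(x, y, n_boot: int = 500, ci_level: float = 0.95,
                    rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Optional case-resampling bootstrap CI for the central point."""
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    stats_ = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), size=len(x))
        if len(np.unique(x[idx])) < 4:
            continue
        try:
            fit = fit_sigmoid(x[idx], y[idx], n_starts=2)
        except (ValueError, DegenerateFitError):
            continue
        if fit.converged:
            stats_.append(fit.xc)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(stats_, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


@dataclass
class BoundaryShift:
    """Comparison of two boundary fits."""

    delta_xc: float                 # fit_b.xc - fit_a.xc
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    disjoint: bool

    def to_dict(self) -> dict:
        return {"delta_xc": self.delta_xc, "ci_a": list(self.ci_a),
                "ci_b": list(self.ci_b), "disjoint": self.disjoint}


def compare_boundaries(fit_a: BoundaryFit, fit_b: BoundaryFit) -> BoundaryShift:
    """Boundary shift between two converged fits; flags disjoint 95% CIs."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    ci_a, ci_b = fit_a.ci95_xc, fit_b.ci95_xc
    disjoint = ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]
    return BoundaryShift(delta_xc=fit_b.xc - fit_a.xc, ci_a=ci_a, ci_b=ci_b,
                         disjoint=bool(disjoint))
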