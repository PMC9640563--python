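"""Per-location trend models for visual-field sensitivity over time.

Five models are fitted to (time, sensitivity) pairs at a single test
location:

* ``OLSLR`` — ordinary least-squares line ``y = a*x + b`` (the reference).
* ``EXPONENTIAL`` — ``y = exp(a*x + b)``, least squares in dB space.
* ``QUADRATIC`` — ``y = a*x^2 + b*x + c``.
* ``M_ROBUST`` — straight line fitted by Huber M-estimation (IRLS).
* ``LOGISTIC`` — ``y/40 = 1 / (1 + exp(a*x + b))``, least squares on the
  0–1 scale after dividing sensitivities by the 40 dB ceiling.

``x`` is time in years from the first examination and ``y`` the point-wise
sensitivity in dB.  All fitters are deterministic: the nonlinear models are
initialised from a log- or logit-transform straight-line fit and refined by
least squares; if refinement fails or does not improve the objective, the
initialiser fit is returned with ``converged=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

#: Huber tuning constant (95 % efficiency at the Gaussian model)
HUBER_K = 1.345
#: normal consistency factor for the median-absolute-deviation scale
MAD_NORMAL = 0.6745

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
ROBUST_SCALE_FLOOR = 1e-6

MIN_WINDOW = 5
MAX_WINDOW = 12


class SingularDesignError(ValueError):
    """The design matrix is rank deficient (e.g. all times identical)."""


class DegenerateDataError(ValueError):
    """The response admits no meaningful fit (e.g. all zero for the exponential)."""


class ModelKind(Enum):
    OLSLR = "OLSLR"
    EXPONENTIAL = "EXPONENTIAL"
    QUADRATIC = "QUADRATIC"
    M_ROBUST = "M_ROBUST"
    LOGISTIC = "LOGISTIC"


#: parameter-vector length per model
MODEL_ARITY = {
    ModelKind.OLSLR: 2,
    ModelKind.EXPONENTIAL: 2,
    ModelKind.QUADRATIC: 3,
    ModelKind.M_ROBUST: 2,
    ModelKind.LOGISTIC: 2,
}


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters of one model at one location.

    ``params`` is (a, b) for the two-parameter models and (a, b, c) for the
    quadratic; ``scale`` is the robust residual-scale estimate (M_ROBUST
    only), in dB.
    """

    model: ModelKind
    params: tuple[float, ...]
    scale: float | None = None
    converged: bool = True
    n_obs: int = 0


def _check_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    return x, y


def fit_olslr(x, y) -> FitResult:
    """Ordinary least-squares line y = a*x + b (closed-form normal equations)."""
    x, y = _check_xy(x, y, 2)
    if np.ptp(x) == 0:
        raise SingularDesignError("all time values identical")
    a, b = np.polyfit(x, y, 1)
    return FitResult(ModelKind.OLSLR, (float(a), float(b)), n_obs=x.size)


def fit_quadratic(x, y) -> FitResult:
    """Least-squares parabola y = a*x^2 + b*x + c."""
    x, y = _check_xy(x, y, 3)
    if np.unique(x).size < 3:
        raise SingularDesignError("need at least 3 distinct time values")
    a, b, c = np.polyfit(x, y, 2)
    return FitResult(ModelKind.QUADRATIC, (float(a), float(b), float(c)), n_obs=x.size)


def _safe_exp(z: np.ndarray | float) -> np.ndarray | float:
    return np.exp(np.clip(z, -700.0, 700.0))


def _exp_curve(params, x):
    return _safe_exp(params[0] * x + params[1])


def _logistic_curve(params, x):
    # unit-scale logistic; multiply by 40 dB for predictions
    return 1.0 / (1.0 + _safe_exp(params[0] * x + params[1]))


def _refine(curve: Callable, x: np.ndarray, y_target: np.ndarray,
            p0: np.ndarray) -> tuple[np.ndarray, bool]:
    """Least-squares refinement of ``curve`` from ``p0``.

    Returns the better of (refined, initial) by sum of squared residuals, so
    the refined objective never exceeds the initialiser's.
    """
    def resid(p):
        return curve(p, x) - y_target

    sse0 = float(np.sum(resid(p0) ** 2))
    try:
        sol = least_squares(resid, p0, method="lm", max_nfev=2000)
        sse1 = float(np.sum(sol.fun ** 2))
        if np.all(np.isfinite(sol.x)) and sse1 <= sse0:
            return sol.x, bool(sol.success)
    except Exception:
        pass
    return p0, False


def fit_exponential(x, y) -> FitResult:
    """Exponential decay/growth y = exp(a*x + b), least squares in dB space.

    Initialised from an OLS line through log(max(y, 0.1)).
    """
    x, y = _check_xy(x, y, 2)
    if np.any(y < 0):
        raise ValueError("sensitivities must be non-negative")
    if np.all(y == 0):
        raise DegenerateDataError("all sensitivities zero; exponential undefined")
    if np.ptp(x) == 0:
        raise SingularDesignError("all time values identical")
    p0 = np.polyfit(x, np.log(np.maximum(y, 0.1)), 1)
    params, ok = _refine(_exp_curve, x, y, p0)
    return FitResult(ModelKind.EXPONENTIAL, tuple(map(float, params)),
                     converged=ok, n_obs=x.size)


def fit_logistic(x, y) -> FitResult:
    """Logistic curve y/40 = 1/(1 + exp(a*x + b)).

    Sensitivities are divided by the 40 dB ceiling so the response lies in
    [0, 1].  The initialiser clamps the scaled response to [0.01, 0.99] only
    to keep the logit finite; the least-squares objective uses the unclamped
    values.
    """
    x, y = _check_xy(x, y, 2)
    if np.ptp(x) == 0:
        raise SingularDesignError("all time values identical")
    yp = y / 40.0
    ypc = np.clip(yp, 0.01, 0.99)
    # logit(p) = -(a*x + b)  =>  regress -logit on x
    p0 = np.polyfit(x, -np.log(ypc / (1.0 - ypc)), 1)
    params, ok = _refine(_logistic_curve, x, yp, p0)
    return FitResult(ModelKind.LOGISTIC, tuple(map(float, params)),
                     converged=ok, n_obs=x.size)


def _mad_scale(r: np.ndarray) -> float:
    """Robust residual scale: median(|r|) / 0.6745."""
    return float(np.median(np.abs(r)) / MAD_NORMAL)


def huber_rho(r: np.ndarray, scale: float, k: float = HUBER_K) -> np.ndarray:
    """Huber loss per residual at the given scale: quadratic within k*scale,
    linear beyond."""
    t = k * scale
    a = np.abs(r)
    return np.where(a <= t, 0.5 * r ** 2, t * a - 0.5 * t ** 2)


def huber_objective(x, y, params, scale: float, k: float = HUBER_K) -> float:
    """Total Huber objective of a straight line (a, b) on the data."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = y - (params[0] * x + params[1])
    return float(np.sum(huber_rho(r, scale, k)))


def fit_m_robust(x, y) -> FitResult:
    """Straight line by Huber M-estimation via iteratively reweighted least
    squares.

    Starts at the OLS solution; each iteration re-estimates the scale as
    MAD/0.6745 of the current residuals and applies Huber weights
    ``min(1, k*scale/|r|)`` with k = 1.345.  Stops when the largest
    coefficient change falls below 1e-8 or after 100 iterations.  If the
    robust scale collapses below 1e-6 (at least half the residuals exactly
    zero) the OLS fit is returned unchanged.
    """
    x, y = _check_xy(x, y, 2)
    if np.ptp(x) == 0:
        raise SingularDesignError("all time values identical")
    ols = fit_olslr(x, y)
    a, b = ols.params
    converged = False
    sigma = _mad_scale(y - (a * x + b))
    if sigma < ROBUST_SCALE_FLOOR:
        return FitResult(ModelKind.M_ROBUST, ols.params, scale=sigma,
                         converged=True, n_obs=x.size)
    for _ in range(IRLS_MAX_ITER):
        r = y - (a * x + b)
        sigma = _mad_scale(r)
        if sigma < ROBUST_SCALE_FLOOR:
            break
        absr = np.abs(r)
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, np.where(absr > 0, HUBER_K * sigma / absr, np.inf))
        a_new, b_new = np.polyfit(x, y, 1, w=np.sqrt(w))
        if max(abs(a_new - a), abs(b_new - b)) < IRLS_TOL:
            a, b = a_new, b_new
            converged = True
            break
        a, b = a_new, b_new
    return FitResult(ModelKind.M_ROBUST, (float(a), float(b)), scale=float(sigma),
                     converged=converged, n_obs=x.size)


FITTERS: dict[ModelKind, Callable[..., FitResult]] = {
    ModelKind.OLSLR: fit_olslr,
    ModelKind.EXPONENTIAL: fit_exponential,
    ModelKind.QUADRATIC: fit_quadratic,
    ModelKind.M_ROBUST: fit_m_robust,
    ModelKind.LOGISTIC: fit_logistic,
}


def fit_model(model: ModelKind, x, y) -> FitResult:
    """Dispatch to the fitter for ``model``."""
    return FITTERS[model](x, y)


def predict(fit: FitResult, x_new, clamp: bool = False):
    """Evaluate a fitted model at new times (years).

    The logistic output is rescaled by the 40 dB ceiling.  With ``clamp``
    the result is truncated into the instrument range [0, 40] dB (off by
    default; exponential and logistic predictions are bounded below by 0,
    and the logistic above by 40, without clamping).
    """
    x_new = np.asarray(x_new, dtype=float)
    p = fit.params
    if fit.model in (ModelKind.OLSLR, ModelKind.M_ROBUST):
        out = p[0] * x_new + p[1]
    elif fit.model is ModelKind.QUADRATIC:
        out = p[0] * x_new ** 2 + p[1] * x_new + p[2]
    elif fit.model is ModelKind.EXPONENTIAL:
        out = _safe_exp(p[0] * x_new + p[1])
    elif fit.model is ModelKind.LOGISTIC:
        out = 40.0 * _logistic_curve(p, x_new)
    else:  # pragma: no cover
        raise ValueError(f"unknown model {fit.model}")
    if clamp:
        out = np.clip(out, 0.0, 40.0)
    return float(out) if out.ndim == 0 else out


class PointwiseFitError(RuntimeError):
    """A per-location fit failed; carries the failing location index."""

    def __init__(self, point_index: int, cause: Exception):
        super().__init__(f"fit failed at location {point_index}: {cause}")
        self.point_index = point_index
        self.cause = cause


@dataclass
class PointwiseFit:
    """One model fitted independently at each of the 68 locations of one eye."""

    eye_id: str
    model: ModelKind
    n_used: int
    fits: list[FitResult]

    def predict(self, x_new: float, clamp: bool = False) -> np.ndarray:
        return np.array([predict(f, x_new, clamp) for f in self.fits])


def fit_pointwise(series, n_used: int, model: ModelKind) -> PointwiseFit:
    """Fit ``model`` at each of the 68 locations using tests 1..n_used.

    ``x`` is time in years from the first examination, ``y`` the location's
    sensitivities.  Windows run from 5 tests (shorter series are too noisy
    for trend analysis) up to one short of the 13-test series.  The
    polynomial models are fitted for all locations in a single vectorised
    normal-equations solve; the nonlinear and robust models are fitted
    location by location.
    """
    if not (MIN_WINDOW <= n_used <= min(MAX_WINDOW, len(series.tests))):
        raise ValueError(
            f"n_used must be in [{MIN_WINDOW}, {min(MAX_WINDOW, len(series.tests))}], "
            f"got {n_used}"
        )
    x = series.times()[:n_used]
    Y = series.sensitivity_matrix()[:n_used]
    if model is ModelKind.OLSLR:
        coefs = np.polyfit(x, Y, 1)
        fits = [FitResult(model, (float(coefs[0, j]), float(coefs[1, j])),
                          n_obs=n_used) for j in range(Y.shape[1])]
    elif model is ModelKind.QUADRATIC:
        coefs = np.polyfit(x, Y, 2)
        fits = [FitResult(model, tuple(float(c) for c in coefs[:, j]),
                          n_obs=n_used) for j in range(Y.shape[1])]
    else:
        fitter = FITTERS[model]
        fits = []
        for j in range(Y.shape[1]):
            try:
                fits.append(fitter(x, Y[:, j]))
            except DegenerateDataError:
                # all-zero location: the floor is its own prediction
                if model is ModelKind.EXPONENTIAL:
                    fits.append(FitResult(model, (0.0, -700.0), converged=False,
                                          n_obs=n_used))
                else:  # pragma: no cover
                    raise
            except Exception as exc:
                raise PointwiseFitError(j, exc) from exc
    return PointwiseFit(eye_id=series.eye_id, model=model, n_used=n_used, fits=fits)
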