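"""Penalized B-spline smoothing of noisy time courses.

Each observed component is approximated by a cubic B-spline expansion
``sum_k beta_k phi_k(t)`` whose coefficients minimise

    || y - Phi beta ||^2 + lambda * || D beta ||^2,

where ``Phi`` is the basis evaluated at the observation times and ``D``
is the order-2 difference operator on coefficients — the standard
P-spline finite-difference approximation of the curvature penalty. The
null space of the penalty contains straight lines, so for very large
``lambda`` the fit collapses onto the least-squares line. The smoothing
parameter is chosen per component by exact leave-one-out
cross-validation (refitting, not a hat-matrix shortcut: with ~30 points
per series the refits are cheap and the score is exact).

The fitted spline supplies both the smoothed trajectory and — the
quantity that everything downstream depends on — its first derivative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import ConfigurationError, DomainError, FittingError

__all__ = [
    "SplineFit",
    "fit_penalized_spline",
    "select_lambda_loocv",
    "evaluate_spline",
    "default_lambda_grid",
    "default_basis_dimension",
]

logger = logging.getLogger(__name__)


def default_lambda_grid(n_points: int = 25, low: float = 1e-4,
                        high: float = 1e4) -> np.ndarray:
    """Logarithmically spaced smoothing-parameter grid (25 points, 1e-4..1e4)."""
    return np.logspace(np.log10(low), np.log10(high), n_points)


def default_basis_dimension(n_times: int, cap: int = 20) -> int:
    """Default basis dimension min(n+1, 20).

    The cross-validated penalty controls the effective flexibility, so K
    only needs enough headroom; past ~20 basis functions the fit for a
    30-point series no longer changes.
    """
    return max(4, min(n_times, cap))


def _knots(t0: float, tn: float, k_dim: int) -> np.ndarray:
    """Uniform (unclamped) cubic knot vector giving K basis functions.

    Equally spaced knots extending three intervals beyond each end of
    the domain — the standard P-spline construction. Uniform spacing is
    what makes the order-2 coefficient-difference penalty exact: its
    null space (coefficient sequences linear in the index) then maps
    precisely onto straight-line functions.
    """
    delta = (tn - t0) / (k_dim - 3)
    return t0 + (np.arange(k_dim + 4) - 3.0) * delta


def _design(times: np.ndarray, knots: np.ndarray, k_dim: int,
            derivative: int = 0) -> np.ndarray:
    basis = BSpline(knots, np.eye(k_dim), 3, extrapolate=True)
    if derivative:
        basis = basis.derivative(derivative)
    return basis(times)


@dataclass
class SplineFit:
    """A fitted penalized spline for one component.

    Evaluable anywhere in ``domain`` for the value (order 0) or the first
    derivative (order 1); no extrapolation.
    """

    basis_kind: str
    k_dim: int
    knots: np.ndarray
    lam: float
    coefficients: np.ndarray
    domain: tuple

    def __call__(self, times, derivative_order: int = 0):
        return evaluate_spline(self, times, derivative_order)


def fit_penalized_spline(times, values, k_dim: int = None,
                         lam: float = 0.0) -> SplineFit:
    """Fit a cubic P-spline with fixed smoothing parameter ``lam``.

    Solves the normal equations ``(Phi' Phi + lam D'D) beta = Phi' y``
    exactly; raises :class:`FittingError` when they are singular (e.g.
    ``lam = 0`` with more basis functions than distinct observations).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.size < 4:
        raise FittingError("need at least four observations")
    if values.shape != times.shape:
        raise FittingError("times and values must match in length")
    if np.any(np.diff(times) <= 0):
        raise FittingError("times must be strictly increasing")
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    if k_dim is None:
        k_dim = default_basis_dimension(times.size)
    if k_dim < 4:
        raise ConfigurationError("cubic B-splines require K >= 4")

    knots = _knots(times[0], times[-1], k_dim)
    phi = _design(times, knots, k_dim)
    dmat = np.diff(np.eye(k_dim), n=2, axis=0)
    lhs = phi.T @ phi + lam * dmat.T @ dmat
    try:
        beta = np.linalg.solve(lhs, phi.T @ values)
    except np.linalg.LinAlgError as exc:
        raise FittingError(f"singular normal equations: {exc}") from exc
    if not np.all(np.isfinite(beta)):
        raise FittingError("non-finite spline coefficients")
    return SplineFit(
        basis_kind="cubic-bspline",
        k_dim=k_dim,
        knots=knots,
        lam=float(lam),
        coefficients=beta,
        domain=(float(times[0]), float(times[-1])),
    )


def select_lambda_loocv(times, values, k_dim: int = None,
                        lambda_grid=None):
    """Choose the smoothing parameter by leave-one-out cross-validation.

    For every grid value, each observation is left out in turn, the
    spline is refitted on the remaining points and the squared prediction
    error at the held-out time is accumulated. Returns ``(lambda*,
    cv_scores)`` with ties broken toward the larger (smoother) lambda; a
    failing leave-one-out fit scores its lambda as +inf with a warning.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ConfigurationError("lambda grid must be non-empty")
    if times.size < 5:
        raise FittingError("LOOCV needs at least five observations")
    if k_dim is None:
        k_dim = default_basis_dimension(times.size)

    mask = np.ones(times.size, dtype=bool)
    scores = np.empty(lambda_grid.size)
    for g, lam in enumerate(lambda_grid):
        total = 0.0
        try:
            for j in range(times.size):
                mask[j] = False
                fit = fit_penalized_spline(times[mask], values[mask],
                                           k_dim=min(k_dim, times.size - 1),
                                           lam=lam)
                lo, hi = fit.domain
                t_j = min(max(times[j], lo), hi)
                total += (values[j] - fit(t_j)) ** 2
                mask[j] = True
        except FittingError as exc:
            mask[:] = True
            logger.warning("LOOCV fit failed at lambda=%g: %s", lam, exc)
            total = np.inf
        scores[g] = total

    # argmin with ties resolved toward the larger lambda
    best = lambda_grid.size - 1 - int(np.argmin(scores[::-1]))
    return float(lambda_grid[best]), scores


def evaluate_spline(fit: SplineFit, times, derivative_order: int = 0):
    """Evaluate a fitted spline (order 0) or its first derivative (order 1)."""
    if derivative_order not in (0, 1):
        raise ConfigurationError("derivative_order must be 0 or 1")
    t_arr = np.asarray(times, dtype=float)
    lo, hi = fit.domain
    eps = 1e-10 * max(1.0, abs(lo), abs(hi))
    if np.any(t_arr < lo - eps) or np.any(t_arr > hi + eps):
        raise DomainError(f"evaluation outside the fit domain [{lo}, {hi}]")
    t_arr = np.clip(t_arr, lo, hi)
    basis = BSpline(fit.knots, fit.coefficients, 3, extrapolate=True)
    if derivative_order:
        basis = basis.derivative()
    out = basis(t_arr)
    return out if np.ndim(times) else float(out)
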