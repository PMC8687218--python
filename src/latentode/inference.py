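"""Extraction and maximum-likelihood estimation of a latent network input.

The method runs in two steps. First, penalized splines smooth each
observed time course, giving trajectories and — crucially — their
derivatives. Each component then yields a raw residual signal

    h0_i(t_j) = d/dt xhat_i^spl(t_j) - psi_i(k, xhat^spl(t_j)),

which, by the governing identity ``h = (xdot_i - psi_i)/a_i``, equals
``a_i h(t_j)`` up to smoothing error. Second, for a candidate support
(the set of components with nonzero weight), the per-component signals
are aggregated into one latent course

    hhat_a(t_j) = (1/N_a) * sum_{i in support} h0_i(t_j) / a_i,

the forced ODE is re-solved with this course, and the weights ``a``
(together with any free rates and unknown initial values) are chosen to
maximise the observation likelihood, with the noise variance profiled
out analytically. The scale of ``(a, h)`` is not identifiable —
``a_i h = (xi a_i)(h / xi)`` — so weights are normalised to unit L1 norm
(a single weight is restricted to ±1), and the joint sign is fixed by
orienting the estimated latent course to non-negative mean.

Partially observed networks run the same machinery on the observed
channels, with the unobserved coordinates standing in via the ODE
solution; extraction and re-solution alternate until the latent course
and the log-likelihood stabilise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, nnls

from .exceptions import (
    ConfigurationError,
    DomainError,
    IntegrationError,
    InvalidSupportError,
    InvalidWeightsError,
    UndefinedError,
)
from .io import TimeSeriesData
from .network import HiddenSignal, LinearPropagator, NetworkModel, solve_ode
from .splines import fit_penalized_spline, select_lambda_loocv

__all__ = [
    "NoiseModel",
    "LatentEstimate",
    "FitContext",
    "prepare_context",
    "residual_signal",
    "aggregate_hidden",
    "log_likelihood",
    "sigma2_mle",
    "estimate_latent",
    "estimate_latent_partial",
]

logger = logging.getLogger(__name__)

#: convergence of the outer estimation loop
LOGLIK_TOL = 1e-6
H_TOL = 1e-4
MAX_OUTER_ITER = 100

_SIGMA2_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Noise models
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Observation-noise specification.

    ``normal``: observation = truth + eps, eps ~ N(0, sigma2).
    ``lognormal``: observation = truth * exp(eps), eps ~ N(0, sigma2);
    equivalently the log-observation is Gaussian around log(truth), and
    the density carries the Jacobian term ``-log(obs)``. Requires
    positive truth and observations.
    """

    kind: str
    sigma2: float

    def __post_init__(self):
        if self.kind not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if not self.sigma2 > 0:
            raise ConfigurationError("sigma2 must be positive")

    def log_density_sum(self, obs: np.ndarray, fit: np.ndarray) -> float:
        """Sum of log observation densities given fitted values."""
        obs = np.asarray(obs, dtype=float)
        fit = np.asarray(fit, dtype=float)
        n = obs.size
        if self.kind == "normal":
            ssr = float(np.sum((obs - fit) ** 2))
            jac = 0.0
        else:
            if np.any(fit <= 0):
                logger.warning("non-positive fitted value under lognormal "
                               "noise; likelihood is -inf")
                return -np.inf
            if np.any(obs <= 0):
                raise ConfigurationError("lognormal noise requires positive "
                                         "observations")
            ssr = float(np.sum((np.log(obs) - np.log(fit)) ** 2))
            jac = -float(np.sum(np.log(obs)))
        return (-0.5 * n * math.log(2.0 * math.pi * self.sigma2)
                - ssr / (2.0 * self.sigma2) + jac)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def residual_signal(model: NetworkModel, spline_fits: Sequence,
                    component_index: int, times,
                    rates: Optional[np.ndarray] = None) -> np.ndarray:
    """Raw latent signal of one component from smoothed trajectories.

    ``spline_fits`` are N objects evaluable as ``fit(t, order)`` for the
    smoothed value (order 0) and derivative (order 1) — spline fits for
    observed components, ODE-based stand-ins otherwise.
    """
    n = model.n_components
    if not 0 <= component_index < n:
        raise IndexError(f"component index {component_index} out of range")
    times = np.asarray(times, dtype=float)
    xs = np.vstack([np.asarray(f(times, 0), dtype=float)
                    for f in spline_fits])
    dx_i = np.asarray(spline_fits[component_index](times, 1), dtype=float)
    k = model.rate_values if rates is None else rates
    psi_i = np.array([model.psi(xs[:, j], times[j], rates=k)[component_index]
                      for j in range(times.size)])
    return dx_i - psi_i


def aggregate_hidden(h0_table: np.ndarray, a: np.ndarray, times=None,
                     interpolation: str = "linear") -> HiddenSignal:
    """Pointwise aggregation ``(1/N_a) sum_{a_i != 0} h0_i / a_i``.

    Each supported component carries an estimate of ``a_i h``; dividing
    by the weight and averaging pools them into one latent course.
    """
    h0_table = np.atleast_2d(np.asarray(h0_table, dtype=float))
    a = np.asarray(a, dtype=float)
    support = np.flatnonzero(a)
    if support.size == 0:
        raise InvalidWeightsError("all-zero weight vector: no signal to "
                                  "aggregate")
    vals = h0_table[support] / a[support, None]
    hidden = vals.mean(axis=0)
    if times is None:
        times = np.arange(hidden.size, dtype=float)
    return HiddenSignal(times=np.asarray(times, dtype=float), values=hidden,
                        interpolation=interpolation)


def log_likelihood(model: NetworkModel, data: TimeSeriesData, a,
                   noise: NoiseModel, h, x0=None, rates=None) -> float:
    """Log-likelihood of the data under the forced-ODE trajectories.

    Solves the system with forcing ``a_i h(t)``, then sums the log
    densities over the *observed* components and all time points; latent
    components contribute nothing.
    """
    work = model if rates is None else model.with_rates(rates)
    try:
        traj = solve_ode(work, data.times, a=a, h=h, x0=x0)
    except IntegrationError:
        return -np.inf
    obs = data.observed_indices
    return noise.log_density_sum(data.values[obs], traj[obs])


def sigma2_mle(data, fitted_trajectories, noise_kind: str = "normal") -> float:
    """Analytic noise-variance maximiser: the mean squared residual.

    Over all observed entries (observed components only in the partial
    case); for lognormal noise the same formula applies to the
    log-residuals.
    """
    if isinstance(data, TimeSeriesData):
        obs = data.observed_indices
        y = data.values[obs]
        f = np.atleast_2d(np.asarray(fitted_trajectories, dtype=float))
        if f.shape[0] == data.n_components:
            f = f[obs]
    else:
        y = np.atleast_2d(np.asarray(data, dtype=float))
        f = np.atleast_2d(np.asarray(fitted_trajectories, dtype=float))
    if y.size == 0:
        raise UndefinedError("no observed entries")
    if y.shape != f.shape:
        raise ConfigurationError("data and fit shapes differ")
    if noise_kind == "lognormal":
        resid = np.log(y) - np.log(f)
    else:
        resid = y - f
    return float(np.mean(resid ** 2))


# ---------------------------------------------------------------------------
# Estimation context (splines fitted once per dataset, cached)
# ---------------------------------------------------------------------------

@dataclass
class FitContext:
    """Pre-smoothed dataset shared by all candidate-support fits."""

    model: NetworkModel
    data: TimeSeriesData
    noise_kind: str
    times: np.ndarray = None
    dt: Optional[float] = None
    obs_rows: np.ndarray = None
    spline_fits: dict = field(default_factory=dict)
    xs: np.ndarray = None       # stand-in value table, (N, n+1)
    dxs: np.ndarray = None      # stand-in derivative table (observed rows)
    log_jac: float = 0.0
    _prop_cache: dict = field(default_factory=dict)

    @property
    def n_obs_entries(self) -> int:
        return int(self.obs_rows.size * self.times.size)


def prepare_context(model: NetworkModel, data: TimeSeriesData,
                    noise_kind: Optional[str] = None,
                    k_dim: Optional[int] = None,
                    lambda_grid=None) -> FitContext:
    """Fit LOOCV-tuned splines to every observed component.

    For lognormal noise the splines are fitted on the log scale (keeping
    the additive-error smoothing objective coherent with the
    multiplicative noise) and mapped back: ``x = exp(g)``,
    ``xdot = exp(g) gdot``.
    """
    if noise_kind is None:
        noise_kind = data.noise_kind or "normal"
    if noise_kind not in ("normal", "lognormal"):
        raise ConfigurationError(f"unknown noise kind {noise_kind!r}")
    if data.n_components != model.n_components:
        raise ConfigurationError("data rows must match model components")
    times = data.times
    diffs = np.diff(times)
    dt = float(diffs[0]) if np.allclose(diffs, diffs[0], rtol=1e-9) else None
    obs_rows = data.observed_indices

    ctx = FitContext(model=model, data=data, noise_kind=noise_kind,
                     times=times, dt=dt, obs_rows=obs_rows)
    n = model.n_components
    ctx.xs = np.full((n, times.size), np.nan)
    ctx.dxs = np.full((n, times.size), np.nan)
    for row in obs_rows:
        y = data.values[row]
        target = np.log(y) if noise_kind == "lognormal" else y
        lam, _ = select_lambda_loocv(times, target, k_dim=k_dim,
                                     lambda_grid=lambda_grid)
        fit = fit_penalized_spline(times, target, k_dim=k_dim, lam=lam)
        ctx.spline_fits[int(row)] = fit
        g = fit(times, 0)
        dg = fit(times, 1)
        if noise_kind == "lognormal":
            ctx.xs[row] = np.exp(g)
            ctx.dxs[row] = np.exp(g) * dg
        else:
            ctx.xs[row] = g
            ctx.dxs[row] = dg
    if noise_kind == "lognormal":
        ctx.log_jac = -float(np.sum(np.log(data.values[obs_rows])))
    return ctx


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _psi_rows(ctx: FitContext, k: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """psi_i(k, xhat(t_j)) for the requested rows on the full grid."""
    model = ctx.model
    if model.is_linear:
        a_mat = model.linear.matrix(k)
        out = a_mat[rows] @ ctx.xs
        drift = model.linear.drift(k)
        if drift is not None:
            out = out + drift[rows, None]
        return out
    cols = [model.psi(ctx.xs[:, j], ctx.times[j], rates=k)
            for j in range(ctx.times.size)]
    return np.array(cols).T[rows]


def _h_grid(ctx: FitContext, k: np.ndarray, support: np.ndarray,
            a_supp: np.ndarray) -> np.ndarray:
    h0 = ctx.dxs[support] - _psi_rows(ctx, k, support)
    return (h0 / a_supp[:, None]).mean(axis=0)


def _trajectories(ctx: FitContext, k: np.ndarray, x0: np.ndarray,
                  a_full: Optional[np.ndarray],
                  h_grid: Optional[np.ndarray]) -> Optional[np.ndarray]:
    model = ctx.model
    a_masked = None
    if a_full is not None:
        a_masked = np.where(model.hidden_slots, a_full, 0.0)
    if model.is_linear and ctx.dt is not None:
        key = k.tobytes()
        prop = ctx._prop_cache.get(key)
        if prop is None:
            if len(ctx._prop_cache) > 8:
                ctx._prop_cache.clear()
            prop = LinearPropagator(model.linear.matrix(k), ctx.dt,
                                    drift=model.linear.drift(k))
            ctx._prop_cache[key] = prop
        try:
            return prop.propagate(x0, a_masked, h_grid,
                                  n_steps=ctx.times.size - 1)
        except (ValueError, FloatingPointError):
            return None
    h = (None if h_grid is None
         else HiddenSignal(ctx.times, h_grid, interpolation="linear"))
    work = model.with_rates(k)
    try:
        return solve_ode(work, ctx.times, a=a_masked, h=h, x0=x0)
    except (IntegrationError, DomainError):
        return None


def _profiled_loglik(ctx: FitContext, traj: Optional[np.ndarray]):
    """(loglik, sigma2) with sigma^2 replaced by its analytic maximiser."""
    if traj is None or not np.all(np.isfinite(traj[ctx.obs_rows])):
        return -np.inf, np.nan
    y = ctx.data.values[ctx.obs_rows]
    f = traj[ctx.obs_rows]
    if ctx.noise_kind == "lognormal":
        if np.any(f <= 0):
            return -np.inf, np.nan
        resid = np.log(y) - np.log(f)
    else:
        resid = y - f
    t_total = resid.size
    sigma2 = max(float(np.mean(resid ** 2)), _SIGMA2_FLOOR)
    loglik = (-0.5 * t_total * (math.log(2.0 * math.pi * sigma2) + 1.0)
              + ctx.log_jac)
    return loglik, sigma2


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass
class LatentEstimate:
    """One fitted latent-input model.

    ``a`` is the full-length weight vector, zero off the support and
    L1-normalised on it; ``hidden`` is the estimated latent course on the
    observation grid (zero signal for the null model).
    """

    support: tuple
    a: np.ndarray
    sigma2: float
    hidden: HiddenSignal
    trajectories: np.ndarray
    loglik: float
    rates_hat: dict
    x0_hat: np.ndarray
    n_a: int
    converged: bool
    noise_kind: str
    n_obs_components: int
    n_times: int

    @property
    def aic(self) -> float:
        from .selection import information_criterion
        return information_criterion(self.loglik, self.n_a, self.n_times,
                                     self.n_obs_components, kind="aic")

    @property
    def bic(self) -> float:
        from .selection import information_criterion
        return information_criterion(self.loglik, self.n_a, self.n_times,
                                     self.n_obs_components, kind="bic")


# ---------------------------------------------------------------------------
# Maximum-likelihood estimation, fully observed networks
# ---------------------------------------------------------------------------

def _init_rates(ctx: FitContext, model: NetworkModel,
                free_idx: np.ndarray) -> np.ndarray:
    """Gradient-matching warm start for free rates of linear networks.

    Regresses the smoothed derivatives on the flow terms (non-negative
    least squares); falls back to the model's current values.
    """
    k = model.rate_values.copy()
    if free_idx.size == 0:
        return k
    if model.is_linear and model.linear.entries is not None:
        obs = ctx.obs_rows
        n_t = ctx.times.size
        target = ctx.dxs[obs].ravel().copy()
        cols = []
        for e in free_idx:
            tgt, src = model.linear.entries[e]
            contrib = np.zeros((model.n_components, n_t))
            contrib[tgt] += ctx.xs[src]
            contrib[src] -= ctx.xs[src]
            cols.append(contrib[obs].ravel())
        # subtract the contribution of the fixed rates
        fixed = k.copy()
        fixed[free_idx] = 0.0
        target -= (model.linear.matrix(fixed)[obs] @ ctx.xs).ravel()
        design = np.column_stack(cols)
        mask_ok = np.all(np.isfinite(design), axis=1) & np.isfinite(target)
        if mask_ok.sum() >= free_idx.size:
            try:
                sol, _ = nnls(design[mask_ok], target[mask_ok])
                k[free_idx] = sol
            except (ValueError, RuntimeError):
                pass
    return np.maximum(k, 0.0)


def _run_fit(ctx: FitContext, support: np.ndarray, rng: np.random.Generator,
             n_restarts: int, maxfev_factor: int,
             init: Optional[dict] = None):
    """Optimise (a restricted to the support, free rates, unknown x0).

    Returns (a_full, k, x0, h_grid, traj, loglik, sigma2, converged).
    """
    model = ctx.model
    n = model.n_components
    free_idx = np.flatnonzero(model.free_rate_mask)
    unk_idx = np.flatnonzero(model.unknown_x0_mask)
    d = support.size
    n_u = d if d >= 2 else 0

    init = init or {}
    k_init = np.asarray(init.get("rates", _init_rates(ctx, model, free_idx)),
                        dtype=float)
    x0_init = np.asarray(init.get("x0", model.initial_values),
                         dtype=float).copy()
    obs_scale = float(np.nanmean(np.abs(ctx.xs[ctx.obs_rows]))) or 1.0

    def unpack(theta, sign_a):
        k = model.rate_values.copy()
        pos = n_u
        if free_idx.size:
            # clamp against simplex excursions: rates beyond e^+-40 are
            # unphysical and only exist to be rejected
            k[free_idx] = np.exp(np.clip(theta[pos:pos + free_idx.size],
                                         -40.0, 40.0))
            pos += free_idx.size
        x0 = x0_init.copy()
        if unk_idx.size:
            x0[unk_idx] = theta[pos:pos + unk_idx.size]
        if d == 0:
            return k, x0, None, None
        if d == 1:
            a_supp = np.array([float(sign_a)])
        else:
            u = theta[:n_u]
            s = float(np.sum(np.abs(u)))
            if s < 1e-10:
                return k, x0, None, "degenerate"
            a_supp = u / s
        return k, x0, a_supp, None

    # a large finite penalty keeps the simplex well-defined where the
    # likelihood is -inf (solver failure, non-positive lognormal fit, ...)
    bad = 1e100

    def objective(theta, sign_a=1.0):
        k, x0, a_supp, flag = unpack(theta, sign_a)
        if flag == "degenerate":
            return bad
        if d == 0:
            traj = _trajectories(ctx, k, x0, None, None)
        else:
            if np.any(np.abs(a_supp) < 1e-12):
                return bad
            h_grid = _h_grid(ctx, k, support, a_supp)
            if not np.all(np.isfinite(h_grid)):
                return bad
            a_full = np.zeros(n)
            a_full[support] = a_supp
            traj = _trajectories(ctx, k, x0, a_full, h_grid)
        loglik, _ = _profiled_loglik(ctx, traj)
        return -loglik if np.isfinite(loglik) else bad

    def initial_theta():
        parts = []
        if n_u:
            u0 = init.get("u")
            if u0 is None:
                k0 = k_init
                h0 = ctx.dxs[support] - _psi_rows(ctx, k0, support)
                rms = np.sqrt(np.mean(h0 ** 2, axis=1)) + 1e-12
                ref = h0[int(np.argmax(rms))]
                signs = np.sign(h0 @ ref)
                signs[signs == 0] = 1.0
                u0 = signs * rms
                u0 = u0 / np.sum(np.abs(u0))
            parts.append(np.asarray(u0, dtype=float))
        if free_idx.size:
            parts.append(np.log(np.maximum(k_init[free_idx], 1e-4)))
        if unk_idx.size:
            guesses = x0_init[unk_idx].copy()
            for pos, row in enumerate(unk_idx):
                if row in ctx.obs_rows and np.isfinite(ctx.xs[row, 0]):
                    guesses[pos] = ctx.xs[row, 0]
            bad = ~np.isfinite(guesses) | (guesses == 0)
            guesses[bad] = obs_scale
            parts.append(guesses)
        return np.concatenate(parts) if parts else np.array([])

    def solve_for_sign(sign_a):
        theta0 = initial_theta()
        if theta0.size == 0:
            return np.array([]), objective(theta0, sign_a), True
        best = (None, np.inf, False)
        starts = [theta0]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(theta0 + 0.3 * rng.standard_normal(theta0.size)
                          * np.maximum(np.abs(theta0), 0.1))
        maxfev = maxfev_factor * max(1, theta0.size)
        for start in starts:
            res = minimize(objective, start, args=(sign_a,),
                           method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-8,
                                    "maxfev": maxfev, "maxiter": maxfev})
            if res.fun < best[1]:
                best = (res.x, res.fun, bool(res.success))
        return best

    if d == 1:
        cands = [(s,) + tuple(solve_for_sign(s)) for s in (1.0, -1.0)]
        sign_a, theta_opt, f_opt, ok = min(cands, key=lambda c: c[2])
    else:
        sign_a = 1.0
        theta_opt, f_opt, ok = solve_for_sign(sign_a)

    k, x0, a_supp, _ = unpack(theta_opt, sign_a)
    if d == 0:
        a_full = np.zeros(n)
        h_grid = None
        traj = _trajectories(ctx, k, x0, None, None)
    else:
        h_grid = _h_grid(ctx, k, support, a_supp)
        a_full = np.zeros(n)
        a_full[support] = a_supp
        traj = _trajectories(ctx, k, x0, a_full, h_grid)
        # fix the joint sign of (a, h): latent course has non-negative mean
        if float(np.mean(h_grid)) < 0:
            a_full, a_supp, h_grid = -a_full, -a_supp, -h_grid
    loglik, sigma2 = _profiled_loglik(ctx, traj)
    return a_full, k, x0, h_grid, traj, loglik, sigma2, bool(ok)


def _normalize_support(model: NetworkModel, support) -> np.ndarray:
    support = np.asarray(sorted(set(int(i) for i in support)), dtype=int)
    if support.size and (support.min() < 0
                         or support.max() >= model.n_components):
        raise InvalidSupportError("support index out of range")
    if np.any(~model.hidden_slots[support]):
        raise InvalidSupportError("support includes a component without a "
                                  "latent-weight slot")
    return support


def _build_estimate(ctx, support, a_full, k, x0, h_grid, traj, loglik,
                    sigma2, converged) -> LatentEstimate:
    if h_grid is None:
        h_grid = np.zeros(ctx.times.size)
    return LatentEstimate(
        support=tuple(int(i) for i in support),
        a=a_full,
        sigma2=sigma2,
        hidden=HiddenSignal(ctx.times, h_grid, interpolation="linear"),
        trajectories=traj,
        loglik=loglik,
        rates_hat=dict(zip(ctx.model.rate_names, np.asarray(k).tolist())),
        x0_hat=x0,
        n_a=int(support.size),
        converged=converged,
        noise_kind=ctx.noise_kind,
        n_obs_components=int(ctx.obs_rows.size),
        n_times=int(ctx.times.size),
    )


def estimate_latent(model: NetworkModel, data: TimeSeriesData,
                    support=(), noise_kind: Optional[str] = None,
                    context: Optional[FitContext] = None,
                    seed: int = 0, n_restarts: int = 2,
                    maxfev_factor: int = 300,
                    init: Optional[dict] = None,
                    k_dim: Optional[int] = None,
                    lambda_grid=None) -> LatentEstimate:
    """Fit the latent input on a fully observed network.

    ``support`` lists the components allowed a nonzero weight; the empty
    support is the null model (no latent input). Free rates and unknown
    initial values (flagged on the model) are estimated jointly; the
    noise variance is profiled out analytically at every step.
    """
    support = _normalize_support(model, support)
    if context is None:
        context = prepare_context(model, data, noise_kind, k_dim=k_dim,
                                  lambda_grid=lambda_grid)
    if np.any(~data.observed_mask):
        raise ConfigurationError(
            "estimate_latent requires a fully observed network; use "
            "estimate_latent_partial"
        )
    rng = np.random.default_rng(seed)
    out = _run_fit(context, support, rng, n_restarts, maxfev_factor,
                   init=init)
    return _build_estimate(context, support, *out)


# ---------------------------------------------------------------------------
# Partially observed networks
# ---------------------------------------------------------------------------

def estimate_latent_partial(model: NetworkModel, obs_map, data: TimeSeriesData,
                            support=(), noise_kind: Optional[str] = None,
                            context: Optional[FitContext] = None,
                            seed: int = 0, n_restarts: int = 2,
                            maxfev_factor: int = 300,
                            max_outer_iter: int = MAX_OUTER_ITER,
                            k_dim: Optional[int] = None,
                            lambda_grid=None) -> LatentEstimate:
    """Latent-input estimation when only M < N components are measured.

    The model must already be expressed in the observed coordinates (the
    observation channels are affine in single model coordinates, so the
    user — or :func:`~latentode.network.transform_linear_network` for
    linear systems — supplies the transformed equations). A preliminary
    pass solves the system with no latent input to stand in for the
    unobserved coordinates; the procedure then alternates residual
    extraction on the observed channels, ML update of the weights, noise
    and unknown initial values, and re-solution of the unobserved
    coordinates, until the latent course and the log-likelihood settle.
    """
    obs_set = set(int(i) for i in np.asarray(obs_map.index, dtype=int))
    data_obs = set(int(i) for i in data.observed_indices)
    if obs_set != data_obs:
        raise ConfigurationError("observation map and data mask disagree")
    support = _normalize_support(model, support)
    if any(int(i) not in obs_set for i in support):
        raise InvalidSupportError("support must lie within the observed "
                                  "components")
    if len(obs_set) == model.n_components:
        return estimate_latent(model, data, support, noise_kind,
                               context=context, seed=seed,
                               n_restarts=n_restarts,
                               maxfev_factor=maxfev_factor,
                               k_dim=k_dim, lambda_grid=lambda_grid)

    if context is None:
        context = prepare_context(model, data, noise_kind, k_dim=k_dim,
                                  lambda_grid=lambda_grid)
    ctx = context
    n = model.n_components
    unobs = np.flatnonzero(~data.observed_mask)
    # unobserved starting values are always unknown parameters
    work = ctx.model
    mask = work.unknown_x0_mask.copy()
    mask[unobs] = True
    from dataclasses import replace as _replace
    ctx.model = _replace(work, unknown_x0_mask=mask)

    rng = np.random.default_rng(seed)

    # preliminary: solve with h == 0 to stand in for unobserved coordinates
    null_fit = _run_fit(ctx, np.array([], dtype=int), rng, n_restarts,
                        maxfev_factor)
    traj = null_fit[4]
    if traj is not None:
        ctx.xs[unobs] = traj[unobs]
    if support.size == 0:
        return _build_estimate(ctx, np.array([], dtype=int), *null_fit)

    h_prev = np.zeros(ctx.times.size)
    loglik_prev = null_fit[5]
    warm = {"rates": null_fit[1], "x0": null_fit[2]}
    converged_outer = False
    best = None
    stalled = 0
    for _ in range(max_outer_iter):
        out = _run_fit(ctx, support, rng, n_restarts, maxfev_factor,
                       init=warm)
        a_full, k, x0, h_grid, traj, loglik, sigma2, ok = out
        if traj is not None:
            ctx.xs[unobs] = traj[unobs]
        if best is None or (np.isfinite(loglik)
                            and loglik > best[5] + LOGLIK_TOL):
            best = out
            stalled = 0
        else:
            # the alternation stopped improving: a non-convergent (often
            # oscillating or diverging) run; keep the best iterate
            stalled += 1
        dh = float(np.max(np.abs(h_grid - h_prev)))
        dll = abs(loglik - loglik_prev) if np.isfinite(loglik) else np.inf
        h_prev, loglik_prev = h_grid.copy(), loglik
        warm = {"rates": k, "x0": x0,
                "u": a_full[support] if support.size >= 2 else None}
        if dh < H_TOL and dll < LOGLIK_TOL:
            converged_outer = True
            best = out
            break
        if stalled >= 5:
            break
    if not converged_outer:
        logger.warning("partial-observation alternation did not converge; "
                       "returning the best-likelihood iterate")
    a_full, k, x0, h_grid, traj, loglik, sigma2, ok = best
    est = _build_estimate(ctx, support, a_full, k, x0, h_grid, traj,
                          loglik, sigma2, bool(ok) and converged_outer)
    return est
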