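"""ODE network models with an additive latent input.

A network of :math:`N` components follows

.. math::

    \\dot x_i(t) = \\psi_i(k, x(t)) + a_i h(t),

where :math:`\\psi_i` encodes the known interaction structure with
non-negative rate parameters :math:`k`, :math:`h(t)` is an unobserved,
non-parametric time course (the *latent input* or *hidden influence*) and
the weights :math:`a_i` quantify how strongly it activates
(:math:`a_i > 0`) or inhibits (:math:`a_i < 0`) each component.

This module provides the model container, builders for the network
families used throughout the package (general linear mass-transport
networks, the four-component feedback cascade, and the JAK2-STAT5
signalling models including their linear-chain-trick delay variants),
and numerical integration with or without the latent forcing term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.linalg import expm

from .exceptions import (
    ConfigurationError,
    DomainError,
    IntegrationError,
    InvalidModelError,
)

__all__ = [
    "HiddenSignal",
    "ObservationMap",
    "NetworkModel",
    "LinearStructure",
    "build_linear_network",
    "build_cascade_model",
    "build_jakstat_model",
    "add_flow",
    "transform_linear_network",
    "solve_ode",
    "LinearPropagator",
]


# ---------------------------------------------------------------------------
# Latent signal container
# ---------------------------------------------------------------------------

@dataclass
class HiddenSignal:
    """A latent time course known at grid points, evaluable anywhere between.

    Parameters
    ----------
    times
        Strictly increasing observation times ``t_0 ... t_n``.
    values
        Signal values at the grid points; finite.
    interpolation
        Off-grid evaluation rule, ``"linear"`` (default; bounded and
        shape-preserving) or ``"cubic"``.
    """

    times: np.ndarray
    values: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise InvalidModelError("HiddenSignal needs at least two time points")
        if self.values.shape != self.times.shape:
            raise InvalidModelError("times and values must have identical shape")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidModelError("HiddenSignal times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidModelError("HiddenSignal values must be finite")
        if self.interpolation not in ("linear", "cubic"):
            raise ConfigurationError(
                f"unknown interpolation rule {self.interpolation!r}"
            )
        self._cubic = None

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def __call__(self, t):
        """Evaluate the signal at ``t`` (scalar or array) inside the domain."""
        t_arr = np.asarray(t, dtype=float)
        lo, hi = self.domain
        eps = 1e-12 * max(1.0, abs(lo), abs(hi))
        if np.any(t_arr < lo - eps) or np.any(t_arr > hi + eps):
            raise DomainError(
                f"evaluation outside the signal domain [{lo}, {hi}]"
            )
        t_arr = np.clip(t_arr, lo, hi)
        if self.interpolation == "linear":
            out = np.interp(t_arr, self.times, self.values)
        else:
            if self._cubic is None:
                self._cubic = CubicSpline(self.times, self.values)
            out = self._cubic(t_arr)
            # grid points return the stored values exactly, not to
            # spline-evaluation rounding
            pos = np.searchsorted(self.times, t_arr)
            pos = np.clip(pos, 0, self.times.size - 1)
            exact = self.times[pos] == t_arr
            out = np.where(exact, self.values[pos], out)
        return out if np.ndim(t) else float(out)


# ---------------------------------------------------------------------------
# Observation map (affine channels onto model coordinates)
# ---------------------------------------------------------------------------

@dataclass
class ObservationMap:
    """Affine observation channels ``y_m = b_m * x_{index_m} + c_m``.

    Only affine maps are supported; with a non-linear readout the residual
    extraction identity no longer isolates ``h`` linearly.
    """

    index: np.ndarray
    scale: Optional[np.ndarray] = None
    offset: Optional[np.ndarray] = None

    def __post_init__(self):
        self.index = np.asarray(self.index, dtype=int)
        m = self.index.size
        if m < 1:
            raise InvalidModelError("at least one observed channel is required")
        if len(set(self.index.tolist())) != m:
            raise InvalidModelError("observed indices must be distinct")
        if self.scale is None:
            self.scale = np.ones(m)
        if self.offset is None:
            self.offset = np.zeros(m)
        self.scale = np.asarray(self.scale, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.scale.shape != (m,) or self.offset.shape != (m,):
            raise InvalidModelError("scale/offset must match the channel count")
        if np.any(self.scale == 0):
            raise InvalidModelError("observation scales must be nonzero")

    @property
    def n_observed(self) -> int:
        return int(self.index.size)


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------

class LinearStructure:
    """Linear(-affine) right-hand side ``psi(k, x) = A(k) x + d(k)``.

    ``entries`` optionally records, per rate, the mass flow ``source ->
    target`` it parameterises; structural edits (adding a flow during
    network repair) are only possible when this bookkeeping is present.
    """

    def __init__(self, matrix_fn, drift_fn=None, entries=None):
        self.matrix_fn = matrix_fn
        self.drift_fn = drift_fn
        self.entries = entries  # list of (target, source) per rate, or None

    def matrix(self, k: np.ndarray) -> np.ndarray:
        return self.matrix_fn(np.asarray(k, dtype=float))

    def drift(self, k: np.ndarray) -> Optional[np.ndarray]:
        if self.drift_fn is None:
            return None
        return self.drift_fn(np.asarray(k, dtype=float))


@dataclass
class NetworkModel:
    """An N-component ODE system with slots for an additive latent input.

    The right-hand side contract: ``rhs(k, x, t)`` returns the N
    derivatives; terms must be locally Lipschitz on the non-negative
    orthant (a documented contract enforced by the builders, not checked
    generically). ``hidden_slots`` marks the components whose equation
    carries a latent-weight slot ``a_i``.
    """

    n_components: int
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    rate_names: tuple
    rate_values: np.ndarray
    component_names: tuple
    initial_values: np.ndarray
    free_rate_mask: np.ndarray = None
    unknown_x0_mask: np.ndarray = None
    hidden_slots: np.ndarray = None
    linear: Optional[LinearStructure] = None

    def __post_init__(self):
        n = self.n_components
        self.rate_values = np.asarray(self.rate_values, dtype=float)
        self.initial_values = np.asarray(self.initial_values, dtype=float)
        if len(self.component_names) != n or self.initial_values.shape != (n,):
            raise InvalidModelError("component metadata does not match N")
        if len(self.rate_names) != self.rate_values.size:
            raise InvalidModelError("rate names and values differ in length")
        if np.any(self.rate_values < 0) or not np.all(
            np.isfinite(self.rate_values)
        ):
            raise InvalidModelError("rates must be finite and non-negative")
        if self.free_rate_mask is None:
            self.free_rate_mask = np.zeros(self.rate_values.size, dtype=bool)
        if self.unknown_x0_mask is None:
            self.unknown_x0_mask = np.zeros(n, dtype=bool)
        if self.hidden_slots is None:
            self.hidden_slots = np.ones(n, dtype=bool)
        self.free_rate_mask = np.asarray(self.free_rate_mask, dtype=bool)
        self.unknown_x0_mask = np.asarray(self.unknown_x0_mask, dtype=bool)
        self.hidden_slots = np.asarray(self.hidden_slots, dtype=bool)

    # -- convenience -------------------------------------------------------

    @property
    def is_linear(self) -> bool:
        return self.linear is not None

    def rates_dict(self) -> dict:
        return dict(zip(self.rate_names, self.rate_values.tolist()))

    def with_rates(self, values: np.ndarray) -> "NetworkModel":
        """Copy of the model with the full rate vector replaced."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.rate_values.shape:
            raise InvalidModelError("rate vector has the wrong length")
        return replace(self, rate_values=values)

    def with_initial_values(self, x0: np.ndarray,
                            known: bool = True) -> "NetworkModel":
        x0 = np.asarray(x0, dtype=float)
        mask = (np.zeros(self.n_components, dtype=bool)
                if known else self.unknown_x0_mask)
        return replace(self, initial_values=x0, unknown_x0_mask=mask)

    def psi(self, x: np.ndarray, t: float = 0.0,
            rates: Optional[np.ndarray] = None) -> np.ndarray:
        """Evaluate the deterministic part of the right-hand side."""
        k = self.rate_values if rates is None else np.asarray(rates, float)
        return np.asarray(self.rhs(k, np.asarray(x, dtype=float), t), float)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _flow_structure(entries, n):
    """LinearStructure for mass flows: rate e moves material source->target."""

    def matrix_fn(k):
        a_mat = np.zeros((n, n))
        for rate, (target, source) in zip(k, entries):
            if target != source:
                a_mat[target, source] += rate
            a_mat[source, source] -= rate
        return a_mat

    return LinearStructure(matrix_fn, entries=list(entries))


def _linear_model(entries, names, values, initial_values, component_names,
                  free_mask=None):
    n = len(component_names)
    structure = _flow_structure(entries, n)

    def rhs(k, x, t):
        return structure.matrix(k) @ x

    return NetworkModel(
        n_components=n,
        rhs=rhs,
        rate_names=tuple(names),
        rate_values=np.asarray(values, dtype=float),
        component_names=tuple(component_names),
        initial_values=np.asarray(initial_values, dtype=float),
        free_rate_mask=free_mask,
        linear=structure,
    )


def build_linear_network(k_matrix, initial_values,
                         free_rates: bool = False) -> NetworkModel:
    """Mass-transport network ``dx_i/dt = sum_u (k_iu x_u - k_ui x_i)``.

    ``k_matrix[i, u]`` is the non-negative rate of the flow from component
    ``u`` into component ``i``; the same amount leaves ``u``, so total mass
    is conserved whenever the latent weights sum to zero.
    """
    k_matrix = np.asarray(k_matrix, dtype=float)
    if k_matrix.ndim != 2 or k_matrix.shape[0] != k_matrix.shape[1]:
        raise InvalidModelError("k_matrix must be square")
    if np.any(k_matrix < 0) or not np.all(np.isfinite(k_matrix)):
        raise InvalidModelError("k_matrix entries must be finite and >= 0")
    n = k_matrix.shape[0]
    initial_values = np.asarray(initial_values, dtype=float)
    if initial_values.shape != (n,):
        raise InvalidModelError("initial_values must have length N")

    entries, names, values = [], [], []
    for i in range(n):
        for u in range(n):
            if i != u and k_matrix[i, u] != 0.0:
                entries.append((i, u))
                names.append(f"k_{i + 1}_{u + 1}")
                values.append(k_matrix[i, u])
    free = np.full(len(names), bool(free_rates))
    return _linear_model(
        entries, names, values, initial_values,
        tuple(f"x{i + 1}" for i in range(n)), free_mask=free,
    )


def build_cascade_model(k, feedback_rate: Optional[float] = None,
                        initial_values=None,
                        free_rates: bool = False) -> NetworkModel:
    """Four-component forward cascade ``x1 -> x2 -> x3 -> x4``.

    Rates ``k = (k1, k2, k3)`` drive the forward flows; when
    ``feedback_rate`` is given an additional flow ``x4 -> x1`` closes the
    loop. The chain transports mass, so the component total is conserved.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (3,) or np.any(k < 0):
        raise InvalidModelError("cascade needs three non-negative rates")
    if feedback_rate is not None and feedback_rate < 0:
        raise InvalidModelError("feedback rate must be non-negative")
    if initial_values is None:
        initial_values = np.array([1.0, 0.0, 0.0, 0.0])
    entries = [(1, 0), (2, 1), (3, 2)]
    names = ["k1", "k2", "k3"]
    values = list(k)
    if feedback_rate is not None:
        entries.append((0, 3))
        names.append("k_fb")
        values.append(float(feedback_rate))
    free = np.full(len(names), bool(free_rates))
    return _linear_model(entries, names, values, initial_values,
                         ("x1", "x2", "x3", "x4"), free_mask=free)


def add_flow(model: NetworkModel, source: int, target: int,
             name: Optional[str] = None, value: float = 0.0,
             free: bool = True) -> NetworkModel:
    """Return a copy of a linear network with one extra flow source->target.

    The structural edit used during network repair; only linear networks
    built from flow entries support it.
    """
    if not model.is_linear or model.linear.entries is None:
        raise InvalidModelError("structural edits require a flow-based "
                                "linear network")
    if value < 0:
        raise InvalidModelError("flow rates must be non-negative")
    n = model.n_components
    if not (0 <= source < n and 0 <= target < n) or source == target:
        raise InvalidModelError("invalid flow endpoints")
    entries = list(model.linear.entries) + [(target, source)]
    names = list(model.rate_names) + [
        name or f"k_{target + 1}_{source + 1}"
    ]
    values = list(model.rate_values) + [float(value)]
    free_mask = np.concatenate([model.free_rate_mask, [bool(free)]])
    out = _linear_model(entries, names, values, model.initial_values,
                        model.component_names, free_mask=free_mask)
    return replace(out, unknown_x0_mask=model.unknown_x0_mask.copy(),
                   hidden_slots=model.hidden_slots.copy())


def transform_linear_network(model: NetworkModel,
                             obs_map: ObservationMap) -> NetworkModel:
    """Re-express a linear network in affinely transformed coordinates.

    Observed coordinates become ``y_i = b_i x_i + c_i``; the remaining
    coordinates are kept as-is. With ``y = T x + c`` the dynamics turn into
    ``dy/dt = T A T^{-1} (y - c)``, i.e. a linear system with a constant
    drift, and the latent slot weights transform as ``a~_i = b_i a_i``
    (absorbed into the estimated weights, so slots are unchanged).
    """
    if not model.is_linear:
        raise InvalidModelError("only linear networks can be transformed "
                                "automatically")
    n = model.n_components
    b = np.ones(n)
    c = np.zeros(n)
    b[obs_map.index] = obs_map.scale
    c[obs_map.index] = obs_map.offset
    base = model.linear

    def matrix_fn(k):
        a_mat = base.matrix(k)
        return (b[:, None] * a_mat) / b[None, :]

    def drift_fn(k):
        return -matrix_fn(k) @ c

    structure = LinearStructure(matrix_fn, drift_fn)

    def rhs(k, x, t):
        return structure.matrix(k) @ x + structure.drift(k)

    names = tuple(
        f"y{np.where(obs_map.index == i)[0][0] + 1}"
        if i in obs_map.index else model.component_names[i]
        for i in range(n)
    )
    return NetworkModel(
        n_components=n,
        rhs=rhs,
        rate_names=model.rate_names,
        rate_values=model.rate_values.copy(),
        component_names=names,
        initial_values=b * model.initial_values + c,
        free_rate_mask=model.free_rate_mask.copy(),
        unknown_x0_mask=model.unknown_x0_mask.copy(),
        hidden_slots=model.hidden_slots.copy(),
        linear=structure,
    )


# ---------------------------------------------------------------------------
# JAK2-STAT5 signalling models
# ---------------------------------------------------------------------------

_JAKSTAT_VARIANTS = ("base", "base_lc", "delay", "delay_observed")


def build_jakstat_model(variant: str, rates: dict, tau: Optional[float] = None,
                        epor_a=None, initial_x1: Optional[float] = None):
    """STAT5 nucleocytoplasmic-cycling models driven by activated Epo receptor.

    States of the base model: cytoplasmic unphosphorylated STAT5 (x1),
    phosphorylated monomeric STAT5 (x2), phosphorylated dimeric STAT5 (x3)
    and nuclear STAT5 (x4); ``EpoR_A(t)`` is the measured Epo-induced
    receptor phosphorylation, supplied as an exogenous time course
    (callable or :class:`HiddenSignal`).

    Variants
    --------
    ``base``
        The four-state cycle without latent slots.
    ``base_lc``
        The first three states with latent-weight slots ``a1..a3`` (the
        nuclear state is dropped because it is never measured).
    ``delay``
        Adds the delayed nuclear export ``x4 -> x1`` through the linear
        chain trick: two auxiliary states ``z1, z2`` with time scale
        ``tau`` approximate the delay, rate ``k4`` closes the loop.
    ``delay_observed``
        The delay model re-expressed in the measured coordinates
        ``y1 = k5 (x2 + 2 x3)`` and ``y2 = k6 (x1 + x2 + 2 x3)`` together
        with the unobserved ``x3, z1, z2``; also returns the
        :class:`ObservationMap` marking ``y1, y2`` as the observed
        channels. In these coordinates the latent slots carry the
        transformed weights ``(k5 (a2 + 2 a3), k6 (a1 + a2 + 2 a3), a3)``.

    Unless ``initial_x1`` is supplied, ``x1(0)`` (and hence ``y2(0)``) is
    flagged unknown, to be estimated from data; all other species start
    at zero.
    """
    if variant not in _JAKSTAT_VARIANTS:
        raise ConfigurationError(
            f"unknown JAK2-STAT5 variant {variant!r}; "
            f"expected one of {_JAKSTAT_VARIANTS}"
        )
    if epor_a is None:
        raise ConfigurationError("an EpoR_A(t) input time course is required")
    epo = epor_a if callable(epor_a) else (lambda t: float(epor_a))

    needed = {"base": ("k1", "k2", "k3"),
              "base_lc": ("k1", "k2", "k3"),
              "delay": ("k1", "k2", "k3", "k4"),
              "delay_observed": ("k1", "k2", "k3", "k4", "k5", "k6", "k7")}
    names = needed[variant]
    try:
        k_values = np.array([float(rates[nm]) for nm in names])
    except KeyError as exc:
        raise ConfigurationError(f"missing rate {exc.args[0]!r}") from exc
    if np.any(k_values < 0):
        raise InvalidModelError("rates must be non-negative")
    if variant in ("delay", "delay_observed"):
        if tau is None or tau <= 0:
            raise ConfigurationError("delay variants require tau > 0")

    x1_0 = 1.0 if initial_x1 is None else float(initial_x1)
    x1_known = initial_x1 is not None

    if variant == "base":
        def rhs(k, x, t):
            k1, k2, k3 = k
            e = epo(t)
            return np.array([
                -k1 * x[0] * e,
                -k2 * x[1] ** 2 + k1 * x[0] * e,
                -k3 * x[2] + 0.5 * k2 * x[1] ** 2,
                k3 * x[2],
            ])

        comp = ("x1", "x2", "x3", "x4")
        x0 = np.array([x1_0, 0.0, 0.0, 0.0])
        unknown = np.array([not x1_known, False, False, False])
        slots = np.zeros(4, dtype=bool)

    elif variant == "base_lc":
        def rhs(k, x, t):
            k1, k2, k3 = k
            e = epo(t)
            return np.array([
                -k1 * x[0] * e,
                -k2 * x[1] ** 2 + k1 * x[0] * e,
                -k3 * x[2] + 0.5 * k2 * x[1] ** 2,
            ])

        comp = ("x1", "x2", "x3")
        x0 = np.array([x1_0, 0.0, 0.0])
        unknown = np.array([not x1_known, False, False])
        slots = np.ones(3, dtype=bool)

    elif variant == "delay":
        tau_f = float(tau)

        def rhs(k, x, t):
            k1, k2, k3, k4 = k
            e = epo(t)
            return np.array([
                -k1 * x[0] * e + 2.0 * k4 * x[5],
                -k2 * x[1] ** 2 + k1 * x[0] * e,
                -k3 * x[2] + 0.5 * k2 * x[1] ** 2,
                k3 * x[2] - k4 * x[5],
                (x[2] - x[4]) / tau_f,
                2.0 * (x[4] - x[5]) / tau_f,
            ])

        comp = ("x1", "x2", "x3", "x4", "z1", "z2")
        x0 = np.array([x1_0, 0.0, 0.0, 0.0, 0.0, 0.0])
        unknown = np.array([not x1_known] + [False] * 5)
        slots = np.array([True, True, True, False, False, False])

    else:  # delay_observed, coordinates (y1, y2, x3, z1, z2)
        tau_f = float(tau)

        def rhs(k, x, t):
            k1, k2, k3, k4, k5, k6, k7 = k
            e = epo(t)
            y3 = k7 * e
            y1, y2, x3, z1, z2 = x
            return np.array([
                k1 * k5 * y2 * y3 / (k6 * k7)
                - k1 * y1 * y3 / k7
                - 2.0 * k3 * k5 * x3,
                -2.0 * k3 * k6 * x3 + 2.0 * k4 * k6 * z2,
                -k3 * x3 + k2 * y1 ** 2 / (2.0 * k5 ** 2)
                - 2.0 * k2 * y1 * x3 / k5 + 2.0 * k2 * x3 ** 2,
                (x3 - z1) / tau_f,
                2.0 * (z1 - z2) / tau_f,
            ])

        comp = ("y1", "y2", "x3", "z1", "z2")
        k6 = k_values[5]
        x0 = np.array([0.0, k6 * x1_0, 0.0, 0.0, 0.0])
        unknown = np.array([False, not x1_known, False, False, False])
        slots = np.array([True, True, True, False, False])

    rate_names = names + (("tau",) if variant in ("delay", "delay_observed")
                          else ())
    rate_values = (np.append(k_values, float(tau))
                   if variant in ("delay", "delay_observed") else k_values)
    if variant in ("delay", "delay_observed"):
        # tau enters through the closure, not through the k vector passed
        # to rhs; keep it in the rate table for bookkeeping only.
        base_rhs = rhs

        def rhs(k, x, t, _f=base_rhs, _m=len(names)):
            return _f(k[:_m], x, t)

    model = NetworkModel(
        n_components=len(comp),
        rhs=rhs,
        rate_names=tuple(rate_names),
        rate_values=rate_values,
        component_names=comp,
        initial_values=x0,
        unknown_x0_mask=unknown,
        hidden_slots=slots,
    )
    if variant == "delay_observed":
        return model, ObservationMap(index=[0, 1])
    return model


# ---------------------------------------------------------------------------
# Numerical integration
# ---------------------------------------------------------------------------

def _forced_rhs(model: NetworkModel, a, h):
    k = model.rate_values
    if h is None:
        return lambda t, x: model.rhs(k, x, t)
    a_eff = np.zeros(model.n_components)
    if a is not None:
        a_arr = np.asarray(a, dtype=float)
        if a_arr.shape != (model.n_components,):
            raise InvalidModelError("weight vector a must have length N")
        a_eff = np.where(model.hidden_slots, a_arr, 0.0)
    return lambda t, x: model.rhs(k, x, t) + a_eff * h(t)


def solve_ode(model: NetworkModel, times, a=None, h=None,
              method: str = "rk45", rtol: float = 1e-8, atol: float = 1e-10,
              rk4_substeps: int = 16, x0=None) -> np.ndarray:
    """Integrate the network, optionally forced by ``a_i h(t)``.

    Parameters
    ----------
    model
        The network; all initial values must be resolved (no unknown
        flags) unless ``x0`` overrides them.
    times
        Output grid (increasing). When ``h`` is present, the grid must lie
        inside its domain.
    a, h
        Latent weights and signal. ``h`` absent means the plain system;
        ``a`` is then ignored. A signal of zeros is equivalent to no
        forcing.
    method
        ``"rk45"`` — adaptive Runge-Kutta 4(5) (default); ``"rk4"`` —
        classic fixed-step fourth-order scheme with ``rk4_substeps`` steps
        per output interval (used for convergence checks).

    Returns
    -------
    ndarray of shape ``(N, len(times))``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ConfigurationError("times must be strictly increasing")
    if x0 is None:
        if np.any(model.unknown_x0_mask):
            raise ConfigurationError(
                "model has unknown initial values; pass x0 explicitly"
            )
        x0 = model.initial_values
    x0 = np.asarray(x0, dtype=float)

    if h is not None and isinstance(h, HiddenSignal):
        lo, hi = h.domain
        eps = 1e-9 * max(1.0, abs(hi))
        if times[0] < lo - eps or times[-1] > hi + eps:
            raise DomainError("requested times exceed the latent signal domain")

    fun = _forced_rhs(model, a, h)

    if method == "rk45":
        # a piecewise-linear latent signal has derivative kinks at its
        # grid points; integrating segment-by-segment between the knots
        # keeps the right-hand side smooth within every solver step and
        # preserves the advertised accuracy
        if isinstance(h, HiddenSignal):
            knots = h.times[(h.times > times[0]) & (h.times < times[-1])]
            segments = np.unique(np.concatenate([[times[0]], knots,
                                                 [times[-1]]]))
        else:
            segments = np.array([times[0], times[-1]])
        out = np.empty((x0.size, times.size))
        state = x0.copy()
        filled = 0
        if times[0] == segments[0]:
            out[:, 0] = state
            filled = 1
        for lo, hi in zip(segments[:-1], segments[1:]):
            if hi <= lo:
                continue
            t_eval = times[(times > lo) & (times <= hi)]
            wanted = t_eval.size
            if not wanted or t_eval[-1] < hi:
                t_eval = np.append(t_eval, hi)
            sol = solve_ivp(fun, (lo, hi), state, t_eval=t_eval,
                            method="RK45", rtol=rtol, atol=atol)
            if not sol.success or not np.all(np.isfinite(sol.y)):
                t_fail = sol.t[-1] if sol.t.size else lo
                raise IntegrationError(
                    f"integration failed near t = {t_fail}",
                    time=float(t_fail)
                )
            out[:, filled:filled + wanted] = sol.y[:, :wanted]
            filled += wanted
            state = sol.y[:, -1]
        return out

    if method == "rk4":
        out = np.empty((x0.size, times.size))
        x = x0.copy()
        out[:, 0] = x
        for j in range(times.size - 1):
            t = times[j]
            dt = (times[j + 1] - times[j]) / rk4_substeps
            for _ in range(rk4_substeps):
                s1 = fun(t, x)
                s2 = fun(t + dt / 2, x + dt / 2 * s1)
                s3 = fun(t + dt / 2, x + dt / 2 * s2)
                s4 = fun(t + dt, x + dt * s3)
                x = x + dt / 6 * (s1 + 2 * s2 + 2 * s3 + s4)
                t += dt
            if not np.all(np.isfinite(x)):
                raise IntegrationError(
                    f"integration failed near t = {t}", time=float(t)
                )
            out[:, j + 1] = x
        return out

    raise ConfigurationError(f"unknown solver method {method!r}")


class LinearPropagator:
    """Exact stepping for ``dx/dt = A x + a h(t) + d`` on a uniform grid.

    ``h`` is taken piecewise linear between grid points, which makes the
    per-interval problem linear time-invariant in an augmented state; one
    matrix exponential then propagates the solution exactly. Used as the
    fast inner-loop solver of the likelihood machinery for linear
    networks (the adaptive solver gives the same trajectories to within
    its tolerance).
    """

    def __init__(self, a_matrix: np.ndarray, dt: float,
                 drift: Optional[np.ndarray] = None):
        n = a_matrix.shape[0]
        self.n = n
        self.dt = float(dt)
        eye = np.eye(n)
        big = np.zeros((3 * n, 3 * n))
        big[:n, :n] = a_matrix
        big[:n, n:2 * n] = eye
        big[n:2 * n, 2 * n:] = eye
        ebig = expm(big * self.dt)
        self.e_step = ebig[:n, :n]
        # G1 = int_0^dt e^{A (dt - s)} ds ; G2 = int_0^dt e^{A (dt - s)} s ds
        self.g1 = ebig[:n, n:2 * n]
        self.g2 = ebig[:n, 2 * n:]
        self.drift = None if drift is None else self.g1 @ drift

    def propagate(self, x0: np.ndarray, a: Optional[np.ndarray],
                  h_values: Optional[np.ndarray],
                  n_steps: Optional[int] = None) -> np.ndarray:
        """Trajectory at the grid times; ``h_values`` given on that grid."""
        if h_values is None:
            n_steps = int(n_steps)
            forced0 = forced1 = None
        else:
            h_values = np.asarray(h_values, dtype=float)
            n_steps = h_values.size - 1
            slopes = np.diff(h_values) / self.dt
            u0 = self.g1 @ a
            u1 = self.g2 @ a
            forced0 = np.outer(h_values[:-1], u0)
            forced1 = np.outer(slopes, u1)
        out = np.empty((self.n, n_steps + 1))
        x = np.asarray(x0, dtype=float)
        out[:, 0] = x
        for j in range(n_steps):
            x = self.e_step @ x
            if forced0 is not None:
                x = x + forced0[j] + forced1[j]
            if self.drift is not None:
                x = x + self.drift
            out[:, j + 1] = x
        return out
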