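"""Synthetic benchmark data: random linear networks, the feedback
cascade, noise generators and the simulation-study harness.

The generators define the package's reference study conditions: random
mass-transport networks with rates drawn uniformly on [0, 1] and latent
weights uniform on [-1, 1] (L1-normalised), sampled at 30 equally spaced
time points, corrupted by log-normal multiplicative noise at sigma in
{0.01, 0.1, 0.3}, with 100%, 67% or 33% of the components observed.
Every run is driven by the same single-peaked latent input so that
replicates are comparable, and each dataset carries a full truth bundle
(noise-free trajectories, generating weights, rates, signal, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError
from .io import TimeSeriesData
from .network import (
    HiddenSignal,
    ObservationMap,
    build_cascade_model,
    build_linear_network,
    solve_ode,
)

__all__ = [
    "default_hidden_influence",
    "simulate_linear_dataset",
    "score_s",
    "StudyConfig",
    "StudyResult",
    "run_simulation_study",
    "cascade_experiment",
    "CASCADE_DEFAULTS",
]

logger = logging.getLogger(__name__)

#: reference conditions of the misspecified-cascade experiment; the
#: feedback rate, noise level, initial state and time span are the
#: package's documented defaults (the forward rates are the reference
#: estimates of the true cascade).
CASCADE_DEFAULTS = {
    "rates": (0.15, 0.29, 0.20),
    "feedback_rate": 0.2,
    "sigma": 0.1,
    "noise_kind": "lognormal",
    "initial_values": (2.0, 0.5, 0.5, 0.5),
    "t_span": (0.0, 30.0),
    "n_times": 30,
}


def default_hidden_influence(times) -> HiddenSignal:
    """The fixed single-peaked latent input used by every simulation run.

    A Gaussian bump of unit height, peaking at 40% of the time span with
    width 15% of the span — deterministic, no randomness involved.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ConfigurationError("times must be strictly increasing")
    span = times[-1] - times[0]
    mu = times[0] + 0.4 * span
    width = 0.15 * span
    values = np.exp(-0.5 * ((times - mu) / width) ** 2)
    return HiddenSignal(times=times, values=values, interpolation="linear")


def _apply_noise(truth: np.ndarray, sigma: float, noise_kind: str,
                 rng: np.random.Generator) -> np.ndarray:
    eps = sigma * rng.standard_normal(truth.shape)
    if noise_kind == "normal":
        return truth + eps
    if noise_kind == "lognormal":
        return truth * np.exp(eps)
    raise ConfigurationError(f"unknown noise kind {noise_kind!r}")


def _observed_count(fraction: float, n: int) -> int:
    if not 0 < fraction <= 1:
        raise ConfigurationError("observed fraction must lie in (0, 1]")
    return int(math.ceil(fraction * n))


def simulate_linear_dataset(n_components: int = 3,
                            observed_fraction: float = 1.0,
                            sigma: float = 0.1,
                            noise_kind: str = "lognormal",
                            seed: int = 0,
                            n_times: int = 30,
                            t_span=(0.0, 10.0)) -> TimeSeriesData:
    """One random mass-transport network with a shared latent input.

    Draws the pairwise rates ``k_iu ~ U[0, 1]``, latent weights
    ``a_i ~ U[-1, 1]`` (L1-normalised) and initial values ``U[0.5, 1.5]``,
    integrates the forced network on 30 equally spaced time points and
    applies the requested noise. The lowest-index components are the
    observed ones. Log-normal noise requires strictly positive
    trajectories; a draw violating this is redrawn (deterministically
    from the same seed stream).
    """
    if n_components < 1:
        raise ConfigurationError("need at least one component")
    m_obs = _observed_count(observed_fraction, n_components)
    rng = np.random.default_rng(seed)
    times = np.linspace(t_span[0], t_span[1], n_times)
    h_true = default_hidden_influence(times)

    for attempt in range(50):
        k_matrix = rng.uniform(0.0, 1.0, (n_components, n_components))
        np.fill_diagonal(k_matrix, 0.0)
        a_true = rng.uniform(-1.0, 1.0, n_components)
        a_true = a_true / np.sum(np.abs(a_true))
        x0 = rng.uniform(0.5, 1.5, n_components)
        model = build_linear_network(k_matrix, x0)
        truth = solve_ode(model, times, a=a_true, h=h_true)
        if noise_kind != "lognormal" or np.min(truth) > 1e-8:
            break
        logger.debug("redrawing network (attempt %d): trajectory touched "
                     "zero under lognormal noise", attempt)
    else:
        raise ConfigurationError("could not draw a positive-trajectory "
                                 "network in 50 attempts")

    values = _apply_noise(truth, sigma, noise_kind, rng)
    mask = np.zeros(n_components, dtype=bool)
    mask[:m_obs] = True
    if noise_kind == "lognormal":
        values = np.where(mask[:, None], values, np.nan)
    else:
        values[~mask] = np.nan
    return TimeSeriesData(
        times=times,
        values=values,
        observed_mask=mask,
        noise_kind=noise_kind,
        sigma=sigma,
        truth={
            "trajectories": truth,
            "h_true": h_true,
            "a_true": a_true,
            "k_matrix": k_matrix,
            "x0": x0,
            "seed": seed,
        },
    )


def score_s(h_est: HiddenSignal, h_true: HiddenSignal) -> float:
    """Mean absolute deviation between two latent courses on one grid."""
    if (h_est.times.shape != h_true.times.shape
            or not np.allclose(h_est.times, h_true.times,
                               rtol=1e-9, atol=1e-12)):
        raise AlignmentError("latent courses live on different grids")
    return float(np.mean(np.abs(h_est.values - h_true.values)))


# ---------------------------------------------------------------------------
# Simulation-study harness
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Grid of study cells: sizes x noise levels x observed fractions."""

    sizes: Sequence[int] = (3, 6, 9)
    noise_levels: Sequence[float] = (0.01, 0.1, 0.3)
    observed_fractions: Sequence[float] = (1.0, 2.0 / 3.0, 1.0 / 3.0)
    replicates: int = 100
    base_seed: int = 0
    noise_kind: str = "lognormal"

    def __post_init__(self):
        for frac in self.observed_fractions:
            for n in self.sizes:
                _observed_count(frac, n)
        if self.replicates < 1:
            raise ConfigurationError("need at least one replicate")


@dataclass
class StudyResult:
    summary: pd.DataFrame
    replicates: pd.DataFrame


def _replicate_seed(base_seed: int, cell: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(cell), int(rep)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_simulation_study(config: StudyConfig,
                         progress: bool = False) -> StudyResult:
    """Run the recovery study over all cells of the configuration grid.

    Per replicate: simulate a random network, select the latent support
    by forward stepwise search (BIC), and score the estimated latent
    course against the generating one by its mean absolute deviation.
    Per-cell output: mean and 5%/95% quantiles of the score, plus the
    count of failed replicates (logged and excluded, never fatal).
    """
    from .selection import select_support  # local import avoids a cycle

    rows = []
    cell_no = 0
    for n in config.sizes:
        for frac in config.observed_fractions:
            for sigma in config.noise_levels:
                for rep in range(config.replicates):
                    seed = _replicate_seed(config.base_seed, cell_no, rep)
                    try:
                        s_val = _one_replicate(n, frac, sigma,
                                               config.noise_kind, seed)
                        rows.append({"cell": cell_no, "n": n, "frac": frac,
                                     "sigma": sigma, "rep": rep,
                                     "seed": seed, "s": s_val,
                                     "failed": False})
                    except Exception as exc:  # noqa: BLE001
                        logger.warning(
                            "replicate failed (n=%d frac=%.2f sigma=%g "
                            "rep=%d): %s", n, frac, sigma, rep, exc)
                        rows.append({"cell": cell_no, "n": n, "frac": frac,
                                     "sigma": sigma, "rep": rep,
                                     "seed": seed, "s": np.nan,
                                     "failed": True})
                if progress:
                    logger.info("cell %d done (n=%d frac=%.2f sigma=%g)",
                                cell_no, n, frac, sigma)
                cell_no += 1
    reps = pd.DataFrame(rows)
    groups = reps.groupby(["cell", "n", "frac", "sigma"], as_index=False)
    summary = groups.agg(
        mean_s=("s", "mean"),
        q05=("s", lambda s: s.quantile(0.05)),
        q95=("s", lambda s: s.quantile(0.95)),
        n_failed=("failed", "sum"),
    )
    return StudyResult(summary=summary, replicates=reps)


def _one_replicate(n: int, frac: float, sigma: float, noise_kind: str,
                   seed: int) -> float:
    from .selection import select_support

    data = simulate_linear_dataset(n_components=n, observed_fraction=frac,
                                   sigma=sigma, noise_kind=noise_kind,
                                   seed=seed)
    truth = data.truth
    model = build_linear_network(truth["k_matrix"], truth["x0"])
    obs_map = None
    if not np.all(data.observed_mask):
        obs_map = ObservationMap(index=data.observed_indices)
    sel = select_support(model, data, strategy="forward", criterion="bic",
                         noise_kind=noise_kind, obs_map=obs_map, seed=seed)
    return score_s(sel.chosen.hidden, truth["h_true"])


# ---------------------------------------------------------------------------
# Misspecified-cascade experiment
# ---------------------------------------------------------------------------

def cascade_experiment(seed: int = 0, rates=None,
                       feedback_rate: Optional[float] = None,
                       sigma: Optional[float] = None,
                       noise_kind: Optional[str] = None,
                       initial_values=None, n_times: Optional[int] = None,
                       t_span=None):
    """Data from the feedback cascade plus the feedback-free hypothesis.

    Simulates the true four-component forward cascade closed by an
    end-to-start feedback loop, observes all components under the
    configured noise, and returns ``(data, starting_model)`` where the
    starting model is the feedback-free cascade with free rates — the
    misspecified initial hypothesis of the repair workflow. All defaults
    come from :data:`CASCADE_DEFAULTS`.
    """
    cfg = CASCADE_DEFAULTS
    rates = np.asarray(cfg["rates"] if rates is None else rates, dtype=float)
    feedback_rate = (cfg["feedback_rate"] if feedback_rate is None
                     else float(feedback_rate))
    sigma = cfg["sigma"] if sigma is None else float(sigma)
    noise_kind = cfg["noise_kind"] if noise_kind is None else noise_kind
    x0 = np.asarray(cfg["initial_values"] if initial_values is None
                    else initial_values, dtype=float)
    n_times = cfg["n_times"] if n_times is None else int(n_times)
    t_span = cfg["t_span"] if t_span is None else t_span

    rng = np.random.default_rng(seed)
    times = np.linspace(t_span[0], t_span[1], n_times)
    true_model = build_cascade_model(rates, feedback_rate=feedback_rate,
                                     initial_values=x0)
    truth = solve_ode(true_model, times)
    values = _apply_noise(truth, sigma, noise_kind, rng)
    data = TimeSeriesData(
        times=times,
        values=values,
        component_names=("x1", "x2", "x3", "x4"),
        noise_kind=noise_kind,
        sigma=sigma,
        truth={
            "trajectories": truth,
            "rates": rates,
            "feedback_rate": feedback_rate,
            "x0": x0,
            "seed": seed,
            # the repair target: the missing feedback drains x4 into x1,
            # so the latent component should activate x1 and inhibit x4
            "a_pattern": {"positive": 0, "negative": 3},
        },
    )
    starting_model = build_cascade_model(rates, feedback_rate=None,
                                         initial_values=x0, free_rates=True)
    return data, starting_model
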