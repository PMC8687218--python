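"""Support selection for the latent input, and guided network repair.

All candidate models are nested: the null model (no latent input) sits
inside every supported model, and the number of nonzero latent weights
``N_a`` is the only part of the parameter count that varies between
candidates — so it replaces the full parameter dimension in the AIC/BIC
penalty. Selection searches supports by exhaustive enumeration (best
subset), greedy growth (forward) or greedy pruning (backward), always
minimising the chosen criterion.

The repair workflow turns a selected latent component into a structural
hypothesis: a weight pattern that activates one component and inhibits
another suggests a missing flow from the inhibited to the activated
component. The edit is applied, rates refitted, and the search repeats
until no latent component improves the criterion.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .exceptions import ConfigurationError
from .inference import (
    FitContext,
    LatentEstimate,
    estimate_latent,
    estimate_latent_partial,
    prepare_context,
)
from .network import NetworkModel, add_flow

__all__ = [
    "information_criterion",
    "SelectionResult",
    "select_support",
    "default_edit_interpreter",
    "RepairIteration",
    "RepairReport",
    "repair_network",
]

logger = logging.getLogger(__name__)

#: strict-improvement guard against floating-point noise
IMPROVEMENT_EPS = 1e-6


def information_criterion(loglik: float, n_a: int, n_plus_1: int,
                          n_obs_components: int, kind: str = "bic",
                          bic_sample: str = "total") -> float:
    """AIC/BIC with the latent-support size as the parameter count.

    ``bic_sample="total"`` (default) penalises with ``log((n+1) * N)``,
    the log of the total number of observations entering the likelihood
    (N = observed components); ``"per_time"`` uses ``N * log(n+1)``, the
    alternative reading of the penalty, for parity experiments.
    """
    if n_a < 0 or n_plus_1 <= 0 or n_obs_components <= 0:
        raise ConfigurationError("counts must be positive, n_a >= 0")
    if kind == "aic":
        return -2.0 * loglik + 2.0 * n_a
    if kind == "bic":
        if bic_sample == "total":
            penalty = math.log(n_plus_1 * n_obs_components)
        elif bic_sample == "per_time":
            penalty = n_obs_components * math.log(n_plus_1)
        else:
            raise ConfigurationError(f"unknown bic_sample {bic_sample!r}")
        return -2.0 * loglik + penalty * n_a
    raise ConfigurationError(f"unknown criterion kind {kind!r}")


@dataclass
class SelectionResult:
    """Outcome of a support search.

    ``path`` records every evaluated support as ``(support, criterion,
    accepted)``; accepted entries form the (monotone) search path and the
    chosen model minimises the criterion among them.
    """

    strategy: str
    criterion: str
    path: list
    chosen: LatentEstimate
    chosen_criterion: float

    def path_table(self):
        import pandas as pd
        return pd.DataFrame(
            [{"step": s, "support": "+".join(str(i + 1) for i in supp) or "-",
              "criterion": c, "accepted": acc}
             for s, (supp, c, acc) in enumerate(self.path)]
        )


def _criterion_of(est: LatentEstimate, kind: str, bic_sample: str) -> float:
    return information_criterion(est.loglik, est.n_a, est.n_times,
                                 est.n_obs_components, kind=kind,
                                 bic_sample=bic_sample)


def select_support(model: NetworkModel, data, strategy: str = "forward",
                   criterion: str = "bic", noise_kind: Optional[str] = None,
                   obs_map=None, context: Optional[FitContext] = None,
                   seed: int = 0, bic_sample: str = "total",
                   candidates=None, **fit_kwargs) -> SelectionResult:
    """Search latent-weight supports and return the criterion minimiser.

    ``best_subset`` fits every subset of the candidate components
    (including the empty one); ``forward`` grows the support greedily
    from empty, ``backward`` prunes it from full, both stopping when no
    strict criterion decrease remains. Candidate components default to
    those with a latent slot (restricted to the observed ones under
    partial observation). A failing fit scores +inf and the search
    continues.
    """
    if strategy not in ("best_subset", "forward", "backward"):
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    if context is None:
        context = prepare_context(model, data, noise_kind)
    if candidates is None:
        candidates = np.flatnonzero(model.hidden_slots)
        if obs_map is not None:
            candidates = np.intersect1d(candidates,
                                        np.asarray(obs_map.index, dtype=int))
    candidates = [int(i) for i in candidates]

    cache: dict = {}
    warm: dict = {}

    def fit(support):
        key = tuple(sorted(support))
        if key in cache:
            return cache[key]
        try:
            if obs_map is None:
                est = estimate_latent(model, context.data, key,
                                      noise_kind, context=context, seed=seed,
                                      init=warm.get("init"), **fit_kwargs)
            else:
                est = estimate_latent_partial(model, obs_map, context.data,
                                              key, noise_kind,
                                              context=context, seed=seed,
                                              **fit_kwargs)
            crit = _criterion_of(est, criterion, bic_sample)
        except Exception as exc:  # noqa: BLE001 - any single failure scored
            logger.warning("fit failed for support %s: %s", key, exc)
            est, crit = None, np.inf
        cache[key] = (est, crit)
        return est, crit

    path = []

    if strategy == "best_subset":
        best_key, best_crit = (), np.inf
        for r in range(len(candidates) + 1):
            for combo in itertools.combinations(candidates, r):
                est, crit = fit(combo)
                path.append((combo, crit, False))
                if crit < best_crit:
                    best_key, best_crit = combo, crit
        # flag the winner (and keep the path in evaluation order)
        path = [(supp, crit, supp == best_key) for supp, crit, _ in path]
        chosen, chosen_crit = cache[tuple(sorted(best_key))]

    else:
        grow = strategy == "forward"
        current = () if grow else tuple(candidates)
        est, crit = fit(current)
        path.append((current, crit, True))
        best_est, best_crit = est, crit
        if best_est is not None:
            warm["init"] = {"rates": np.array(
                [best_est.rates_hat[nm] for nm in model.rate_names]),
                "x0": best_est.x0_hat}
        while True:
            if grow:
                moves = [tuple(sorted(current + (c,)))
                         for c in candidates if c not in current]
            else:
                moves = [tuple(i for i in current if i != c)
                         for c in current]
            if not moves:
                break
            step_best = None
            for move in moves:
                est, crit = fit(move)
                path.append((move, crit, False))
                # strict '<' keeps the first (lowest-index) move on ties
                if step_best is None or crit < step_best[1]:
                    step_best = (move, crit, est)
            if step_best[1] < best_crit - IMPROVEMENT_EPS:
                current, best_crit, best_est = step_best[0], step_best[1], \
                    step_best[2]
                path = [(s, c, acc or s == current) for s, c, acc in path]
                if best_est is not None:
                    warm["init"] = {"rates": np.array(
                        [best_est.rates_hat[nm] for nm in model.rate_names]),
                        "x0": best_est.x0_hat}
            else:
                break
        chosen, chosen_crit = best_est, best_crit

    if chosen is None:
        raise ConfigurationError("every candidate fit failed")
    return SelectionResult(strategy=strategy, criterion=criterion, path=path,
                           chosen=chosen, chosen_criterion=chosen_crit)


# ---------------------------------------------------------------------------
# Misspecified-network repair
# ---------------------------------------------------------------------------

def default_edit_interpreter(est: LatentEstimate):
    """Map a latent weight pattern to a candidate structural edit.

    The latent course activates the most positively weighted component
    and drains the most negatively weighted one — the signature of a
    missing flow from the inhibited component to the activated one.
    Returns ``(source, target)`` or None when the pattern has no clear
    positive/negative pair.
    """
    a = est.a
    i_pos = int(np.argmax(a))
    i_neg = int(np.argmin(a))
    if a[i_pos] <= 0 or a[i_neg] >= 0:
        return None
    return i_neg, i_pos


@dataclass
class RepairIteration:
    model_rates: tuple
    null_criterion: float
    selection: SelectionResult
    chosen_support: tuple
    chosen_criterion: float
    a_hat: np.ndarray
    rates_hat: dict
    edit: Optional[tuple]


@dataclass
class RepairReport:
    iterations: list
    final_model: NetworkModel
    stop_reason: str

    def to_text(self) -> str:
        lines = []
        for it_no, it in enumerate(self.iterations):
            lines.append(f"iteration {it_no}: rates {list(it.model_rates)}")
            lines.append(f"  null criterion   {it.null_criterion:.4f}")
            lines.append(f"  chosen support   "
                         f"{list(i + 1 for i in it.chosen_support) or '-'} "
                         f"(criterion {it.chosen_criterion:.4f})")
            lines.append("  rates_hat        "
                         + ", ".join(f"{k}={v:.4g}"
                                     for k, v in it.rates_hat.items()))
            if it.edit is not None:
                lines.append(f"  edit: add flow x{it.edit[0] + 1} "
                             f"-> x{it.edit[1] + 1}")
        lines.append(f"stop: {self.stop_reason}")
        return "\n".join(lines)


def repair_network(model: NetworkModel, data,
                   edit_interpreter: Optional[Callable] = None,
                   criterion: str = "bic", strategy: str = "forward",
                   noise_kind: Optional[str] = None, max_edits: int = 5,
                   seed: int = 0, edit_init_rate: float = 0.1,
                   **fit_kwargs) -> RepairReport:
    """Iteratively repair a misspecified network guided by latent components.

    Each round fits the current structure (free rates, null model), runs
    support selection, and — when a latent component improves the
    criterion — translates its weight pattern into a structural edit (a
    new flow, initialised at ``edit_init_rate`` and refitted). The loop
    stops when the null model wins, the pattern is uninterpretable, or
    ``max_edits`` edits have been applied.
    """
    if edit_interpreter is None:
        edit_interpreter = default_edit_interpreter
    if not np.any(model.free_rate_mask):
        logger.warning("repair without free rates: structure edits cannot "
                       "be refitted")
    current = model
    base_ctx = prepare_context(model, data, noise_kind)
    iterations = []
    stop_reason = "edit budget exhausted"
    for _ in range(max_edits + 1):
        # splines do not depend on the structure: reuse them
        ctx = replace(base_ctx, model=current, _prop_cache={})
        sel = select_support(current, data, strategy=strategy,
                             criterion=criterion, noise_kind=noise_kind,
                             context=ctx, seed=seed, **fit_kwargs)
        null_crit = next((c for s, c, _ in sel.path if s == ()), np.inf)
        chosen = sel.chosen
        edit = None
        improves = (chosen.n_a > 0
                    and sel.chosen_criterion < null_crit - IMPROVEMENT_EPS)
        if improves:
            edit = edit_interpreter(chosen)
        iterations.append(RepairIteration(
            model_rates=current.rate_names,
            null_criterion=null_crit,
            selection=sel,
            chosen_support=chosen.support,
            chosen_criterion=sel.chosen_criterion,
            a_hat=chosen.a.copy(),
            rates_hat=dict(chosen.rates_hat),
            edit=edit,
        ))
        if not improves:
            stop_reason = "null model selected: no latent component improves " \
                          f"the {criterion.upper()}"
            break
        if edit is None:
            stop_reason = "uninterpretable pattern"
            break
        source, target = edit
        current = add_flow(current, source, target, value=edit_init_rate,
                           free=True)
    return RepairReport(iterations=iterations, final_model=current,
                        stop_reason=stop_reason)
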