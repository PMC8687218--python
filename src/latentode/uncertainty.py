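"""Fisher information diagonals and Cramér–Rao lower bounds.

Under Gaussian observation noise with a deterministic mean trajectory,
the expected Fisher information for a latent weight ``a_k`` is

    I_k = (1/sigma^2) * sum_i sum_j (d xhat_i(t_j) / d a_k)^2,

and the entry for the noise variance itself is ``N (n+1) / (2 sigma^4)``
in closed form. The trajectory sensitivities are computed by central
finite differences of the ODE solution in the *raw* weight
parameterisation (no re-normalisation during the perturbation). The
per-parameter CRLB is the reciprocal of the diagonal entry — a lower
bound on the mean squared error of any unbiased estimator.

For log-normal noise the same expressions apply on the log scale
(sensitivities of ``log xhat``); this is an extension beyond the normal
model, flagged by the ``method`` string of the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, IntegrationError
from .network import HiddenSignal, NetworkModel, solve_ode

__all__ = ["FisherDiagnostics", "fisher_diagonal"]


@dataclass
class FisherDiagnostics:
    """Diagonal expected Fisher information for (a_1..a_N, sigma^2)."""

    info_diag: np.ndarray
    crlb: np.ndarray
    method: str
    parameter_names: tuple

    def table(self):
        import pandas as pd
        return pd.DataFrame({"parameter": list(self.parameter_names),
                             "info": self.info_diag, "crlb": self.crlb})


def fisher_diagonal(model: NetworkModel, a, sigma2: float, h: HiddenSignal,
                    x0=None, times=None, delta_scale: float = 1e-4,
                    noise_kind: str = "normal") -> FisherDiagnostics:
    """Diagonal Fisher information at the weight vector ``a``.

    Sensitivities come from re-solving the ODE at ``a_k ± delta`` with
    ``delta = delta_scale * max(|a_k|, 1)``. A weight on a component
    whose equation carries no latent slot cannot move the trajectories:
    its information is exactly zero and its CRLB infinite.
    """
    if not sigma2 > 0:
        raise ConfigurationError("sigma2 must be positive")
    if noise_kind not in ("normal", "lognormal"):
        raise ConfigurationError(f"unknown noise kind {noise_kind!r}")
    a = np.asarray(a, dtype=float)
    n = model.n_components
    if a.shape != (n,):
        raise ConfigurationError("a must have length N")
    if times is None:
        times = h.times
    times = np.asarray(times, dtype=float)
    n_times = times.size

    def solve_at(weights):
        traj = solve_ode(model, times, a=weights, h=h, x0=x0)
        if noise_kind == "lognormal":
            if np.any(traj <= 0):
                raise IntegrationError("non-positive trajectory under "
                                       "lognormal noise")
            traj = np.log(traj)
        return traj

    info = np.empty(n + 1)
    for k in range(n):
        delta = delta_scale * max(abs(a[k]), 1.0)
        up, down = a.copy(), a.copy()
        up[k] += delta
        down[k] -= delta
        try:
            sens = (solve_at(up) - solve_at(down)) / (2.0 * delta)
        except IntegrationError as exc:
            raise IntegrationError(
                f"sensitivity solve failed for a_{k + 1}: {exc}"
            ) from exc
        info[k] = float(np.sum(sens ** 2)) / sigma2
    info[n] = n * n_times / (2.0 * sigma2 ** 2)

    with np.errstate(divide="ignore"):
        crlb = np.where(info > 0, 1.0 / np.where(info > 0, info, 1.0), np.inf)
    names = tuple(f"a_{i + 1}" for i in range(n)) + ("sigma2",)
    return FisherDiagnostics(
        info_diag=info,
        crlb=crlb,
        method=f"central-fd(delta_scale={delta_scale:g}, "
               f"noise={noise_kind})",
        parameter_names=names,
    )
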