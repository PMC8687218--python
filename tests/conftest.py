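import logging

import numpy as np
import pytest

from latentode import (
    TimeSeriesData,
    build_linear_network,
    default_hidden_influence,
    solve_ode,
)

logging.getLogger("latentode").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def linear3_noisefree():
    """A 3-component linear network driven by the standard latent bump,
    observed without noise; truth bundled alongside."""
    rng = np.random.default_rng(5)
    k = rng.uniform(0, 1, (3, 3))
    np.fill_diagonal(k, 0)
    x0 = np.array([1.0, 1.2, 0.8])
    times = np.linspace(0, 10, 30)
    h_true = default_hidden_influence(times)
    a_true = np.array([0.6, -0.4, 0.0])
    model = build_linear_network(k, x0)
    truth = solve_ode(model, times, a=a_true, h=h_true)
    data = TimeSeriesData(times=times, values=truth, noise_kind="normal")
    return {"model": model, "data": data, "times": times,
            "h_true": h_true, "a_true": a_true, "truth": truth,
            "k_matrix": k, "x0": x0}
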