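import numpy as np
import pytest

from rlcfit import SimulationSpec, generate_curve
from rlcfit.synthetic_data import REFERENCE_PARAMS


@pytest.fixture(scope="session")
def reference_params():
    return REFERENCE_PARAMS


@pytest.fixture
def noise_free_curve():
    """Factory: exact (noise-free) curve generated from a reference model."""

    def make(model, **kwargs):
        spec = SimulationSpec(model=model, params=REFERENCE_PARAMS[model],
                              noise_sd_rel=0.0, **kwargs)
        return generate_curve(spec)

    return make


def random_valid_params(model: str, rng: np.random.Generator):
    """One random peaked parameter set for ``model`` (used by oracle tests)."""
    from rlcfit import light_models as lm

    if model == "eilers_peeters":
        a = 10 ** rng.uniform(-6, -4)
        c = rng.uniform(0.5, 5.0)
        b = rng.uniform(0.1, 3.0) * np.sqrt(a * c)
        return lm.EilersPeetersParams(a=a, b=b, c=c)
    if model == "platt":
        ps = rng.uniform(10.0, 200.0)
        alpha = rng.uniform(0.1, 0.9)
        return lm.PlattParams(ps=ps, alpha=alpha,
                              beta=alpha * rng.uniform(0.01, 0.3))
    if model == "walsby":
        etr_max = rng.uniform(10.0, 200.0)
        alpha = rng.uniform(0.1, 0.9)
        return lm.WalsbyParams(etr_max=etr_max, alpha=alpha,
                               beta=-alpha * rng.uniform(0.01, 0.5))
    if model == "vollenweider":
        pmax = rng.uniform(10.0, 200.0)
        a = 10 ** rng.uniform(-3, -1.5)
        return lm.VollenweiderParams(pmax=pmax, a=a,
                                     alpha=a * rng.uniform(0.1, 2.0),
                                     n=rng.uniform(0.5, 3.0))
    raise ValueError(model)


def grid_search_max(model: str, params, n_grid: int = 10**6):
    """Independent dense-grid oracle for the curve maximum.

    Brackets the peak by doubling the range until the coarse maximum is
    interior, then scans ``n_grid`` points; stays independent of the
    closed-form/derive code path it checks.
    """
    from rlcfit import light_models as lm

    U = 100.0
    for _ in range(30):
        coarse = np.linspace(0.0, U, 2048)
        vals = np.asarray(lm.predict(model, params, coarse))
        if int(np.argmax(vals)) < len(coarse) - 1:
            break
        U *= 2.0
    grid = np.linspace(0.0, U, n_grid)
    vals = np.asarray(lm.predict(model, params, grid))
    k = int(np.argmax(vals))
    return float(grid[k]), float(vals[k])
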