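"""Shared fixtures.

The heavy scenario runs (200 replicates each) are built lazily and cached
for the whole session so that the monotonicity checks and the printed-value
gates reuse the same trajectories instead of re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from straysim import MetapopulationParams, default_params, run_metapopulation, run_scenario
from straysim.experiments import scenario_params
from straysim.params import replace

REPLICATES = 200

# scenario name -> (kind, constructor args, seed)
_SCENARIOS = {
    # single streams: (phos, hatchery mean, total generations)
    "control": ((0.0, None, 25), 301),
    "phos30_lag5": ((0.3, 15.0, 25), 302),
    "phos30_lag10": ((0.3, 20.0, 25), 303),
    "phos30_lag15": ((0.3, 25.0, 25), 304),
    "phos10_lag10_full": ((0.1, 20.0, 50), 305),
    "phos01_lag15": ((0.01, 25.0, 25), 306),
    "phos20_lag15": ((0.2, 25.0, 25), 307),
    # metapopulations: (phos,)
    "meta_phos0": ((0.0,), 308),
    "meta_phos30": ((0.3,), 309),
}


def _build(name: str):
    args, seed = _SCENARIOS[name]
    if name.startswith("meta"):
        (phos,) = args
        mp = MetapopulationParams.default(phos=phos)
        mp = MetapopulationParams(
            tuple(replace(p, n_generations_total=25) for p in mp.deme_params)
        )
        return run_metapopulation(mp, REPLICATES, base_seed=seed)
    phos, mu_h, gens = args
    params = scenario_params(phos, mu_h, n_generations=gens)
    return run_scenario(params, REPLICATES, base_seed=seed)


@pytest.fixture(scope="session")
def runs():
    """Lazy cache of the 200-replicate scenario results used by the
    statistical tests."""
    cache: dict = {}

    def get(name: str):
        if name not in cache:
            cache[name] = _build(name)
        return cache[name]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return default_params()
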