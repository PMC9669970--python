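"""Shared fixtures.

Expensive simulations are session-scoped so that acceptance checks that
examine different aspects of the same experiment reuse one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from locint.continuous import (
    GAP_EPOCHS,
    ContinuousConfig,
    StimulusSpec,
    run_continuous_experiment,
)
from locint.discrete import (
    DiscreteConfig,
    StimulusProtocol,
    activated_populations,
    gap_holding_population,
    population_rate_table,
    resumption_population,
    run_discrete_experiment,
)


@pytest.fixture(scope="session")
def discrete_gap_outcomes():
    """(n_activated, holder, resumption, rate table) for 10 seeds of the
    two-epoch discrete-integrator protocol."""
    cfg = DiscreteConfig()
    proto = StimulusProtocol()
    out = []
    for seed in range(1, 11):
        _, rates = run_discrete_experiment(cfg, proto, 1100.0, seed)
        out.append(
            (
                len(activated_populations(rates)),
                gap_holding_population(rates),
                resumption_population(rates),
                rates,
            )
        )
    return out


@pytest.fixture(scope="session")
def continuous_gap_raster():
    """One ring-integrator run with the two-epoch (gap) protocol."""
    stim = StimulusSpec(alpha=8.0, epochs=GAP_EPOCHS)
    return run_continuous_experiment(ContinuousConfig(), stim, 1000.0, seed=2)


@pytest.fixture(scope="session")
def integrator_rasters_600():
    """Ring-integrator runs (constant stimulus, 600 ms) for seeds 1-3,
    shared by the readout ramping/stepping checks."""
    out = {}
    for seed in (1, 2, 3):
        stim = StimulusSpec(alpha=8.0, epochs=((100.0, 600.0),))
        out[seed] = run_continuous_experiment(ContinuousConfig(), stim, 600.0, seed)
    return out
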