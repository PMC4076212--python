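import numpy as np
import pytest

from geoadd.geoadditive import MCMCConfig, gibbs_sampler, parameter_recovery
from geoadd.preprocess import build_analysis_set
from geoadd.synthetic import SimulationConfig, make_lattice_graph, simulate_survey


@pytest.fixture(scope="session")
def lattice6():
    return make_lattice_graph(6)


@pytest.fixture(scope="session")
def recovery_run(lattice6):
    """One full-model fit on a simulated 6x6-lattice survey with known truth.

    n = 10,000 individuals, structured spatial variance 0.5; a single chain of
    2,500 iterations (500 burn-in, thin 4). Shared across tests that check
    recovery, chain health and posterior summaries.
    """
    config = SimulationConfig(n_individuals=10_000, graph=lattice6,
                              tau2_spat=0.5, seed=42)
    records, truth = simulate_survey(config)
    analysis = build_analysis_set(records)
    mcmc = MCMCConfig(iterations=2500, burn_in=500, thinning=4, seed=7)
    draws = gibbs_sampler(analysis, graph=lattice6, config=mcmc)
    report = parameter_recovery(records, truth, lattice6, draws=draws)
    return {"records": records, "truth": truth, "graph": lattice6,
            "analysis": analysis, "draws": draws, "report": report}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
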