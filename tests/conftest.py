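import pytest

from trasplice import (
    SimulationParams,
    make_design,
    simulate_atlas,
    simulate_counts,
    simulate_gene_models,
)


def small_params(**overrides) -> SimulationParams:
    """Desk-scale simulation: quick but with every effect class populated."""
    defaults = dict(
        n_genes=150,
        n_tissues=12,
        frac_tra=0.4,
        depth_range=(500.0, 1500.0),
        n_replicates=3,
        seed=7,
    )
    defaults.update(overrides)
    p = SimulationParams(**defaults)
    p.validate()
    return p


@pytest.fixture(scope="session")
def params():
    return small_params()


@pytest.fixture(scope="session")
def det_params():
    return small_params(nb_dispersion=None)


@pytest.fixture(scope="session")
def simulated(params):
    """(atlas, truth, models, design, counts) under stochastic noise."""
    atlas, truth = simulate_atlas(params)
    models = simulate_gene_models(params)
    design = make_design(params)
    counts, _ = simulate_counts(params, models, design)
    return atlas, truth, models, design, counts


@pytest.fixture(scope="session")
def det_simulated(det_params):
    """Deterministic-mode counterpart: counts equal rounded expectations."""
    atlas, truth = simulate_atlas(det_params)
    models = simulate_gene_models(det_params)
    design = make_design(det_params)
    counts, _ = simulate_counts(det_params, models, design)
    return atlas, truth, models, design, counts
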