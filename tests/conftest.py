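import numpy as np
import pytest

from quam import FieldSpec, ScenarioConfig, generate_population, render_fields


@pytest.fixture(scope="session")
def clean_scenario() -> ScenarioConfig:
    """Small all-singlet scenario with no distractors, for exact round trips."""
    return ScenarioConfig(n_cells=40, cluster_fraction=0.0, border_fraction=0.0,
                          glia_density=0.0, debris_density=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_population(clean_scenario):
    return generate_population(clean_scenario)


@pytest.fixture(scope="session")
def noise_free_spec() -> FieldSpec:
    """Noise-free, unquantized, low-gain camera: no clipping at any exposure."""
    return FieldSpec(background_noise_sd=0.0, quantize=False, gain=200.0)


@pytest.fixture(scope="session")
def noise_free_field(clean_population, noise_free_spec):
    fields = render_fields(clean_population, noise_free_spec, 0.96, seed=12)
    assert len(fields) == 1
    return fields[0]


@pytest.fixture(scope="session")
def standard_fixture_fields():
    """The standard synthetic fixture set: realistic camera, clusters, border
    cells, glia and debris distractors; >= 500 eligible singlet neurons."""
    scenario = ScenarioConfig(n_cells=650, seed=21)
    pop = generate_population(scenario)
    pop.attrs["glia_density"] = scenario.glia_density
    pop.attrs["debris_density"] = scenario.debris_density
    return render_fields(pop, FieldSpec(), 0.96, seed=22)


def match_accepted_to_truth(accepted, truth, max_dist_px=15.0):
    """Pair accepted objects with ground-truth cells by centroid distance."""
    from scipy.spatial import cKDTree

    if not accepted:
        return np.zeros(len(truth), dtype=bool), np.zeros(0, dtype=bool)
    cents = np.array([o.centroid for o in accepted])
    truth_xy = np.c_[truth["center_y"], truth["center_x"]]
    tree = cKDTree(cents)
    d, _ = tree.query(truth_xy)
    truth_found = d < max_dist_px
    ttree = cKDTree(truth_xy)
    d2, _ = ttree.query(cents)
    accepted_is_cell = d2 < max_dist_px
    return truth_found, accepted_is_cell
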