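import numpy as np
import pytest

from imitrsa.synth import generate_design
from imitrsa.synth.cohort import simulate_trial_betas
from imitrsa.synth.patterns import GroundTruth, generate_patterns

GRID_SMALL = (6, 6, 6)


@pytest.fixture(scope="session")
def small_designs():
    """One Chinese and one Spanish run on a 6x6x6 grid."""
    d_cn = generate_design("s01", "chinese", seed=11, grid_shape=GRID_SMALL)
    d_es = generate_design("s01", "spanish", seed=12, grid_shape=GRID_SMALL)
    return d_cn, d_es


@pytest.fixture(scope="session")
def small_beta_sets(small_designs):
    """Simulated trial betas for both languages (perception) with a planted
    cross-language correlation in a central region."""
    d_cn, d_es = small_designs
    region = np.zeros(GRID_SMALL, dtype=bool)
    region[1:4, 1:4, 1:4] = True
    gt = GroundTruth(
        group="control_adults",
        region_masks={"region": region},
        rho_cross_language={"region": 0.6},
        rho_repetition={"region": 0.7},
        seed=21,
    )
    betas = simulate_trial_betas(gt, d_cn, d_es, beta_noise_sd=0.5, rng=np.random.default_rng(21))
    return betas, region


@pytest.fixture(scope="session")
def null_beta_sets(small_designs):
    """Trial betas with no structure anywhere (pure noise patterns)."""
    d_cn, d_es = small_designs
    gt = GroundTruth(
        group="children", region_masks={}, rho_cross_language={}, rho_repetition={}, seed=33
    )
    return simulate_trial_betas(gt, d_cn, d_es, beta_noise_sd=0.5, rng=np.random.default_rng(33))
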