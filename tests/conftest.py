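import numpy as np
import pytest

from fibrilbind.lattice import LatticeModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_model(rng, three_state_prob=0.5, weight_range=(0.01, 10.0),
                 factor_range=(0.05, 20.0)) -> LatticeModel:
    """Random 2- or 3-state lattice model for property tests."""
    if rng.random() < three_state_prob:
        return LatticeModel.three_state(
            conc_ratio_l=rng.uniform(*weight_range),
            conc_ratio_i=rng.uniform(*weight_range),
            alpha_l=rng.uniform(*factor_range),
            alpha_i=rng.uniform(*factor_range),
            chi=rng.uniform(*factor_range),
        )
    return LatticeModel.two_state(
        conc_ratio=rng.uniform(*weight_range),
        alpha_l=rng.uniform(*factor_range),
    )
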