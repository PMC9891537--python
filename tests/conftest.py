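import numpy as np
import pytest

from notchdimer import ExternalSignal, ModelParameters


@pytest.fixture
def baseline_t1() -> ModelParameters:
    """Baseline monomer-trans / dimer-cis parameter set."""
    return ModelParameters.t1()


@pytest.fixture
def no_contact() -> ExternalSignal:
    return ExternalSignal()


@pytest.fixture
def trans_bath() -> ExternalSignal:
    """Fixed bath of 1500 trans ligand monomers."""
    return ExternalSignal(L_ext=1500.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230120)


def random_params(rng: np.random.Generator, **fixed) -> ModelParameters:
    """Log-uniform draw within ±10x of the baseline rates."""
    def draw(base):
        return base * 10.0 ** rng.uniform(-1, 1)

    kw = dict(
        b_L=draw(200.0), b_N=draw(200.0), k_d=draw(1e-4),
        beta=draw(0.1), beta_S=draw(0.5), k_r=draw(0.1),
    )
    kw.update(fixed)
    return ModelParameters(**kw)
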