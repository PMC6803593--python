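import pytest

from kdqolmap import toy_3l, toy_5l
from kdqolmap.synthetic import (SyntheticConfig, default_true_aldvmm,
                                default_true_suropm, gen_dataset)

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def vs3():
    return toy_3l()


@pytest.fixture(scope="session")
def vs5():
    return toy_5l()


@pytest.fixture(scope="session")
def aldvmm_dataset(vs3):
    """n=400 3L dataset from the adjusted-normal-mixture DGP with truth."""
    cfg = SyntheticConfig(n=400, seed=42, outcome_dgp="aldvmm_dgp")
    df, sidecar = gen_dataset(cfg, vs3)
    return df, sidecar


@pytest.fixture(scope="session")
def response_dataset(vs3):
    """n=400 3L dataset from the joint ordered-probit DGP with truth."""
    cfg = SyntheticConfig(n=400, seed=43, outcome_dgp="response_dgp")
    df, sidecar = gen_dataset(cfg, vs3)
    return df, sidecar


@pytest.fixture(scope="session")
def true_aldvmm(vs3):
    return default_true_aldvmm(vs3)


@pytest.fixture(scope="session")
def true_suropm():
    return default_true_suropm(3)
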