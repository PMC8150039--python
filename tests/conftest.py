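import numpy as np
import pytest

from speccurve import cleaning as cl
from speccurve import simulate as sim
from speccurve.curve import SpecificationCurve, build_default_space


@pytest.fixture(scope="session")
def survey424():
    """Clean-conditions sample of 424 respondents with known truth."""
    cfg = sim.GeneratorConfig(n_respondents=424, dropout_rate=0.0,
                              careless_rate=0.0, outlier_rate=0.05, seed=11)
    return sim.generate_dataset(cfg)


@pytest.fixture(scope="session")
def scored424(survey424):
    df, _ = survey424
    cleaned, _ = cl.clean_dataset(df)
    return cl.score_dataset(cleaned)


@pytest.fixture(scope="session")
def curve_results(scored424):
    space = build_default_space(scored424)
    return SpecificationCurve(scored424, space,
                              covariate_detail=True).fit()


@pytest.fixture(scope="session")
def factor_items():
    """Continuous one-factor item data: n=424, 5 items, loadings 0.7."""
    rng = np.random.default_rng(5)
    n, k, lam = 424, 5, 0.7
    F = rng.standard_normal(n)
    return lam * F[:, None] + np.sqrt(1 - lam ** 2) \
        * rng.standard_normal((n, k))
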