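import numpy as np
import pytest

import axondist as ad


@pytest.fixture(scope="session")
def lognormal_sample() -> ad.DiameterSample:
    """n=1000 log-normal diameters at the micrometre scale of real data."""
    vals = ad.get_family("log_normal").sample([-0.7, 0.5], 1000, seed=42)
    return ad.DiameterSample(vals, region="sim", specimen="lognormal")


@pytest.fixture(scope="session")
def small_gev_pooled() -> ad.DiameterSample:
    """Pooled corpus-callosum-like dataset scaled down for fast ranking tests."""
    cfg = ad.SyntheticConfig(
        generating_family="generalized_extreme_value",
        params=(0.45, 0.15, 0.2),
        n_per_region={"genu": 1500, "body": 1000, "splenium": 1400},
        seed=11,
        truncation=(0.03, 3.09),
    )
    return ad.pooled(ad.generate_dataset(cfg))


@pytest.fixture(scope="session")
def small_ranked(small_gev_pooled) -> ad.SelectionTable:
    return ad.fit_and_rank(
        small_gev_pooled, options=ad.FitOptions(n_restarts=2, seed=3)
    )
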