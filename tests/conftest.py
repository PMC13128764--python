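import dataclasses

import numpy as np
import pytest

import cortclust as cc


@pytest.fixture(scope="session")
def remission_cohort():
    """Default three-cluster remission cohort (n=77, fixed counts 23/15/39)."""
    return cc.generate_cohort(cc.default_remission_config(seed=0))


@pytest.fixture(scope="session")
def remission_matrix(remission_cohort):
    return remission_cohort.to_matrix()


@pytest.fixture(scope="session")
def fitted_kpod(remission_matrix):
    return cc.KPOD(n_clusters=3, random_state=0).fit(remission_matrix)


@pytest.fixture()
def clean_config():
    """Generator config with every missingness mechanism switched off."""
    return cc.default_remission_config(
        seed=0, censor_hazard=0.0, sporadic_missing_rate=0.0)


def exact_moment_sample(rng, mean, sd, n):
    """A sample with exactly the requested mean and sample SD (ddof=1)."""
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x
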