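import warnings

import numpy as np
import pytest

import abdev
from abdev.simulate import PlatformSim, SimConfig
from abdev.training import CvSettings


@pytest.fixture(scope="session")
def sim_records():
    """50 anchor-valid synthetic Fv records shared across tests."""
    return abdev.generate_fv(seed=11, n=50)


@pytest.fixture(scope="session")
def small_suite():
    """A 3-platform suite (HIC, SMAC, HEK) trained on 60 simulated Fvs.

    Reduced CV (1 repeat x 5 folds) keeps this fast; the suite exercises
    both transforms, both directions, and the worst-10% threshold rule.
    """
    dataset = abdev.simulate_dataset(n=60, seed=5,
                                     platforms=["HIC", "SMAC", "HEK"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        suite = abdev.train_all(dataset, cv=CvSettings(folds=5, repeats=1,
                                                       seed=7))
    return dataset, suite


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def hic_like_config(n: int, seed: int, signal_fraction: float = 0.6
                    ) -> SimConfig:
    """Single-platform generative config mirroring the HIC story:

    positive aromatic effect, negative absolute-charge effect, Gumbel
    noise, 10% of values at the 25-min censoring ceiling."""
    return SimConfig(n=n, seed=seed, platforms={
        "HIC": PlatformSim({"aro": 1.0, "absQ": -0.7}, "gumbel",
                           signal_fraction, loc=10.0, scale=1.8,
                           censor_fraction=0.1),
    })
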