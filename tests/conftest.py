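import logging

import numpy as np
import pytest

from spovsim import load_config

logging.getLogger("spovsim").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240923)


@pytest.fixture
def small_config():
    """A reduced cohort for fast engine-level tests."""
    return load_config(
        {
            "environment": "rich",
            "strategy_pair": ["EARLY-SPOV", "MFCL"],
            "n_females": 80,
            "n_males": 80,
            "different": 0.7,
            "max_generations": 50,
        }
    )


@pytest.fixture
def neutral_config():
    """Both phenotypes parameterized identically: pure drift dynamics.

    The spillover slot is given the MFCL life history and the MFCL attack
    rule, the environment's spillover-mortality multiplier is set to 1, and
    juvenile survival is equal, so the allele is selectively neutral.
    """
    mfcl_like = {
        "name": "SPOV",
        "fem_mat_mean": 56.0,
        "fem_mat_sd": 0.5,
        "cw_intercept": 3.21,
        "cw_mat_slope": 0.024,
        "cw_cl_slope": 0.39,
        "cw_sd": 0.4679,
        "intake_multiplier": 1.0,
        "mortality_rate": 0.0030,
        "vol_intercept": -2297.64,
        "vol_cw_slope": 217.88,
        "vol_cond_slope": 123.44,
        "vol_sd": 129.59,
        "bcd": True,
        "attack_family": "mfcl",
    }
    return load_config(
        {
            "environment": {"richness": "rich", "mort_multiplier": 1.0},
            "spillover_strategy": mfcl_like,
            "mfcl_strategy": "MFCL",
            "different": 1.0,
            "initial_state": 0.5,
        }
    )
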