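import numpy as np
import pandas as pd
import pytest

from anthrorisk import GeneratorConfig, calibrate, generate_cohort


def simulate_single_index(eta_fn, seed, n=20000, lam0=0.0035, k=0.085,
                          aref=50.0, horizon=20.0):
    """Independent single-covariate survival simulator used as the oracle
    for hazard-curve recovery: Gompertz baseline on the age timescale,
    true log hazard ``eta_fn(z)``, administrative censoring."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(18, 85, n)
    z = rng.standard_normal(n)
    eta = eta_fn(z)
    u = rng.uniform(size=n)
    cum = lam0 / k * np.exp(k * (age - aref)) - np.log(u) / np.exp(eta)
    death_age = aref + np.log(k * cum / lam0) / k
    fu = np.minimum(death_age - age, horizon)
    return pd.DataFrame(
        dict(z=z, age=age, exit_age=age + fu,
             died=((death_age - age) < horizon).astype(int))
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort under the default study conditions."""
    return generate_cohort(calibrate(GeneratorConfig(n=4000, seed=42)))


@pytest.fixture(scope="session")
def calibrated_default_config():
    return calibrate(GeneratorConfig(n=4000, seed=42))
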