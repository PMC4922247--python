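import numpy as np
import pandas as pd
import pytest

from scopetrack.synthetic import SimConfig, TruePhenotype, generate_cohort


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A scaled-down study: few fish, short track, fast traces."""
    return SimConfig(n_fish=4, seed=11, n_days_track=2)


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    return generate_cohort(small_sim_config)


@pytest.fixture
def example_phenotype() -> TruePhenotype:
    return TruePhenotype(
        fish_id="FX",
        body_mass=54.2,
        fork_length=16.4,
        body_depth=16.4 / 5.9,
        true_smr=79.0,
        true_mmr=392.8,
        recovery_halflife=0.7,
        activity_propensity=0.05,
        mean_active_speed=0.15,
    )


def make_lmm_dataset(
    rng,
    n_fish: int = 16,
    n_obs: int = 12,
    beta_fl: float = 8.0,
    sigma_a: float = 100.0,
    sigma_j_values=(50.0, 200.0),
    null_covariate: bool = True,
) -> pd.DataFrame:
    """Draw one dataset from the heteroscedastic random-intercept model."""
    fl = rng.normal(16.4, 1.4, n_fish)
    x = rng.normal(0.0, 1.0, n_fish)
    sj = rng.choice(np.asarray(sigma_j_values, dtype=float), n_fish)
    a = rng.normal(0.0, sigma_a, n_fish)
    rows = []
    for j in range(n_fish):
        y = -900.0 + beta_fl * fl[j] + a[j] + rng.normal(0.0, sj[j], n_obs)
        for v in y:
            rows.append(
                {
                    "fish_id": f"F{j:02d}",
                    "fl": fl[j],
                    "x": x[j],
                    "y": v,
                    "sigma_j_true": sj[j],
                }
            )
    return pd.DataFrame(rows)
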