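import numpy as np
import pandas as pd
import pytest

from resilipig.simulate import SimConfig, simulate_cohort


def make_daily(records):
    """records: list of (animal_id, age, fi, dur)."""
    return pd.DataFrame(records, columns=["animal_id", "age", "fi", "dur"])


@pytest.fixture(scope="session")
def small_cohort():
    """Four batches, enough animals for structural checks, fast."""
    cfg = SimConfig(n_batches=4, pigs_per_batch=60, n_sires=24, dams_per_sire=2, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def quiet_cohort():
    """No illness, no noise, no recording artefacts: exact baselines."""
    cfg = SimConfig(
        n_batches=1,
        pigs_per_batch=12,
        n_sires=4,
        dams_per_sire=2,
        episode_rate=0.0,
        fi_noise_sd=0.0,
        dur_noise_sd=0.0,
        weight_noise_sd=0.0,
        spike_rate=0.0,
        missing_rate=0.0,
        seed=5,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def paper_scale_run(tmp_path_factory):
    """One full pipeline run (simulate -> clean -> traits -> genetics) on a
    default-scale cohort; shared across end-to-end tests."""
    from resilipig.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("e2e")
    cfg = RunConfig(outdir=str(out), sim=SimConfig(seed=2), seed=2)
    run_pipeline(cfg)
    return out
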