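import numpy as np
import pytest

from mscmir import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down study design: 4 donors x P3/P5/P7 x 3 reps, 60 sequences."""
    return sd.SimulationConfig(
        n_donors=4,
        n_sequences=60,
        n_mirnas=25,
        n_duplicate_pairs=5,
        n_negative_controls=50,
        n_rrna_trna=2,
        expressed_fraction=0.5,
        passage_effects={
            "seq0020": {"P5": 0.3, "P7": 0.5},
            "seq0021": {"P7": -0.5},
        },
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return sd.simulate_experiment(small_cfg)


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Degenerate generator: no noise anywhere, no effects."""
    cfg = sd.SimulationConfig(
        n_donors=3, n_sequences=20, n_mirnas=10, n_duplicate_pairs=2,
        n_negative_controls=20, n_rrna_trna=0, expressed_fraction=0.5,
        sigma_probe=0.0, sigma_array=0.0, sigma_donor=0.0, sigma_seq_array=0.0,
        negctl_sd=0.0,
        seed=3,
    )
    return cfg, sd.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def qpcr_cfg():
    return sd.study_qpcr_config(seed=11)


@pytest.fixture(scope="session")
def qpcr_sim(qpcr_cfg):
    return sd.simulate_qpcr(qpcr_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
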