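import numpy as np
import pytest

from neobp.pipeline import PipelineConfig, run_end_to_end
from neobp.simulate import (HfovConfig, MotionConfig, NoiseConfig, PatientMeta,
                            SimulationConfig, simulate_patient)

FS = 125.0


def clean_noise(**overrides) -> NoiseConfig:
    """Noise model with every disturbance switched off."""
    base = dict(baseline_drift_amp=0.0, respiratory_amp=0.0, hf_noise_sd=0.0,
                hfov=HfovConfig(enabled=False),
                motion_bursts=MotionConfig(rate_per_min=0.0),
                ial_respiratory_amp_mmhg=0.0, ial_noise_sd_mmhg=0.0)
    base.update(overrides)
    return NoiseConfig(**base)


@pytest.fixture(scope="session")
def meta():
    return PatientMeta(patient_id="P0", age_days=10, weight_kg=2.5,
                       ga_weeks=34.0, sex="male")


@pytest.fixture(scope="session")
def clean_patient(meta):
    """Noiseless recording, zero lag, identity-equivalent transform."""
    cfg = SimulationConfig(duration_s=60.0, seed=3, lag_samples=0,
                           noise=clean_noise())
    return simulate_patient(meta, cfg)


@pytest.fixture(scope="session")
def noisy_patient(meta):
    """Default-noise recording with a known 37-sample inter-stream lag."""
    cfg = SimulationConfig(duration_s=120.0, seed=42, lag_samples=37)
    return simulate_patient(meta, cfg)


@pytest.fixture(scope="session")
def full_run():
    """The headline synthetic-cohort experiment: 24 patients, 10-minute
    recordings, default noise, individual-grouped 10-fold CV."""
    cfg = PipelineConfig(n_patients=24, sim_seed=42, fold_seed=7, train_seed=7,
                         log_level="WARNING")
    return run_end_to_end(cfg)


@pytest.fixture(scope="session")
def noiseless_run():
    """Parameter-recovery experiment: noise off, so the only errors are
    the model's own."""
    sim = SimulationConfig(duration_s=240.0, noise=clean_noise())
    cfg = PipelineConfig(n_patients=10, simulation=sim, cv_folds=5,
                         sim_seed=42, fold_seed=7, train_seed=7,
                         log_level="WARNING")
    return run_end_to_end(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
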