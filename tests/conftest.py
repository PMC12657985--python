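import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import airedna as a

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_config() -> a.SimulationConfig:
    """The default study conditions: 6 weekly events, 4 samplers,
    replicate design with duplicated gelatin/PTFE filters."""
    return a.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(study_config):
    return a.simulate_dataset(study_config)


@pytest.fixture(scope="session")
def fitted(dataset):
    """One scaled-down fit (4 chains x 500+500) of the study-condition
    simulation, shared by diagnostics/PPC/derived tests."""
    return a.fit(dataset, mcmc=a.McmcConfig.reduced(seed=23))


def water_only_config(**kw) -> a.SimulationConfig:
    """Small count+water-only study (no air samplers): cheap fits."""
    kw.setdefault("samplers", ())
    kw.setdefault("eta", np.array([]))
    kw.setdefault("tau", np.array([]))
    kw.setdefault("rho", np.array([]))
    kw.setdefault("calib", a.QpcrCalibration(beta1=np.array([-1.4427])))
    return a.SimulationConfig(**kw)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def true_param_table(cfg: a.SimulationConfig) -> dict[str, float]:
    """Ground-truth values keyed like FitResult summary rows."""
    truth = {"omega_log": cfg.omega_log}
    for j, s in enumerate(cfg.samplers):
        truth[f"eta[{s}]"] = float(cfg.eta[j])
        truth[f"tau[{s}]"] = float(cfg.tau[j])
    for r, s in enumerate(cfg.replicated):
        truth[f"rho[{s}]"] = float(cfg.rho[r])
    return truth

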