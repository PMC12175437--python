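import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def time_grid():
    return np.arange(0.0, 60.0, 0.5)


@pytest.fixture()
def aif_params():
    from hfpefcmr import AIFParams

    return AIFParams(onset_time=8.0, amplitude=50.0, shape_alpha=3.0,
                     scale_beta=2.0, baseline=10.0)


@pytest.fixture()
def noiseless_study(aif_params):
    """Dual-bolus study with known rest/stress flows and no noise."""
    from hfpefcmr import TissueGenParams, synth_perfusion_study

    return synth_perfusion_study(
        rest=TissueGenParams(true_mbf=1.0, fermi_mu=4.0, fermi_k=1.2),
        stress=TissueGenParams(true_mbf=2.27, fermi_mu=4.0, fermi_k=1.2),
        aif=aif_params,
        scaling_factor=10.0,
        seed=42,
    )
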