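import numpy as np
import pytest
from hypothesis import settings, HealthCheck

# reproducible hypothesis runs, no local example database
settings.register_profile(
    "ci", derandomize=True, max_examples=50, database=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_strike():
    """A noise-free default strike scenario with its ground truth."""
    import strikelab as sl

    scn = sl.StrikeScenario()
    return scn, sl.strike_ground_truth(scn)


@pytest.fixture
def model_design():
    """A small, noise-free physical-model design (1 trial per cell x 2 samples)."""
    import strikelab as sl

    design = []
    for ty, f_mean, v_mean in (("atrH", 22.38, 0.075), ("atrS", 18.63, 0.205)):
        for s in (1, 2):
            for fr in ("H", "L"):
                design.append(sl.ModelTrialScenario(
                    atr_type=ty, friction=fr, sample_id=f"{ty}{s}", repeat=0,
                    true_release_force=f_mean, post_release_peak_speed=v_mean,
                    spring_saturation_force=30.0, seed=7))
    return design
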