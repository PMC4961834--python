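import numpy as np
import pytest

from melrhythm import SamplingProfile, SecretionParams, evaluate_model

THREE_HOURLY = np.arange(0.0, 24.0, 3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20160713)


def make_profile(params: SecretionParams, times=THREE_HOURLY, noise_cv=0.0,
                 rng=None, subject_id="S001") -> SamplingProfile:
    """Sample a (optionally noisy) profile from the secretion model."""
    times = np.asarray(times, dtype=float)
    clean = np.asarray(evaluate_model(params, times))
    if noise_cv > 0:
        clean = np.maximum(clean * (1.0 + rng.normal(0, noise_cv, size=len(times))), 0.0)
    return SamplingProfile(subject_id=subject_id, times=times, concentrations=clean)


def circular_distance(a: float, b: float, period: float = 24.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def random_valid_params(rng, n=1):
    """Uniform draws over the physiological parameter box."""
    out = [
        SecretionParams(
            b1=rng.uniform(0.0, 20.0),
            b2=rng.uniform(40.0, 250.0),
            b3=rng.uniform(0.0, 24.0),
            b4=rng.uniform(4.0, 10.0),
        )
        for _ in range(n)
    ]
    return out[0] if n == 1 else out
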