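import warnings

import numpy as np
import pytest

import paravox as pv

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def clean_vowel():
    """Noiseless jitter/shimmer-free 1.5 s /a/ at 120 Hz, 44.1 kHz."""
    w, truth = pv.synth_vowel(
        pv.SynthesisSpec(f0_hz=120.0, duration_s=1.5, seed=0)
    )
    return w, truth


@pytest.fixture(scope="session")
def trimmed_clean_vowel(clean_vowel):
    w, _ = clean_vowel
    return pv.trim_to_voiced_second(w)


@pytest.fixture(scope="session")
def sine_100hz():
    t = np.arange(44100) / 44100.0
    return pv.Waveform(np.sin(2 * np.pi * 100.0 * t), 44100, "sine100")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def informative_cohort():
    """60-subject cohort, 33 features, 5 informative at effect size 1.5."""
    return pv.synth_cohort(
        pv.CohortSpec(
            n_per_class=30,
            n_features=33,
            informative=(0, 5, 10, 20, 30),
            effect_sizes=(1.5,) * 5,
            seed=42,
        )
    )
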