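import numpy as np
import pytest

import fetalhr as f


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic recording (all artifact classes enabled)."""
    return f.simulate_recording(f.SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def sim_clean():
    """Artifact-free recording: no resets, modulation, bursts or mains."""
    cfg = f.SimulationConfig(
        seed=11,
        n_resets_per_channel=0,
        modulation_depth=0.0,
        motion_burst_rate=0.0,
        powerline_rel=0.0,
    )
    return f.simulate_recording(cfg)


@pytest.fixture(scope="session")
def separated_clean(sim_clean):
    """Preprocessed + separated + maternal-cancelled clean recording."""
    rec, truth = sim_clean
    pre, _ = f.preprocess_recording(rec)
    cm = f.fast_ica(f.make_bipolar(pre.x).Y, seed=11)
    mqrs, _ = f.detect_mqrs(cm, rec.fs)
    em = f.cancel_mecg(cm, mqrs, rec.fs)
    return rec, truth, cm, mqrs, em


def spike_train(times_s, n_samples, fs, width_s=0.01, amplitudes=None):
    """Biphasic Gaussian spikes at given times (helper for detector tests)."""
    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)
    amplitudes = amplitudes if amplitudes is not None else np.ones(len(times_s))
    for tc, a in zip(times_s, amplitudes):
        x += a * np.exp(-((t - tc) ** 2) / (2 * width_s**2))
        x -= 0.5 * a * np.exp(-((t - tc - 2.5 * width_s) ** 2) / (2 * width_s**2))
    return x
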