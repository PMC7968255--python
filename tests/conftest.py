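import numpy as np
import pytest

from cochleamod import preproc, synth


def make_epochs(cfg: synth.GeneratorConfig, condition: str, n_trials: int,
                rng: np.random.Generator, highpass: bool = True) -> preproc.EpochSet:
    """Epochs straight from the trial generator (no session assembly)."""
    data = np.stack([synth.simulate_ear_trial(cfg, condition, rng)
                     for _ in range(n_trials)])
    if highpass:
        data = preproc.highpass_oae(data, cfg.sampling_rate)
    return preproc.EpochSet(
        subject_id="test", ear="left", condition=condition, data=data,
        sampling_rate=cfg.sampling_rate, trial_index=np.arange(n_trials),
        trial_conditions=np.asarray([condition] * n_trials, dtype=object))


def envelope_psd_oracle(trials: np.ndarray, fs: float, average: bool = True):
    """Independent envelope-spectrum oracle: full-band Hilbert magnitude,
    demeaned, plain rFFT periodogram, averaged across trials."""
    from scipy.signal import hilbert

    env = np.abs(hilbert(trials, axis=-1))
    env = env - env.mean(axis=-1, keepdims=True)
    spec = np.abs(np.fft.rfft(env, axis=-1)) ** 2 / env.shape[-1]
    freqs = np.fft.rfftfreq(trials.shape[-1], 1.0 / fs)
    if average:
        spec = spec.mean(axis=0)
    return freqs, spec


@pytest.fixture(scope="session")
def quiet_cfg():
    """No per-subject peak jitter, no artifacts: deterministic f_m."""
    return synth.GeneratorConfig(subject_peak_jitter_sd=0.0, artifact_rate=0.0)
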