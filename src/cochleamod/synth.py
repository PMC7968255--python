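"""Seeded synthetic cohorts for the ear-canal modulation pipeline.

The generator is phenomenological: it emulates the statistical structure of
ongoing otoacoustic activity (OOA) recorded in a sealed ear canal during
silent cue-target intervals, together with behavioral trial tables and a
source-space power grid carrying a planted condition effect and a planted
across-subject brain-cochlea correlation.  No biophysical cochlear model is
attempted.

Each ear-canal trial is a broadband noise carrier (bandpassed to the cochlear
response band, 1000-2000 Hz by default) multiplied by a slow envelope

    e(t) = max(eps, 1 + d_c sin(2 pi f_m t + phi) + a(t))

where ``d_c`` is the condition-specific modulation depth, ``phi`` is drawn
uniformly per trial (``random`` phase mode) or held fixed (``locked``), and
``a(t)`` is 1/f^chi shaped low-frequency noise band-limited below 30 Hz.
White measurement noise is added after the multiplication.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

ENVELOPE_FLOOR = 0.05
APERIODIC_CUTOFF_HZ = 30.0
ACCURACY_P = 0.93
SATURATION_RUN_MS = 50.0


@dataclass(frozen=True)
class RTParams:
    """Lognormal reaction-time model (milliseconds).

    ``mu``/``sigma`` parameterize the lognormal on the log scale; ``shift_ms``
    is added to auditory-condition draws (attention to the upcoming tone slows
    the cued pitch judgment in the emulated task).
    """

    mu: float = 6.14
    sigma: float = 0.35
    shift_ms: float = 59.2


@dataclass(frozen=True)
class GeneratorConfig:
    sampling_rate: float = 10_000.0
    epoch_duration: float = 3.0
    n_trials_per_condition: int = 40
    carrier_band: tuple[float, float] = (1000.0, 2000.0)
    mod_freq: float = 6.0
    depth_auditory: float = 0.25
    depth_visual: float = 0.15
    phase_mode: str = "random"  # or "locked"
    locked_phase: float = np.pi / 2
    carrier_mode: str = "constant_modulus"  # or "noise"
    envelope_aperiodic_exponent: float = 0.8
    aperiodic_sd: float = 0.4
    noise_sd: float = 0.05
    artifact_rate: float = 0.05
    full_scale: float = 5.0
    n_subjects: int = 12
    subject_peak_jitter_sd: float = 0.5
    grid_shape: tuple[int, int, int] = (8, 8, 8)
    planted_brain_effect: float = 0.5
    planted_correlation: float = -0.8
    rt_params: RTParams = field(default_factory=RTParams)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.depth_auditory < 1 and 0 <= self.depth_visual < 1):
            raise ValueError("modulation depths must lie in [0, 1)")
        if self.sampling_rate <= 2 * self.carrier_band[1]:
            raise ValueError("sampling_rate must exceed twice the carrier band upper edge")
        if self.carrier_band[0] >= self.carrier_band[1]:
            raise ValueError("carrier_band must be (low, high) with low < high")
        if abs(self.planted_correlation) >= 1:
            raise ValueError("planted_correlation must lie in (-1, 1)")
        if self.phase_mode not in ("random", "locked"):
            raise ValueError("phase_mode must be 'random' or 'locked'")
        if self.epoch_duration <= 0 or self.n_trials_per_condition < 1:
            raise ValueError("epoch_duration and n_trials_per_condition must be positive")
        if not (0 <= self.artifact_rate <= 1):
            raise ValueError("artifact_rate must be a probability")

    @property
    def n_epoch_samples(self) -> int:
        return int(round(self.epoch_duration * self.sampling_rate))


@dataclass
class SyntheticSubject:
    subject_id: str
    recordings: dict  # ear -> 1-D waveform (arbitrary units)
    trial_table: pd.DataFrame
    sampling_rate: float
    mod_freq: float  # subject-level true modulation frequency (ground truth)


@dataclass
class BrainPowerGrid:
    """subjects x voxels x frequencies x conditions source power.

    ``power`` is strictly positive (arbitrary units); condition axis is
    ordered (auditory, visual).  Ground-truth planted voxel blocks are kept
    for recovery checks; they are metadata, not used by any analysis stage.
    """

    power: np.ndarray  # (n_subjects, n_voxels, n_freqs, 2)
    freqs: np.ndarray  # Hz, 1 Hz steps
    voxel_positions: np.ndarray  # (n_voxels, 3) lattice coords, 1 cm spacing
    grid_shape: tuple[int, int, int]
    conditions: tuple[str, str] = ("auditory", "visual")
    posterior_block: np.ndarray | None = None  # planted condition-effect voxels
    temporal_block: np.ndarray | None = None  # planted correlation voxels


def _shaped_lowfreq_noise(n: int, fs: float, exponent: float, sd: float,
                          rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent amplitude-shaped noise, band-limited below 30 Hz."""
    if sd == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    band = (f > 0) & (f <= APERIODIC_CUTOFF_HZ)
    amp[band] = f[band] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * amp, n)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def _bandpassed_carrier(n: int, fs: float, band: tuple[float, float],
                        rng: np.random.Generator,
                        mode: str = "constant_modulus") -> np.ndarray:
    """Broadband noise-like carrier, regenerated per trial.

    ``noise``: white noise bandpassed with a 4th-order zero-phase Butterworth
    (Gaussian; its Hilbert envelope shows Rayleigh fading).  The default
    ``constant_modulus`` additionally normalizes the analytic signal to unit
    modulus, keeping the noise-like phase structure of the band while making
    the carrier's own envelope exactly flat, so the imposed envelope e(t) is
    the only full-band amplitude modulation.
    """
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    if mode == "noise":
        s = x.std()
        return x / s if s > 0 else x
    if mode != "constant_modulus":
        raise ValueError(f"unknown carrier_mode {mode!r}")
    z = signal.hilbert(x)
    mag = np.abs(z)
    mag[mag == 0] = 1.0
    return np.real(z / mag)


def simulate_ear_trial(config: GeneratorConfig, condition: str,
                       rng: np.random.Generator,
                       return_envelope: bool = False):
    """One 3-s ear-canal epoch: AM noise carrier plus measurement noise.

    With ``return_envelope`` the generative envelope e(t) is returned
    alongside the waveform (ground truth for recovery checks).
    """
    config.validate()
    if condition not in ("auditory", "visual"):
        raise ValueError(f"unknown condition {condition!r}")
    n = config.n_epoch_samples
    fs = config.sampling_rate
    depth = config.depth_auditory if condition == "auditory" else config.depth_visual

    carrier = _bandpassed_carrier(n, fs, config.carrier_band, rng,
                                  config.carrier_mode)
    t = np.arange(n) / fs
    if config.phase_mode == "locked":
        phi = config.locked_phase
        rng.uniform(0, 2 * np.pi)  # burn a draw so both modes consume the stream alike
    else:
        phi = rng.uniform(0, 2 * np.pi)
    a = _shaped_lowfreq_noise(n, fs, config.envelope_aperiodic_exponent,
                              config.aperiodic_sd, rng)
    envelope = np.maximum(ENVELOPE_FLOOR,
                          1.0 + depth * np.sin(2 * np.pi * config.mod_freq * t + phi) + a)
    wave = carrier * envelope + config.noise_sd * rng.standard_normal(n)
    if return_envelope:
        return wave, envelope
    return wave


def inject_saturation(waveform: np.ndarray, run_length_ms: float,
                      full_scale: float, sampling_rate: float = 10_000.0,
                      start: int | None = None) -> np.ndarray:
    """Clip a contiguous run to exactly +/- full_scale; rest untouched.

    ``start`` is the first sample of the run (defaults to centered); a zero
    run length returns the input unchanged.
    """
    n_run = int(round(run_length_ms * sampling_rate / 1000.0))
    if n_run == 0:
        return waveform
    if n_run < 0 or n_run > waveform.size:
        raise ValueError("saturation run must fit inside the epoch")
    if start is None:
        start = (waveform.size - n_run) // 2
    if start < 0 or start + n_run > waveform.size:
        raise ValueError("saturation run must fit inside the epoch")
    out = waveform.copy()
    seg = out[start:start + n_run]
    out[start:start + n_run] = np.where(seg >= 0, full_scale, -full_scale)
    return out


def _trial_schedule(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_per = config.n_trials_per_condition
    conditions = np.array(["auditory"] * n_per + ["visual"] * n_per)
    rng.shuffle(conditions)

    rt_p = config.rt_params
    rts = np.exp(rng.normal(rt_p.mu, rt_p.sigma, size=2 * n_per))
    rts = rts + np.where(conditions == "auditory", rt_p.shift_ms, 0.0)
    accuracy = (rng.random(2 * n_per) < ACCURACY_P).astype(int)
    artifact = rng.random(2 * n_per) < config.artifact_rate

    # cue 1 s, cue-target interval 2 s, target 0.1 s, 0.5 s to response
    # screen, the reaction time itself, then 1-2 s uniform inter-trial jitter
    cue_onsets = np.empty(2 * n_per)
    t = 0.5
    for i in range(2 * n_per):
        cue_onsets[i] = t
        t += 1.0 + 2.0 + 0.1 + 0.5 + rts[i] / 1000.0 + rng.uniform(1.0, 2.0)
    return pd.DataFrame({
        "trial": np.arange(2 * n_per),
        "condition": conditions,
        "cue_onset": cue_onsets,
        "interval_onset": cue_onsets + 1.0,
        "reaction_time_ms": rts,
        "accuracy": accuracy,
        "artifact_flag": artifact.astype(int),
    })


def simulate_subject(config: GeneratorConfig, subject_id: str,
                     rng: np.random.Generator) -> SyntheticSubject:
    """Two-ear session: continuous recordings plus the behavioral table."""
    config.validate()
    fm = config.mod_freq + config.subject_peak_jitter_sd * rng.standard_normal()
    fm = float(np.clip(fm, 1.0, 12.0))
    subject_cfg = replace(config, mod_freq=fm)

    table = _trial_schedule(config, rng)
    fs = config.sampling_rate
    n_epoch = config.n_epoch_samples
    total = int(round((table["interval_onset"].iloc[-1] + config.epoch_duration + 1.0) * fs))

    recordings = {}
    for ear in ("left", "right"):
        rec = config.noise_sd * rng.standard_normal(total)
        for _, row in table.iterrows():
            seg = simulate_ear_trial(subject_cfg, row["condition"], rng)
            if row["artifact_flag"]:
                pos = int(rng.integers(0, n_epoch - int(SATURATION_RUN_MS * fs / 1000.0)))
                seg = inject_saturation(seg, SATURATION_RUN_MS, config.full_scale,
                                        fs, start=pos)
            i0 = int(round(row["interval_onset"] * fs))
            rec[i0:i0 + n_epoch] = seg
        recordings[ear] = rec
    return SyntheticSubject(subject_id=subject_id, recordings=recordings,
                            trial_table=table, sampling_rate=fs, mod_freq=fm)


def subject_rngs(config: GeneratorConfig) -> list[np.random.Generator]:
    """Independent per-subject streams, fully determined by config.seed."""
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(s) for s in ss.spawn(config.n_subjects)]


def iter_cohort(config: GeneratorConfig):
    """Yield subjects one at a time (sessions are memory-heavy)."""
    for i, rng in enumerate(subject_rngs(config)):
        yield simulate_subject(config, f"S{i + 1:02d}", rng)


def simulate_cohort(config: GeneratorConfig) -> list[SyntheticSubject]:
    return list(iter_cohort(config))


def _corner_block(grid_shape, corner: str, extent: int) -> np.ndarray:
    """Flat voxel indices of a cubic block in one lattice corner."""
    nx, ny, nz = grid_shape
    idx = np.arange(nx * ny * nz).reshape(grid_shape)
    if corner == "posterior":
        return idx[:extent, :extent, :extent].ravel()
    if corner == "temporal":
        return idx[-extent:, -extent:, -extent:].ravel()
    raise ValueError(corner)


def simulate_brain_power(config: GeneratorConfig, per_subject_ooa_ami: np.ndarray,
                         rng: np.random.Generator,
                         freqs: np.ndarray | None = None) -> BrainPowerGrid:
    """Source-space power with a planted condition effect and a planted
    across-subject correlation between one voxel block's AMI and the cochlear
    AMI vector.

    The "posterior" block receives a multiplicative auditory > visual effect
    at 8-25 Hz.  The "temporal" block's condition effect is scaled per subject
    as ``g_i = rho * z_i + sqrt(1 - rho^2) * eps_i`` with ``z_i`` the
    standardized cochlear AMI, so the across-subject correlation between the
    block's AMI and the cochlear AMI approaches the configured rho (negative
    rho plants the brain-cochlea anticorrelation).
    """
    config.validate()
    ooa = np.asarray(per_subject_ooa_ami, dtype=float)
    if ooa.size != config.n_subjects:
        raise ValueError("per_subject_ooa_ami length must equal n_subjects")
    if freqs is None:
        freqs = np.arange(1.0, 31.0)
    n_s = config.n_subjects
    n_v = int(np.prod(config.grid_shape))
    n_f = freqs.size

    base_profile = 1.0 / freqs  # 1/f cortical background
    log_noise = 0.3 * rng.standard_normal((n_s, n_v, n_f, 2))
    power = base_profile[None, None, :, None] * np.exp(log_noise)

    extent = max(1, min(config.grid_shape) // 3)
    posterior = _corner_block(config.grid_shape, "posterior", extent)
    temporal = _corner_block(config.grid_shape, "temporal", extent)

    cond_band = (freqs >= 8) & (freqs <= 25)
    power[np.ix_(np.arange(n_s), posterior, np.where(cond_band)[0], [0])] *= \
        (1.0 + config.planted_brain_effect)

    rho = config.planted_correlation
    sd = ooa.std()
    z = (ooa - ooa.mean()) / sd if sd > 0 else np.zeros(n_s)
    g = rho * z + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_s)
    g = np.clip(g, -3.0, 3.0)
    # per-unit condition gain in the correlated block: +-30% per SD of g
    # expresses the association at single-cell level (cell-wise r ~ 0.8 rho
    # against the lognormal power noise), not only in the block average
    amp = 0.3
    corr_band = (freqs >= 3) & (freqs <= 25)
    fsel = np.where(corr_band)[0]
    gain = 1.0 + amp * g  # per subject
    power[np.ix_(np.arange(n_s), temporal, fsel, [0])] *= \
        gain[:, None, None, None]
    power[np.ix_(np.arange(n_s), temporal, fsel, [1])] *= \
        (2.0 - gain)[:, None, None, None]

    pos = np.stack(np.unravel_index(np.arange(n_v), config.grid_shape), axis=1).astype(float)
    return BrainPowerGrid(power=power, freqs=freqs, voxel_positions=pos,
                          grid_shape=config.grid_shape,
                          posterior_block=posterior, temporal_block=temporal)
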