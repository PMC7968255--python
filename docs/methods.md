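# Methods

`cochleamod` analyzes slow amplitude modulations of ongoing otoacoustic
activity (OOA) — the sound a sealed-ear-canal microphone picks up from the
cochlea during silent periods — and relates their attentional modulation to
cortical oscillatory power. Because raw two-ear microphone recordings from a
real cohort are large and not required to exercise the analysis, the package
ships a first-class synthetic-data generator whose outputs carry the
statistical structure the analysis assumes. This note documents the
generative model, the signal path, the statistical machinery, the numerical
choices, and what the synthetic results do and do not show about real data.

## Generative model

Each trial of the emulated task is a cue (1 s), a silent cue-target interval
(2 s), an audiovisual target, and a response period; inter-trial intervals
are jittered uniformly between 1 and 2 s. A session holds 40 trials per
attention condition (auditory/visual) per the emulated design, sampled at
10 kHz on two ear channels.

The ear-canal signal during an epoch is

    x(t) = c(t) * e(t) + sigma_n * w(t)
    e(t) = max(eps, 1 + d_c sin(2 pi f_m t + phi) + a(t))

* `c(t)` — broadband carrier restricted to the cochlear response band
  (1000–2000 Hz). The default carrier is the analytic-normalized
  ("constant-modulus") version of bandpassed white noise: the band's
  noise-like phase structure is kept but the carrier's own Hilbert envelope
  is exactly flat. A plain Gaussian noise carrier (`carrier_mode="noise"`)
  is also available, but its Rayleigh-fading envelope spreads fluctuation
  power (variance ≈ 0.43 of the squared mean) across the carrier bandwidth,
  which buries the 1/f envelope component above a few hertz and makes the
  generative aperiodic exponent unrecoverable from the envelope spectrum at
  any realistic amplitude; the constant-modulus default removes that floor
  at the full-band level while narrow sub-bands retain realistic fading.
  Carriers are regenerated per trial so no evoked structure arises from the
  carrier itself.
* `d_c` — condition-dependent modulation depth (defaults: 0.25 attend-
  auditory, 0.15 attend-visual), encoding the attentional enhancement of the
  cochlear rhythm.
* `f_m` — modulation frequency, default 6 Hz (the theta rhythm the analysis
  targets), jittered across subjects with SD 0.5 Hz. The jitter keeps
  cohort-level recovery tests sharp; real cohorts show larger interindividual
  spread (SD 1.5–2.3 Hz), so cohort-level peak-frequency variance here is
  optimistic.
* `phi` — per-trial uniform phase by default (an induced, non-phase-locked
  rhythm); `phase_mode="locked"` fixes it, producing an evoked rhythm.
* `a(t)` — aperiodic envelope fluctuation: white noise spectrally shaped to
  amplitude ∝ f^(−chi/2) below 30 Hz and zero above, scaled to SD 0.4
  (chosen so the aperiodic component dominates residual measurement/envelope
  floors across 1–30 Hz while clipping at the envelope floor stays rare).
* `eps = 0.05` — hard envelope floor; keeps the modulation well defined at
  high depths without rejecting configurations.
* `sigma_n` — white measurement noise, default 0.05 relative to the
  unit-power carrier.

Saturation artifacts (the main reason real trials are discarded) are
injected on a configurable fraction of trials (default 5%) as 50 ms runs
clipped exactly at the recording rail (full scale 5.0). Only this artifact
class is modeled; movement/swallowing noise is not, so automated rejection
here is easier than manual rejection on real data.

Reaction times are lognormal (mu 6.14, sigma 0.35 on the log scale, i.e.
mean ≈ 493 ms, SD ≈ 178 ms) with a +59.2 ms shift in the auditory
condition, matching the emulated study's behavioral summary; accuracy is
Bernoulli at 93% (a ceiling, which is why group analyses use RT only).

### Source-power grid

`simulate_brain_power` builds a subjects × voxels × frequencies × conditions
array on a cubic lattice (default 8×8×8 voxels at 1 cm): lognormal power
(log-SD 0.3) on a 1/f profile, with
* a "posterior" corner block receiving a multiplicative auditory > visual
  effect (default +50%) at 8–25 Hz — the classical posterior alpha/beta
  attention effect; and
* a "temporal" corner block whose condition effect is scaled per subject by
  `g_i = rho * z_i + sqrt(1 − rho²) * eps_i`, `z_i` the standardized
  cochlear AMI, so the across-subject correlation between the block's AMI
  and the cochlear AMI approaches the configured `rho` (default −0.8,
  emulating the observed cortico-cochlear anticorrelation). The per-unit
  condition gain is ±30% per SD of `g`, which expresses the association at
  single-cell level (cell-wise r ≈ 0.8·rho against the power noise), not
  only in the block average; planted blocks are recorded as metadata for
  recovery tests only.

## Signal path

1. **High-pass** 500 Hz, 6th-order Butterworth, applied forward–backward
   (zero phase) — removes low-frequency microphone/physiological drift while
   keeping the 1000–2000 Hz band untouched.
2. **Epoching**: 3 s epochs locked to the cue-target-interval onset;
   out-of-bounds onsets are dropped per trial with reason codes.
3. **Saturation rejection**: trials containing ≥ 2 ms of samples at
   ≥ 99.9% of full scale are rejected (full scale inferred from the data
   when not supplied — clipped runs sit exactly at the rail).
4. **Bandpass bank**: 201 windows centered 1000…2000 Hz (5 Hz spacing),
   each center ± 30 Hz. The explicit window count fixes the 5 Hz step; a
   101-window/10 Hz variant is config-exposed. Filtering and the analytic
   signal are computed jointly in the frequency domain: multiplying the
   epoch FFT by the squared magnitude response of a 4th-order Butterworth
   bandpass equals zero-phase filtering, and zeroing negative frequencies
   yields the analytic signal in the same pass. Envelopes (Hilbert
   magnitudes) are computed on the full 3 s epoch — the analysis window is
   cut afterwards so filter edge effects stay outside it — then resampled
   to 500 Hz (their information content for this analysis lies below
   30 Hz).
5. **Modulation spectra** over the window 0.25–1.95 s (1.7 s of the
   cue-target interval): per band, envelopes are demeaned (otherwise the DC
   envelope level leaks into the 1 Hz bins), Hann-tapered, and Fourier
   transformed with zero padding to a 0.25 Hz grid (native resolution
   1/1.7 s ≈ 0.59 Hz); one-sided power is kept on 1–30 Hz.
   *Induced* spectra transform each trial and average the power — they keep
   non-phase-locked rhythms. *Evoked* spectra average the envelope across
   trials first — only phase-locked components survive the averaging (a
   non-locked component attenuates as 1/n in power); complex coefficients
   are retained so the evoked phase is defined.

## Spectral parameterization

Band-averaged spectra are decomposed in log10-power space as

    log10 P(f) = b − chi·log10 f + Σ_k A_k exp(−(f − CF_k)² / (2 s_k²))

Fixed (no-knee) aperiodic mode, since a single slope per spectrum is
reported. The aperiodic line is fit robustly (three passes, positive
residuals down-weighted by exp(−r/s)) so peaks do not drag the baseline;
peaks are extracted iteratively from the flattened spectrum (largest
residual above max(2 SD, 0.05), Gaussian guess from the half-height width),
jointly refit by bounded least squares, and the aperiodic component is refit
on the peak-removed spectrum. Bounds: CF inside the fit range, sigma in
[0.25, 6] Hz (prevents spike/plateau degeneracies). Peaks whose centers lie
within 2 sigma of a larger peak are pruned — on an oversampled grid a narrow
spectral line otherwise gets tiled by several minimum-width Gaussians.

The *primary* low-frequency peak is the largest-amplitude peak below 11 Hz
(the lowest-CF alternative is a one-line change); subjects without one are
flagged, not dropped.

**Peak significance** uses Dixon's Q (classic gap/range r10 ratio, embedded
two-sided 95% critical values for n = 3…30): the peak bin's
aperiodic-flattened log-power is tested as an outlier against non-peak bins.
Two choices matter here: (a) the comparison runs on flattened power, so the
1/f trend does not dominate the comparison; (b) the comparison sample
excludes only the tested peak's 1.5 × BW neighborhood — excluding *all*
fitted-peak neighborhoods strips the largest background excursions and
inflates Q (measured false-positive rate 21% vs 3% on pure-aperiodic
spectra). The sample is thinned to ≤ 29 evenly spaced bins (~1 Hz apart) so
Dixon's applicability range holds on the oversampled grid. Per-spectrum
successes are aggregated with an exact two-sided binomial test against 0.5.

## Group statistics

* **AMI** = (auditory − visual)/(auditory + visual) × 100 per
  band × modulation-frequency cell; bounded in [−100, 100]; 0/0 cells are
  NaN and excluded from pooling. Pooling is the mean of cell-wise AMI
  (averaging the index, not the power) over 1000–2000 Hz and the per-ear
  peak-frequency ranges (left 3–10 Hz, right 1–10 Hz); the power-first
  alternative is provided (`pool_ami_power_first`).
* **t tests**: one-sample/paired, with the one-tailed direction fixed as
  auditory > visual for AMI tests; zero-variance inputs return an error
  status rather than a p-value.
* **FDR**: Benjamini–Hochberg at q = 0.05 (statsmodels), applied within the
  same test families as the emulated analysis.
* **Uniformity**: one-sample KS against Uniform(support); the support
  defaults to the 1–11 Hz peak-search range (config-exposed). Both the
  classical D ∈ [0,1] and the sqrt(n)-scaled value are reported, because R
  uniformity packages print the scaled convention.
* **Circular common-median test**: the circle is split by the diameter
  *perpendicular* to the pooled circular median (near half vs far half);
  per-group side counts form a 1-df chi-square. Splitting by the diameter
  through the median (the CircStat convention) has zero power against
  antipodal shifts and would make the test useless for phase comparisons;
  the chosen split detects both small and antipodal median differences and
  is calibrated under the null (measured ≥ 90% retention at kappa = 2).
  When all pooled mass falls on one side the split carries no evidence and
  the statistic is 0; vanishing resultant length is a degenerate status.
* **Repeated-measures ANOVA**: main effects only for fully crossed
  two-level within-subject designs (2×2×2 on peak frequency and slope,
  2×2 on AMI), each factor tested against its factor × subject interaction,
  F(1, n−1) — identical to the squared paired t on collapsed means.
  Sums of squares below 1e−12 of the total are treated as zero so
  identical-cell inputs give F = 0 and deterministic shifts give an explicit
  zero-error-variance status.
* **Median splits**: per subject and condition separately (avoiding
  between-subject and intermodal RT confounds); ties at the median go to
  "fast" (config-exposed).

## Cluster-based permutation inference

Cell statistics: paired t (condition contrast) or Pearson r converted to
t = r·sqrt((n−2)/(1−r²)) (brain–cochlea correlation), on voxels ×
frequencies restricted to 3–25 Hz. Cells beyond the two-sided parametric
threshold at p < 0.05 (config-exposed) form clusters under a spatio-spectral
neighborhood: 26-connected lattice neighbors at the same frequency plus the
same voxel at adjacent 1 Hz bins; no diagonal space–frequency edges. The
cluster mass (sum of t, sign-consistent) is referred to the permutation
distribution of the maximal |mass|: per-subject sign flips of condition
differences, or permutation of the cochlear vector (preserving the brain
maps' spatial covariance). p_mc = (1 + #{null ≥ observed})/(1 + n_perm),
never exactly zero. Sign flips leave each cell's mean square unchanged, so
permutation t maps are computed for all flips at once from a single matrix
product. Measured family-wise type-I error over 500 null replicates
(6×6×6 grid, n = 10, 500 permutations): 0.056.

## Problem sizes and runtime choices

Default configuration: 12 subjects, 40 trials/condition, 3 s epochs at
10 kHz, 201 bands, 500 permutations. The test suite and the acceptance
script run the same pipeline at reduced band counts (3–21 windows — band
count is an analysis resolution choice, not a study condition; AMI pooling
and peak recovery are insensitive to it) and, for replicate-based
calibration checks, at the smallest cohort sizes the corresponding
properties specify. Aperiodic-exponent estimation uses the single wideband
(1000–2000 Hz) envelope rather than the narrow-band bank: a ±30 Hz band's
intrinsic fading concentrates its modulation floor below ~60 Hz, swamping
the 1/f envelope component, whereas the full-band envelope spreads the same
floor over the full carrier bandwidth.

## What the synthetic results do not show

The generator is phenomenological: no transmission-line/outer-hair-cell
cochlear mechanics, no MEG forward model, no sensor noise or head movement,
no manual artifact classes beyond saturation, and absolute levels are
arbitrary units (real OOA levels in dB SPL are not modeled). Passing tests
demonstrate that the *analysis* recovers planted structure under realistic
noise — not that real cochleae behave this way. Real-data peak-frequency
spread, rejection rates, and evoked-phase structure will differ; in
particular the default random-phase generator produces genuinely weak
evoked spectra, so evoked-peak statistics on synthetic defaults mainly
exercise the machinery.
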