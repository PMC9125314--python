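# Methods

This note documents the models, estimators, numerical choices and known
limitations of `eegcomplex`. Units are microvolts (μV) for signals, Hz for
frequencies, and nats for entropy.

## Preprocessing

The default chain mirrors a standard resting-state pipeline: resample to
500 Hz (polyphase, anti-aliased) → zero-phase two-pass Hamming-window FIR
bandpass 0.5–45 Hz → optional channel subset → segmentation into 2-s epochs
→ absolute-amplitude artifact rejection at 100 μV → common average
reference.

- **Filter design.** The lower transition bandwidth is
  `min(max(lo/2, 2 Hz), lo)`, which keeps the stopband edge at or above
  `lo/2`; with the Hamming window this gives > 20 dB two-pass attenuation at
  `lo/2` even for the 0.5 Hz edge. Two-pass filtering is implemented as FFT
  convolution with odd-reflection padding and matches
  `scipy.signal.filtfilt` to machine precision; zero phase matters because
  downstream PAC estimates depend on preserved phase relations. Filter
  length is capped at a third of the signal, widening the transition on very
  short inputs.
- **Artifact rejection** is automated thresholding on the peak absolute
  value per epoch (a manual-inspection step is not reproducible); the
  threshold is configurable, 100 μV by default.
- **Sensor neighborhoods** come from layout-plane distance (default radius
  1.3 × median nearest-neighbor distance) or Delaunay triangulation. The
  layout plane is unitless; simulated montages live on the unit disc in
  concentric rings.

## Multiscale sample entropy

`SampEn(m, r)` is −ln(A/B), with B the number of template pairs of length
m = 2 within Chebyshev tolerance r and A the same pairs extended to m + 1;
self-matches are excluded (Richman–Moorman). The tolerance is
r = 0.15 × sample SD (ddof = 1) of the **original** series and is *not*
re-estimated on coarse-grained copies — the convention of the physionet
`mse` tool. Coarse-graining takes means over non-overlapping windows of
length τ (scale 1 is the raw series); scales 1–20 and a 60-s analysis
window are the defaults. When no templates match, the value is NaN
(flagged undefined) and excluded from downstream statistics, never zeroed.
The production kernel is a numba double loop with early abort; the test
suite holds it to exact (A, B) equality with a vectorized brute-force
oracle. Because r tracks the SD, SampEn is exactly invariant to affine
amplitude changes.

Maps over channels use either the first qualifying window (`mode="first"`,
optionally requiring all samples under the artifact threshold) or the mean
curve across all complete windows (`mode="mean"`).

## Spectral power

The Morlet transform is implemented as analytic Gaussian filtering in the
frequency domain: at center f the transfer is
`2·exp(−(ν−f)²/(2σ_f²))` for ν ≥ 0 with σ_f = f/ω and ω = 6. The gain of 2
at the center makes a sinusoid of amplitude a map to power a². The analytic
coefficient is evaluated on a demodulated, decimated grid (the truncated
band fits into a short inverse FFT), which changes nothing about the time
average but makes the 90-frequency grid affordable. Time points within one
e-folding time σ_t = ω/(2πf) of the epoch edges (capped at a quarter epoch)
are excluded from the time average to bound circular-convolution bias.
Frequencies with fewer than 3 cycles per epoch (below 1.5 Hz on 2-s epochs)
are computed but flagged unreliable and never enter band summaries.

The multitaper alternative uses DPSS tapers with time-half-bandwidth
NW = bandwidth × T/2 (default 2 Hz full bandwidth on 2-s epochs → 3
tapers). Both estimators accept `density=True`, reporting μV²/Hz (Morlet:
divide by the noise-equivalent bandwidth 2√π·σ_f; multitaper: 2|X|²/fs).
Density is the unit in which the two methods are directly comparable —
with amplitude normalization the Morlet response to broadband noise scales
as f·S(f) while the multitaper estimates S(f), so cross-method agreement
should always be assessed on densities (the test suite requires channel-wise
Pearson ≥ 0.9 on simulated cohorts).

## Phase–amplitude coupling

For a phase band Φ and the gamma amplitude band, the signal is zero-phase
bandpass filtered in each band (transition 25% of band width, at least
1 Hz), the Hilbert transform provides phase φ(t) and envelope A(t), and

    MI = | ⟨ A(t) · e^{iφ(t)} ⟩ |

is computed per 2-s epoch and averaged. Filtering and Hilbert transforms
run on the *continuous* recording (a 1–4 Hz FIR needs far more than 2 s of
data); epoched input is supported with widened transitions. Normalizations:

- `raw` (default): the mean-vector MI itself. It scales linearly with the
  amplitude of the high-frequency signal.
- `mean_amp`: MI divided by the time-mean envelope. This removes the
  amplitude scale — and with it per-subject gain differences, which
  otherwise multiply the MI noise floor into between-subject variance. Group
  contrasts in the acceptance tests use this mode.
- `surrogate_z`: z-score against circularly time-shifted envelopes
  (shifts ≥ 1 s; ≥ 100 surrogates), for single-recording inference.

**Sideband caveat.** Amplitude modulation of a carrier at f_c by a phase
frequency f_p puts sidebands at f_c ± f_p. With α_high (10–13 Hz) phase and
a 30–45 Hz amplitude band, much of the sideband energy falls outside the
amplitude filter, so the estimator sees an attenuated (~4× smaller)
modulation depth. This is inherent to the band definitions, not to the
implementation; injected coupling depths therefore map monotonically but
sublinearly onto measured MI, and validation of the signal generator uses a
wider amplitude band (24–51 Hz) where the full modulation is visible.

## Cluster-based permutation inference

Per pixel (channel × scale/frequency/band-pair), group contrasts use the
classical pooled-variance two-sample t and score associations the Spearman
rho, t-transformed via t = ρ√((n−2)/(1−ρ²)) so cluster masses are
commensurable. Pixels with two-tailed P < 0.05 are clustered under the
combined adjacency: spatial sensor neighbors within a feature, plus
consecutive scales or frequency bins within a channel; PAC band pairs are
clustered spatially only, one map per pair. The cluster statistic is the
mass (sum of t); pixel count is available by option. The null is the
per-permutation maximum cluster statistic per sign (group labels shuffled,
or scores shuffled for correlation designs), Monte-Carlo
p = (b + 1)/(n_perm + 1), doubled within tail and capped at 1 (FieldTrip's
two-tailed convention). When fewer distinct label splits than `n_perm`
exist, the test switches to complete enumeration (with a warning) and
reports exact p values. Permutation t maps are computed by matrix algebra
over all permutations at once; a small relative tolerance (1e-8) in the
null ≥ observed comparison keeps the identity permutation counted as a tie.
Type-I calibration on Gaussian null maps (the acceptance suite) lands the
family-wise rate near and slightly below the nominal 0.05, as expected for
the doubled within-tail convention.

## Behavioral statistics

- Chi-square: Pearson statistic on the 2×2 table, df = 1, **no** Yates
  correction (the continuity-corrected value would not reproduce the
  published gender P of 0.5550).
- Group differences of continuous variables: two-sided permutation test on
  the difference of means, complete enumeration for small samples.
- Subscale structure: per-group Pearson matrices with t-transform P values;
  constant columns yield flagged-undefined (NaN) entries.
- Comparison of two correlations: Fisher z = atanh(r), normal approximation
  with variance 1/(n−3) per group, one-tailed P = Φ̄(|z₁−z₂|/SE). This
  normal form (despite sometimes being labeled a t-test) reproduces the
  published subscale-comparison P values (0.0363, 0.0795, 0.0162) to four
  decimals. Published correlation magnitudes are used where the printed
  signs contradict the accompanying text; |z₁−z₂| is unaffected.
- RRS subscale percentages are computed as subscale-sum / total-sum × 100 —
  an assumption, since the denominator of published subscale percentages is
  not defined anywhere.

## Synthetic cohorts

Per channel, a recording is 1/f^slope background noise (spectrally shaped
white noise, slope 1.0, 10 μV RMS) plus band-limited Gaussian oscillations
(defaults: alpha 10 ± 2 Hz at 6 μV on all channels; gamma 30–45 Hz at
3 μV). Defaults mirror the study design being emulated: 24 patients vs 22
controls, 91 channels, 500 Hz, 6-min recordings.

- **Group effects**: a multiplicative gamma-power factor (default 1.5,
  patient group) applied to components whose center lies in the gamma band,
  and an additive coupling-depth delta (default −0.2) — each restricted to
  named channel subsets. Per-subject lognormal amplitude jitter (σ = 0.15)
  and small coupling jitter (σ = 0.05) provide between-subject variability.
- **Coupling** replaces the plain gamma component on PAC channels with
  `carrier·(1 + k·cos φ)/√(1 + k²/2)` where φ is the Hilbert phase of a
  narrowband low-frequency carrier that also appears in the signal (so the
  phase is physically present); the √ factor keeps gamma power independent
  of k. An oscillation spec overlapping a channel's PAC phase band is
  suppressed on that channel — an independent oscillation in the same band
  would dilute the measured phase and silently destroy the injected
  coupling.
- **Scores**: latent trivariate Gaussians with the configured per-group
  correlation matrix (defaults: published per-group magnitudes), optionally
  mixed with standardized EEG-feature latents (e.g. reflective-rumination ↔
  gamma gain, ρ = 0.6 in the patient group), then mapped through the normal
  CDF onto Likert sums (12–48, 5–20, 5–20). Correlations are honored before
  discretization; feature couplings slightly perturb the inter-subscale
  structure.

What the generator does **not** emulate: volume conduction and spatially
correlated sources, eye/muscle artifacts (beyond optional amplitude
spikes), non-stationarity, alpha reactivity, or realistic head geometry.
A green recovery test therefore establishes that the estimators and the
cluster inference recover effects of the injected kind at the injected
size — not that they would behave identically on real scalp EEG.

## Scaled-down validation worlds

The recovery and robustness checks run on desk-scale cohorts chosen before
the tests were frozen: 30-channel, 60-s, 15+15-subject cohorts for cluster
recovery (gamma ×1.5 on ten channels; full α_high–γ decoupling on ten
disjoint channels; 1000 permutations), and 6-channel 10+10 cohorts for the
half-length robustness check, with MSE summarized over scales 1–2 from
three 8-s windows (halved to 4-s windows, mirroring the halving of the
60-s entropy epoch) and a 180-s recording for the PAC arm, where MI
estimation noise at 30 s of data would dominate. The PAC contrast for the
robustness check is full decoupling (k 0.5 → 0) because of the ~4×
sideband attenuation described above; the check's subject is retention
under halving, which presupposes a clearly detectable full-length
contrast.

## Known limitations

- EDF support is a minimal internal 16-bit codec (equal rates, μV);
  exotic EDF variants are out of scope.
- The comodulogram mode (0.5 Hz stepping of the phase-band center) is not
  implemented; one MI per (full phase band × full gamma band) pair is the
  analysis unit, matching the per-pair cluster statistics reported in this
  literature.
- Monte-Carlo subject-order invariance of cluster P values is exact only
  under complete enumeration; with random sampling it holds in
  distribution.
- Sample entropy on very long windows is O(N²); the numba kernel makes the
  default 60-s windows practical, but large montages at full scale are
  minutes of compute.
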