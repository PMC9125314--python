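# eegcomplex

Resting-state EEG complexity analysis for case–control studies, built around
the question of how temporal complexity and cross-frequency coupling of
spontaneous brain rhythms differ between depressed patients and healthy
controls, and how they relate to rumination questionnaire scores.

The package implements, as reusable library code with a thin CLI:

- **Multiscale sample entropy (MSE).** Sample entropy
  `SampEn(m, r) = −ln(A/B)` (template length m = 2, tolerance
  r = 0.15 × SD, Chebyshev distance, self-matches excluded) evaluated on
  coarse-grained series (non-overlapping window means, scales τ = 1…20) over
  60-s windows. The inner template count is a numba kernel that exactly
  matches a brute-force O(N²) oracle.
- **Spectral power.** Morlet wavelet power (central angle frequency ω = 6) on
  a 0.5–45 Hz grid with 0.5 Hz steps over 2-s epochs, plus a DPSS multitaper
  estimator (NW = 2, 3 tapers) as a cross-method check; both can report
  spectral density (μV²/Hz) for direct comparison.
- **Phase–amplitude coupling (PAC).** The mean-vector modulation index
  `MI = |⟨A(t)·e^{iφ(t)}⟩|` from Hilbert phase of six low-frequency bands
  (δ 1–4, θ 4–8, α_low 8–10, α_high 10–13, β_low 13–20, β_high 20–30 Hz) and
  the gamma (30–45 Hz) amplitude envelope, per 2-s epoch, averaged.
- **Cluster-based permutation statistics.** Mass-univariate equal-variance
  t maps (group contrasts) and Spearman maps (score associations) over
  channels × scales/frequencies/band-pairs, clustered by sensor adjacency
  (plus consecutive scales/frequencies), cluster mass = Σt, Monte-Carlo
  max-statistic null with 10,000 permutations by default.
- **Behavioral statistics.** Pearson chi-square (2×2, df = 1, no continuity
  correction), two-sided permutation mean tests, per-group Pearson
  correlation matrices of the three RRS rumination subscales (depressive,
  brooding, reflective), and Fisher-z comparison of two independent
  correlations, `z = atanh(r)`, SE = √(1/(n₁−3) + 1/(n₂−3)).
- **Synthetic cohorts.** Because no raw EEG ships with the package, a
  simulator generates 91-channel, 500 Hz eyes-closed-like recordings (1/f
  background, posterior-alpha-like oscillation, gamma, optional
  phase-locked gamma modulation) with group effects of known size and
  Likert-sum RRS scores from a Gaussian copula with configurable
  inter-subscale correlations — every analysis stage is testable against
  ground truth.

## Worked example

```python
import numpy as np
import eegcomplex as ec

# a small cohort: gamma power raised ×1.5 in the patient group on E1–E3
cfg = ec.SimulationConfig(
    n_mdd=6, n_hc=6, n_channels=8, duration=60.0, seed=7, pac_specs=[],
    group_effects=ec.GroupEffects(gamma_power_factor=1.5,
                                  gamma_channels=["E1", "E2", "E3"]),
)
recordings, table, truth = ec.gen_cohort(cfg)

# preprocess and build per-subject power maps
maps = []
for rec in recordings:
    rec = ec.average_reference(ec.bandpass(rec, 0.5, 45.0))
    maps.append(ec.morlet_power(ec.segment(rec, 2.0)).data)

fm = ec.FeatureMap(np.stack(maps), recordings[0].montage.channel_names,
                   tuple(np.arange(1, 91) * 0.5), "frequency")
graph = ec.build_neighborhood(recordings[0].montage)
result = ec.permutation_test(fm, table["group"].to_numpy(), graph,
                             n_perm=1000, seed=7)
top = result.significant()[0]
print(f"cluster P = {top.p_mc:.4f}, sign {top.sign:+d}, "
      f"channels {[recordings[0].montage.channel_names[c] for c in top.channels]}")
```

prints (after a notice that the 924 distinct label splits of a 6+6 cohort
are enumerated completely, making the P value exact)

```
cluster P = 0.0043, sign +1, channels ['E1', 'E2', 'E3']
```

a significant positive power cluster exactly on the three channels that
carry the injected gamma effect.

Behavioral statistics work directly on score tables:

```python
from eegcomplex import chi_square_2x2, fisher_z_compare
stat, p = chi_square_2x2(11, 13, 12, 10)   # gender split of a 24 vs 22 cohort
print(round(p, 4))                          # 0.555
print(round(fisher_z_compare(0.62, 24, 0.86, 22).p_one_tailed, 4))  # 0.0363
```

## Command line

```bash
eegcomplex simulate --config cohort.yaml --out data/ --seed 1
eegcomplex run-all --config run.yaml --out results/ --seed 1
eegcomplex behavioral --scores data/scores.csv --out results/
```

`run-all` executes simulate → preprocess (resample 500 Hz, 0.5–45 Hz
bandpass, 2-s epochs, 100 μV rejection, average reference) → MSE/power/PAC
feature maps → cluster permutation tests (group contrast and per-group
subscale correlations) → behavioral tables, writing CSV matrices, cluster
reports and a `runlog.json` with parameters, seeds and output digests;
re-running with the same config and seed reproduces identical digests.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json` runs
the full pipeline end to end on a small simulated cohort (12 subjects,
8 channels, all three feature families, cluster statistics at 500
permutations, behavioral tables) and writes the results JSON to the given
path.
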