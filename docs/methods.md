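# Methods

## Signal model and preprocessing

A CTG record is a pair of aligned series: fetal heart rate `F(t)` (beats/min)
and uterine activity `U(t)` (mmHg or arbitrary units), sampled at `fs = 4 Hz`.
Clinical traces carry sensor-loss artifacts (abrupt drops/spikes, missing
stretches) and a large, slowly drifting baseline.

Preprocessing runs three steps, in order, identically on both channels:

1. **Sliding-median outlier correction.** At each sample the median `μ̄` over
   a centred 10-s window is computed (non-finite samples ignored). Samples
   strictly outside `[μ̄ − 0.33·b, μ̄ + 0.33·b]`, with
   `b = max(|μ̄|, 10⁻⁶)`, are replaced by `μ̄`. The interval is closed (values
   exactly on the boundary are kept), the window is truncated at the record
   edges, and the absolute floor keeps the multiplicative rule defined for
   near-zero or negative medians (possible for centred UC). Non-finite runs
   no longer than 10 s are filled from the same windowed median; longer runs
   are left in place as gap markers.
2. **Long-gap excision.** Missing runs longer than `gap_max_s = 10 s` are cut
   out and the flanking segments concatenated; a log of `(start_s, length_s)`
   intervals is kept so a downstream user can split the record instead. When
   a whole record is processed, the excision mask is the union over both
   channels, keeping them aligned.
3. **Causal band-pass.** A 6th-order Butterworth band-pass, 0.004–0.5 Hz.
   "6th order" is read as the order of the band-pass transfer function (three
   analog poles per edge); the filter runs forward-only (causal, as phase
   distortion from zero-phase filtering would corrupt instantaneous-phase
   features downstream), implemented in second-order sections with the state
   initialised to the first sample's step steady state so the ~140 bpm
   baseline does not excite a long start-up transient. The low edge removes
   the baseline trend.

## Bivariate EMD

The channels are combined into `z(t) = F(t) + jU(t)` and decomposed by
directional-projection sifting into complex IMFs `γₘ(t)` and a residual
trend `r(t)`, with `z = Σ γₘ + r` holding exactly by construction
(telescoping).

One sifting pass: project `z` onto `K` directions `θ_k = 2πk/K`; find the
local maxima of each real projection `Re(e^{-jθ_k} z)`; cubic-spline the
*complex* samples of `z` at those maxima times into a directional envelope;
average the envelopes into the local mean `m(t)`; subtract. Only maxima
envelopes are needed — the direction set covers the full circle, so the
minima of one direction are the maxima of the opposite one. Directions whose
projection has fewer than two maxima are skipped; sifting of a component
requires at least two usable directions.

Numerical choices:

- **Direction count** `K = 64` by default (configurable). Dataset-scale runs
  in the test suite use `K = 16`; a stability test verifies that doubling K
  moves each IMF's energy by less than 5% of the signal energy on a two-tone
  fixture.
- **Splines** are natural cubics through the knots, with the two outermost
  maxima mirrored about each record endpoint before interpolation (suppresses
  end swings). The spline solve is implemented directly on a banded system —
  envelope construction dominates the sifting cost.
- **Stop rule** (per sift): Rilling-style amplitude criterion — stop when
  `|m(t)|/a(t) < θ₁ = 0.05` on at least 95% of samples and `< θ₂ = 0.5`
  everywhere, where `a(t)` is the mean directional envelope modulus; hard cap
  of 50 iterations (a capped sift returns the current remainder with a
  warning flag). A fixed-iteration mode (10 passes) is available.
- **Decomposition termination**: after `M = 5` IMFs (the default feature
  contract) or when the residual yields fewer than two maxima in every
  direction, whichever comes first.
- A classical univariate EMD (maxima + minima envelopes, same stop rules) is
  provided for channel-by-channel comparison studies; the feature pipeline
  never uses it.

Degenerate geometry worth knowing about: if the two channels are exactly
proportional, `z(t)` lies on a line in the complex plane and directional
envelopes carry much less information (projections near the orthogonal
direction see only noise). Decomposition still works but converges slowly and
can shed low-energy spurious modes. Physiological channels — and the
synthetic generator's defaults, which include non-zero inter-channel phase
lags — are genuinely bivariate.

## Features

Per IMF channel, the analytic signal `x + jH(x)` gives instantaneous
amplitude (modulus), phase (unwrapped angle) and frequency (phase derivative
by central differences, one-sided at the ends, in rad/s; negative samples are
retained). Per bivariate IMF:

| feature | definition | units |
|---|---|---|
| `mjia` | mean of `A^multi = sqrt(A_F² + A_U²)` | signal units |
| `mmam` | mean of `dA^multi/dt` (first differences × fs) | units/s |
| `vmam` | population variance of `dA^multi/dt` about `mmam` | (units/s)² |
| `wmf_fhr`, `wmf_uc` | `Σ A f² / Σ A f` per channel | rad/s |
| `me_fhr`, `me_uc` | `ln` of mean squared IMF amplitude | log energy |
| `psi` | `(1/T)·sqrt[(Σ cos Δφ)² + (Σ sin Δφ)²]`, `Δφ = φ_F − φ_U` | [0, 1] |

Notes:

- `psi` is the circular resultant length of the inter-channel phase
  difference: exactly 1 when `Δφ` is constant, `O(1/sqrt(T))` for unrelated
  phases. A variant sometimes written without the square root scales like `T`
  under perfect locking and cannot lie in [0, 1]; the square-rooted form is
  the one implemented.
- `wmf` weights by `A·f` (as defined here), not the more conventional `A²`;
  it is invariant to amplitude rescaling and undefined (NaN, imputed
  downstream) when `Σ A·f ≤ 0`.
- Discrete "integrals" are arithmetic means over samples (`1/T` with `T` the
  sample count).
- All features are computed over interior samples — 5% trimmed at each end by
  default (configurable) — to suppress Hilbert and spline edge artifacts.
- With `M = 5` IMFs the feature vector has exactly 40 named entries
  (`{stem}_{m}`); records that decompose into fewer IMFs, or degenerate
  channels, yield NaN entries that the pipeline imputes with training-set
  medians.

The joint instantaneous frequency
`f^multi = (A_F² f_F + A_U² f_U)/(A_F² + A_U²)` is exposed for analysis but
is not part of the 40-feature set (the per-channel WMFs are).

## Feature pipeline

- **Normalization**: `(x − mean)/(max − min)` with parameters learned on
  training rows only and applied unchanged to test rows; columns constant on
  the fit subset are dropped with a warning.
- **RFE**: linear SVM (C = 1), smallest squared weight eliminated each round,
  ties broken toward the lowest feature index; `p − 1` fits for `p` features.
- **Belsley diagnostics**: columns equilibrated to unit norm, SVD, condition
  indices `σ_max/σ_i`, variance-decomposition proportions; a near dependency
  is flagged at condition index > 30 with ≥ 2 proportions > 0.5 (classical
  thresholds, configurable). Exact rank deficiency reports an infinite
  condition index.
- **SMOTE**: per minority sample, `over_pct/100` synthetic points drawn
  uniformly on segments toward members of its `k = 5` nearest minority
  neighbours (`k` reduced with a warning for tiny minorities); the majority
  class is then randomly undersampled to `under_pct/100` of the grown
  minority. "Under-sampling by 100%" is read as: reduce the majority to 100%
  of the oversampled minority size, so the default (400, 100) yields an
  exactly balanced training set with the minority at 5× its original count.
  All randomness is seeded.

## Evaluation harness

Stratified 80/20 hold-out, repeated over `n_runs = 30` seeded runs (per-run
seed = `seed0 + run`). Stratification is a deliberate strengthening of plain
random splitting: with ~8% minority prevalence an unstratified 20% test set
regularly contains no cesarean rows, leaving sensitivity undefined. Per run:
split → impute (training medians) → optional SMOTE (training rows only) →
normalize (fit on the training rows) → train → score the untouched test rows.
The input matrix is never mutated; a dedicated test asserts test rows are
bit-unchanged.

Classifiers: Gini decision tree with a coarse complexity cap
(`max_leaf_nodes = 4`); Gaussian-kernel SVM with box constraint and kernel
scale chosen by validation accuracy on an inner 75/25 split over a small
logarithmic grid (C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 1}; the chosen pair
is logged); AdaBoost over 20 depth-1 trees with learning rate 0.5. Labels are
vaginal = 0, cesarean = 1 project-wide; cesarean is the ROC-positive class.
Metrics: sensitivity (cesarean recall), specificity (vaginal recall), AUC by
trapezoidal ROC integration (equal to the normalized Mann–Whitney statistic;
asserted in tests), and MSE of 0/1 labels (= 1 − accuracy, exactly).

## Synthetic generator

`gen_record` builds each channel as a baseline (140 bpm FHR, 20 a.u. UC) plus
shared AM/FM tones inside 0.004–0.5 Hz with per-tone UC phase lags, additive
Gaussian noise, and optional seeded artifacts (additive spikes; NaN gaps with
ground-truth positions kept in metadata). Default tones: 0.25 Hz
(contraction-band, lag π/3) and 0.02 Hz (slow oscillation, lag π/2); the lags
make the complex trajectory genuinely bivariate and mimic the delayed FHR
response to contractions. Everything is reproducible from the record seed;
dataset seeds are spawned from a master seed.

Two-class datasets plant a directional cesarean-like contrast: UC tone
amplitudes scaled down and a tighter (less jittered) phase lag, i.e. lower UC
mode energies and higher PSI — directions, not magnitudes, of what
cesarean-bound tracings show clinically. Presets: `strong_contrast` (UC × 0.4
against 0.15 lognormal record-to-record amplitude jitter — cleanly separable,
for recovery tests), `moderate_contrast` (UC × 0.7 against 0.35 jitter plus
the phase-locking contrast — overlapping classes where no single feature
separates, the regime where training on imbalanced data visibly collapses
sensitivity), and `null_contrast` (labels carry no signal).

What the generator does **not** emulate: FHR morphology (baseline variability
structure, accelerations/decelerations), stage-I/II labor segmentation,
nonstationary drift of the coupling, or clinical metadata. Passing tests
therefore demonstrate correctness of the decomposition, features and
evaluation machinery — not clinical performance on real tracings.

## Problem sizes

Tests and examples run at desk scale as the package's own defaults: records
of 300–600 s at 4 Hz (real intrapartum records are up to ~90 min; duration is
a free parameter everywhere), `K = 16` directions for dataset-sized
experiments (64 for single-record analyses), datasets of 50 + 50 (balanced),
200 + 20 (the 10:1 imbalanced design), and 30 evaluation runs.

## Known limitations

- BEMD is strictly bivariate; no n-variate extension, no noise-assisted
  (ensemble) variant, no online/streaming sifting.
- The sifting stop thresholds, direction count and boundary rule are
  conventions, not identities; different choices move mode boundaries
  slightly (guarded by the stability property test, but not eliminated).
- Instantaneous frequency by phase differentiation is noisy at low amplitude;
  edge trimming and the amplitude weighting in WMF mitigate but do not remove
  this.
- WFDB reading requires the optional `wfdb` dependency; only two-signal
  records are supported.
- `mmam` telescopes to the scaled end-to-end amplitude difference; on long
  stationary records it concentrates near zero and carries little signal — it
  is kept for completeness of the feature contract.
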