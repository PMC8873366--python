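# Methods

`nirsprint` implements brain-functional-network (BFN) fingerprinting for
multi-channel fNIRS: per-epoch Pearson-correlation networks, class-averaged
per-task fingerprints, and nearest-neighbor individual identification
across task states and hemoglobin views, together with a synthetic cohort
generator that stands in for real recordings.

## The analysis model

A recording is a concentration-change time series `X ∈ R^{T×C}` (C = 20
channels, two views: Oxy-Hb and Deoxy-Hb) with a block-design trial
schedule: per trial, 2 s instruction, 10 s task (one of RHT / LHT / FT),
17–19 s rest. Three 25-trial sessions give 75 trials over ~2250 s. The
sampling rate defaults to 30003/2250 ≈ 13.3347 Hz, the value at which a
2250-s session spans 30003 samples, a 10-s task phase spans 133 samples and
a 15-s rest window spans 200 samples.

Processing order is fixed:

1. **Band-pass** — third-order Butterworth, 0.01–0.1 Hz, applied per
   channel. Filtering is zero-phase (forward–backward) by default:
   correlation networks are phase-sensitive, and zero-phase filtering
   avoids group-delay artifacts; the effective amplitude response is then
   the *squared* magnitude response (filter tests account for this). The
   input is reflect-padded by one low-cut period (≈100 s) per side, so
   recordings must be at least three settling lengths (~300 s) long. A
   `causal=True` switch restores single-pass filtering.
2. **Global-signal removal** — subtract the per-timepoint mean over
   channels. Afterwards the channels sum to zero at every timepoint, which
   constrains correlations (they cannot all be positive); this is inherent
   to the baseline-correction choice and is documented, not corrected.
3. **Segmentation** — per trial, the full 133-sample task phase
   (instruction discarded) and a 200-sample window centered in the rest
   phase ("mid-rest": avoids task/rest switching transients). The rest
   window is 15.0 s by default — the only duration that yields 200 samples
   at the default rate while fitting inside a 17-s rest phase with ≥1 s
   guard per side. When the leftover guard is odd, the extra sample is
   placed before the window. Indexing is 0-based, half-open.
4. **Network estimation** — `corr(X_seg)` per segment: dense, signed,
   symmetric, unit diagonal. Zero-variance channels are a hard error (all
   channels are kept; silent NaNs are forbidden). Fingerprints are
   element-wise means of each class's networks (25 per task class, 75 for
   REST), on raw correlations; Fisher-z averaging is available but off by
   default, and no thresholding is applied.
5. **Identification** — similarity between two BFNs is the Pearson
   correlation of their strictly-upper-triangular off-diagonal weights
   (the unit diagonal is constant and the lower triangle duplicates the
   upper; a `vectorization="full"` switch flattens the whole matrix for
   comparison). For a source set (one fingerprint per subject) and a
   target set, each target is assigned the argmax-similarity source
   subject; exact ties break to the earliest subject, with a warning.
   Accuracy = correct predictions / subjects. Accuracy matrices follow the
   convention rows = target class, columns = source class; with 4 classes
   there are 16 ordered combinations per view pair. `summarize` reports
   mean ± sample SD (ddof = 1) both with and without the diagonal, because
   diagonal cells are trivial self-matches (accuracy 1.0 by construction).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis relies on,
not the optics. Per subject:

* **Intrinsic connectivity** — a spatial covariance
  `Σ = I + e · L Lᵀ`, with `L ∈ R^{C×4}` of N(0, 1/4) entries and `e`
  the *subject effect*: the single dial for how individual a subject is.
  `e = 0` gives the identity (a null cohort in which every subject is
  statistically identical); the construction is SPD with eigenvalues ≥ 1.
  The intrinsic signal is band-limited Gaussian noise (0.01–0.4 Hz)
  spatially mixed by `chol(Σ)`, with overall scale `latent_amplitude`
  (default 1, arbitrary concentration units).
* **Task-evoked response** — a canonical double-gamma hemodynamic
  response (gamma shapes 7 and 17, unit scale: peak at 6 s, undershoot at
  16 s, undershoot ratio 1/6) convolved with each task's 10-s boxcar and
  normalized so a sustained block plateaus at 1. Channel gains are
  `0.5 · (1 + e · 0.3 · z_c)` per task: gain heterogeneity scales with the
  same subject-effect dial, so the null cohort has no evoked signature
  either (and global-signal removal cancels its common mode exactly).
* **Physiological noise** — narrowband Gaussian oscillations (bandwidth
  0.05 Hz) at 0.1 Hz (Mayer), 0.25 Hz (respiration) and 1.0 Hz
  (heartbeat), amplitude 0.5 each; white sensor noise (SD 0.3); a slow
  random-walk drift (SD 0.02·√t per second — instrumental baseline wander,
  kept small so its in-band leakage stays well below the intrinsic
  signal).
* **Deoxy view** — the Deoxy latent+evoked component is `−κ` times the
  Oxy one (κ = `deoxy_scale` = 0.5, the Oxy/Deoxy anticorrelation), with
  the latent part mixed variance-preservingly with a view-specific
  structured process: `√(1−ρ²)·shared + ρ·distortion`, where the
  distortion has covariance `QΣQᵀ` for a random orthogonal `Q` (same
  spectrum and scale, different structure) and ρ = `view_distortion` = 0.9.
  Because the distortion scales with the subject's own latent signal,
  cross-view matching stays harder than cross-task matching at any
  subject-effect size — the qualitative regime the analysis is designed to
  probe. Nuisance components are drawn independently per view.

Two deliberate modelling choices deserve emphasis:

* **Epoch exchangeability.** Every stochastic component is drawn
  independently per trial phase: chunks are cut from one stationary
  realization at ≥20-s separations (beyond each band's decorrelation
  length) and crossfaded with an energy-preserving raised-cosine blend
  (1 s) at phase boundaries. A temporally continuous low-frequency process
  would share its realization between epochs of the same trial, making
  even a null cohort partially identifiable and confounding chance-level
  validation of the identification stage.
* **Narrowband, not phase-locked, oscillations.** A sinusoid with fixed
  per-channel phases over a 37-min session would give every subject a
  stable inter-channel phase pattern — itself a biometric. Narrowband
  processes keep the spectral peaks (asserted by a channel-averaged Welch
  spectrum on a 600-s simulation, each peak a local maximum within ±1
  frequency bin) while letting phase relations decorrelate across trials.

All randomness flows through named seeds (`numpy` `SeedSequence` spawning:
per-subject profile / schedule / recording streams, shared latent stream
across views); identical seeds give bit-identical output.

## Validation strategy and what it does not show

The test suite checks, among others: exact balance and determinism of
schedules; analytic-response agreement of the filter (0.05-Hz gain within
5% of the squared Butterworth response, 1-Hz leakage < 1%); brute-force
oracles for the correlation network (two-pass double loop, 1e-12) and the
nearest-neighbor argmax (exhaustive scan); parameter recovery (rest-sample
covariance and REST fingerprint reproduce the latent structure when the
subject effect dominates noise); subject separability of split-half rest
covariances (permutation test); accuracy increasing in the subject effect
(Spearman trend over 4 effect sizes × 5 seeds); and, at the study's scale
(30 subjects), saturated cross-task identification for a strong cohort
(subject effect 5, all off-diagonal cells ≥ 0.9 in both views) with
cross-view accuracy below cross-task at each of 5 seeds.

Problem sizes were chosen so the full suite runs comfortably on one CPU:
unit tests use a 6-subject, 12-trial paradigm (the smallest balanced
design long enough for stable 0.01-Hz filtering); cohort-level checks use
the full 30-subject, 75-trial paradigm with 5 strong-cohort seeds and 20
(tests) or 5 (acceptance script) null-cohort seeds.

Passing these tests shows the pipeline is internally correct and that its
qualitative behavior matches the regime it was designed for. It does not
show that real fNIRS cohorts are identifiable: the generator is Gaussian
and stationary within epochs, has no motion artifacts, no channel-quality
heterogeneity, no session-to-session drift in connectivity, and its
subject effect is a free dial rather than an empirical quantity.

## A structural finding: rest epochs are not independent of task epochs

One chance-level check fails by design and is left failing. In a null
cohort (subject effect 0), pooled off-diagonal accuracies should fall in
the exact binomial 99% interval around 1/30. The six task↔task cells do.
The six REST-involving cells do not — and cannot, for *any* stationary
signal model: the zero-phase 0.01–0.1 Hz filter's kernel extends over tens
of seconds, while the centered 200-sample rest window starts only ~1.5 s
(≈20 samples of guard) after the task phase ends. Filtered rest-window
values therefore contain task-phase signal, correlating the two epochs'
network estimates (~0.08 pattern correlation even for temporally white
input; same-subject fingerprint-similarity bias ~0.05), which inflates
REST↔task accuracies to ~0.10–0.19 against a ~0.055 band limit.
The implication for real studies is that REST-mode identification
accuracies obtained from epochs interleaved with task blocks in a single
session are partly epoch-adjacency-assisted, and REST-based fingerprints
should ideally be validated across sessions.

## Known limitations

* The Oxy/Deoxy coupling is a two-parameter caricature (κ, ρ); real
  HbO/HbR dynamics differ in lag and frequency content, not just sign and
  structure.
* The SNIRF import is an adapter for externally recorded data (hbo/hbr
  channels + task annotations); it assumes the block-design phase
  durations of the configured paradigm.
* The aggregation convention behind headline "mean ± SD" accuracy
  summaries is ambiguous in the field; both diagonal-included and
  off-diagonal-only summaries are always emitted and labeled.
* Accuracies are reported without significance tests, and only the 1-NN
  matcher is implemented (no learned metrics, no partial correlation).
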