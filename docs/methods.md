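# Methods

## The problem

A self-paced (asynchronous) brain–computer interface must decide, from EEG
alone, whether a user is about to move — with no cue and no trial clock.
The usable signature is the movement-related cortical potential (MRCP): a
slow cortical negativity, strongest over the midline motor area (Cz for
lower-limb movement), that develops over the 1–2 seconds before voluntary
movement onset and lives almost entirely below 5 Hz. Detecting it on
single trials is hard, and reported performance depends heavily on three
preprocessing/classification choices that are usually made ad hoc:

* the **frequency band** the EEG is filtered to,
* the **spatial filter** used to build the channel/component the detector
  sees,
* the **detector** itself.

`mrcpbench` treats these as a fully crossed factorial experiment: 5 bands
([0.01–1], [1–2], [2–3], [3–4], [4–5] Hz) × 5 spatial representations
(NoF = raw channels, surface Laplacian, ICA, CSP, PCA) × 6 detectors
(LDA, SVM, 1-NN-Euclidean, 1-NN-DTW, matched filter MF, DBA template
matching TM). With 19 raw channels, 9 Laplacian surrogates, 19 ICA
components, 19 principal components and 1 CSP channel, one subject's grid
has 5 × (19+9+19+19+1) × 6 = **2,010** combinations; keeping the best
channel/component per (band, filter, detector) cell leaves the
5 × 5 × 6 = **150**-cell table analysed by repeated-measures ANOVA.

## Synthetic sessions

Real MRCP datasets are scarce, so the benchmark ships a generator whose
ground truth is known exactly.

* **Protocol.** `n_trials` self-paced ballistic dorsiflexions with idle
  gaps drawn uniformly from `idle_range` (default 3–7 s). Trials whose
  onset follows the previous offset by less than 4 s are *kept in the
  recording* but dropped at segmentation, mirroring how short-gap trials
  are discarded when labelling real data.
* **MRCP waveform.** A linear negative ramp from 0 to −`mrcp_amplitude`
  over `mrcp_duration` (2 s), rebounding linearly to baseline over 0.5 s
  after onset; a half-cosine variant is available (`mrcp_shape`). The ramp
  is the simplest shape with the canonical properties (slow, monotone
  negativity peaking at onset).
* **Topography.** Weight 1.0 at `focus_channel` (Cz), 0.6 at its montage
  neighbours, 0.3 elsewhere; configurable per channel. This is an
  attenuation profile, not a volume-conduction model.
* **Noise.** Per-channel white or 1/f-amplitude ("pink", default) noise,
  `noise_sd = 0.5`. Pink noise is the harder and more realistic case: about
  half its power falls inside the [0.01–1] Hz analysis band, directly
  masking the MRCP.
* **EMG.** Bursts spanning onset→offset: rectified white noise under a
  Hann envelope floored at 20% of its peak, with the noise carrier floored
  at 25% of its scale, on a Gaussian baseline 10× weaker. The floors give
  the burst sample-exact edges, so with `noise_sd = 0` threshold detection
  recovers the labelled events with zero sample error — the property the
  test suite pins. `detect_emg_events` rectifies, smooths with a 50 ms
  moving average, thresholds, merges runs closer than `min_gap_s`, and
  refines each run's edges on the raw rectified amplitude.
* **Defaults as study conditions.** `mrcp_amplitude = 2.0` with pink
  `noise_sd = 0.5` was calibrated once so that detector and channel
  rankings are non-degenerate at desk scale: the surface-Laplacian
  channel-F1 map peaks at the generating focus in ≥ 8/9 subjects while F1
  stays well below ceiling on off-focus channels. The generator does not
  attempt to match any human subject's SNR.

What the generator deliberately omits: volume conduction (channel noise is
independent, so spatial filtering carries no SNR benefit here — only a
localization one), ocular/cardiac artifacts, non-stationarity across a
session, and mains interference. Passing tests therefore demonstrate
correct mechanics and faithful relative behaviour of the factors, not
human-data performance levels.

## Pipeline

Per subject and band:

1. **Causal band-pass** — second-order Butterworth applied forward only
   (an asynchronous detector cannot use zero-phase filtering), in
   second-order sections. For the [0.01–1] Hz band at high sampling rates
   the single band-pass design is numerically delicate; an equivalent
   high-pass + low-pass cascade is used automatically above 512 Hz and
   exposed as `design_sos(..., cascade=True)`. Unstable designs raise an
   error naming that fallback.
2. **Segmentation** — MRCP epoch = [onset − 2 s, onset), non-MRCP epoch =
   [offset, offset + 2 s), half-open windows at native rate; 0-based
   indices; short-gap trials dropped whole; epochs that leave the
   recording dropped individually; every drop logged.
3. **Stratified split** — per class, shuffle (seeded) and take
   floor(2/3 · n) for training; remainder for test. Train/test class
   counts then match per-subject totals the way a 2/3–1/3 stratified draw
   must (e.g. 184/163 pooled → 122/108 train, 62/55 test).
4. **Decimation** — epochs are FIR-anti-aliased and decimated to 64 Hz by
   default (2,048 → 128 samples). Raw sample vectors are the detector
   features; 128 samples against a few hundred training epochs is the
   tractable regime. Decimation can be disabled.
5. **Spatial filtering** — fitted on training epochs only, applied to all:
   * *NoF*: identity, 19 outputs.
   * *SL*: surrogate = channel − mean(neighbours) at the nine interior
     10–20 sites (all neighbour weights equal); the neighbour graph is the
     standard 4-connected scalp grid (midline sites gain both frontal /
     both occipital neighbours) and ships as an editable JSON table.
   * *ICA*: FastICA (deflation, tanh contrast, seeded) on the
     concatenated training epochs; non-convergence retried with fresh
     seeds and flagged. 19 unmixed components.
   * *CSP*: generalized eigenproblem of the class-mean covariances,
     ridge-regularized (λ = 1e-6 · trace/n); the single filter maximizing
     MRCP/non-MRCP variance ratio (flag to favour the other class). 1
     output.
   * *PCA*: eigenvectors of the pooled training covariance; 19 components.
   Component signs are normalized (largest-magnitude weight positive).
6. **Per-output z-normalization** — each single-channel output epoch is
   z-normalized (population SD) before detection; constant epochs are
   rejected as degenerate. **Order matters**: normalizing the 19 raw
   channels individually *before* a surface Laplacian equalizes their
   amplitudes and cancels exactly the topography the Laplacian measures
   (verified empirically: SL detection stops responding to effect size).
   Spatial filters therefore see unnormalized µV-scale epochs; detectors
   see normalized series. For NoF the two orders coincide.
7. **Detection** — six detectors on the raw (decimated) sample vector:
   * *LDA* with Ledoit-Wolf shrinkage of the pooled covariance (features
     ≳ epochs);
   * *SVM* with an inner 3-fold grid search (linear / RBF;
     C ∈ {0.1, 1, 10, 100}; γ ∈ {scale, 0.01, 0.1}) scored by F1;
   * *1-NN* under Euclidean and under Sakoe-Chiba-banded DTW (r = 10% of
     the epoch length, squared point costs, square-rooted total); ties go
     to the lowest training index;
   * *MF*: template = mean of training MRCP epochs; statistic = max of
     the same-length convolution with the time-reversed template;
   * *TM*: template = DBA barycenter of training MRCP epochs
     (medoid-initialized, banded at 10%, ≤ 10 iterations, 1e-4 relative
     tolerance; the sum-of-alignment-costs objective is non-increasing and
     the best template is kept); statistic = −DTW distance to the
     template.
   MF/TM thresholds are the training-set F1 maximizer over midpoints of
   consecutive distinct statistics (ties → lowest threshold, i.e. the
   most sensitive rule); decision convention statistic ≥ threshold ⇒ MRCP.
   Calibrating thresholds on training data avoids leakage; an opt-in
   `test_set_thresholds` flag reproduces the optimistic variant for
   comparison.
8. **Scoring and selection** — F1 with MRCP as positive class (F1 = 0
   when no true positives). Within each (band, filter, detector) cell the
   channel/component with the highest *test* F1 is kept — this mirrors the
   original protocol's per-channel selection and is knowingly model
   selection on test data; the raw per-channel grid is always emitted
   alongside so either analysis is possible.

Degenerate cells (e.g. too few epochs for the SVM's inner CV) are recorded
with a reason in a `missing` table, never silently dropped; they are
imputed per subject by that subject's cell mean only when assembling the
balanced ANOVA design.

## Repeated-measures ANOVA

The 150-cell × subject table is a fully within-subject 5 × 5 × 6 design.
For each effect E the implementation builds orthonormal within-subject
contrasts (Kronecker products of per-factor orthonormalized Helmert
contrasts; collapsed factors contribute the unit-norm averaging row), so

* SS_effect = n‖z̄‖², SS_error = Σᵢ‖zᵢ − z̄‖² with the effect-by-subject
  error term, df = d_E and (n−1)·d_E;
* the stacked contrasts are an orthonormal basis of the within-subject
  space, hence all effect + error SS sum exactly to the total
  within-subject SS (tested to 1e-8), and the SS coincide with the
  balanced-design Type III decomposition;
* the Greenhouse-Geisser epsilon is estimated per effect from its own
  contrast-score covariance S as ε = tr(S)²/(d_E·tr(S²)), clipped to
  [1/d_E, 1]; both dfs are multiplied by ε before the F lookup;
* partial η² = SS_effect/(SS_effect + SS_error).

Cross-checks in the test suite: the two-level case equals the paired-t²
identity; uncorrected three-way F values match `statsmodels.AnovaRM` to
1e-8; one-way ε and GG-corrected p match `pingouin.rm_anova` to 1e-8.
Simple-effects one-way ANOVAs (filter within band, band within filter)
and Bonferroni-adjusted paired post hoc comparisons use the same
machinery at the study-wide α = 0.01. Estimated marginal means are cell
means averaged over the remaining factors, with between-subject SE.

`simulate_f1_table` generates factorial F1 responses (subject random
intercept + iid noise) with an injected +0.17 advantage for one
(filter, band) cell across all detectors — the size of the gap between
the best band/filter combination and the field. Across 200 simulated
tables the GG-corrected SF × Freq interaction is detected at p < 0.01 in
every repetition, while the untouched SF × Classifier interaction rejects
at ≤ 1.5% (GG is conservative); under a global null all seven effect
lines hold the ≤ 1.5% empirical level at α = 0.01 (2,000 repetitions).

## Numerical and design choices

* z-normalization uses the population (1/N) standard deviation.
* Epsilon of a single contrast (2-level factor) is exactly 1.
* DTW band width is ⌈r·n⌉ samples; with the band forced to the diagonal
  the distance equals the Euclidean distance.
* The demo/desk scale is fs = 64–128 Hz, 16–90 trials per session,
  9-subject cohorts; all factorial arithmetic (2,010 / 150) is
  scale-independent. The full-rate 1024 Hz path is exercised through the
  same code (the EDF writer/reader round-trips it).
* Seeds: every stochastic step (session noise, splits, FastICA, SVM CV)
  derives its seed deterministically from the run seed via
  `numpy.random.SeedSequence`; identical configuration + seed reproduces
  results byte-identically.

## Known limitations

* Synthetic noise is spatially independent, so spatial filters cannot
  show the SNR gains they deliver on volume-conducted real EEG; their
  comparison here is about localization and mechanics only.
* Channel selection by test-set F1 (step 8) inflates absolute F1 values;
  it is retained deliberately as the benchmarked protocol.
* MF/TM compress the class into one template; on non-stationary real
  data this is a known weakness, and the synthetic generator (stationary
  within a session) is kinder to them than reality.
* No artifact simulation or rejection; no online/streaming latency
  accounting; Mauchly's sphericity test is not reported (the GG-corrected
  results are used throughout).
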