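# Methods

`semrsa` implements a representational similarity analysis (RSA) of
intracranial (ECoG) recordings against a hybrid semantic similarity model,
together with a synthetic-data generator that makes the whole chain testable
against known ground truth. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic studies do and do
not establish about real data.

## The semantic model

Concepts are described by property norms: a concept × feature table in which
each feature is a short phrase ("is comfortable", "has cushions"). Each
feature phrase is mapped into a distributional word-vector space:

1. tokens are lowercased and a fixed set of relational markers is removed
   (`is, has, have, a, an, the, of, on, in, made, used, for, to, like, by,
   with`), leaving content words — "is sat on" → `sat`;
2. the feature vector is the unweighted mean of the embedding vectors of its
   in-vocabulary content words; out-of-vocabulary words are logged and
   skipped, and a feature with no in-vocabulary content word is skipped with
   a warning (a concept that loses all its features is an error);
3. the concept vector is the unweighted mean of its feature vectors
   (weight-proportional averaging is available for weighted norms);
4. the semantic representational dissimilarity matrix (RDM) is the cosine
   distance `1 − v_i·v_j/(‖v_i‖‖v_j‖)` over all concept pairs.

No stemming or lemmatization is applied: matching is exact lowercase. The
stopword list is configurable; the default reproduces the standard worked
example (armchair → comfortable/cushions/sat) and is deliberately small.

## Preprocessing

Voltage epochs (default −1500…3000 ms at 400 Hz) pass through:

- **Notch filter** — zero-phase 4th-order Butterworth band-stop at 60, 120,
  180 Hz, ±1.5 Hz edges. Zero-phase filtering of finite epochs leaves edge
  transients of roughly the inverse bandwidth (~0.3 s); epochs are padded
  well beyond the −100…1000 ms analysis range precisely so these transients
  fall outside it.
- **Baseline correction** — per trial and electrode, subtract the mean over
  −500…0 ms.
- **Bad-channel detection** — a deterministic surrogate for visual
  inspection: a channel is bad if it contains non-finite samples or if the
  robust z-score (median/MAD) of its log total variance exceeds 4. The
  heuristic needs a reasonable number of channels to estimate its scale;
  with very few, MAD-based scores are unstable.
- **Common average reference (CAR)** — subtract the mean of good channels
  at every sample; bad channels are excluded from the average but
  re-referenced. Note that CAR redistributes any strong localized signal
  into every channel with weight 1/n_good; the synthetic grids therefore
  include non-ROI contacts (default 30) so the dilution matches a realistic
  grid size. Even so, weak leaked model correlations in non-target regions
  are expected and visible at group level — a property of CAR itself, not a
  bug in the simulation.
- **Saccade-component removal (optional)** — FastICA with
  N = round(0.75 × n_good) components on concatenated good-channel epochs.
  A copy of the activations is band-passed to 20–190 Hz (the range where
  saccadic spike potentials dominate), convolved with a saccade template,
  and suprathreshold peaks (mean + 3 SD of the rectified convolution,
  ≥ 50 ms apart) are counted as events/s. The two components with the most
  events are subtracted from the data (`clean = data − A[:, drop] S[drop]`),
  which keeps the PCA residual and makes the `n_drop = 0` path exactly the
  identity. The default template is a biphasic difference of Gaussians
  (σ = 5 and 15 ms, opposite polarity); real-data users should supply their
  own. FastICA stopping at `max_iter` is recorded in the report rather than
  raised; only degenerate (non-finite) unmixing is an error. The adaptive
  event threshold is scale-invariant, so discrimination comes from the event
  *rate*: band-limited Gaussian activity crosses 3 SD at ~1.7 events/s, so
  saccade-dominated components are separable at physiological saccade rates
  (~3/s) but not at very low rates.
- **Repetition averaging** — the mean over all repetitions of each kept
  item, pooled across sessions (sessions are not averaged separately first;
  with equal trial counts the two conventions coincide).

## Neural RDMs

Per ROI (MTG, ITG, TP, anterior fusiform, PRC), each item's pattern at time
t is the concatenation of all ROI electrodes' samples in the closed window
t ± 50 ms (41 samples per electrode at 400 Hz). Cosine-distance RDMs are
computed at every sample from −100 to 1000 ms (441 time points at 400 Hz).
Patterns are not z-scored before the distance (configurable upstream).
An item with a zero-norm pattern aborts the computation rather than being
dropped, protecting item alignment.

## Phase RDMs

Oscillatory phase is extracted with Morlet wavelets (via
`mne.time_frequency.tfr_array_morlet`) on 60 log-spaced frequencies from 4
to 190 Hz, with cycle counts rising linearly in log-frequency from 5 to 15,
at output times 200…400 ms in 20 ms steps. The epoch must contain the
5-cycle wavelet at 4 Hz (1.25 s) around every output time. At each
(frequency, time) cell the item × item dissimilarity is the mean over
electrodes of the circular distance `π − |π − |a−b| mod 2π|` ∈ [0, π].
Zero-amplitude samples have undefined phase; they are masked and an item
pair that is masked everywhere is an error. Band summaries average tau over
grid cells within theta 4–8, alpha 9–14, beta 15–30, low gamma 30–70, and
high gamma 70–150 Hz (the 9–14 Hz alpha definition is the default; 8–14 is
a config override).

## Inference

- **Kendall's Tau-A** between the strictly-lower-triangle vectors of the
  neural and model RDMs (name-aligned): (C − D) / (n(n−1)/2), ties counted
  in neither C nor D and the denominator not tie-corrected.
- **Wilcoxon signed-rank** against zero, one-sided for positive RSA
  effects. The null distribution is exact for n ≤ 25 — all 2ⁿ sign
  assignments of the observed midranks, computed by generating-function
  convolution over doubled ranks — and a continuity-corrected normal
  approximation beyond.
- **Cluster-mass permutation.** Pointwise one-sided Wilcoxon tests at
  α = 0.05 define significant time points; maximal contiguous runs form
  clusters whose mass is the sum of the standardized Wilcoxon statistic
  (W⁺ − μ)/σ over the run (cluster *size* is available as an alternative).
  The null flips each participant's entire timecourse sign with an
  independent fair coin per permutation (default 10,000 draws) and records
  the maximum cluster mass; cluster p = (#{null ≥ observed} + 1)/(n_perm + 1).
  An `exhaustive` option enumerates all 2ⁿ distinct flip patterns instead —
  deterministic and invariant to participant relabeling, with
  p = #{≥ observed}/2ⁿ. With n = 8 participants the flip orbit has only 256
  elements, so the attainable p floor is 1/256 ≈ 0.004 regardless of the
  number of sampled permutations.
- **Window tests** average tau over the closed 200–400 ms window per
  participant before the Wilcoxon test (taus are averaged, not RDMs).
- **Region contrasts** use the two-sample rank-sum test
  (`scipy.stats.mannwhitneyu`, exact for small tie-free samples) at
  α = 0.025, plus the paired count of participants with target-ROI tau
  strictly greater (ties count as not greater).
- **Band tests** compute tau per (frequency, time) cell, average within
  band and window per participant, then test each band one-sided.

### Calibration findings

Two empirical properties of this inference chain are worth knowing:

1. The sign-flip/Wilcoxon machinery assumes each participant's tau is
   symmetrically distributed under the null. Tau between a noise RDM and a
   *structured* (category-blocked) model RDM is mildly right-skewed with a
   slightly negative median, which makes the one-sided test conservative:
   on raw snr = 0 cohorts the measured family-wise false-positive rate is
   ≈ 0.02 at α = 0.05. Under a sign-symmetric-by-construction null (each
   participant's timecourse multiplied by an independent fair ±1) the test
   is exact: measured rates across 200-run studies scatter binomially
   around ≈ 0.05. The calibration study symmetrizes for this reason.
2. With temporally uncorrelated data and few participants, cluster masses
   tie heavily across the 256-element flip orbit (the Wilcoxon z takes few
   distinct values), which is also conservative. Real sliding-window tau
   series are smooth, and with smooth timecourses the measured rate is
   nominal.

## The synthetic-data generator

The generator is first-class, tested code; all outputs are bit-reproducible
from their (`CohortSpec`, seed) inputs.

- **Norms**: category-blocked binary features — a concept carries a feature
  of its own category block with probability 0.8, others with 0.1; every
  concept is guaranteed ≥ 1 feature. This induces a category-structured
  semantic RDM (within < between distances).
- **Embeddings**: unit-norm Gaussian vectors, deterministic per
  (word, seed), so the same word always maps to the same vector.
- **Cohorts** (defaults: 8 participants, 12 items × 5 repetitions × 1
  session, 2 electrodes per ROI plus 30 non-ROI contacts in the pipeline
  configuration, 400 Hz, epochs −1.5…3 s):
  - Background noise is a sum of random-phase sinusoids with 1/f amplitude
    (log-log PSD slope ≈ −1 over 2–100 Hz), independent per trial and
    electrode, with per-electrode log-normal amplifier gains (σ = 0.5) so
    channel variances are realistically heterogeneous.
  - The target geometry is realized exactly: the cosine-similarity Gram
    S = 1 − D of the target RDM is eigendecomposed (with a PSD check —
    an unrealizable target raises an error suggesting a higher embedding
    dimension), giving unit-norm latent item coordinates whose pairwise
    cosine distances equal the target.
  - **Amplitude code**: inside the effect window (default 200–400 ms) the
    target-ROI pattern of each item is an orthonormal mixture of its latent
    coordinates expressed in a smooth sine basis that vanishes at the
    window edges and stays below ~40 Hz. Smoothness matters: a broadband
    injected pattern would ring through the notch filter and smear the
    effect far outside the injected window. The signal is scaled so its RMS
    is `snr` times the noise RMS. The sliding ±50 ms analysis window sees
    the full basis only when it coincides with the effect window, so the
    recovered tau peaks near 1 only there; elsewhere in the window the
    restriction of the basis lowers tau to ≈ 0.6 even at high SNR, which is
    the expected behavior of partially overlapping windows.
  - **Phase code**: instead of amplitude, each target-ROI electrode carries
    a band-limited oscillation (carrier at the geometric band center) whose
    per-item phase offset is π/2 times the projection of the item's latent
    coordinates on a random electrode-specific direction; the envelope is
    Hann-tapered over one wavelet half-span around the window so no
    item-specific broadband transient leaks into other bands. The
    band-specificity study uses oscillation amplitude 2× the broadband
    background RMS — a prominent but physiological low-frequency rhythm
    (much larger amplitudes would make the effect channels variance
    outliers to the bad-channel heuristic, as they would in real data).
  - Optional 60 Hz line noise (random phase per trial/channel) and saccade
    artifacts (template pulse trains on two random spatial components) can
    be injected; ground truth records windows, geometry, band, and artifact
    components for recovery scoring.

### What the synthetic studies do not show

The generator emulates the *statistical* structure the analysis relies on
(pattern geometry in a time window, band-limited phase coding, 1/f noise,
line noise, template artifacts), not biophysics: no volume conduction or
spatial correlation between electrodes, no epileptiform activity, no
trial-order or repetition-suppression effects, no behavioral variability.
Passing studies therefore establish that the chain is correct and calibrated
under its own assumptions — not that real ATL recordings contain these
effects.

## Problem sizes and runtime choices

Simulation studies use the default small cohort scale (12 items, 2
electrodes/ROI, 1 session): 200 runs for null calibration (reduced to 500
permutations per run), 50 runs for effect recovery and band specificity,
100 runs for artifact-component ranking. The full-pipeline demo runs the
default 8-participant cohort with 2,000 permutations. These sizes keep each
study in the minutes range on one CPU while leaving binomial error on rate
estimates at a few percent.

## Known limitations

- CAR leakage places weak, consistently positive model correlations in
  non-target regions at high SNR; region contrasts remain clearly in favor
  of the target ROI, but per-region cluster tests on synthetic cohorts can
  reach significance in non-target regions for this reason.
- The exact Wilcoxon implementation enumerates sign assignments of
  *midranks*; with heavy ties this is the standard conditional-on-ranks
  exact test, not a tie-free approximation.
- The bad-channel heuristic and the saccade event-rate ranking are
  deterministic surrogates for manual steps; their thresholds (z = 4,
  mean + 3 SD) are configurable and were chosen as standard values, not
  fitted.
- Embeddings are synthetic random vectors: they test plumbing and
  invariances, not semantic content. Real analyses should load pretrained
  vectors via the standard text format reader.
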