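# Methods

`prestim` implements a single-trial analysis of how the brain state
immediately preceding a nociceptive stimulus shapes its perception, together
with a synthetic-data generator that plants the effects the analysis is
designed to recover.  This note documents the models, the statistical
procedures, the numerical choices, and what the simulations do and do not
show about real recordings.

## The scientific model

On every trial a brief painful laser pulse of one of four energies (E1–E4)
is delivered and the subject reports perceived intensity on a 0–10 visual
analog scale (VAS).  The working model is that, beyond the stimulus energy,
the rating is modulated by the prestimulus state of two cortical systems
indexed by (i) alpha-band (8–15 Hz) and gamma-band (74–87 Hz) EEG
oscillation power in the few hundred milliseconds before the stimulus, and
(ii) the BOLD level of positively and negatively predictive region sets at
stimulus onset (which, through hemodynamic lag, reflects prestimulus neural
activity).  Both EEG features enter negatively: higher prestimulus alpha or
gamma power predicts lower perceived intensity.

## Synthetic data

### EEG (`synthgen.generate_eeg_dataset`)

Per subject, 4 energies x 10 trials of −500..1000 ms epochs at 1000 Hz:

* **Background**: Gaussian noise with a 1/f^chi amplitude spectrum
  (chi = 1), scaled to 10 µV broadband rms — a standard stylization of
  resting EEG.
* **Oscillatory bursts**: one alpha and one gamma burst per trial, confined
  to a −300..0 ms Hann envelope, with per-trial frequency drawn uniformly in
  the band and log-normal amplitude (median 8 µV alpha, 3 µV gamma,
  log-SD 0.5).  The *latent* squared amplitudes are the trial's "true"
  prestimulus powers.
* **Evoked response**: a negative Gaussian deflection at 200 ms (N2) and a
  positive one at 350 ms (P2) whose amplitudes scale with stimulus energy
  (E1–E4 magnitudes 4.3/10.4/22.3/28.1 µV and 3.4/8.5/18.0/23.7 µV,
  the typical graded vertex-potential amplitudes for this paradigm).
  Optional parameters let prestimulus power also modulate evoked amplitude;
  they default to 0 so that rating modulation and evoked modulation are
  independent pathways.
* **Ratings**: `base(energy) + beta_alpha*z(alpha power) +
  beta_gamma*z(gamma power) + noise`, clipped to 0..10, where `z` is the
  within-energy standardization of the *latent* powers.  Defaults:
  per-energy baselines 3.8/4.9/6.6/7.7 VAS, `beta_alpha = beta_gamma =
  −0.5`, noise SD 0.8 VAS.  The noise level makes the within-energy rating
  SD ≈ 1.07, in the range typical for this paradigm, and keeps fewer than
  1 % of trials at the clip boundaries.  Because the rating model uses the
  latent amplitudes and not re-estimated powers, recovery tests measure the
  analysis pipeline rather than the generator.
* `redundant_bands=True` makes the gamma latent a deterministic copy of the
  alpha latent — the degenerate case in which the two features carry no
  independent information.
* One "electrode of interest" (C4) carries the planted effects; further
  channels are attenuated copies plus independent noise.

### BOLD (`synthgen.generate_bold_dataset`)

A small voxel grid (default 12 x 12 x 8) scanned at TR = 1.5 s; 40 events
with 27–33 s inter-stimulus intervals (TR-aligned by default).  Each voxel
receives white noise, slow drift (linear + slow cosine), and an evoked
response: energy-scaled sticks convolved with the canonical double-gamma
HRF.  Two disjoint cubic masks additionally receive a low-pass-filtered
(0.05 Hz cutoff) unit-variance Gaussian process, so onset samples are
autocorrelated like resting-state signal.  The process values at trial
onsets enter the rating model with effect size +0.5 (positive mask) and
−0.5 (negative mask).

## Analysis pipeline

1. **Preprocessing** (`tf`): 1–100 Hz zero-phase Butterworth band-pass
   (4th order, forward-backward), ±100 µV amplitude rejection, prestimulus
   baseline correction.  Ocular-artifact correction is out of scope for
   synthetic data; a threshold-rejection hook stands where an external
   cleaning step would plug in.
2. **Spectrogram** (`tf.wft_spectrogram`): windowed Fourier transform with
   a fixed 200 ms Hann taper, power P(t,f) = |F(t,f)|².  A 200 ms window has
   5 Hz natural resolution; the 1 Hz grid is obtained by zero-padding each
   tapered segment to 1 s.  The epoch is reflect-padded by half a window so
   the time grid spans the full −500..1000 ms; padded estimates are flagged,
   and estimates within ±100 ms of stimulus onset unavoidably mix pre- and
   poststimulus signal (a property test plants a poststimulus burst and
   confirms the leakage).  No spectrogram baseline correction is applied —
   prestimulus and poststimulus power must stay on one scale.
3. **Within-energy normalization** (`plsmap.normalize_within_energy`):
   features and ratings are z-scored within each stimulus energy (sample
   SD), removing the stimulus-energy confound from the trial-to-trial
   relationship.
4. **PLS regression** (`plsmap.simpls`): the coefficient map alpha(t,f) of
   the multivariate linear regression from the flattened spectrogram to the
   normalized rating, estimated with SIMPLS (3 latent components by
   default).  SIMPLS is deterministic, coincides with NIPALS PLS1 for a
   single response, and converges to ordinary least squares at full rank —
   both facts are exercised as tests.  Zero-variance feature columns are
   dropped with a warning and get zero coefficients.
5. **Cluster statistics** (`clusterstat`): per grid point, a one-sample
   t-test of the subject coefficients against zero; significant points
   (p < 0.05) of equal t-sign form connected clusters (4-connectivity on
   time-frequency grids, 6-connectivity on voxel grids; positive and
   negative t never join); clusters of more than 20 points are kept and
   scored by the sum of their t values (Sigma-T).  Band rules label the
   largest prestimulus low-frequency cluster "Pre-ABO" and the largest
   prestimulus/poststimulus gamma (≥30 Hz) cluster "Pre-GBO"/"Post-GBO"
   (ties by |Sigma-T|).
6. **Permutation inference**: ratings are shuffled *within energy stratum*
   (normalization is within energy, so unstratified shuffling would break
   exchangeability), the PLS fit and group t recomputed, 1000 times by
   default, with the add-one correction p = (b+1)/(M+1).  Two schemes:
   * `"mask"` (default): Sigma-T* is accumulated inside the *observed*
     cluster masks.  This conditions on cluster geometry selected from the
     same data and is anticonservative under the null — measured at ~25–33 %
     any-cluster false-positive rate on null cohorts.  It is the convention
     this pipeline mirrors and remains the default.
   * `"maxstat"`: clusters are re-formed on every permuted map and the
     maximal |Sigma-T| forms the reference distribution.  This controls the
     family-wise error (measured ~2–3 % on null cohorts, slightly
     conservative because many null cohorts produce no cluster at all) and
     is the scheme used wherever type-I error control is the question.
   Permutation fits are batched (`simpls_multi`) so a 20-subject, 200-
   permutation analysis takes about a second on the reduced grid.
7. **Median split** (`stateeffects`): trials are scored by mean power in a
   cluster mask and split at the median *within each energy* so the
   energy x split repeated-measures design stays balanced (with an odd
   count the median trial is dropped; stable sort makes ties
   deterministic).  Cell means of ratings, evoked waveforms and N2/P2 peaks
   feed balanced RM-ANOVAs.
8. **Repeated-measures ANOVA** (`_anova`): textbook balanced univariate
   decompositions, vectorized over trailing axes so per-timepoint waveform
   ANOVAs and calibration simulations are cheap; verified against pingouin.
   Tukey post-hoc comparisons use *pair-specific* paired-difference error
   terms against the studentized range (df = n−1) rather than the pooled
   error MS: in the accuracy comparisons one condition (the combined
   feature set) shares trials with each single set, so sphericity is
   violated by construction and pooling would mis-weight the contrasts.
   For two levels this reduces exactly to the paired t-test.  A
   Greenhouse–Geisser correction is available but off by default.
9. **Decoding** (`predict`): within-energy-normalized ratings below/above 0
   define low/high-pain trials (exact zeros dropped); a linear SVM (C = 1)
   with leave-one-out cross-validation predicts the held-out trial, with
   feature standardization computed on the training fold only; single-class
   training folds fall back to majority vote.  Per-subject accuracies of
   the single and combined feature sets are compared with one-way RM-ANOVA
   plus the Tukey post-hoc above.
10. **BOLD** (`boldpls`): drift removal by discrete-cosine projection below
    1/128 Hz; evoked GLM with one HRF-convolved stick regressor per energy
    (canonical double-gamma: delays 6/16 s, dispersions 1, undershoot ratio
    1/6, 32 s support, peak-normalized); the prestimulus analysis takes the
    volume at (or immediately before — floor rule) each onset and reuses
    steps 3–6 over voxels, yielding Pos-BOLD/Neg-BOLD clusters whose mean
    onset signals feed the decoder.  Onsets in the synthetic design are
    TR-aligned, so the floor rule is exact there; interpolation is not
    provided.

## Simulation scale

Analyses in the tests and the reproduction script run on a 2 Hz x 20 ms
spectrogram grid with one EEG channel.  The 200 ms analysis window smooths
the time-frequency plane far below that spacing (resolution ~5 Hz x 200 ms),
so cluster detection is unchanged relative to the nominal 1 Hz x 1 ms grid;
the full grid remains the API default.  Cohort sizes follow the study
conditions of the simulations: 20–30 subjects x 40 trials (EEG), 16 subjects
(BOLD), 200 permutations in rate studies and 1000 in single-cohort analyses.

## What the simulations show — and what they do not

Passing recovery tests show that the pipeline detects planted prestimulus
effects of standardized size 0.5 at these cohort sizes, that its null
behaviour is calibrated (maxstat clusters, RM-ANOVA, split analysis), and
that its numerics agree with independent oracles.  They do not show that
real EEG exhibits such effects: the generator has no ocular or muscle
artifacts, no 1/f slope variation, no topographic structure beyond
attenuated channel copies, stationary burst statistics, and a rating model
that is exactly linear in the latent powers.

One quantitative observation matters for interpreting the decoding results:
with 40 trials per subject, LOOCV accuracy has binomial noise of ~8
percentage points per subject.  A combined-feature advantage of ~5 points —
about what standardized effects of 0.5 per band produce after realistic
single-trial power-estimation noise — then yields pairwise t statistics
around 2–3 at 30 subjects, so cohort-level significance of the synergy is
*frequent but not guaranteed* (observed in roughly a third of simulated
cohorts, versus ~three quarters even with noiseless ground-truth features).
Detecting the synergy reliably needs either more trials per subject or
larger cohorts; the redundant-bands control shows the complementary null
behaviour at the nominal rate.

## Known limitations

* The default mask-fixed permutation scheme does not control the
  family-wise error; use `scheme="maxstat"` when calibrated inference is
  required.
* Spectrogram estimates within half a window of the epoch edges use
  reflect-padded data and are flagged rather than removed.
* The RM-ANOVA assumes balanced complete designs; unbalanced data must be
  balanced upstream (the within-energy median split guarantees this).
* BOLD spatial preprocessing (realignment, normalization, smoothing) is out
  of scope; synthetic data are generated on the final grid.
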