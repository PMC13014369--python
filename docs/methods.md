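# Methods

## Problem setting

Intracranial EEG (iEEG) monitoring for drug-resistant epilepsy produces
multichannel recordings in which clinicians mark a subset of electrodes as
the seizure onset zone (SOZ). Two questions follow: which electrodes belong
to the SOZ, and — given a planned resection based on the labelled SOZ — will
the patient be seizure-free after surgery? This package answers both from
ictal spectral power alone.

## Preprocessing

Order is fixed: artifact-channel exclusion → notch filter → common average
reference (CAR) → epoching. CAR is computed after exclusion so artifact
channels cannot contaminate the reference. Artifact detection itself is out
of scope: the API accepts an exclusion list (clinical practice is visual
review).

The notch is a second-order IIR notch applied forward–backward (zero phase),
default 60 Hz with harmonics up to the 3rd and 2 Hz bandwidth. Zero-phase
filtering preserves the seizure-onset timing that the epoching depends on.
The filter family, bandwidth and harmonic count are this module's choices;
no specific filter is mandated by the analysis design.

Epochs: ictal = [onset, onset + 20 s), baseline = [onset − 30 s,
onset − 20 s). Time→sample mapping is floor(t·fs) with half-open intervals,
so durations are exact in samples and no resampling ever occurs. The
baseline epoch is computed and exported but not consumed by the classifiers
(features are raw ictal power); it exists for the spectral-contract checks
and for users who want baseline-normalized displays.

## Multitaper spectral estimation

Per 2.5 s window (step 0.5 s), the PSD is the unweighted mean of K = 5
DPSS-tapered periodograms at time–bandwidth NW = 3, scaled as a one-sided
density so that ∫PSD df approximates the windowed signal variance (window
means are removed first). NW and K are not dictated by the analysis design;
NW = 3 / K = 5 are the common defaults for 2.5 s iEEG windows and both are
exposed in `SpectralConfig`. Unweighted taper averaging (rather than
adaptive eigenvalue weighting) keeps the estimator exactly reproducible by a
brute-force oracle (explicit tapers × explicit DFT), which the test suite
verifies to 1e-8 relative error.

Band aggregation is a simple mean over the PSD bins in each half-open band
[lo, hi), so the six bands partition 0.5–150 Hz without double counting the
shared edges at 4, 8, 13, 30 and 90 Hz. Windows start at the epoch start and
no padding is used, giving W = floor((T − 2.5)/0.5) + 1: 36 ictal windows
and 16 baseline windows.

## Group statistics

Per seizure, electrodes split into labelled-SOZ and non-SOZ populations;
each population's mean power time series (per band) is summarized by its
trapezoidal AUC over the window-center grid. One AUC per
(seizure, group, band) is the unit of analysis — group means are computed
per seizure recording first, then contrasted across recordings. The four
contrasts (seizure-free SOZ vs SF non-SOZ, NSF-SOZ vs NSF-nonSOZ, SF-SOZ vs
NSF-SOZ, SF-nonSOZ vs NSF-nonSOZ) × six bands give 24 Bonferroni-corrected
comparisons.

The two-sample tests are Welch (unequal variance) with Welch–Satterthwaite
degrees of freedom. Welch was chosen deliberately: from the published
summary statistics of SOZ channel counts per outcome group
(14.5 ± 10.8, n = 14 vs 11.0 ± 4.7, n = 7), Welch reproduces the reported
two-sided p = 0.316 while the pooled-variance test gives ≈ 0.43.

Deciles use linear interpolation between order statistics (so the 100th
decile is exactly the group maximum). Min–max normalization maps each
(band, group, window) decile vector to [1, 10]; a degenerate all-equal
vector maps to all ones for both groups, making the ratio 1 (uninformative)
rather than undefined. Normalized ratios are therefore always in [0.1, 10].

## Stacked ensembles

Base learners: one 100-tree random forest per band (scikit-learn defaults
otherwise; no depth or feature-subsampling search, and no class
re-weighting — the PPV-constrained threshold is the imbalance control).
Meta-learner: penalized logistic regression on the six base-probability
columns. Stacking hygiene: meta-features are always out-of-fold base
probabilities from a stratified 5-fold split inside the training set
(clamped to the minority-class count when smaller); thresholds are tuned on
the cross-validated ensemble probabilities of the training set only.

Penalty strengths are stated in the glmnet convention (penalty per averaged
observation loss) and mapped to scikit-learn via C = 1/(n·λ). The electrode
model uses ridge (mixing 0) with λ chosen by internal cross-validated
log-loss over a log-spaced grid; the outcome model uses mixing 0.5 with
λ = 0.1 fixed — the decile-ratio features are already normalized, and a
mild fixed penalty avoids over-regularizing them.

Threshold tuning searches the sorted unique predicted probabilities plus a
sentinel above the maximum (an exact finite search, verified against brute
force). The electrode rule maximizes true positives subject to PPV ≥ 0.95,
ties broken toward the lower threshold; if no threshold is feasible the
sentinel is returned with a warning flag and nothing is labelled positive.
The outcome rule maximizes accuracy by default; the PPV-constrained rule is
available behind `threshold_mode="ppv"` because both tuning criteria are
defensible and the choice is exposed rather than hidden.

Cross-validation is leave-one-patient-out: all seizures and electrodes of
the held-out patient are absent from base training, meta training and
threshold tuning, enforced by a runtime audit that raises on any
patient-id intersection. Per-seizure binary calls are combined by majority
vote (positive at exactly 50%) per electrode (electrode model) or per
patient (outcome model). Baselines: a single pooled forest on all 6 × 36
features ("simple"), and the unweighted mean of the six per-band
probabilities without a meta-learner ("averaged").

A fold of the outcome CV whose training patients are single-class is
flagged and predicted with the training majority class; crashing the whole
CV for one degenerate fold would discard the informative folds.

## Synthetic cohorts — what they emulate and what they do not

Background: per-channel independent 1/f^β Gaussian noise (β = 1 default)
synthesized in the frequency domain, normalized to 50 μV RMS, plus a 60 Hz
line sinusoid of 5 μV (50 Hz selectable). Onset morphologies are additive
amplitude-modulated templates for the eight seizure-onset classes
(low-voltage fast activity and its spiking/polyspike/slow-wave variants,
rhythmic slow spikes, sharp theta/alpha, beta sharp, delta-brush), scaled to
`amplitude_gain` × the channel's background RMS, with onset at 60 s into a
90 s record so both epochs always fit. Template parameters (chirp range,
spike rates, brush frequency) are module defaults chosen to put energy in
each class's carrier bands; no quantitative morphology parameters are
claimed beyond the tested spectral contract: at gain ≥ 3 every class raises
ictal/baseline power by > 2× in at least one carrier band on injected
channels while non-injected channels stay < 1.5×.

Deliberately not modelled: volume conduction and spatial correlation between
channels, electrode geometry, propagation delays, non-stationary artifacts.
Consequently a green recovery test establishes that the pipeline extracts
band-power signatures it was designed for — not that it handles correlated
noise fields or ambiguous clinical onsets. Mislabelling (`label_noise`) is a
label *swap* (a true-SOZ label moves to a background channel) so the
labelled set keeps its size and the decile features stay defined; the
outcome rule marks a patient seizure-free iff the labelled set covers the
true SOZ, emulating "resection covered the real onset zone".

Default cohort dimensions (8 patients × 40 channels × 4 SOZ × 2 seizures,
500 Hz) keep a full leave-one-patient-out run around a minute on one CPU
while leaving every per-fold training set with both classes and hundreds of
rows. 500 Hz is the minimum sampling rate that supports the 150 Hz analysis
ceiling.

## Numerical conventions and degenerate cases

- SEM of an n = 1 group is defined as 0; empty groups are rejected.
- Zero-variance Welch inputs: equal means → p = 1; unequal → p = 0 with
  infinite t (flagged by sign).
- Confusion metrics are exact rationals; any zero denominator yields an
  undefined flag (None), never a silent 0. Percentages round half away from
  zero at one decimal.
- ROC AUC is the midrank Mann–Whitney statistic; exact against pair
  counting, including ties.
- Forest feature importances are impurity-decrease values normalized to sum
  to 1 within each band; an all-zero importance vector falls back to
  uniform. Per-band sum-to-one is this package's convention for the
  importance-over-time display.

## Known limitations

- Determinism of the full pipeline is per-platform (BLAS/fft reductions);
  all stochastic components are seeded and runs are reproducible on a fixed
  platform.
- The published clinical headline numbers (prediction thresholds near 86%
  and 74%, per-band meta coefficients, outcome AUC) are properties of a
  specific multi-centre dataset and are not reproduction targets for the
  synthetic world; the acceptance suite instead checks oracle equivalence
  and ground-truth recovery.
- Recordings are read/written only in the plain dialect (numeric matrix +
  JSON sidecar + events.tsv); vendor formats require conversion upstream.
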