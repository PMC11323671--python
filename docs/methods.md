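# Methods

`ehrsyneval` evaluates synthetic longitudinal electronic health records
(EHRs) against real ones along three axes: **fidelity** (does synthetic
data look like real data?), **utility** (can it replace real data in
downstream clinical prediction?), and **privacy risk** (does it leak real
patients' sensitive attributes?).  A record is a row of static patient
attributes (age, gender, race, deceased — categorical attributes carry an
explicit `unknown` missing-category) plus one variable-length sequence of
ICD-9 diagnosis chapters.  Of the 17 numeric-code ICD-9 chapters, the
three essentially absent in an ischaemic-heart-disease cohort
(pregnancy/childbirth, congenital anomalies, perinatal conditions) are
omitted, leaving a 14-class sequence vocabulary; V/E supplementary codes
are treated as unmapped and excluded from sequences.

## The cohort simulator

Because evaluation metrics can only be validated against data whose
ground truth is known, the package ships a simulator rather than relying
on credentialed hospital extracts.  It mirrors the two-step structure of
attribute-conditional sequence generators:

1. **Static attributes.** Age ~ truncated normal (default mean 71 y,
   SD 11 y on [18, 100], matching an elderly cardiac cohort); gender and
   race from configurable probability vectors, race carrying an `unknown`
   mass of 0.11 by default (the level of race missingness typical of
   critical-care registries); in-hospital death from a logistic link on
   standardized age, P(deceased) = sigmoid(b0 + b1·(age − mean)/SD),
   default b0 = logit(0.10), b1 = 0.8.
2. **Sequences.** Each patient is assigned one of (by default) four
   strata defined by gender × age-above/below-mean, and a chapter
   sequence is drawn as a first-order Markov chain from that stratum's
   14×14 transition matrix, with an independently drawn length.  Default
   matrices mix a self-transition diagonal, a pull toward the circulatory
   chapter, and a reproducible stratum-specific random component, so
   sequences depend learnably on attributes (which the TSTR and attack
   calibrations can switch off via `n_strata=1`).  Lengths follow a
   discretized truncated normal on [5, 37] (mean 15, SD 7): the support
   is the one the data model guarantees; the shape within it is a
   modeling choice, not an empirical claim.

All randomness flows from one integer seed through named SHA-256-derived
substreams (`named_rng`), so each stage is independently reproducible and
identical (config, seed) pairs give byte-identical cohorts.

Two injectors create failure modes with known ground truth.
`inject_mode_collapse(k)` resamples the whole cohort with replacement
from k prototype records — realistic marginals, destroyed variety.
`perturb_config(shift)` mixes every transition matrix toward a
column-permuted reference with weight `shift`, a one-parameter family of
distribution shifts from none (0) to a fully redirected chain (1).

What the simulator does **not** emulate: within-patient non-Markovian
history effects, co-occurring diagnoses per admission, informative
sequence truncation, measurement noise in age, or correlations between
race and outcomes.  Passing calibration here therefore shows the metrics
behave correctly when their assumptions hold; it does not certify
behavior on real hospital data.

## Distances for mixed-type longitudinal records

Static records are compared with **Gower distance**: range-normalized
absolute difference |x−y|/range for numerics (ranges always computed on
the pooled real∪synthetic data, so distances are comparable across
origins; a zero pooled range contributes 0), 0/1 mismatch for
categoricals, averaged over features.  Note the known asymmetry of
Gower: a categorical feature contributes its maximum (1) on *any*
mismatch, so categorical differences tend to overshadow numeric ones.

Sequences are compared with **dynamic time warping** under the same
Gower local cost (0/1 for the single categorical chapter feature).  The
alignment is monotone, continuous, and anchored at both endpoints
(classic diagonal/up/right step pattern, no window), and the cumulative
cost is divided by the geometric mean √(len_a·len_b), which penalizes
length disparity more heavily than arithmetic-mean scaling.  DTW is a
pseudo-metric: it is symmetric and non-negative with zero self-distance,
but distinct sequences can be distance 0 and the triangle inequality
fails; nothing downstream assumes otherwise.

The combined record distance averages the two parts with the whole
sequence counting as one extra feature: weight 1/(k+1) for k static
features (0.2 by default).  This is the least-surprising reading of
"averaging static and sequential distances" and is exposed as a
parameter.  The pairwise kernel is numba-compiled; a plain-NumPy DTW
remains the reference implementation and the tests cross-check the two.

## Low-dimensional projections and the mixing score

tSNE and UMAP embed the pooled distance matrix in 2-D in
precomputed-distance mode, random initialization, fixed seed (data-space
initialization is unavailable when only distances are given, and
initialization is a known driver of differences between the two
algorithms).  The neighbor-count hyperparameter (perplexity in tSNE,
`n_neighbors` in UMAP) is exposed under one name and swept over
{15, 25, 50}, six panels by default.  Secondary hyperparameters stay at
library defaults and are recorded in the run log.

Visual overlap judgments are made testable by the **mixing score**: the
mean over synthetic points of the fraction of their k nearest 2-D
neighbors that are real.  Under perfect mixing with equal pool sizes it
concentrates near 0.5; complete separation drives it to 0; mode collapse
(dense synthetic clouds embedded inside the real cloud) pulls it down by
crowding each synthetic point's neighborhood with its own duplicates.

## Classifier two-sample goodness-of-fit

Pooled records get the binary origin label z (1 = synthetic).
Approximating the posterior p(z|X) by minimizing cross-entropy is
equivalent to the variational approximation of that posterior, so the
package trains an ordinary binary classifier and never implements the
variational form separately.  Held-out accuracy near 50% means the model
class cannot tell the datasets apart; high accuracy certifies a
difference.  The converse is weaker — a chance-level classifier does not
prove equality of the joint distributions, only that this model family,
through a univariate compression, finds no difference — which is why the
held-out *prediction distributions* are also tested (two-sample
Kolmogorov–Smirnov, asymptotic p) and plotted as Gaussian KDEs with
Scott's-rule bandwidth.  Concentrated synthetic prediction mass is the
univariate signature of mode collapse.  A multidimensional latent
extension (VAE encoder + multivariate GoF test) is a documented
extension point, not implemented.

Cross-validation is 10-fold, stratified on z; each fold's training split
donates 10% (stratified) to validation for early stopping.  KS is
computed per fold on that fold's held-out predictions — pooling folds
would correlate samples — and the headline p is the median across folds,
with every fold reported.  Accuracy uses the fixed 0.5 threshold;
calibration designs use equal-size pools so the threshold is fair.

## The recurrent backbone

One architecture serves the discriminator, both TSTR tasks and the
attack model: a dense ReLU branch for static inputs (min-max-scaled
numerics, scaler fitted on training data only; one-hot categoricals
including `unknown`) and a GRU branch over the one-hot chapter sequence,
concatenated into a joint ReLU layer feeding the output head(s) — binary
sigmoid, multiclass softmax, or scalar regression trained with absolute
error so the reported MAE matches the objective.  GRUs rather than LSTMs
because sequences are short (≤ 37 steps); chapter embeddings are one-hot
because a 14-symbol vocabulary does not warrant learned embeddings.

The network is implemented directly on NumPy arrays in float32 with
manual backpropagation through time (the recurrence compiled with
numba), Adam, and early stopping on validation loss with
best-state restoration.  Padding steps are identity updates under the
mask and are skipped outright, so the recurrent summary is exactly the
state after the last valid step and appending padding can never change a
prediction.  Default sizes — GRU 32, static branch 16, joint 32, batch
256, ≤ 60 epochs, patience 8, learning rate 3e-3 — train in a few
seconds on cohorts of a few thousand patients on one CPU; the replicated
calibration studies in the test suite shorten the schedule (≤ 12 epochs,
patience 3), which the null/power results show is already converged for
those designs.  Training is single-threaded-deterministic: identical
(spec, config, seed, data) reproduce identical parameters.

## Utility: train-synthetic-test-real (TSTR)

Two tasks compare a real-trained against a synthetic-trained model, both
scored on real held-out folds. **Mortality**: binary prediction of the
deceased flag (excluded from inputs) from the remaining statics plus the
sequence; folds stratified on the label; metric is rank-based
(trapezoidal) AUC. **Next-step diagnosis**: every patient contributes
one instance per prefix of length ≥ 1 (full prefix + statics → next
chapter); folds split by *patient*, never by instance, so no patient's
prefixes straddle a fold boundary; metric is 14-class accuracy.  The
synthetic-trained model uses the full synthetic dataset — mirroring how
released synthetic data would actually be used — and, because that
training set does not vary with the fold and training is deterministic,
is trained once and scored on every fold.

## Privacy: attribute inference attack (AIA)

Threat model: the adversary holds incomplete real records and the
released synthetic dataset, but not the generative model.  For each of
the 7 non-empty subsets of {age, gender, race}, one shared backbone with
a head per sensitive feature is trained on synthetic records using every
feature *not* in the subset (including deceased and the sequence), then
evaluated on 10 folds of the real data (the synthetic training set is
not folded; the real evaluation set is).  Age is scored as MAE in years,
gender/race as accuracy, each against a naive baseline computed on real
data: the mean-age predictor's MAE and majority-class accuracy.  Attack
metrics near baseline mean the synthetic release adds essentially
nothing to what marginals already reveal.

## Calibration designs and problem sizes

The statistical guarantees in the test suite use these fixed designs
(all sizes chosen as the smallest at which the quantities are stable):

- **Discriminator null**: 20 replicates of a 2000-patient default cohort
  split into iid halves; mean 10-fold accuracy must sit in [0.45, 0.55]
  and per-fold KS rejections at α=0.05 at most 15%.
- **Power**: 20 replicates of default vs `shift=0.3` cohorts (1000 per
  side); detection = mean accuracy ≥ 0.60 with all fold KS p < 0.01,
  required in ≥ 18/20.  Mode collapse (k=3) must give accuracy ≥ 0.70
  with > 80% of synthetic predictions above 0.5.
- **TSTR sanity**: a copy-of-real synthetic set must match the
  real-trained model within 0.02 per fold on both tasks.  The designs
  saturate their signals (mortality slope 5 on standardized age;
  transition rows dominated by self + circulatory transitions) so both
  models converge to the same Bayes ranking — with weak signals the
  per-fold metric noise itself exceeds 0.02.  Zero-signal twins
  (slope 0, uniform transitions) must sit at AUC 0.5 and accuracy 1/14
  within 3 SEs.
- **AIA**: with sensitive attributes independent of everything
  (`n_strata=1`, slope 0), attack accuracy must stay within ±0.05 of the
  majority baseline and MAE within [0.9, 1.2]× the mean-predictor MAE
  (10 replicates); with a deterministic leak (age = 20 + sequence
  length in both cohorts) the attack MAE must fall at least 5× below
  baseline.

## Numerical choices and degenerate inputs

Distances validate symmetry to 1e-12 with exact zero diagonals; simplex
inputs (probability vectors, transition rows) must sum to 1 within 1e-9.
Binary predictions are clipped to (1e-7, 1 − 1e-7) before the
cross-entropy.  A KDE over constant predictions has no bandwidth under
Scott's rule and raises with guidance rather than returning a
degenerate curve.  Ties in nearest-neighbor queries resolve by index
order; the self-point is excluded explicitly (coincident points make
"self is nearest" unreliable).  Mortality TSTR refuses a single-class
deceased column; the next-step task refuses cohorts with no sequence of
length ≥ 2; `split_holdout` refuses empty parts.

## Known limitations

- The simulator's first-order Markov sequences cannot probe metrics'
  sensitivity to longer-range temporal structure.
- The GoF test inherits the classifier-two-sample caveat: chance-level
  accuracy is evidence of similarity only relative to the model class.
- The AIA is one attack; a stronger adversary (different architecture,
  auxiliary data) could extract more, so baseline-level results bound
  *this* attack's risk, not all risk.
- Runtime of the pairwise DTW matrix is quadratic in pooled cohort size;
  projections are intended for cohorts of a few thousand records.
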