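# Methods

## Scope and model of the data

`trajbench` benchmarks binary time-series classifiers on semi-synthetic
cohorts of short clinical-measurement trajectories: yearly sampled series of
at most 16 points shaped like BMI, fasting glucose, or systolic blood
pressure curves.  The premise is that electronic-health-record measurement
series have strong serial correlation and characteristic data pathologies
(missing visits, irregular spacing, outcome imbalance), and that classifier
robustness to these should be measured where the ground truth is known.
Each simulated cohort plants a controlled two-class signal on top of a
single reference curve and then degrades the data along those axes.

## Reference trajectories

A reference is one prepared measurement series: interior gaps are filled
with the mean of the nearest observed neighbours, boundary gaps carry the
nearest observation outward (consistent with the LOCF/LOCB convention used
downstream), and the series is divided by its median (even length: mean of
the two middle order statistics).  Because real patient curves are rarely
shareable, a generator produces synthetic stand-ins: a cubic trend with
random coefficients plus window-3 moving-average-smoothed Gaussian noise,
clipped to a physiologic range per measurement kind (BMI-like 15-40,
glucose-like 70-200 mg/dL, SBP-like 90-160 mmHg).  The construction keeps
lag-1 autocorrelation above 0.5 (in practice above 0.9), the property of
real series that the simulation is meant to preserve.  Six references per
measurement kind are generated and seed cohorts round-robin, so any one
cohort inherits the correlation structure of a single curve.

## Cohort simulation

**Magnitude cohorts.** Each trajectory is the reference plus one additive
per-individual offset: class 0 offsets ~ Normal(0, σ), class 1 offsets ~
Normal(δ, σ).  δ (effect size) is the difference of class means; σ
(dispersion) generates distributional overlap.  A single offset per
trajectory preserves the reference's shape, so the two classes differ in
level only.

**Shape cohorts.** The reference is summarized by least squares on a
ten-column orthonormal polynomial basis (QR of the Vandermonde matrix of
the centered time grid, constant column removed, signs fixed by the
trailing element).  A permutation screen finds the most shape-influential
coefficient: each coefficient j is re-drawn 1000 times from
Normal(c_j, |c_j| + 1e-6) and the mean squared error of the rebuilt curve
against the original fit recorded; the largest mean MSE wins, ties to the
lowest index.  One standard-normal draw vector is shared across
coefficients (common random numbers), which makes equal perturbation
scales tie exactly and reduces Monte-Carlo noise; under the orthonormal
basis the expected MSE is (|c_j| + 1e-6)^2 / T, so the screen is in effect
a magnitude ranking, which is the intended behaviour of a "most influential
coefficient" search.  Cohorts then re-draw that coefficient per individual
from Normal(0, σ·s) (class 0) or Normal(δ·s, σ·s) (class 1), with
s = |c_j*| (RMS of all coefficients if c_j* = 0) so the shared δ/σ grids
are meaningful on the coefficient's own scale.  Because basis columns are
orthogonal to the constant, modulation changes shape but not the series
mean.

**Condition grids.** Effect sizes {0.25..2.75 step 0.5}; dispersions
{0.25..2.0 step 0.35}; missingness {0, 10, 25, 50}% (exactly round(m·T)
uniformly chosen points dropped per trajectory); irregularity none /
moderate / high, with per-individual dropped-visit counts drawn from
scaled betas — Beta(2,4) on [0,3] (mean 1) and Beta(4,2) on [2,5]
(mean 4), rounded to integers, never removing the last observation;
imbalance ratios {1, 0.75, 0.5, 0.25} by down-sampling class 1 to
round(r·n_class0).  Degradations compose in that order.  Cohorts hold up
to 2000 trajectories per class.

**Class overlap.** A trajectory overlaps when its value lies inside the
opposite class's [min, max] envelope at every time point; overlap is the
overlapping fraction of all trajectories, computed before missingness.
For per-individual offset signals this reduces to the offset falling inside
the opposite class's offset range, so overlap is a monotone function of
δ/σ at a given cohort size — which is why the benchmark's overlap-binned
claims are statements about separability.  Note the envelope width grows
with cohort size (extreme order statistics), so overlap must be measured
at the intended cohort size; the desk-scale runner therefore simulates at
2000/class and subsamples afterwards for training.

## Preprocessing

Gaps are imputed by last observation carried forward (backward for a
missing head).  Cohorts are split 70/30 into train+validation and test,
stratified by class; k folds (3 for simulated cohorts; a single 25%
validation holdout in desk-scale runs) partition the training portion; 20%
of training rows are flagged for hyperparameter tuning.  Training is
balanced by down-sampling the majority class inside the training partition
only; validation and test keep natural imbalance.  Normalization
statistics are computed per time point on training rows only and applied
everywhere (executable order imputation → split → normalization, so no
test-set statistic leaks into features): z-scoring for raw and
interval-feature inputs, min-max for the angular-field encoder.

## Feature front-ends

**Interval statistics (time-series-forest style).** 64 random contiguous
intervals (uniform start, uniform length ≥ 3) are drawn once per cohort
and shared by all samples; each contributes mean, sample standard
deviation (n−1), and OLS slope, giving a 3-channel sequence ordered by
interval start so that 1-D convolutions see spatially coherent features.

**Gramian angular summation field.** The series is min-max rescaled and
encoded as angles φ_t = arccos(x̃_t); the image is
G[i,j] = cos(φ_i + φ_j) = x̃_i x̃_j − √(1−x̃_i²)√(1−x̃_j²), with diagonal
2x̃² − 1.  The rescale target is [0, 1], not [−1, 1]: the summation field
is invariant to a global sign flip (arccos(−x) = π − arccos(x) leaves the
cosine of summed angles unchanged), so a symmetric [−1, 1] rescale maps a
level-shifted class and its mirror image to identical pictures and erases
exactly the signal a magnitude cohort plants.  With [0, 1] the encoding is
injective; in measurements on an easy magnitude cohort the image
classifier's AUC moves from 0.55 (aliased) to 0.97 (injective) while the
diagonal identity and reconstruction property are unaffected.  The
general-purpose min-max normalizer still defaults to [−1, 1]; only the
angular-field input pipeline requests [0, 1].

## The classifier zoo

Nine architectures share a 2-unit softmax head (class-1 probability is the
reported score): an MLP (3 × 500 ReLU units, dropout 0.1/0.2/0.3), a fully
convolutional network (128/256/128 filters, lengths 8/5/3, global average
pooling), the MLP and a six-layer 1-D CNN (32,32,32,32,64,128 filters,
length 3, max-pool stride 2 after layers 2 and 4) on interval features, a
six-layer 3×3 2-D CNN with the same filter plan on angular-field images, a
three-block residual network (64/128/128 filters, kernels 8/5/3, batch
norm, shortcut additions), a parallel LSTM + convolutional network with
concatenated heads, a convolutional-recurrent hybrid (32→64 filters into a
64-unit LSTM with dropouts 0.1/0.5), and a 4-layer Transformer encoder
(multi-head self-attention + feed-forward, residual connections, layer
norm, dropout, sinusoidal position encoding, default 4 heads × size 8).
Networks whose trunk ends in global average pooling (FCNN, ResNet) have
parameter counts independent of series length; the MLP's first layer does
not.

No deep-learning framework is used: the layers run on a small reverse-mode
autodiff engine over float32 numpy arrays (im2col convolutions, explicit
LSTM step loop, fused softmax cross-entropy), which is ample for series of
≤16 points and keeps the package self-contained.  Gradient correctness is
pinned by central-difference checks in the test suite.

**Training protocol.** Adam (Adadelta available by configuration),
initial learning rate 1e-3, binary cross-entropy through the 2-unit
softmax.  The learning rate is multiplied by 0.92 whenever the training
loss fails to improve for three consecutive epochs; training stops early
after 15 epochs without validation-AUC improvement, hard cap 500 epochs
(desk scale: 100); the best-validation weights are
restored, and per-epoch loss/AUC/learning-rate traces are retained so the
schedule can be audited.  Hyperparameters (dropout, batch size; kernel
size and widths for CNNs; dense size for MLPs; LSTM size; heads, head
size, feed-forward width, learning rate for the Transformer) are searched
with a successive-halving bandit on the 20% tuning subset: sampled
configurations are trained briefly, the top third survives with threefold
more epochs, up to a configurable evaluation budget (100 at full scale).

## Statistical evaluation

AUC is the primary metric (Mann-Whitney concordance, ties half).  Model
comparison across conditions uses the Friedman rank test on the
conditions × models AUC table (fold-averaged test AUCs, one row per
cohort) with the Nemenyi critical difference
CD = q_α √(k(k+1)/(6N)) at α = 0.05 as post-hoc, rendered as a
critical-difference diagram.  Paired AUC comparisons on a shared test set
use DeLong's placement-value test (two-sided normal reference), with
Benjamini-Hochberg adjustment across comparisons.  Overfitting is
summarized as mean (train AUC − test AUC) per architecture.  The test
suite verifies DeLong against a 10,000-resample paired bootstrap and its
type-I error under a simulated null, and the Friedman p-value's uniformity
under a column-exchangeable null.

## Observation-window pipeline

The growth-record pipeline emulates predicting a later-childhood outcome
from early BMI: per-visit height/weight records (ages 2-18) pass
record-level plausibility bounds (height ≤25 or ≥100 in, weight ≤5 or
≥1000 lb excluded) and patient-level modified z-score exclusions (weight z
outside (−5, 8], height z outside (−5, 4], BMI z outside (−4, 8]) against
packaged age-sex reference tables — synthetic stand-ins for national
growth references, pluggable with real tables.  Height and weight are
smoothed per individual by local linear regression with a
generalized-cross-validation-selected bandwidth (series under 4 points pass
through flagged), BMI = 703·lb/in² is computed, trajectories are averaged
into integer-year segments with interior gaps linearly interpolated and no
extrapolation, and case records at/after outcome onset are dropped.  One
dataset is built per observation window [a, b] with 2 ≤ a < b ≤ 12 (the
window list is configuration; the default enumerates all 55), keeping
patients with full coverage; the outcome is assessed in the fixed 13-18
prediction window.  Window AUCs are compared to the best window with
DeLong on the intersection of test patients and BH adjustment.

The synthetic record generator plants the outcome signal as an elevated
BMI-trajectory z-slope in cases (0.22 z/year versus 0 for controls, case
prevalence 6.6%), with irregular visit spacing and a small implausible
fraction to exercise QC.  It emulates level and slope structure of real
growth data, but not secular trends, sibling correlation, informative
(outcome-dependent) visit frequency, or measurement-device artifacts — so
a passing pipeline demonstrates mechanical and statistical correctness,
not clinical performance on real records.

## Desk-scale reproduction sizes

The full benchmark grid (12,672 cohorts × 9 models, 3-fold CV, 500-epoch
caps) is cluster-scale.  The packaged acceptance runner reproduces the
headline claims at workstation scale, as the package's own choice of
problem size: cohorts simulated at 2000/class (so overlap filters keep
their intended geometry) and subsampled to 250/class (150/class for the
imbalance sweep) for training; a stratified Latin-transversal sample of
the 6×6 effect/dispersion grid plus three high-separation cells for the
overlap-filtered claims; a single validation fold; epoch cap 100 with the
protocol's patience-15 early stopping; default hyperparameters except the Transformer's
attention geometry, which is tuned with a small bandit budget.  Seeds fix
every random draw end to end.

## Known limitations

* The per-individual offset/coefficient signal makes the best achievable
  AUC Φ(δ/(σ√2)) for any classifier; grid-averaged summaries are therefore
  bounded by the grid average of that quantity (~0.81), which matters when
  comparing against aggregate summaries computed under other generative
  conventions.
* Wall-clock training-duration accounting is recorded per run but is
  hardware-dependent and never asserted.
* The numpy engine is single-threaded GEMM-bound; it is sized for T ≤ 16
  series, not images or long sequences.
* Synthetic references and growth tables are stand-ins; conclusions about
  real EHR data require re-running with real reference inputs.
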