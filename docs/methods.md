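# Methods

`sozmark` implements a seizure-onset-zone (SOZ) marker pipeline for
intracranial EEG and a surgical-outcome predictor built on top of it. This
note records the models, the defaults and why they are what they are, what
the synthetic cohort does and does not emulate, and the numerical
conventions a maintainer would need.

## Signal standardization

All recordings are resampled to 512 Hz (polyphase), notch-filtered around
the 60 Hz mains line (fourth-order Butterworth band-stop, 59–61 Hz) and
band-pass filtered 0.5 Hz–0.999×Nyquist with a fourth-order Butterworth.
Both filters are applied forward–backward (zero phase); whether the original
processing chain was zero-phase is unknowable from its description, and the
zero-phase choice avoids injecting filter latency into windowed markers. The
band edge sits just below Nyquist because an analog-prototype Butterworth
cannot be designed exactly at Nyquist. The analysis epoch runs from 30 s
before the annotated seizure onset to the seizure end; records starting
later than that are clamped to the record start and flagged.

Two sliding-window schemes cover the epoch: 250 ms windows with 125 ms step
for the fragility marker (128 samples, enough for least squares on ≤ ~100
channels) and 2.5 s windows with 500 ms step for everything else. Trailing
partial windows are discarded — fragility's least-squares fit needs a
constant per-window sample count — so window counts follow
`floor((T − L)/S) + 1`.

## The 21 markers

**Neural fragility.** Each 250 ms window is fit as a linear one-step system
x(t+1) = A x(t) (A = X₁X₀⁺ by least squares over the window's transition
pairs; rank-deficient windows fall back to ridge with
α = 1e−6·tr(X₀X₀ᵀ)/N and a warning). The fragility of channel j is the
minimum Euclidean norm of a perturbation confined to column j of A that
places an eigenvalue at a target σ+iω on the unit circle. Writing
r = eⱼᵀ(A−λI)⁻¹, the matrix determinant lemma reduces eigenvalue placement
to the single complex constraint r·d = −1; stacking it as B = [Im r; Re r],
b = (0,−1)ᵀ gives the least-norm solution d = Bᵀ(BBᵀ)⁻¹b with
‖d‖² = bᵀ(BBᵀ)⁻¹b. Real targets use the single real constraint. The
constraint's sign convention is not taken on trust: the test suite asserts
that eig(A + deⱼᵀ) actually contains the target (1e−6) and that no feasible
perturbation sampled in the constraint space is shorter.

The target grid is 21 angles on the closed upper half of the unit circle
(radius 1.0 — marginal instability). For real A the conjugate target yields
the same minimal norm (the sign flip of the Im row leaves b and the norm
invariant), so the lower half-plane is covered for free. Per window the
channel score is the minimum over the grid, then inverted and normalized as
(max−d̂)/max ∈ [0,1]: most fragile channel highest, least fragile 0.

**Six band powers.** Delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–90, high-gamma 90 Hz–Nyquist (high-frequency oscillations fall in this
last band). Per 2.5 s window and channel: mean magnitude of the plain
(untapered) DFT over the band's bins — the defining transform is a plain
Fourier integral, so no taper by default; `mode="power"` averages |F|²
instead, since "average value" is ambiguous between the two. Bands are
half-open [lo, hi) so they tile the spectrum without overlap; the top band
includes the Nyquist bin. Columns are min-max normalized across channels
within each window (constant columns map to zeros by convention).

**14 centrality markers.** Connectivity is Pearson correlation (time
domain) or band-averaged magnitude-squared coherence
|G_ij|²/(G_ii·G_jj) (frequency domain), with cross-spectra estimated by
Welch averaging — 256-sample (0.5 s) Hann segments, 50 % overlap — inside
each 2.5 s window; scaling constants cancel in the quotient, and the
implementation is pinned to `scipy.signal.coherence` by test. Each basis
(correlation, or coherence in each of the six bands) feeds weighted degree
centrality (off-diagonal row sum / (N−1)) and eigenvector centrality
(leading eigenvector, unit norm, nonnegative orientation; power iteration
on W + sI with s = max row sum so the Perron pair dominates, dense `eigh`
fallback, tol 1e−10). Correlation weights enter as absolute values —
centralities need nonnegative weights for Perron–Frobenius to apply — and
the N in the degree denominator is the full node count, since these graphs
are dense and weighted. Degree maps are min-max normalized per window;
eigenvector maps are not (their columns already carry unit Euclidean norm,
and rescaling would break the fixed-point reading). That yields the
registry: 1 fragility + 6 spectral + 7 degree + 7 eigenvector = 21. The
per-family enumeration is an interpretation — the families and the total
are fixed, but no source lists all 21; this decomposition is the only one
consistent with correlation as a time-domain and coherence as a six-band
frequency-domain measure.

## Per-patient features and the hybrid marker

For outcome prediction the resected channels are treated as the
clinician-recognized SOZ. Per marker, values are summed per window over the
resected group and over its complement ("accumulate" is read as a sum; a
mean would differ only by the group-size factor), and each series
contributes its quantiles at levels 0.1, 0.2, …, 1.0 (linear
interpolation), resected block first: a 20-vector per marker and patient.

Per marker, training-set PCA keeps the smallest component count whose
cumulative explained-variance ratio reaches 0.85; means and loadings are
frozen and applied to held-out patients (no leakage, asserted by test). The
hybrid marker concatenates the reduced features of the seven retained
markers — fragility plus the six band powers — standardizes on the
training split, and keeps the support of an L1-penalized (LASSO) regression
of the outcome: 50 log-spaced penalties in [1e−4·λ_max, λ_max], 5-fold CV,
minimum-error rule. PCA-then-LASSO rather than LASSO on the raw 7×20
features is a genuine ordering choice (each marker "first undergoes feature
extraction"); the raw ordering remains available by composing the same
operations. When the CV support is empty — which a shuffled-label null
produces by design — the pipeline falls back to the full concatenated
feature set so the null accuracy remains measurable; the `assemble_hybrid`
operation itself still rejects an empty support.

## The GA-trained network and baselines

The classifier ("GNN", genetic neural network — not a graph network) is a
single-hidden-layer perceptron: logistic(W₂·tanh(W₁x+b₁)+b₂), hidden width
10. Its flat weight vector is the individual of a real-coded genetic
algorithm minimizing fitness = max{MSE_train, MSE_test}, where both mean
squared errors are class-weighted (weights inversely proportional to class
frequency, guarding against outcome imbalance) and the test term is the
repeat's held-out 10 % split. Operators: tournament selection (k = 3),
arithmetic-blend crossover (rate 0.8, α ~ U(0,1)), per-gene Gaussian
mutation (rate 0.05, sd 0.05), elitism 2, population 50, 200 generations,
init U(−0.5, 0.5). The search domain is the box [−1, 1]^L (mutations
clipped): with standardized inputs and tanh units, bounding the weights
keeps the represented functions smooth, which is the only regularization
the MSE fitness gets — its test term averages only a handful of patients,
and unbounded weights let sharp overfit boundaries win it. A probability
above 0.5 — strictly — predicts surgical success.

The six baselines (logistic regression, decision tree, backprop MLP with
the same 10-unit hidden layer, SVM, Gaussian naive Bayes, k-NN) are
scikit-learn estimators behind a uniform fit/predict-probability interface,
class-weighted where supported, with explicit configured hyperparameters
(no internal search).

## Experiment protocol and statistics

A fixed 20 % verification set (lock box, round(0.2n) patients) is drawn once
per experiment; the remainder is re-partitioned 7:1 into training and test
sets on each of 10 repeats (n = 79 gives 16/55/8). Feature reducers and the
LASSO are refit on each repeat's training split only. Each of the 21×7 =
147 marker×model combinations reports mean accuracy on the pooled
training-test patients and on the verification set; combinations in the
top 25 % of both rankings are intersected. Everything is deterministic
given the master seed (per-combination seeds derive from it via CRC32 +
SeedSequence), which the test suite checks bit-for-bit.

Paired tests: exact-binomial McNemar on discordant correctness (two-sided
p = 2·P(X ≤ min(b,c)), X ~ Bin(b+c, ½), capped at 1; p = 1 with no
discordance), with per-patient majority vote across repeats as the pooling
rule on the verification set; DeLong's test for correlated AUCs via the
structural-components variance (zero variance → p = 1), cross-checked
against a bootstrap in the tests; Mann–Whitney U for covariate effects
(exact for ≤ 20 untied observations, tie-corrected normal approximation
otherwise, p = 1 for all-tied input); ROC/AUC with half-credit ties,
identical to the normalized Mann–Whitney statistic by construction.

## The synthetic cohort

Each patient is a VAR(1) process driven by unit white noise. The
background transition matrix has diagonal persistence U(0.3, 0.9) plus weak
off-diagonal coupling (scale 0.4 before rescaling to spectral radius 0.9):
mostly autonomous channels with moderate cross-talk, which keeps baseline
inter-channel coherence low the way background iEEG is. At onset the
intra-SOZ block is boosted (×1.5) and the matrix rescaled to radius 0.99 —
near-marginal instability with the dominant mode localized on the SOZ — and
the SOZ channels additionally receive 40–80 Hz band-limited activity (sd 3
relative to unit noise) drawn from a shared generator (amplitude fraction
0.8) plus a per-channel remainder, so they gain both gamma power and mutual
gamma-band coherence. Resection masks implement the outcome mechanism:
intended successes resect the whole SOZ plus up to two extra channels;
intended failures overlap it by at most half; the recorded label is the
overlap rule's verdict (≥ 90 % coverage = success) flipped with probability
`label_noise`. Sex and handedness are drawn independently of outcome, so
covariate tests face a true null. Defaults: 60 patients, 16 channels, 4
SOZ, 40 s pre-onset, 60 s seizure, success rate 0.55.

What passing tests on this cohort show — and what they do not: the
generator reproduces the statistical structure the markers assume
(post-onset destabilization, SOZ-confined gamma and coherence elevation,
outcome tied to resection/SOZ overlap), so end-to-end results demonstrate
that the pipeline recovers a signal of that form. It contains no seizure
biophysics, no artifacts, no electrode geometry, no volume conduction and
no patient heterogeneity beyond sampling noise, so accuracies on it say
nothing quantitative about clinical cohorts.

## Problem sizes and numerical conventions

The shipped end-to-end experiment uses the 60-patient default cohort with
label noise 0.1 and ten protocol repeats; the determinism check runs all
147 combinations on a 20-patient cohort with 10 s seizures and a reduced GA
budget (population 16, 30 generations) — sizes chosen so the whole suite
runs comfortably on one CPU. Null calibration averages the GA network's
verification accuracy over several independent label shuffles because a
single 12-patient lock box quantizes accuracy in steps of 1/12.

Degenerate inputs are handled by stated conventions rather than NaNs:
constant vectors min-max-normalize to zeros; zero-variance channels get
zero correlation entries (unit diagonal) with a warning; a window whose
entire target grid fails is flagged missing; all-tied rank tests return
p = 1. HDF5 is the internal container because EDF quantizes to 16 bits and
would break bit-exact round trips; EDF is read-only.

## Known limitations

The fragility target grid, taper choice, quantile levels, GA operators and
baseline hyperparameters are defensible defaults, not uniquely determined;
all are exposed in config. Eigenvector centrality of a near-regular graph
is weakly informative (its fixed point is nearly flat). The LASSO
minimum-error rule on small cohorts often keeps very few features, which
caps every downstream classifier; that behavior is inherent to the
prescribed construction, not a bug. Verification-set accuracy on small
lock boxes is dominated by which patients (and which noisy labels) land in
them — the per-repeat spread reported alongside means should always be
read together with them.
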