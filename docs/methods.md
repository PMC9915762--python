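# Methods

`valuebind` implements, end to end and on synthetic data, an analysis of how
neural populations bind offer value to spatial position through
semi-orthogonal subspaces. This note records the models, the statistical
procedures, the numerical choices, and the places where the design was
genuinely open.

## The task and behavioral model

The simulated task is a two-offer risky choice: on each trial two gamble
offers appear in sequence (1000 ms stimulus onset asynchrony) on opposite
sides of a display. An offer is a probability p, drawn uniformly on a 1%
grid, and a stake s in {0.125, 0.165, 0.240} mL (safe / medium / large),
with offer kinds sampled at 12.5% / 43.75% / 43.75%. Safe offers pay with
certainty. Trial durations are lognormal with median 3.5 s and a tail width
solved so that a configurable fraction (1% by default) exceeds the 7-s
inattentiveness cutoff; the analysis filter removes those trials and all
trials containing a safe offer.

Choices follow a softmax over relative subjective value,
P(choose offer 1) = logistic((SV1 − SV2)/τ), with SV = w(p)·u(s). The model
space crosses two utilities (u(s) = s or s^α) with two probability weights
(w(p) = p or the two-parameter Prelec function w(p) = exp(−β(−ln p)^γ)),
giving four nested models. Generator defaults are α = 0.7, γ = 0.5, β = 1,
τ = 0.03: with the task's stake range this produces a suboptimal-choice
rate near 16% and choice accuracy near 84%, i.e. the regime a trained
subject occupies in this task. Models are fitted by penalized maximum
likelihood in log-parameter space (weak lognormal priors, log-SD 1.0;
10 seeded multistarts with L-BFGS-B) and compared by a Laplace
approximation to the log evidence; 95% intervals are Wald intervals from
the inverse Hessian. The Laplace route is deterministic and asymptotically
matches free-energy comparison; the prior width is the standard
weakly-informative choice and supplies the Occam factor that lets the
simplest true model win on nested simulations.

## The linear-nonlinear population code

Neural responses to the 2×2 grid of (value level, context level) — context
being spatial side or offer epoch — follow

    r(x) = L x_z + M f_N(x) + ε,    ε ~ N(0, σ² I),

with L an N×2 matrix of orthogonal columns of norms d_LV (value) and d_LA
(context), and M an N×4 matrix of mutually orthogonal columns, orthogonal
to L, each of norm m = d_N/√2, carrying the conjunctive one-hot term
f_N(x). Levels are coded ±1/2, so the centroid displacement between the two
levels of a feature equals the corresponding column norm exactly, and the
displacement between the conjunctive parts of any two conditions is exactly
d_N. Squared centroid distances are then d_LV²+d_N² (value-differing
pairs), d_LA²+d_N² (context pairs) and d_LV²+d_LA²+d_N² (diagonal pairs),
and the subspace correlation implied by the geometry is
ρ = d_LV²/(d_LV²+d_N²). The basis is built by QR-orthonormalizing seeded
Gaussian vectors, which guarantees exact orthogonality at any N (rather
than the high-N approximation a random-vector construction gives).

Binned sessions store explicit per-bin start times: 20-ms bins cannot tile
a window starting at 450 ms on a grid anchored at 0, so each 400-ms
analysis window (offer: 0–400 ms; delay: 450–850 ms, per offer epoch)
carries its own 20 aligned bins and window means are exact. Per-bin noise
is scaled by √20 so a window mean has noise SD σ.

## Single-neuron models and stacking

Window rates are z-scored per neuron and window; neurons with fewer than
300 trials or zero variance are excluded with logged reasons. Five
candidate OLS models are fitted per neuron: intercept-only, value+side with
a linear or cubic B-spline value term (3 interior knots at value quantiles;
the spline interaction multiplies side into every spline column), and the
two interaction variants. Side is effects-coded {−1, +1}; value is min-max
normalized to [0, 1].

Models are combined by stacking weights that maximize the leave-one-out log
score of the mixture. For Gaussian OLS the pointwise LOO predictive
densities are exact via hat-matrix identities, so no importance sampling or
k-fold fallback is needed; the stacking objective is concave in the weights
and solved by a single SLSQP run on the simplex. WAIC is reported per model
from draws of the asymptotic-normal coefficient posterior. Both per-model
and pooled family weights (noise / linear / interaction) are reported,
since the linear and interaction families each contain a linear-value and a
spline-value member.

The permutation ANOVA treats value as categorical over 7 quantile levels,
computes type-II F statistics through thin orthonormal design bases (so a
thousand permutations are three matrix products each), permutes the firing
rates against the joint label set, and reports
p = (#(F_perm > F_obs)+1)/(n_perm+1).

## Subspace correlations and the noise ceiling

The value vector for one side is the model-predicted population response at
value 1 minus value 0: v_side = β_value + side·β_interaction (intercept and
side main effect cancel). Similarity is the cosine; Pearson correlation is
available alongside (the two coincide for mean-zero coefficient vectors).

The separation test refits the interaction model on 1000 bootstrap trial
resamples and compares the within-resample left-right correlations against
a same-side ceiling built by pairing the first and last 500 resamples
(500 left-left + 500 right-right pairs); p is the add-one-corrected
fraction of observed ≥ ceiling pairs. One correction to the literal
construction was necessary: same-side pairs share the dataset's estimation
noise through their common center, which counts as signal and makes the
ceiling anticonservative at every SNR (matched-code data is always flagged
as separated). The same-side cross products are therefore debiased by the
bootstrap covariance trace — the same unbiasing idea as the cross-validated
distance below. After the correction, matched-code data passes at the
nominal rate in both high- and low-SNR regimes while orthogonal and
semi-orthogonal codes are still flagged at p < 0.001.

The session-to-behavior link recomputes, per bootstrap resample, both the
subspace correlation and the suboptimal-choice rate on the identical trial
set (500 resamples), correlates the two across resamples, and compares the
empirical r against a permutation null via p = 1 − Φ((r − μ)/σ). The
minimum simultaneous population is 30 neurons, with an effective-sample-size
estimate from the plateau (relative change < 5%) of coefficient variance
over random subpopulations of 5–55 neurons, 500 draws per size.

## Distance estimation and error-rate theory

Pairwise condition distances are estimated with the cross-validated squared
Euclidean estimator (crossnobis without noise whitening): trials are split
into 5 folds per condition and the estimate averages, over ordered fold
pairs, the inner product of independent fold-wise mean-difference vectors.
The estimator is unbiased (zero mean, possibly negative, under identical
distributions). The 4×4 matrix is decomposed into (d_LV, d_LA, d_N) by
nonnegative least squares — the model is linear in the squared distances,
so the optimum is exact — with a 10-start bounded refinement confirming
stability. Noise σ is the SD of within-condition residuals projected on the
unit decoder axis (the unit-projection reading of the printed normalization,
which is ambiguous between v/|v| and v/|v|²); the standard-error distance
ε is the RMS over conditions of the centroid SEM norm, scaling as σ√(N/n).

Closed-form error rates (Φ the standard normal CDF, oriented so every rate
decreases with SNR):

* binding: P ≈ N_S·Φ(−d_S/(2σ)) with d_S = √2·d_N. N_S is computed by
  enumeration over ordered stimulus tuples on the full feature grid, with
  confusable chimeric sets counted as multisets sharing the summed linear
  code; for two stimuli on the 2×2 grid the average is exactly 1/4, and the
  chance rate at d_N = 0 is 12.5%.
* generalization (CCGP): P ≈ Φ(−d_LV²/(2σ√(d_LV²+d_Nε²))) with
  d_Nε² = d_N²+ε², for a prototype decoder trained on the value contrast in
  one context and tested in the other.

Both formulas are validated against brute-force Monte-Carlo oracles on 3×3
parameter grids at 100,000 samples per cell: a maximum-likelihood decoder
over all candidate two-stimulus multisets (ties broken uniformly) for
binding, and a prototype decoder for CCGP. Agreement is within two
Monte-Carlo standard errors per cell. The binding union bound counts only
chimeric confusions, so it is tight when the scaffold distances are large
relative to the noise (each presentation then has at most one competitive
confusable alternative); at small d_LV, d_LA the ML decoder loses errors to
non-chimeric candidate sets and the formula overestimates the chimeric rate
— the oracle grids use d_LV = d_LA = 8 to sit in the regime the derivation
assumes. The adopted constant d_N = √2·m (where m is the column norm of
M) is the reading consistent with the pairwise-displacement algebra and is
confirmed by the oracles. The oracles also confirm the two independence
claims: the binding rate does not move with d_LV, and the CCGP rate does
not move with d_LA.

## Decoding

Value is binarized by midpoint-rank percentiles: low below the 35th, high
above the 65th, the middle 30-percentile band excluded. Pseudopopulations
pool neurons with at least 160 trials per condition (80 for narrow splits),
sampling trials without replacement within condition (with-replacement mode
available), balanced across the four conditions; features are three
non-overlapping 300-ms bins starting 100 ms after offer onset, and all bins
of a trial stay on one side of any split. Preprocessing (per-feature
z-score, then PCA retaining ≥ 99% variance) is learned on training data
only; the classifier is a linear soft-margin SVM (C = 1), with the
prototype decoder available for direct comparison with the theory. Standard
accuracy uses a stratified 10% holdout of the training context; CCGP
accuracy uses all trials of the other context. On simulated populations the
SVM's generalization error matches the closed form within Monte-Carlo error
once ε is set to the training-centroid SEM distance.

## Population structure

The per-neuron sensitivity index z-scores each side's 7-level value profile
with that side's own mean and SD and averages the z-profile difference, so
per-side gain and offset drop out by construction; zero-variance sides are
excluded. Unimodality of the index distribution is tested with Hartigan's
dip statistic — implemented as the classical iterative GCM/LCM
modal-interval algorithm in count units and verified to machine precision
against a linear-programming oracle over piecewise-linear unimodal CDFs —
with bootstrap p-values against the uniform null (the classical
least-favorable calibration null; null tables are cached per sample size).

Neurons contributing to both side subspaces are found by the
participation-ratio contribution v(n)⁴/Σv⁴; the retained set is the
smallest whose cumulative contribution reaches 95% (the count-percentile
reading of "top 95%" is implemented behind a flag — the printed rule is
ambiguous and neither reading is asserted as the original). Retained
neurons are classified gain vs heterogeneous from bootstrap distributions
of the preferred value level per side. Here too the printed null
(randomizing the pooled peak vector and differencing means of
bootstrap-sized groups) has a null SD shrinking as 1/√n_boot and
misclassifies planted gain neurons; the implemented test is the
percentile-bootstrap sign test on the paired per-resample peak differences,
which is calibrated and recovers both planted types.

## Synthetic data: what it does and does not emulate

The generator reproduces the task's offer statistics, softmax choices under
Prelec-warped power utility, and populations with exactly controllable
(d_LV, d_LA, d_N, σ) — which is what makes every downstream stage testable
against ground truth. It does not emulate: temporal dynamics within windows
(the code is constant per epoch), correlated or Poisson-like noise
(isotropic Gaussian by default; an emission layer can be added on top),
unequal conjunctive lengths across conditions (the theory's own
simplification), chosen-value or choice-history signals, or
session-to-session heterogeneity beyond seeds. Passing tests therefore
demonstrate correctness of the estimators and the theory under the model's
assumptions, not robustness to every property of cortical data.

## Problem sizes and tolerances

Default validation sizes were chosen so every check is comfortably
identified: geometry recovery uses N = 100 neurons and 500 trials/condition
at (d_LV, d_LA, d_N, σ) = (1, 2, 1, 0.5), where the crossnobis noise is an
order of magnitude below the 10% recovery band; oracle grids use 100,000
Monte-Carlo samples per cell; calibration suites use 1000 bootstrap
resamples, 999 permutations, and 20–50 seeded replicates. Degenerate inputs
(zero vectors, constant neurons, single-class training sets, empty value
bins, all-tie sessions) raise informative errors rather than propagating
NaNs; distance estimates may legitimately be negative and are only
square-rooted through a sign-preserving map for reporting.
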