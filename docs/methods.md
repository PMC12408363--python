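# Methods

## Task generative process

A session is a sequence of trials with a hidden block state. The first
`n_unbiased = 90` trials are unbiased (P(right) = 0.5). Thereafter the
favoured side alternates in blocks whose lengths are drawn from
`p(l) ∝ exp(−l/τ)·1[20 ≤ l ≤ 100]` with τ = 60 trials; the final block is
truncated at the session end rather than resampled. Within a block the
stimulus appears on the favoured side with probability γ = 0.8. Contrast
magnitudes are drawn independently of side from {0, 0.0625, 0.125, 0.25,
1} with P(0) = 1/9 and the remaining mass uniform over the four non-zero
magnitudes, and signed by the drawn side. Rewards follow the drawn side
even at zero contrast. Sessions default to 645 trials so that ≈ 555
biased trials follow the lead-in. Pseudosessions are fresh draws from
this process matched in length and lead-in to a reference session; they
are the null inputs for every significance procedure in the package.

Trial inclusion marks trials with no response or reaction time outside
[80 ms, 2 s] as excluded, and a session with fewer than 250 included
trials as invalid. Synthetic reaction times are log-normal (median
≈ 0.37 s, σ_log = 0.5) so the filters have non-trivial work; parameters
are configurable.

## Behavioural models

**Bayes-optimal prior.** The observer knows the generative process and
forward-filters the hidden state (favoured side × block age). The block
ends at age `a` with hazard `h(a) = pmf(a) / Σ_{l≥a} pmf(l)` (zero below
the minimum length, one at the maximum), in which case the side flips
and the age resets. The prior for trial `t` conditions on sides
`1..t−1`; lead-in trials return exactly 0.5, and filtering starts at the
first biased trial with equal side probability and age 1. The filter is
exact: tests compare it to brute-force enumeration over all block
partitions on small configurations (agreement ≤ 1e−10).

**History kernels.** The action (stimulus) kernel integrates past
choices (stimulus sides): `π_t = (1−α)π_{t−1} + α·1[event_{t−1}=right]`,
`π_0 = 0.5`. Missed trials leave π unchanged. α → 1 reduces to
"repeat last event", α → 0 keeps π at its initial value.

**Within-trial decision rule.** The percept of a trial with signed
contrast `c` is `ĉ ~ N(c, σ_c²)`. The observer is modelled as knowing
the trial's contrast magnitude |c| (magnitude carries no side
information), so the likelihood is `N(ĉ; ±|c|, σ_c²)` and the posterior
is logistic in ĉ. Consequences: at zero contrast the percept is
uninformative and the choice probability equals the prior exactly;
at high contrast and small σ_c the likelihood dominates. Choices are
probability matching on the posterior by default (greedy available),
mixed with independent left/right lapse rates:
`P(right) = lapse_right + (1 − lapse_left − lapse_right)·m(q)`.
The marginal over ĉ uses 61-point Gauss–Hermite quadrature (agrees with
Monte-Carlo to < 2e−3 in tests). A single scalar σ_c is used; a
contrast-dependent noise model would slot into the same interface.

## Model fitting and comparison

Parameters are sampled with adaptive random-walk Metropolis–Hastings:
four chains, Gaussian proposals whose covariance is re-estimated every
50 steps from the chains' recent halves with a Haario-type acceptance
correction toward 0.3, frozen after the adaptation phase (first half of
the minimum run length) to keep the kept samples from a fixed kernel.
Chains run at most 5 000 steps and stop early — never before 1 000 —
once every parameter's Gelman–Rubin statistic (between/within variance
form, clamped at 1) falls below 1.1. The first half of each chain is
burn-in. Priors are uniform boxes: α ∈ (0.001, 1], σ_c ∈ (0.001, 2],
lapses ∈ [0, 0.499).

Model evidence uses session-level cross-validation: hold out one
session, sample the posterior on the rest, and estimate
`p(A^i | A^{\i}) ≈ (1/N) Σ_n p(A^i | θ_n)` with a log-sum-exp (the mean
of likelihoods, not of log-likelihoods); chains are thinned evenly to at
most 2 000 draws for this average. Subjects need at least two sessions.
Subject-level log evidences feed a variational random-effects selection:
a Dirichlet population prior with concentration 1 per model, updated by
the standard fixed-point iteration; exceedance probabilities come from
10⁵ Dirichlet draws.

## Reversal curves

Accuracy around block switches is summarized per lag with
`p(correct at t) = (B + (A−B)e^{−t/τ})·1[t≥0] + B·1[t<0]`, fitted by
least squares on lag-aggregated zero-contrast means weighted by trial
counts, with bounds A, B ∈ [0, 1], τ ∈ (0.1, 50] and ten restarts around
(0.4, 0.7, 5). The fitted window covers the 5 pre-reversal and 20
post-reversal trials; the boundary trial t = 0 is excluded because the
first stimulus of the new block has not been observed there, so its
accuracy reflects the old block rather than the recovery. τ is reported
in trials; a fit with |A − B| < 1e−3 is flagged τ-unidentifiable.
Cohort-level τ uses a leave-one-mouse-out jackknife (median over
replicates; the jackknife s.e. helper implements
`sqrt((n−1)/n Σ(θ_i − θ̄)²)`).

## Decoding and pseudosession significance

The decoder is L1 (spike counts; robust to outlier units) or L2 (pixel
data; robust to collinearity) linear regression with nested
cross-validation: interleaved random outer folds (5 for spiking, 50 for
imaging) hold out 20% of trials; an inner grid search (5-fold, or
leave-one-out for imaging) selects the regularization weight from the
per-modality grids (spiking {1e−5…1e−1}; imaging {1e−5…1e−2}; behaviour
covariates {1e−4…1e2}; eye position {1e−4…1e4}; contrast decoders add
1.0). The procedure repeats over ten seeded runs; the score is the
median pooled held-out R² across runs (pooled rather than per-fold
averaged: one stable number even with small folds) and the reported
prediction the across-run mean. Grid-edge selections are counted on the
result so unreached bounds are visible.

Both the prior and the activity are slowly autocorrelated, so R² is
calibrated against pseudosessions: M counterfactual task sequences are
resampled, their priors decoded from the *same* activity, and the actual
score compared to these pseudo-scores. `p = (1 + #{null ≥ actual})/(M+1)`
(add-one smoothing; never exactly zero), effect size
`corrected R² = actual − median(null)`. M defaults to 1 000 (200 for
weight significance, slope nulls and neurometric shifts). Tests run the
identical machinery at reduced M and fold counts. Type-I error under a
drift-only generator is checked at 500 null runs against a binomial
band. Decoding weights are flagged per unit outside the 2.5/97.5
percentiles of the pseudoweights. Region maps combine session p-values
with Fisher's method (X² = −2Σ ln p against χ² with 2N d.f.) and apply
Benjamini–Hochberg selection at FDR 1% where maps are merged.

The action-kernel prior can be decoded, but no pseudosession null is
attached to it: its null would require simulating the animal's true
decision process, for which only approximations exist. Analyses that
need pseudo-behaviour (choice-coupling slopes, orthogonalization nulls)
use synthetic sessions: the action-kernel model fitted to the real
session (fast bounded ML fit) and simulated on each pseudosession.

## Neurometric curves

A contrast decoder (same nested-CV engine) produces ŝ per trial. Per
prior condition (Bayes-optimal prior < 0.5 vs > 0.5; exact 0.5 excluded)
and contrast level, the proportion of ŝ > 0 is fitted with
`f(c) = γ + (1−γ−λ)(erf((c−μ)/σ)+1)/2` by binomial maximum likelihood —
γ, λ, σ shared across conditions and μ free — with bounds lapses
∈ [0, 0.3], σ ∈ (0.01, 2], μ ∈ [−0.5, 0.5] and ten restarts. The shift
is `f_high(0) − f_low(0)`; the independent-parameter variant (eight
parameters) exists for BIC comparison. Shift significance decodes pseudo
contrast sequences from the real activity and conditions the fits on the
pseudo priors.

## Granger information flow

Pre-stimulus activity is segmented into ten 50 ms bins (spiking) or nine
frames (imaging) and the prior decoded per region and bin with
internally cross-validated Lasso/Ridge (in-sample predictions: the
overfitting is shared between actual and pseudo decodes and is what lets
the null inherit the regions' common slow drive). Bins are concatenated
trial-major into one series per region. For each directed pair a
bivariate VAR (least squares, AIC order ≤ 5, unit-root series differenced
after an augmented Dickey–Fuller check) yields the Geweke spectral
measure `f_{x→y}(ω) = ln(S_yy / (S_yy − (Σ_xx − Σ_xy²/Σ_yy)|H_yx|²))`,
averaged over a positive-frequency grid (≤ 256 points); constant series
score zero. This parametric route replaces the nonparametric
spectral-factorization implementation used historically: it is
deterministic and equivalent for the linear-Gaussian series produced
here. Pair significance compares the actual score to the top 5% of
pseudo scores; loop statistics report the fraction of significant edges
on directed cycles of length 3 (length exposed as a parameter);
session-level p-values Fisher-combine to region level and again to
coarse groups.

## History and decay analyses

**Orthogonalization** regresses the decoded prior on the last action,
the residual on the second-to-last, and so on to lag K = 10, absorbing
event autocorrelation. On a noiseless kernel target with i.i.d. ±1
events the weights are `α(1−α)^{k−1}/2` (the ±1 coding halves the
indicator slopes) — the closed-loop check used in tests. Nulls use
synthetic-session pseudoactions (or raw pseudostimuli for the stimulus
variant, which needs no behavioural model); the across-session mean
weight is significant above the 95th percentile of pseudo means.

**Neural-agent asymmetry** turns the decoded prior into a greedy agent
(right iff decoded prior > 0.5, ties to left — an explicit, documented
tie-break) and applies the behavioural asymmetry filters without the
zero-contrast restriction, since the agent only sees pre-stimulus
activity.

**Decay rates.** Spike counts: `X_{t,n} ~ Poisson(Q_{t,n})` with
`Q = (1−α_n)Q' + α_n ζ_n^{a}` (two scale parameters keep Q positive);
imaging: Gaussian with `Q = (1−α_n)Q' + α_n ζ_n a` and free σ_n. Missed
trials skip the update. `Q_0` is the stationary mean under the empirical
action frequencies — removing the transient without extra parameters.
Per-unit fits use bounded L-BFGS with ten restarts (α ∈ [0.001, 1]);
units failing all restarts are dropped. Spiking units enter only if the
median count is positive, the mean is ≥ 0.2 spikes/trial ("at least one
spike every five trials"), and a two-sample Kolmogorov–Smirnov test
separates counts at prior > 0.5 vs < 0.5 at p < 0.05. Session-level
neural α is the mean over included units and is correlated (Pearson)
with the behavioural α across sessions; a stimulus-kernel control swaps
the driving events.

## Synthetic data: what it does and does not emulate

Generators cover the statistical structure the analyses assume: prior
coupling with per-unit gains, Poisson/Gaussian emission, slow drift
(random-walk or linear — the confound the pseudosession method defeats),
low-rank pixel mixing, embodiment covariates with per-feature coupling,
and directed lag-1 coupling between regions' binned latents. The
softplus link keeps Poisson rates positive while staying monotone in the
prior, which is all the linear decoder requires. Not emulated:
biophysical spike or calcium dynamics, realistic receptive-field or
noise-correlation structure, non-stationary unit yield, behavioural
video. Passing tests therefore demonstrate that the *procedures* are
correct and calibrated under their stated assumptions, not that real
recordings satisfy those assumptions.

## Problem sizes and numerical choices

The benchmark script simulates 139 mice × 3 sessions × 645 trials for
the observer's accuracy and reversal constants, 200 sessions for the
prior/contrast correlation and 300 for the zero-contrast rate — sizes at
which the Monte-Carlo error is well inside each quantity's tolerance
while a full run stays within a few minutes on one core. Unit tests use
smaller cohorts and reduced decoder settings (fewer folds/runs, M of
40–200) chosen the same way. All randomness flows through
`numpy.random.Generator` seeds; every public simulation function takes a
seed and is bit-reproducible under it. Kernel recursions use
`scipy.signal.lfilter`; kernel priors are clipped to (1e−9, 1−1e−9) so
α = 1 cannot pin probabilities at 0/1; likelihood evaluations clip
probabilities at 1e−300 before logs; Fisher's method clips p = 0 to the
machine floor with a warning.

## Known limitations

- The within-trial likelihood (known-magnitude Gaussian) is one
  defensible reading of a decision model whose full specification lives
  outside the main text of the literature this follows; alternative
  readings (magnitude-marginal likelihoods, contrast-dependent noise)
  would change zero-contrast behaviour only through σ_c.
- Reversal-fit conventions (boundary-trial exclusion, count-weighted
  lags) shift τ by a few tenths of a trial; both choices are documented
  above and the exclusion convention is the implemented default.
- The Granger stage fits VARs across trial boundaries on concatenated
  bins; a per-trial pooled variant would treat boundaries differently
  and is exposed as a natural extension point, not implemented.
- Hierarchical (mouse-level) modelling of the timescale correlation is
  out of scope; the correlation is computed at the session level.
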