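# blockprior

Simulation and analysis of subjective priors in the biased-block visual
decision task, written for computational neuroscientists who want to
test prior-decoding pipelines end to end on fully synthetic data.

In the task, a mouse reports the side of a visual grating whose side is
drawn with probability 0.8 from a hidden "block" that switches uncued
between left- and right-biased states (truncated-exponential block
lengths, scale 60 trials, bounds 20–100, after a 90-trial unbiased
lead-in). On zero-contrast trials only the block prior carries
information, so behaviour and neural activity on those trials expose the
animal's *subjective* prior. The package implements:

- **Task generator** (`taskgen`): the block/stimulus generative process,
  pseudosession resampling, trial/session inclusion filters, CSV I/O.
- **Behavioural agents** (`agents`): the Bayes-optimal prior
  `p(s_t = right | s_{1:t-1})` by exact forward filtering over the hidden
  block state with hazard `h(a) = p(L=a)/p(L≥a)`; exponential action and
  stimulus kernels `π_t = (1-α)π_{t-1} + α·1[event_{t-1}=right]`; a noisy
  within-trial decision rule with lapses, probability matching or greedy.
- **Model fitting** (`behavior_fit`): adaptive Metropolis–Hastings with
  Gelman–Rubin early stopping, leave-one-session-out marginal likelihoods
  `p(A^i|A^{\i}) ≈ (1/N)Σ_n p(A^i|θ_n)`, and random-effects Bayesian
  model selection (Dirichlet population model; frequencies and
  exceedance probabilities).
- **Behavioural statistics** (`behavior_stats`): block-conditioned
  psychometrics, reversal curves with the exponential recovery fit
  `p(correct at t) = (B + (A−B)e^{−t/τ})·1[t≥0] + B·1[t<0]` and
  leave-one-mouse-out jackknife, and the post-outcome asymmetry that
  separates action- from stimulus-integrating strategies.
- **Synthetic neural data** (`synth_neural`): Poisson spike counts and
  Gaussian ΔF/F pixels coupled to any prior trace, with slow drift,
  low-rank spatial mixing, embodiment covariates, kernel-latent emitters
  and multi-region binned series with directed coupling.
- **Decoding** (`decoding`): nested cross-validated L1/L2 regression,
  pseudosession null distributions (p-values and corrected R² = actual −
  median null), Fisher/Benjamini–Hochberg region aggregation, decoding-
  weight significance, sessions-needed subsampling, covariate/residual
  (embodiment) decoding, and the decoded-prior → choice coupling.
- **Neurometrics** (`neurometric`): erf psychometric fits
  `f(c) = γ + (1−γ−λ)(erf((c−μ)/σ)+1)/2` to a contrast decoder's output,
  split by prior condition with shared lapses/slope; the shift
  `f_high(0) − f_low(0)` and its pseudosession significance.
- **Information flow** (`infoflow`): bin-wise prior decoding, spectral
  (VAR/Geweke) Granger causality averaged over frequencies, loop
  statistics and Fisher aggregation across sessions and coarse groups.
- **History analyses** (`history`): stepwise orthogonalization of the
  decoded prior against past actions/stimuli, the greedy decoded-prior
  agent's post-outcome asymmetry, and per-unit exponential decay-rate
  fits (Poisson/Gaussian) with the neural-vs-behavioural timescale
  correlation.

## A worked example

Decode the Bayes-optimal prior from drift-contaminated synthetic spike
counts (`examples/04_decode_prior.py`):

```bash
$ python examples/04_decode_prior.py
prior-coupled  R2=+0.672  corrected R2=+0.639  p=0.010
drift-only     R2=+0.065  corrected R2=+0.047  p=0.099
Fisher combination of p-values {0.02, 0.04}: 0.0065
```

The prior-coupled population decodes far above its pseudosession null
(corrected R² ≈ 0.64, p = 0.01 at M = 100 pseudosessions), while the
drift-only population — whose raw R² is slightly positive purely because
slow drift mimics the block structure — stays inside the null. The last
line shows Fisher's method combining two session-level p-values into a
region-level one.

The other scripts in `examples/` walk through the task generator, the
ideal observer's benchmark behaviour, behavioural model comparison,
neurometric shifts, Granger flow and the history/decay analyses, each
printing a few numbers and what they mean. A thin CLI mirrors the main
entry points (`blockprior simulate-task`, `simulate-neural`, `decode`,
`fit-behavior`, `behavior-report`, `run-all`, `report`).

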