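"""Decode the prior from synthetic spike counts, with drift-proof stats.

Spike counts couple to the Bayes-optimal prior through per-unit gains and
carry a slow random-walk drift — the confound that makes naive
significance tests lie.  Pseudosession resampling builds the null that
absorbs the drift: the corrected R² and p-value come from decoding
counterfactual priors from the same activity.
"""

from blockprior import TaskConfig, generate_session
from blockprior.decoding import (
    DecodeSpec, bayes_prior_target, fisher_combine, pseudosession_significance,
)
from blockprior.synth_neural import SynthNeuralConfig, gen_ephys_counts

cfg = TaskConfig(n_trials=400)
session = generate_session(cfg, seed=11)
prior = bayes_prior_target(session)

spec = DecodeSpec(penalty="L1", grid=(1e-4, 1e-3, 1e-2), outer_folds=5,
                  inner_folds=3, n_runs=3)

for name, gain in (("prior-coupled", 3.0), ("drift-only", 0.0)):
    ncfg = SynthNeuralConfig(n_units=20, gain=gain, drift_amplitude=0.1, seed=12)
    counts = gen_ephys_counts(session, prior, ncfg)
    res = pseudosession_significance(counts, session, spec=spec, M=100, seed=13)
    print(f"{name:14s} R2={res.r2:+.3f}  corrected R2={res.corrected_r2:+.3f}  "
          f"p={res.p_value:.3f}")

print(f"Fisher combination of p-values {{0.02, 0.04}}: "
      f"{fisher_combine([0.02, 0.04]):.4f}")
# The coupled population is significant with a large corrected R2; the
# drift-only population decodes no better than its pseudosession null.
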