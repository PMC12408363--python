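"""Simulate one biased-block session and summarize its structure.

The task hides a block variable: after 90 unbiased trials, the stimulus
appears on one side with probability 0.8 in alternating blocks whose
lengths follow a truncated exponential (scale 60, bounds 20-100 trials).
"""

import numpy as np

from blockprior import TaskConfig, generate_session

cfg = TaskConfig(n_trials=645)
session = generate_session(cfg, seed=1)

bp = session["block_p_right"].to_numpy()
switches = np.flatnonzero(np.diff(bp) != 0) + 1
zc = (session["signed_contrast"] == 0).mean()
right_in_right_blocks = (session.loc[bp == 0.8, "stim_side"] == "right").mean()

print(f"trials: {len(session)}  (lead-in 90 at P(right)=0.5)")
print(f"block switches: {len(switches)} at trials {switches.tolist()}")
print(f"zero-contrast fraction: {zc:.3f}  (target 1/9 = 0.111)")
print(f"P(stimulus right | right block): {right_in_right_blocks:.3f}  (gamma = 0.8)")
# Each biased block favours one side; the observer can only infer the
# current block from the history of stimulus sides.
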