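"""Real-time intention inference with an unpredictable situation switch.

A trained network interacts with the scripted environment: the ball first
follows the behavior the robot intends, then the situation switches at
step 120.  Only the PB state (intention) adapts — 50 momentum updates per
step on the precision-weighted vision error of a 10-step sliding window.
Watch the PB activity migrate from the initial behavior's code to the
post-switch behavior's code.
"""

import numpy as np

from sctrnnpb import (VirtualEnvironment, build_dataset, desk_config,
                      desk_spec, generate_behavior_template,
                      judge_flexibility, success_threshold)
from sctrnnpb.adaptation import run_interaction_trial
from sctrnnpb.training import train_network

spec = desk_spec()
dataset = build_dataset(spec, 2, 2, rng=42)
config = desk_config(k=10.0)
params, _ = train_network(config, dataset, rng=1)
xi = success_threshold(dataset)

behavior = "right"
row = next(i for i, s in enumerate(dataset.train()) if s.behavior == behavior)
template = generate_behavior_template(desk_spec(behavior))
env = VirtualEnvironment(spec, behavior, switch_step=120, trial_length=300,
                         rng=7)
trial = run_interaction_trial(params, config, env, params.u0_pb[row],
                              template.values[0, :8])

print(f"intention starts at the trained {behavior!r} code; "
      f"ball switches at step {trial.switch_step}")
for t in (0, 60, 119, 150, 200, 250, 299):
    err = trial.windowed_error[t]
    print(f"  step {t:3d} [{trial.situations[t]:5s}]  PB activity "
          f"{np.round(trial.pb[t], 2)}  windowed error "
          f"{'--' if np.isnan(err) else f'{err:7.1f}'}")
print(f"recognized the switch (closed-loop generation from final PB "
      f"matches the new behavior): {judge_flexibility(trial, params, dataset, xi)}")
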