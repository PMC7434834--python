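"""The heterogeneity experiment in miniature: homogeneous vs heterogeneous.

Trains two replicates for each focal condition (k = 0.1 homogeneous,
k = 10 heterogeneous) on the same dataset and prints the condition
contrast: homogeneous networks fit the training noise (lower training
error, variance below the injected 0.002 floor) but transfer worse to
test sequences, and develop broader synaptic weights.  About 4 CPU-minutes;
the full pipeline (sctrnnpb.run_pipeline / the `sctrnnpb` CLI) adds
interaction trials and PB maps on top of this.
"""

import numpy as np

from sctrnnpb import (ExperimentPlan, build_dataset, desk_config, desk_spec,
                      overfitting_metrics, run_condition_sweep,
                      weight_distribution_stats)

dataset = build_dataset(desk_spec(), 2, 2, rng=42)
plan = ExperimentPlan(k_values=(0.1, 10.0), n_replicates=2,
                      config=desk_config(), seed=0)
sweep = run_condition_sweep(plan, dataset, progress=True)

print(f"\n{'k':>6} {'train MSE':>10} {'test MSE':>10} {'train var':>10} "
      f"{'weight std':>10}")
for k in plan.k_values:
    models = [sweep.models[(k, r)][0] for r in range(2)]
    reports = [overfitting_metrics(m, dataset) for m in models]
    wstd = weight_distribution_stats(models).std
    print(f"{k:6g} {np.mean([r.train_error for r in reports]):10.5f} "
          f"{np.mean([r.test_error for r in reports]):10.5f} "
          f"{np.mean([r.train_variance for r in reports]):10.5f} "
          f"{wstd:10.3f}")
print("\nhomogeneous (k=0.1): lower training error, higher test error, "
      "variance under the 0.002 floor, broader weights — overfitting to "
      "sensory noise.")
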