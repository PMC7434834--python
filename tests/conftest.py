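"""Shared fixtures.

The expensive session fixtures (trained desk-scale sweeps) are built once
and reused by the acceptance tests; unit tests use tiny networks only.
"""

from __future__ import annotations

import numpy as np
import pytest

from sctrnnpb import (ModelConfig, build_dataset, desk_config, desk_spec,
                      init_parameters)
from sctrnnpb.pipeline import PipelineConfig, generate_data, run_interactions, run_sweep

#: Seed for every deterministic test fixture in the suite.
FIXTURE_SEED = 20260920


@pytest.fixture(scope="session")
def desk_dataset():
    """Desk-scale dataset: 2 behaviors x (2 train + 2 test), T=200."""
    return build_dataset(desk_spec(), n_train_per_behavior=2,
                         n_test_per_behavior=2, rng=FIXTURE_SEED)


@pytest.fixture(scope="session")
def tiny_setup():
    """A 3-context-neuron network and two short sequences for oracle tests."""
    rng = np.random.default_rng(11)
    config = ModelConfig(n_input=3, n_mean=3, n_variance=3, n_context=3,
                         n_pb=2, tau=4.0, bias_variance_k=1.0)
    params = init_parameters(config, rng, n_sequences=2)
    seqs = [rng.uniform(-0.7, 0.7, size=(6, 3)) for _ in range(2)]
    return config, params, seqs


@pytest.fixture(scope="session")
def pipeline_config():
    """Desk pipeline configuration shared by the acceptance suite."""
    return PipelineConfig.desk(master_seed=FIXTURE_SEED,
                               k_values=(0.1, 1.0, 10.0, 100.0),
                               n_replicates=4)


@pytest.fixture(scope="session")
def desk_sweep(pipeline_config):
    """Trained desk-scale sweep: the ordering/acceptance workhorse.

    4 replicates for the focal conditions (k=0.1, 10) and 2 for the
    flanking ones (k=1, 100), all sharing one dataset.
    """
    dataset = generate_data(pipeline_config)
    from sctrnnpb.training import ExperimentPlan, run_condition_sweep
    from sctrnnpb.pipeline import _derived_seed
    plan = ExperimentPlan(k_values=pipeline_config.k_values,
                          n_replicates=pipeline_config.n_replicates,
                          config=pipeline_config.model_config,
                          seed=_derived_seed(pipeline_config.master_seed, 1))
    sweep = run_condition_sweep(plan, dataset,
                                replicates_per_k={1.0: 2, 100.0: 2})
    return dataset, sweep


@pytest.fixture(scope="session")
def desk_interactions(pipeline_config, desk_sweep):
    """Interaction trials for the focal conditions of the trained sweep."""
    dataset, sweep = desk_sweep
    return run_interactions(pipeline_config, dataset, sweep,
                            k_values=(0.1, 10.0))
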