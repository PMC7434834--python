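"""End-to-end experiment pipeline: data -> k-sweep -> simulations -> report.

One :class:`PipelineConfig` (YAML-serializable) drives every stage; all
per-stage seeds derive deterministically from a single master seed, so the
emitted manifest regenerates every number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import model as _m
from . import synthetic as syn
from . import training as tr
from .adaptation import run_interaction_trial
from .model import ModelConfig
from .synthetic import SequenceSpec, VirtualEnvironment


@dataclass
class PipelineConfig:
    sequence_spec: SequenceSpec = field(default_factory=SequenceSpec)
    model_config: ModelConfig = field(default_factory=ModelConfig)
    k_values: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    n_replicates: int = 8
    n_train_per_behavior: int = 3
    n_test_per_behavior: int = 3
    switch_step: int = 120
    trial_length: int = 300
    interaction_trials_per_model: int = 6
    #: per-trial uniform phase offset of the scripted ball, +/- this many
    #: steps — the interaction-phase analogue of the test-split timing
    #: jitter ("the timing ... not exactly the same as the training data")
    interaction_phase_jitter: int = 3
    master_seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if len(self.k_values) == 0:
            raise ValueError("k_values must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def desk(cls, **overrides) -> "PipelineConfig":
        kw = dict(sequence_spec=syn.desk_spec(),
                  model_config=_m.desk_config(),
                  n_replicates=4, n_train_per_behavior=2,
                  n_test_per_behavior=2)
        kw.update(overrides)
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["sequence_spec"] = dataclasses.asdict(self.sequence_spec)
        doc["model_config"] = dataclasses.asdict(self.model_config)
        doc["k_values"] = list(self.k_values)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["sequence_spec"] = SequenceSpec(**doc["sequence_spec"])
        doc["model_config"] = ModelConfig(**doc["model_config"])
        doc["k_values"] = tuple(doc["k_values"])
        return cls(**doc)


def _derived_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_data(config: PipelineConfig) -> syn.SequenceDataset:
    return syn.build_dataset(config.sequence_spec,
                             config.n_train_per_behavior,
                             config.n_test_per_behavior,
                             rng=_derived_seed(config.master_seed, 0))


def run_sweep(config: PipelineConfig, dataset, progress: bool = False):
    plan = tr.ExperimentPlan(k_values=config.k_values,
                             n_replicates=config.n_replicates,
                             config=config.model_config,
                             seed=_derived_seed(config.master_seed, 1))
    return tr.run_condition_sweep(plan, dataset, progress=progress)


def run_interactions(config: PipelineConfig, dataset, sweep,
                     k_values: tuple[float, ...] | None = None) -> dict:
    """Interaction trials per trained model; half start left, half right."""
    xi = ev.success_threshold(dataset)
    spec = config.sequence_spec
    results = {}
    train = dataset.train()
    u0_row = {b: next(i for i, s in enumerate(train) if s.behavior == b)
              for b in ("left", "right")}
    tmpl = {b: syn.generate_behavior_template(replace(spec, behavior=b))
            for b in ("left", "right")}
    for (k, rep), (params, _) in sweep.models.items():
        if k_values is not None and k not in k_values:
            continue
        trials = []
        for j in range(config.interaction_trials_per_model):
            behavior = ("left", "right")[j % 2]
            env_seed = _derived_seed(config.master_seed, 2, int(k * 1000),
                                     rep, j)
            env_rng = np.random.default_rng(env_seed)
            jit = config.interaction_phase_jitter
            jitter = int(env_rng.integers(-jit, jit + 1)) if jit > 0 else 0
            env = VirtualEnvironment(
                spec, initial_situation=behavior,
                switch_step=config.switch_step,
                trial_length=config.trial_length,
                jitter=jitter, rng=env_rng)
            trial = run_interaction_trial(
                params, replace(config.model_config, bias_variance_k=k),
                env, params.u0_pb[u0_row[behavior]],
                tmpl[behavior].values[0, :spec.n_dims_proprio])
            trials.append({
                "trial": trial,
                "flexible": ev.judge_flexibility(trial, params, dataset, xi),
                "generalized": ev.judge_generalization(trial, dataset, xi),
            })
        results[(k, rep)] = trials
    return results


def evaluate_sweep(config: PipelineConfig, dataset, sweep,
                   interactions: dict | None = None) -> pd.DataFrame:
    """Per-model metric table (one row per trained network)."""
    xi = ev.success_threshold(dataset)
    rows = []
    for (k, rep), (params, trace) in sorted(sweep.models.items()):
        sim = ev.judge_mental_simulation(params, config.model_config,
                                         dataset, xi)
        rep_metrics = ev.overfitting_metrics(params, dataset)
        wstats = ev.weight_distribution_stats([params])
        row = {"k": k, "replicate": rep, "final_loss": trace.final_loss,
               "mental_sim_rate": sim["success_rate"],
               "train_error": rep_metrics.train_error,
               "test_error": rep_metrics.test_error,
               "train_variance": rep_metrics.train_variance,
               "test_variance": rep_metrics.test_variance,
               "weight_std": wstats.std, "weight_frac_weak": wstats.frac_weak,
               "xi": xi}
        if interactions and (k, rep) in interactions:
            trials = interactions[(k, rep)]
            row["flexibility_rate"] = float(np.mean([t["flexible"]
                                                     for t in trials]))
            row["generalization_rate"] = float(np.mean([t["generalized"]
                                                        for t in trials]))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(report: pd.DataFrame) -> pd.DataFrame:
    """Condition-level means and SDs over replicates."""
    metrics = [c for c in report.columns if c not in ("k", "replicate", "xi")]
    grouped = report.groupby("k")[metrics]
    table = grouped.agg(["mean", "std", "count"])
    table.columns = ["_".join(c) for c in table.columns]
    std_cols = [c for c in table.columns if c.endswith("_std")]
    table[std_cols] = table[std_cols].fillna(0.0)  # single replicate: SD 0
    return table.reset_index()


def run_pipeline(config: PipelineConfig, progress: bool = False) -> dict:
    """Execute every stage and write a report bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "pipeline_config.yaml")

    dataset = generate_data(config)
    dataset.save(out / "data")

    sweep = run_sweep(config, dataset, progress=progress)
    tr.save_sweep(sweep, out / "checkpoints")

    interactions = run_interactions(config, dataset, sweep)
    trial_dir = out / "trials"
    trial_dir.mkdir(exist_ok=True)
    for (k, rep), trials in interactions.items():
        for j, entry in enumerate(trials):
            entry["trial"].to_csv(trial_dir / f"trial_k{k:g}_r{rep}_{j}.csv")

    report = evaluate_sweep(config, dataset, sweep, interactions)
    report.to_csv(out / "per_model_report.csv", index=False)
    summary = summarize(report)
    summary.to_csv(out / "condition_summary.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"master_seed": config.master_seed,
                   "dataset": dataset.manifest(),
                   "sweep": sweep.manifest}, fh, indent=2, default=str)
    return {"dataset": dataset, "sweep": sweep, "interactions": interactions,
            "report": report, "summary": summary}
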