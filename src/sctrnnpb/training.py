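"""The learning experiment: train replicate networks per heterogeneity k.

A "condition" is one value of the context-bias variance k; replicates of a
condition share the dataset but re-draw all initial parameters (synaptic
weights *and* context biases) from fresh seeds.  A sweep manifest records
every seed so each artifact is regenerable from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import model as _m
from ._kernels import train_loop
from .model import ModelConfig, NetworkParameters
from .synthetic import SequenceDataset


@dataclass
class TrainingTrace:
    """Thinned loss series plus run metadata."""

    loss: np.ndarray            # loss at epochs 0, thin, 2*thin, ...
    final_loss: float
    thin: int
    n_epochs: int
    seed: int
    diverged_epoch: int = -1    # -1 means the run stayed finite

    @property
    def diverged(self) -> bool:
        return self.diverged_epoch >= 0


@dataclass
class ExperimentPlan:
    """A k-sweep: conditions x replicates on one shared dataset."""

    k_values: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    n_replicates: int = 8
    config: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.k_values) == 0:
            raise ValueError("k_values must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SweepResult:
    """Trained checkpoints keyed by (k, replicate) plus the seed manifest."""

    models: dict[tuple[float, int], tuple[NetworkParameters, TrainingTrace]]
    plan: ExperimentPlan
    manifest: dict
    train_mse: dict[tuple[float, int], float] = field(default_factory=dict)

    def converged(self, reference_k: float = 10.0,
                  factor: float = 10.0) -> dict[tuple[float, int], bool]:
        """Flag runs that "could not successfully learn".

        Operationalized as: final mean squared training error larger than
        ``factor`` x the median final training MSE of the reference
        condition (k=10 by default; all finished runs if that condition is
        absent).  Diverged runs are always flagged.
        """
        mses = {key: self.train_mse.get(key, np.inf)
                for key in self.models}
        # runs that aborted (non-finite loss) never produced a model but
        # are still part of the sweep record
        for record in self.manifest.get("runs", []):
            key = (record["k"], record["replicate"])
            if key not in mses:
                mses[key] = np.inf
        ref = [v for (k, _), v in mses.items()
               if k == reference_k and np.isfinite(v)]
        if not ref:
            ref = [v for v in mses.values() if np.isfinite(v)]
        ref_median = float(np.median(ref)) if ref else np.inf
        return {key: bool(np.isfinite(v) and v <= factor * ref_median)
                for key, v in mses.items()}


def stack_training_inputs(dataset: SequenceDataset) -> np.ndarray:
    """Time-major (T, S, n_input) array of the training sequences."""
    train = dataset.train()
    if not train:
        raise ValueError("dataset has no training sequences")
    lengths = {s.n_steps for s in train}
    if len(lengths) > 1:
        raise ValueError("training sequences must share one length")
    return np.ascontiguousarray(np.stack([s.values for s in train], axis=1))


def train_network(config: ModelConfig, dataset: SequenceDataset,
                  rng: np.random.Generator | int | None = None,
                  thin: int = 100
                  ) -> tuple[NetworkParameters, TrainingTrace]:
    """Train one network with momentum gradient descent on the summed NLL.

    Exactly ``config.n_epochs`` updates; per-sequence PB initial states are
    trained jointly with the weights; deterministic under the seed.
    Raises ``FloatingPointError`` naming the epoch if the loss diverges.
    """
    for behavior in ("left", "right"):
        if not dataset.train(behavior):
            raise ValueError(f"dataset has no training sequences for {behavior!r}")
    seed = config.seed
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    elif rng is None:
        rng = np.random.default_rng(seed)
    train = dataset.train()
    params = _m.init_parameters(config, rng, n_sequences=len(train))
    X = stack_training_inputs(dataset)
    loss_log, final_loss, diverged = train_loop(
        params.W_input_to_context, params.W_context_to_context,
        params.W_pb_to_context, params.W_context_to_mean,
        params.W_context_to_variance, params.b_context,
        params.b_mean, params.b_variance, params.u0_pb, params.tau,
        X, config.n_epochs, config.alpha, config.eta, thin,
        _m.VARIANCE_CAP, config.grad_clip_norm)
    trace = TrainingTrace(loss=loss_log, final_loss=float(final_loss),
                          thin=thin, n_epochs=config.n_epochs, seed=seed,
                          diverged_epoch=int(diverged))
    if trace.diverged:
        raise FloatingPointError(
            f"training loss became non-finite at epoch {trace.diverged_epoch}")
    return params, trace


def run_condition_sweep(plan: ExperimentPlan, dataset: SequenceDataset,
                        replicates_per_k: dict[float, int] | None = None,
                        progress: bool = False) -> SweepResult:
    """Train ``|k_values| x n_replicates`` networks on the shared dataset.

    Replicates differ only in the parameter-initialization seed (weights and
    context biases are both re-drawn).  Individual failures are recorded and
    the sweep continues.  ``replicates_per_k`` optionally overrides the
    replicate count for specific conditions.
    """
    root = np.random.SeedSequence(plan.seed)
    models = {}
    train_mse = {}
    manifest = {"plan_seed": plan.seed, "dataset_seed": dataset.seed,
                "config": vars(plan.config).copy(), "runs": []}
    train_seqs = dataset.train()
    for ki, k in enumerate(plan.k_values):
        n_rep = (replicates_per_k or {}).get(k, plan.n_replicates)
        for rep in range(n_rep):
            child = np.random.SeedSequence(entropy=root.entropy,
                                           spawn_key=(ki, rep))
            run_seed = int(child.generate_state(1)[0] % (2**31))
            config = replace(plan.config, bias_variance_k=k, seed=run_seed)
            record = {"k": k, "replicate": rep, "seed": run_seed}
            try:
                params, trace = train_network(config, dataset, rng=run_seed)
                models[(k, rep)] = (params, trace)
                errs = [np.mean((_m.run_open_loop(params, params.u0_pb[i],
                                                  s).y - s.values[1:]) ** 2)
                        for i, s in enumerate(train_seqs)]
                train_mse[(k, rep)] = float(np.mean(errs))
                record["final_loss"] = trace.final_loss
                record["train_mse"] = train_mse[(k, rep)]
                record["status"] = "ok"
            except FloatingPointError as err:
                record["status"] = f"failed: {err}"
            manifest["runs"].append(record)
            if progress:
                print(f"[sweep] k={k} rep={rep} {record['status']}",
                      flush=True)
    return SweepResult(models=models, plan=plan, manifest=manifest,
                       train_mse=train_mse)


def save_sweep(result: SweepResult, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "sweep_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    for (k, rep), (params, trace) in result.models.items():
        stem = directory / f"ckpt_k{k:g}_r{rep}"
        config = replace(result.plan.config, bias_variance_k=k,
                         seed=trace.seed)
        _m.save_checkpoint(stem, params, config,
                           extra={"final_loss": trace.final_loss,
                                  "n_epochs": trace.n_epochs})
        np.savetxt(directory / f"loss_k{k:g}_r{rep}.csv",
                   np.column_stack([np.arange(len(trace.loss)) * trace.thin,
                                    trace.loss]),
                   delimiter=",", header="epoch,loss", comments="")
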