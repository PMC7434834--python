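"""Quantitative analyses: KL similarity score, success judgments,
overfitting metrics, PB-space error maps, weight statistics, periodicity.

Generated and target time series are compared as *distributions of sensory
states*: each dimension's series is compressed along time into a histogram
on (-1, 1) with 50 bins, and the summed per-dimension KL divergence is the
similarity score SS (0 = identical distributions; phase shifts are
invisible by construction).  A behavior is judged correctly reproduced when
SS against its training data falls below the threshold xi = 0.5 x the
minimum cross-behavior SS among training sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model as _m
from .model import ModelConfig, NetworkParameters
from .synthetic import ROLE_PROPRIO, ROLE_VISION, SequenceDataset, SensorySequence

N_BINS_DEFAULT = 50
#: Laplace pseudo-count per bin before normalization; keeps every KL term
#: finite when the reference distribution misses a bin.
SMOOTHING = 1e-6


@dataclass
class StateDistribution:
    """Per-dimension histograms of sensory states on (-1, 1)."""

    probs: np.ndarray       # (D, n_bins), rows sum to 1
    edges: np.ndarray       # (n_bins + 1,)

    @property
    def n_dims(self) -> int:
        return self.probs.shape[0]

    @property
    def n_bins(self) -> int:
        return self.probs.shape[1]


@dataclass
class SimilarityResult:
    per_dim: np.ndarray
    score: float            # SS over the selected (decision) dimensions
    score_all_dims: float   # SS over every sensory dimension
    dims: np.ndarray        # indices of the decision dimensions


@dataclass
class OverfitReport:
    train_error: float
    test_error: float
    train_variance: float
    test_variance: float


@dataclass
class PBMap:
    activities: np.ndarray    # (G,) grid coordinates in activity space
    errors: np.ndarray        # (G, G) mean squared error; nan where |p|>=1
    behavior: str
    area_fraction: float      # fraction of valid cells with error < threshold
    threshold: float
    centroid: np.ndarray      # activity-space centroid of the sub-threshold region


def state_histogram(series: np.ndarray, n_bins: int = N_BINS_DEFAULT) -> StateDistribution:
    """Compress a (T,) or (T, D) series along time into per-dim histograms."""
    values = np.atleast_2d(np.asarray(series, dtype=float))
    if values.shape[0] == 1 and values.ndim == 2 and np.asarray(series).ndim == 1:
        values = values.T
    if np.any(np.abs(values) >= 1.0) or not np.all(np.isfinite(values)):
        raise ValueError("series values must lie strictly inside (-1, 1)")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    D = values.shape[1]
    probs = np.empty((D, n_bins))
    for d in range(D):
        counts, _ = np.histogram(values[:, d], bins=edges)
        smoothed = counts.astype(float) + SMOOTHING
        probs[d] = smoothed / smoothed.sum()
    return StateDistribution(probs=probs, edges=edges)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Sum_b p_b ln(p_b / q_b) with the convention 0 ln(0/q) = 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share their binning")
    mask = p > 0
    if np.any(q[mask] <= 0):
        raise ValueError("q must be positive wherever p is (use smoothing)")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def similarity_score(generated: np.ndarray, target: np.ndarray,
                     dims: np.ndarray | None = None,
                     n_bins: int = N_BINS_DEFAULT) -> SimilarityResult:
    """SS(p||q): summed per-dimension KL between state histograms.

    ``dims`` selects the decision dimensions (default: all columns, callers
    normally pass the proprioceptive/joint indices); the all-dimension score
    is always reported alongside.
    """
    gen = np.atleast_2d(np.asarray(generated, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    if gen.shape[1] != tgt.shape[1]:
        raise ValueError("generated and target must share their dimensions")
    if gen.shape[0] < 1 or tgt.shape[0] < 1:
        raise ValueError("series must be non-empty")
    hp = state_histogram(gen, n_bins)
    hq = state_histogram(tgt, n_bins)
    per_dim = np.array([kl_divergence(hp.probs[d], hq.probs[d])
                        for d in range(gen.shape[1])])
    if dims is None:
        dims = np.arange(gen.shape[1])
    dims = np.asarray(dims, dtype=int)
    return SimilarityResult(per_dim=per_dim,
                            score=float(per_dim[dims].sum()),
                            score_all_dims=float(per_dim.sum()),
                            dims=dims)


def _joint_dims(seq_or_ds) -> np.ndarray:
    roles = (seq_or_ds.channel_roles if hasattr(seq_or_ds, "channel_roles")
             else seq_or_ds)
    return np.array([i for i, r in enumerate(roles) if r == ROLE_PROPRIO])


def success_threshold(dataset: SequenceDataset,
                      n_bins: int = N_BINS_DEFAULT) -> float:
    """xi = 0.5 x the minimum cross-behavior SS over ordered training pairs."""
    left = dataset.train("left")
    right = dataset.train("right")
    if not left or not right:
        raise ValueError("threshold needs >= 1 training sequence per behavior")
    dims = _joint_dims(dataset)
    scores = []
    for a, b in [(x, y) for x in left for y in right] + \
                [(x, y) for x in right for y in left]:
        scores.append(similarity_score(a.values, b.values, dims, n_bins).score)
    return 0.5 * float(min(scores))


def best_match_score(generated: np.ndarray, candidates: list[SensorySequence],
                     dims: np.ndarray, n_bins: int = N_BINS_DEFAULT) -> float:
    return min(similarity_score(generated, c.values, dims, n_bins).score
               for c in candidates)


def judge_mental_simulation(params: NetworkParameters, config: ModelConfig,
                            dataset: SequenceDataset,
                            xi: float | None = None) -> dict:
    """Closed-loop reproduction test: one trial per training sequence.

    Each trial starts from a training sequence's first state with that
    sequence's trained PB value and generates the full length closed-loop.
    Success iff the joint-dimension SS against the behavior's best-matching
    training sequence is below xi.  Returns per-trial results and the rate.
    """
    if xi is None:
        xi = success_threshold(dataset)
    train = dataset.train()
    dims = _joint_dims(dataset)
    results = []
    for i, seq in enumerate(train):
        trace = _m.run_closed_loop(params, params.u0_pb[i], seq.values[0],
                                   seq.n_steps - 1)
        ss = best_match_score(trace.y, dataset.train(seq.behavior), dims)
        results.append({"behavior": seq.behavior, "ss": ss,
                        "success": bool(ss < xi)})
    rate = float(np.mean([r["success"] for r in results]))
    return {"trials": results, "success_rate": rate, "xi": xi}


def judge_flexibility(trial, params: NetworkParameters,
                      dataset: SequenceDataset,
                      xi: float | None = None) -> bool:
    """Did the network recognize the situation switch?

    Closed-loop generation from the PB state at the trial's end must match
    the post-switch behavior's training data (SS < xi on joint dims).
    """
    if trial.u_pb_final is None or trial.n_steps < trial.switch_step:
        raise ValueError("trial is incomplete")
    if xi is None:
        xi = success_threshold(dataset)
    post_behavior = trial.situations[-1]
    ref = dataset.train(post_behavior)
    T = ref[0].n_steps - 1
    trace = _m.run_closed_loop(params, trial.u_pb_final, ref[0].values[0], T)
    dims = _joint_dims(dataset)
    ss = best_match_score(trace.y, ref, dims)
    return bool(ss < xi)


def judge_generalization(trial, dataset: SequenceDataset,
                         xi: float | None = None) -> bool:
    """Did the pre-switch motor pattern match the intended behavior?

    In-silico stand-in for the ball-over-the-line criterion: the joint
    commands during the pre-switch phase are compared (SS on joint dims)
    against the initial behavior's training data.
    """
    if xi is None:
        xi = success_threshold(dataset)
    pre = trial.commands[:trial.switch_step]
    behavior = trial.initial_behavior
    dims_full = _joint_dims(dataset)
    refs = dataset.train(behavior)
    scores = []
    for ref in refs:
        ss = similarity_score(pre, ref.values[:, dims_full],
                              np.arange(pre.shape[1])).score
        scores.append(ss)
    return bool(min(scores) < xi)


def overfitting_metrics(params: NetworkParameters,
                        dataset: SequenceDataset) -> OverfitReport:
    """Open-loop MSE and mean predicted variance per split.

    Test sequences use the trained PB of a matching-behavior training
    sequence (the first one); averages run over steps x dims x sequences.
    """
    train = dataset.train()
    u0_by_behavior = {}
    for i, seq in enumerate(train):
        u0_by_behavior.setdefault(seq.behavior, params.u0_pb[i])
    out = {}
    for split in ("train", "test"):
        errs, vs = [], []
        for i, seq in enumerate(dataset.subset(split)):
            u0 = (params.u0_pb[i] if split == "train"
                  else u0_by_behavior[seq.behavior])
            trace = _m.run_open_loop(params, u0, seq)
            errs.append(np.mean((trace.y - seq.values[1:]) ** 2))
            vs.append(np.mean(trace.v))
        out[split] = (float(np.mean(errs)), float(np.mean(vs)))
    return OverfitReport(train_error=out["train"][0], test_error=out["test"][0],
                         train_variance=out["train"][1],
                         test_variance=out["test"][1])


def pb_error_map(params: NetworkParameters, dataset: SequenceDataset,
                 behavior: str, grid_resolution: int = 41,
                 threshold_factor: float = 2.0) -> PBMap:
    """Open-loop prediction error over a grid of PB activities.

    Grid nodes with |activity| >= 1 are excluded (atanh domain).  The
    sub-threshold region is the set of valid cells whose error is below
    ``threshold_factor`` x the map minimum; its area fraction measures how
    broadly the behavior is represented in PB space.
    """
    if grid_resolution < 11:
        raise ValueError("grid_resolution must be >= 11")
    acts = np.linspace(-1.0, 1.0, grid_resolution)
    valid = np.abs(acts) < 1.0
    av = acts[valid]
    P1, P2 = np.meshgrid(av, av, indexing="ij")
    U0 = np.arctanh(np.column_stack([P1.ravel(), P2.ravel()]))
    refs = dataset.train(behavior)
    if not refs:
        raise ValueError(f"no training data for behavior {behavior!r}")
    errs = np.zeros(U0.shape[0])
    for seq in refs:
        Y, _ = _m.open_loop_batch(params, U0, seq.values)
        errs += np.mean((Y - seq.values[1:][None]) ** 2, axis=(1, 2))
    errs /= len(refs)
    full = np.full((grid_resolution, grid_resolution), np.nan)
    sub = np.zeros((len(av), len(av)), dtype=bool)
    grid = errs.reshape(len(av), len(av))
    threshold = threshold_factor * float(grid.min())
    sub = grid < threshold
    ii = np.where(valid)[0]
    full[np.ix_(ii, ii)] = grid
    area_fraction = float(np.mean(sub))
    if sub.any():
        centroid = np.array([P1[sub].mean(), P2[sub].mean()])
    else:
        centroid = np.full(2, np.nan)
    return PBMap(activities=acts, errors=full, behavior=behavior,
                 area_fraction=area_fraction, threshold=threshold,
                 centroid=centroid)


def pb_map_centroid_distance(map_left: PBMap, map_right: PBMap) -> float:
    """Distance in PB-activity space between the two behaviors' regions."""
    return float(np.linalg.norm(map_left.centroid - map_right.centroid))


@dataclass
class WeightStats:
    std: float
    frac_weak: float
    histogram: np.ndarray
    edges: np.ndarray


def weight_distribution_stats(models: list[NetworkParameters],
                              n_bins: int = 81,
                              weak_threshold: float = 0.01,
                              bound: float | None = None) -> WeightStats:
    """Pooled context-to-context weight distribution over replicates."""
    if not models:
        raise ValueError("need at least one model")
    w = np.concatenate([m.W_context_to_context.ravel() for m in models])
    if bound is None:
        bound = max(1.0, float(np.max(np.abs(w))))
    edges = np.linspace(-bound, bound, n_bins + 1)
    hist, _ = np.histogram(w, bins=edges)
    return WeightStats(std=float(w.std()),
                       frac_weak=float(np.mean(np.abs(w) < weak_threshold)),
                       histogram=hist, edges=edges)


def context_periodicity(trace, period: int) -> np.ndarray:
    """Spectral power concentration at the template frequency, per neuron.

    Ratio of rFFT power within +/-1 bin of the template frequency to the
    total non-DC power.  Requires a trace of >= 3 periods.
    """
    C = trace.c if hasattr(trace, "c") else np.asarray(trace, dtype=float)
    T = C.shape[0]
    if T < 3 * period:
        raise ValueError("trace must cover at least 3 template periods")
    spec = np.abs(np.fft.rfft(C - C.mean(axis=0), axis=0)) ** 2
    spec[0] = 0.0
    k0 = int(round(T / period))
    lo, hi = max(1, k0 - 1), min(spec.shape[0] - 1, k0 + 1)
    total = spec.sum(axis=0)
    total[total == 0] = np.inf  # constant neuron -> index 0
    return spec[lo:hi + 1].sum(axis=0) / total
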