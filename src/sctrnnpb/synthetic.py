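"""Synthetic visuomotor sequences and a scripted interaction environment.

The experiments emulate a humanoid robot playing ball-pass games with a
partner: 8 proprioceptive channels (joint angles) and 2 vision channels
(ball position), all normalized to [-0.8, 0.8], sampled as periodic cycles.
Two behaviors exist ("left" and "right" ball-pass) whose vision trajectories
are mirror images in the horizontal ball coordinate and whose active arm
differs.  Sensor noise is i.i.d. Gaussian with variance 0.002 on every
channel at every step, providing the uncertainty floor the network has to
estimate during learning.

The real-time interaction phase is emulated by :class:`VirtualEnvironment`:
a scripted ball that follows one behavior's vision template and switches to
the other behavior at a fixed step, ignoring the arm (open-loop world).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

ROLE_PROPRIO = "proprio"
ROLE_VISION = "vision"
BEHAVIORS = ("left", "right")

#: Clip bound applied after noise injection; keeps values strictly inside
#: the tanh output range.  At amplitude 0.8 and noise variance 0.002 the
#: clip probability is ~Phi(-4.4), i.e. negligible.
CLIP_BOUND = 0.999


@dataclass(frozen=True)
class SequenceSpec:
    """Geometry and noise level of one behavior's target sequence.

    Defaults are the full-scale experiment values: 10 cycles of 106 steps
    (1,060 steps), 8 + 2 channels, amplitude bound 0.8, noise variance 0.002.
    """

    n_dims_proprio: int = 8
    n_dims_vision: int = 2
    cycle_length: int = 106
    n_cycles: int = 10
    amplitude_bound: float = 0.8
    noise_variance: float = 0.002
    behavior: str = "right"

    def __post_init__(self) -> None:
        if self.cycle_length < 4:
            raise ValueError(f"cycle_length must be >= 4, got {self.cycle_length}")
        if self.n_cycles < 1:
            raise ValueError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if not (0.0 < self.amplitude_bound < 1.0):
            raise ValueError(
                f"amplitude_bound must lie in (0, 1), got {self.amplitude_bound}"
            )
        if self.noise_variance < 0.0:
            raise ValueError(
                f"noise_variance must be >= 0, got {self.noise_variance}"
            )
        if self.n_dims_proprio < 1:
            raise ValueError(f"n_dims_proprio must be >= 1, got {self.n_dims_proprio}")
        if self.n_dims_vision < 1:
            raise ValueError(f"n_dims_vision must be >= 1, got {self.n_dims_vision}")
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"behavior must be one of {BEHAVIORS}, got {self.behavior!r}")

    @property
    def n_dims(self) -> int:
        return self.n_dims_proprio + self.n_dims_vision

    @property
    def n_steps(self) -> int:
        return self.cycle_length * self.n_cycles

    @property
    def channel_roles(self) -> tuple[str, ...]:
        return (ROLE_PROPRIO,) * self.n_dims_proprio + (ROLE_VISION,) * self.n_dims_vision


def desk_spec(behavior: str = "right", **overrides) -> SequenceSpec:
    """Desk-scale spec: 5 cycles of 40 steps (T=200), otherwise full-scale."""
    kw = dict(cycle_length=40, n_cycles=5, behavior=behavior)
    kw.update(overrides)
    return SequenceSpec(**kw)


@dataclass
class SensorySequence:
    """A T x D time series of normalized sensory states."""

    values: np.ndarray
    channel_roles: tuple[str, ...]
    behavior: str
    split: str = "train"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x D matrix")
        if self.values.shape[1] != len(self.channel_roles):
            raise ValueError("channel_roles length must match the number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(np.abs(self.values) >= 1.0):
            raise ValueError("values must lie strictly inside (-1, 1)")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    @property
    def proprio_idx(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == ROLE_PROPRIO])

    @property
    def vision_idx(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == ROLE_VISION])

    def to_csv(self, path: str | Path) -> None:
        header = ",".join(
            f"{role}_{i}" for i, role in enumerate(self.channel_roles)
        )
        np.savetxt(path, self.values, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path, behavior: str, split: str = "train",
                 seed: int | None = None) -> "SensorySequence":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
        roles = tuple(name.rsplit("_", 1)[0] for name in header)
        values = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(values=np.atleast_2d(values), channel_roles=roles,
                   behavior=behavior, split=split, seed=seed)


def generate_behavior_template(spec: SequenceSpec) -> SensorySequence:
    """Noiseless periodic target for one behavior.

    Proprioceptive channels are phase-shifted raised-cosine bump trains; the
    behavior determines which half of the channels is the "active arm"
    (full amplitude) versus the idle arm (30% amplitude).  Vision channel 1
    (horizontal ball position) dwells near the behavior's side and sweeps
    toward the robot once per cycle; left and right are exact mirror images
    in that channel.  Vision channel 2 (depth) is behavior-independent.
    All channels are exactly periodic with period ``cycle_length``.
    """
    P = spec.cycle_length
    T = spec.n_steps
    a = spec.amplitude_bound
    phase = (np.arange(T) % P) / P  # exact periodicity by construction
    values = np.zeros((T, spec.n_dims))

    npd = spec.n_dims_proprio
    half = (npd + 1) // 2
    for d in range(npd):
        offset = d / npd
        bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * (phase - offset)))
        wave = 2.0 * bump**2 - 1.0  # in [-1, 1], sharper than a sinusoid
        active = (d < half) if spec.behavior == "right" else (d >= half)
        amp = a if active else 0.3 * a
        values[:, d] = amp * wave

    side = 1.0 if spec.behavior == "right" else -1.0
    # dwell near the side (|x| = 0.8a) then sweep toward the robot (0.2a)
    vx = side * a * (0.2 + 0.3 * (1.0 + np.cos(2.0 * np.pi * phase)))
    vy = a * (0.1 + 0.25 * (1.0 - np.cos(2.0 * np.pi * phase)))
    values[:, npd] = vx
    if spec.n_dims_vision >= 2:
        values[:, npd + 1] = vy
    for extra in range(2, spec.n_dims_vision):
        values[:, npd + extra] = vy

    return SensorySequence(values=values, channel_roles=spec.channel_roles,
                           behavior=spec.behavior, split="template")


def add_sensory_noise(seq: SensorySequence, variance: float,
                      rng: np.random.Generator) -> SensorySequence:
    """Add i.i.d. Gaussian noise N(0, variance) to every element.

    Outputs are clipped to +/-CLIP_BOUND to stay inside the open interval
    (-1, 1) required downstream.
    """
    if variance < 0:
        raise ValueError(f"noise variance must be >= 0, got {variance}")
    noisy = seq.values + rng.normal(0.0, np.sqrt(variance), size=seq.values.shape)
    np.clip(noisy, -CLIP_BOUND, CLIP_BOUND, out=noisy)
    return replace(seq, values=noisy)


@dataclass
class SequenceDataset:
    """Noisy train/test realizations for both behaviors, plus provenance."""

    sequences: list[SensorySequence]
    specs: dict[str, SequenceSpec]
    seed: int | None = None
    test_phase_jitter: int = 3

    def subset(self, split: str, behavior: str | None = None) -> list[SensorySequence]:
        out = [s for s in self.sequences if s.split == split
               and (behavior is None or s.behavior == behavior)]
        return out

    def train(self, behavior: str | None = None) -> list[SensorySequence]:
        return self.subset("train", behavior)

    def test(self, behavior: str | None = None) -> list[SensorySequence]:
        return self.subset("test", behavior)

    @property
    def channel_roles(self) -> tuple[str, ...]:
        return self.sequences[0].channel_roles

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "test_phase_jitter": self.test_phase_jitter,
            "specs": {b: vars(s).copy() for b, s in self.specs.items()},
            "sequences": [
                {"behavior": s.behavior, "split": s.split, "seed": s.seed,
                 "n_steps": s.n_steps, "n_dims": s.n_dims}
                for s in self.sequences
            ],
        }

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(self.sequences):
            s.to_csv(directory / f"seq_{i:02d}_{s.behavior}_{s.split}.csv")
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)

    def to_npz(self, path: str | Path) -> None:
        arrays = {f"seq_{i:02d}": s.values for i, s in enumerate(self.sequences)}
        np.savez(path, manifest=json.dumps(self.manifest()), **arrays)

    @classmethod
    def from_npz(cls, path: str | Path) -> "SequenceDataset":
        with np.load(path, allow_pickle=False) as archive:
            manifest = json.loads(str(archive["manifest"]))
            sequences = []
            for i, meta in enumerate(manifest["sequences"]):
                spec = SequenceSpec(**manifest["specs"][meta["behavior"]])
                sequences.append(SensorySequence(
                    values=archive[f"seq_{i:02d}"],
                    channel_roles=spec.channel_roles,
                    behavior=meta["behavior"], split=meta["split"],
                    seed=meta["seed"]))
        specs = {b: SequenceSpec(**d) for b, d in manifest["specs"].items()}
        return cls(sequences=sequences, specs=specs, seed=manifest["seed"],
                   test_phase_jitter=manifest["test_phase_jitter"])


def build_dataset(spec: SequenceSpec, n_train_per_behavior: int = 3,
                  n_test_per_behavior: int = 3,
                  rng: np.random.Generator | int | None = None,
                  test_phase_jitter: int = 3) -> SequenceDataset:
    """Noisy realizations of both behavior templates.

    Train sequences differ only in their noise realization; test sequences
    additionally receive a small uniform integer phase jitter (default
    +/-3 steps), emulating timing differences between recordings.
    The given ``spec``'s behavior field is ignored: both behaviors are
    always generated.
    """
    if n_train_per_behavior < 1:
        raise ValueError("n_train_per_behavior must be >= 1")
    if n_test_per_behavior < 0:
        raise ValueError("n_test_per_behavior must be >= 0")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(rng) if rng is not None else 0
        rng = np.random.default_rng(seed)

    sequences: list[SensorySequence] = []
    specs: dict[str, SequenceSpec] = {}
    for behavior in BEHAVIORS:
        bspec = replace(spec, behavior=behavior)
        specs[behavior] = bspec
        template = generate_behavior_template(bspec)
        for split, count in (("train", n_train_per_behavior),
                             ("test", n_test_per_behavior)):
            for _ in range(count):
                base = template
                if split == "test" and test_phase_jitter > 0:
                    shift = int(rng.integers(-test_phase_jitter,
                                             test_phase_jitter + 1))
                    base = replace(template,
                                   values=np.roll(template.values, shift, axis=0))
                noisy = add_sensory_noise(base, bspec.noise_variance, rng)
                sequences.append(replace(noisy, behavior=behavior, split=split))
    return SequenceDataset(sequences=sequences, specs=specs, seed=seed,
                           test_phase_jitter=test_phase_jitter)


@dataclass
class EnvironmentState:
    """Bookkeeping for the scripted interaction environment."""

    step: int = 0
    situation: str = "right"
    switch_step: int = 120
    trial_length: int = 300
    jitter: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.switch_step < self.trial_length):
            raise ValueError(
                f"switch_step must lie in (0, trial_length); got "
                f"switch_step={self.switch_step}, trial_length={self.trial_length}"
            )
        if self.situation not in BEHAVIORS:
            raise ValueError(f"situation must be one of {BEHAVIORS}")


class VirtualEnvironment:
    """Scripted ball: vision follows the active behavior's template.

    The situation flips exactly once, at ``switch_step``.  Joint commands
    are logged but do not influence the ball (open-loop world): task success
    is judged downstream by trajectory similarity rather than ball physics.
    """

    def __init__(self, spec: SequenceSpec, initial_situation: str = "right",
                 switch_step: int = 120, trial_length: int = 300,
                 jitter: int = 0, noise_variance: float | None = None,
                 rng: np.random.Generator | int | None = None):
        self.state = EnvironmentState(step=0, situation=initial_situation,
                                      switch_step=switch_step,
                                      trial_length=trial_length, jitter=jitter)
        self.spec = spec
        self.noise_variance = (spec.noise_variance if noise_variance is None
                               else noise_variance)
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        self.rng = (rng if isinstance(rng, np.random.Generator)
                    else np.random.default_rng(rng))
        self._initial_situation = initial_situation
        self._templates = {}
        for behavior in BEHAVIORS:
            tmpl = generate_behavior_template(replace(spec, behavior=behavior))
            self._templates[behavior] = tmpl.values[:, tmpl.vision_idx]
        self.command_log: list[np.ndarray] = []
        self.observation_log: list[np.ndarray] = []
        self.situation_log: list[str] = []

    @property
    def vision_dim(self) -> int:
        return self.spec.n_dims_vision

    def active_situation(self, step: int) -> str:
        if step < self.state.switch_step:
            return self._initial_situation
        return next(b for b in BEHAVIORS if b != self._initial_situation)

    def step(self, joint_command: np.ndarray) -> np.ndarray:
        """Return the vision observation for the current step, then advance."""
        st = self.state
        if st.step >= st.trial_length:
            raise RuntimeError(
                f"environment exhausted: trial_length={st.trial_length}")
        situation = self.active_situation(st.step)
        st.situation = situation
        template = self._templates[situation]
        row = (st.step + st.jitter) % template.shape[0]
        obs = template[row].copy()
        if self.noise_variance > 0:
            obs += self.rng.normal(0.0, np.sqrt(self.noise_variance), obs.shape)
        np.clip(obs, -CLIP_BOUND, CLIP_BOUND, out=obs)
        self.command_log.append(np.asarray(joint_command, dtype=float).copy())
        self.observation_log.append(obs.copy())
        self.situation_log.append(situation)
        st.step += 1
        return obs


def environment_step(env: VirtualEnvironment, joint_command: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`VirtualEnvironment.step`."""
    return env.step(joint_command)
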