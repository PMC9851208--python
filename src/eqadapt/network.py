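"""Layered dynamical networks and their two-phase relaxation dynamics.

A :class:`LayeredNetwork` is a continuous-valued rate network organised in
layers.  Learning happens in two relaxation phases integrated by explicit
Euler steps:

* the **free phase** presents the input alone and lets every non-input unit
  relax toward a fixed point ``x = p(feedforward + feedback + lateral + bias)``;
* the **clamped phase** additionally drives the output layer toward the
  target — completely (hard clamp, contrastive Hebbian learning) or through a
  nudging term of strength ``beta`` (soft clamp, equilibrium propagation).
  A configurable *teaching delay* lets the first steps of the clamped phase
  run free dynamics, modelling the late arrival of top-down teaching signals.

After the clamped phase an optional **adaptation** relaxation pulls every
unit back toward its free-phase steady state,
``x <- (1 - c) * x + c * x_free``, shrinking the free/clamped activity gap
geometrically before the weight update is computed.

Activities are stored batch-first: each layer of an :class:`ActivityState`
is a ``(batch, units)`` array.  Single vectors are promoted to a batch of 1.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Iterable, Sequence

import numpy as np
import h5py
import yaml
from scipy.special import expit

from .errors import ConfigurationError, StructuralError, ValidationError

__all__ = [
    "ACTIVATIONS",
    "ActivityState",
    "LayeredNetwork",
    "PhaseResult",
    "PhaseSchedule",
    "activation_fn",
    "clamped_step",
    "free_step",
    "run_adaptation",
    "run_clamped_phase",
    "run_free_phase",
    "run_phases",
]


def _hard_sigmoid(z: np.ndarray) -> np.ndarray:
    return np.clip((z + 1.0) / 2.0, 0.0, 1.0)


ACTIVATIONS = {"sigmoid": expit, "hard_sigmoid": _hard_sigmoid}


def activation_fn(name: str):
    """Return the activation callable for ``name`` (sigmoid | hard_sigmoid)."""
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None


@dataclasses.dataclass
class PhaseSchedule:
    """Step counts and constants governing the relaxation phases.

    Parameters
    ----------
    n_free, n_clamped
        Euler steps for the free and clamped phases.
    teach_delay
        Clamped-phase steps before the target engages; until then the
        clamped phase runs free dynamics.
    n_adapt
        Adaptation relaxation steps applied after the clamped phase.
    h
        Euler time-step (0.1 for the dense networks, 1.0 for the
        convolutional one).
    beta
        Nudging strength of the soft clamp; also the ``1/beta`` normaliser
        of the equilibrium-propagation update rule.
    c
        Adaptation coefficient in [0, 1]; per-step pull toward the
        free-phase steady state.
    clamp_mode
        ``"hard"`` sets outputs exactly to the target; ``"soft"`` nudges
        them with strength ``beta``.
    clamp_init_step
        If set, the clamped phase starts from the free-phase state recorded
        at this step instead of the final free state (used by the
        convolutional model).
    """

    n_free: int = 120
    n_clamped: int = 120
    teach_delay: int = 12
    n_adapt: int = 20
    h: float = 0.1
    beta: float = 1.0
    c: float = 0.1
    clamp_mode: str = "hard"
    clamp_init_step: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_free", "n_clamped", "teach_delay", "n_adapt"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.teach_delay > self.n_clamped:
            raise ConfigurationError(
                f"teach_delay ({self.teach_delay}) may not exceed n_clamped ({self.n_clamped})"
            )
        if not 0.0 <= self.c <= 1.0:
            raise ConfigurationError(f"adaptation coefficient c must lie in [0, 1], got {self.c}")
        if self.h < 0:
            raise ConfigurationError(f"Euler step h must be >= 0, got {self.h}")
        if self.clamp_mode not in ("hard", "soft"):
            raise ConfigurationError(f"clamp_mode must be 'hard' or 'soft', got {self.clamp_mode!r}")
        if self.clamp_mode == "soft" and not self.beta > 0:
            raise ConfigurationError(f"soft clamping requires beta > 0, got beta={self.beta}")
        if self.clamp_init_step is not None and not 0 <= self.clamp_init_step <= self.n_free:
            raise ConfigurationError(
                f"clamp_init_step must lie in [0, n_free], got {self.clamp_init_step}"
            )

    # -- plain-text config round-trip ------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseSchedule":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown schedule fields: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "PhaseSchedule":
        text = pathlib.Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))


@dataclasses.dataclass
class ActivityState:
    """Per-layer activity arrays ``(batch, units)`` at one time step.

    The input layer (index 0) is part of the state but is never modified by
    the dynamics.
    """

    layers: list[np.ndarray]

    def __post_init__(self) -> None:
        self.layers = [np.atleast_2d(np.asarray(a, dtype=float)) for a in self.layers]
        batches = {a.shape[0] for a in self.layers}
        if len(batches) != 1:
            raise StructuralError(f"inconsistent batch sizes across layers: {sorted(batches)}")

    @property
    def batch_size(self) -> int:
        return self.layers[0].shape[0]

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(a.shape[1] for a in self.layers)

    def copy(self) -> "ActivityState":
        return ActivityState([a.copy() for a in self.layers])

    def allclose(self, other: "ActivityState", **kw) -> bool:
        return len(self.layers) == len(other.layers) and all(
            np.allclose(a, b, **kw) for a, b in zip(self.layers, other.layers)
        )


@dataclasses.dataclass
class PhaseResult:
    """Recorded outcome of one free/clamped/adaptation pass.

    ``adapted_state`` equals ``clamped_state`` whenever ``n_adapt == 0`` or
    ``c == 0``.  ``schedule`` is the schedule the phases were run with (the
    learning rules read ``beta`` and ``n_adapt`` from it).
    """

    free_state: ActivityState
    clamped_state: ActivityState
    adapted_state: ActivityState
    schedule: PhaseSchedule
    traces: dict[str, list[ActivityState]] | None = None


class LayeredNetwork:
    """Fully connected layered network with optional lateral recurrence.

    Feedback (top-down) weights are the transpose of the forward weights
    scaled by the feedback gain ``gamma``; only one weight matrix per layer
    pair is stored and trained.  Lateral matrices are square with a hard
    zero diagonal (no self-loops) and are not symmetrised.
    """

    def __init__(
        self,
        layer_sizes: Sequence[int],
        weights: Sequence[np.ndarray],
        biases: Sequence[np.ndarray],
        lateral_weights: dict[int, np.ndarray] | None = None,
        feedback_gain: float = 0.0,
        activation: str = "sigmoid",
        seed: int | None = None,
    ) -> None:
        self.layer_sizes = [int(s) for s in layer_sizes]
        if len(self.layer_sizes) < 2 or any(s <= 0 for s in self.layer_sizes):
            raise StructuralError(f"layer_sizes must be >= 2 positive integers, got {layer_sizes}")
        self.weights = [np.asarray(w, dtype=float) for w in weights]
        self.biases = [np.asarray(b, dtype=float) for b in biases]
        self.lateral_weights = {
            int(k): np.asarray(v, dtype=float) for k, v in (lateral_weights or {}).items()
        }
        if feedback_gain < 0:
            raise ConfigurationError(f"feedback gain must be >= 0, got {feedback_gain}")
        self.feedback_gain = float(feedback_gain)
        activation_fn(activation)  # raises on unknown name
        self.activation = activation
        self.seed = seed
        self._validate_shapes()

    # ------------------------------------------------------------------
    def _validate_shapes(self) -> None:
        sizes = self.layer_sizes
        if len(self.weights) != len(sizes) - 1:
            raise StructuralError(
                f"expected {len(sizes) - 1} weight matrices, got {len(self.weights)}"
            )
        for i, w in enumerate(self.weights):
            if w.shape != (sizes[i], sizes[i + 1]):
                raise StructuralError(
                    f"weights[{i}] has shape {w.shape}, expected {(sizes[i], sizes[i + 1])}"
                )
        if len(self.biases) != len(sizes) - 1:
            raise StructuralError(
                f"expected {len(sizes) - 1} bias vectors, got {len(self.biases)}"
            )
        for i, b in enumerate(self.biases):
            if b.shape != (sizes[i + 1],):
                raise StructuralError(
                    f"biases[{i}] has shape {b.shape}, expected {(sizes[i + 1],)}"
                )
        for layer, m in self.lateral_weights.items():
            if layer < 1 or layer >= len(sizes):
                raise StructuralError(f"lateral weights on non-existent layer {layer}")
            n = sizes[layer]
            if m.shape != (n, n):
                raise StructuralError(
                    f"lateral matrix for layer {layer} has shape {m.shape}, expected {(n, n)}"
                )
            if np.any(np.diagonal(m) != 0.0):
                raise StructuralError(f"lateral matrix for layer {layer} has non-zero diagonal")

    @classmethod
    def initialize(
        cls,
        layer_sizes: Sequence[int],
        seed: int = 0,
        feedback_gain: float = 0.0,
        activation: str = "sigmoid",
        lateral_layers: Iterable[int] = (),
    ) -> "LayeredNetwork":
        """Glorot-uniform weights, zero biases, zero lateral matrices."""
        rng = np.random.default_rng(seed)
        sizes = [int(s) for s in layer_sizes]
        weights = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases = [np.zeros(s) for s in sizes[1:]]
        laterals = {int(l): np.zeros((sizes[int(l)], sizes[int(l)])) for l in lateral_layers}
        return cls(
            sizes,
            weights,
            biases,
            lateral_weights=laterals,
            feedback_gain=feedback_gain,
            activation=activation,
            seed=seed,
        )

    # ------------------------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    def initial_state(self, inputs: np.ndarray) -> ActivityState:
        """All-zero non-input activities with the input layer populated."""
        x0 = np.atleast_2d(np.asarray(inputs, dtype=float))
        if x0.shape[1] != self.layer_sizes[0]:
            raise StructuralError(
                f"input has {x0.shape[1]} features, network expects {self.layer_sizes[0]}"
            )
        if not np.all(np.isfinite(x0)):
            raise ValidationError("non-finite values in input")
        b = x0.shape[0]
        return ActivityState([x0] + [np.zeros((b, s)) for s in self.layer_sizes[1:]])

    def check_finite(self) -> None:
        for i, w in enumerate(self.weights):
            if not np.all(np.isfinite(w)):
                raise ValidationError(f"non-finite entries in weights[{i}]")
        for i, b in enumerate(self.biases):
            if not np.all(np.isfinite(b)):
                raise ValidationError(f"non-finite entries in biases[{i}]")
        for layer, m in self.lateral_weights.items():
            if not np.all(np.isfinite(m)):
                raise ValidationError(f"non-finite entries in lateral weights of layer {layer}")

    def copy(self) -> "LayeredNetwork":
        return LayeredNetwork(
            list(self.layer_sizes),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            {k: v.copy() for k, v in self.lateral_weights.items()},
            feedback_gain=self.feedback_gain,
            activation=self.activation,
            seed=self.seed,
        )

    # -- checkpointing ---------------------------------------------------
    def save(self, path: str | pathlib.Path) -> None:
        """Write a single-file HDF5 checkpoint."""
        with h5py.File(path, "w") as f:
            f.attrs["layer_sizes"] = np.asarray(self.layer_sizes)
            f.attrs["feedback_gain"] = self.feedback_gain
            f.attrs["activation"] = self.activation
            if self.seed is not None:
                f.attrs["seed"] = int(self.seed)
            for i, w in enumerate(self.weights):
                f.create_dataset(f"weights/{i}", data=w)
            for i, b in enumerate(self.biases):
                f.create_dataset(f"biases/{i}", data=b)
            for layer, m in self.lateral_weights.items():
                f.create_dataset(f"lateral/{layer}", data=m)

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "LayeredNetwork":
        with h5py.File(path, "r") as f:
            sizes = [int(s) for s in f.attrs["layer_sizes"]]
            weights = [f[f"weights/{i}"][()] for i in range(len(sizes) - 1)]
            biases = [f[f"biases/{i}"][()] for i in range(len(sizes) - 1)]
            laterals = {}
            if "lateral" in f:
                laterals = {int(k): f[f"lateral/{k}"][()] for k in f["lateral"]}
            seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
            return cls(
                sizes,
                weights,
                biases,
                lateral_weights=laterals,
                feedback_gain=float(f.attrs["feedback_gain"]),
                activation=str(f.attrs["activation"]),
                seed=seed,
            )


# ----------------------------------------------------------------------
# Dynamics
# ----------------------------------------------------------------------

def _preactivations(net: LayeredNetwork, layers: list[np.ndarray]) -> list[np.ndarray]:
    """Pre-activation z for every non-input layer, from the previous state.

    z_l = W_{l-1}^T x_{l-1} + gamma * W_l x_{l+1} + L_l x_l + b_l, with the
    feedback term present only for layers that have a successor.
    """
    L = net.n_layers
    zs = []
    for l in range(1, L):
        z = layers[l - 1] @ net.weights[l - 1] + net.biases[l - 1]
        if l < L - 1:
            z = z + net.feedback_gain * (layers[l + 1] @ net.weights[l].T)
        lat = net.lateral_weights.get(l)
        if lat is not None:
            z = z + layers[l] @ lat
        zs.append(z)
    return zs


def _check_state(net: LayeredNetwork, state: ActivityState) -> None:
    if state.layer_sizes != tuple(net.layer_sizes):
        raise StructuralError(
            f"state layer sizes {state.layer_sizes} do not match network {tuple(net.layer_sizes)}"
        )
    for a in state.layers:
        if not np.all(np.isfinite(a)):
            raise ValidationError("non-finite activities in state")


def free_step(net: LayeredNetwork, state: ActivityState, schedule: PhaseSchedule) -> ActivityState:
    """One Euler step of the free dynamics; the input layer is untouched."""
    _check_state(net, state)
    act = activation_fn(net.activation)
    h = schedule.h
    zs = _preactivations(net, state.layers)
    new_layers = [state.layers[0]]
    for x, z in zip(state.layers[1:], zs):
        new_layers.append(x + h * (-x + act(z)))
    return ActivityState(new_layers)


def clamped_step(
    net: LayeredNetwork,
    state: ActivityState,
    target: np.ndarray,
    schedule: PhaseSchedule,
    step_index: int,
) -> ActivityState:
    """One Euler step of the clamped dynamics.

    Before ``teach_delay`` steps have elapsed the teaching signal has not
    arrived and the step is identical to :func:`free_step`.  Afterwards the
    output layer is either set to the target exactly (hard clamp) or nudged
    toward it with strength ``beta`` (soft clamp); hidden layers always
    follow the free dynamics.
    """
    if step_index < 0:
        raise ConfigurationError(f"step_index must be >= 0, got {step_index}")
    y = np.atleast_2d(np.asarray(target, dtype=float))
    if y.shape[1] != net.layer_sizes[-1]:
        raise StructuralError(
            f"target has {y.shape[1]} entries, output layer has {net.layer_sizes[-1]}"
        )
    if step_index < schedule.teach_delay:
        return free_step(net, state, schedule)
    _check_state(net, state)
    act = activation_fn(net.activation)
    h = schedule.h
    zs = _preactivations(net, state.layers)
    new_layers = [state.layers[0]]
    for x, z in zip(state.layers[1:-1], zs[:-1]):
        new_layers.append(x + h * (-x + act(z)))
    x_o = state.layers[-1]
    if schedule.clamp_mode == "hard":
        new_layers.append(np.broadcast_to(y, x_o.shape).copy())
    else:
        if not schedule.beta > 0:
            raise ConfigurationError("soft clamping requires beta > 0")
        new_layers.append(x_o + h * (-x_o + act(zs[-1]) + schedule.beta * (y - x_o)))
    return ActivityState(new_layers)


def run_free_phase(
    net: LayeredNetwork,
    inputs: np.ndarray,
    schedule: PhaseSchedule,
    record_trace: bool = True,
) -> tuple[ActivityState, list[ActivityState]]:
    """Relax from all-zero non-input activities for ``n_free`` steps.

    Returns the final state (the approximate free steady state) and the
    per-step trace including the initial state (length ``n_free + 1``); the
    trace holds only the initial and final state when ``record_trace`` is
    False.
    """
    net.check_finite()
    state = net.initial_state(inputs)
    trace = [state]
    for _ in range(schedule.n_free):
        state = free_step(net, state, schedule)
        if record_trace:
            trace.append(state)
    if not record_trace:
        trace = [trace[0], state]
    return state, trace


def run_clamped_phase(
    net: LayeredNetwork,
    initial: ActivityState,
    target: np.ndarray,
    schedule: PhaseSchedule,
    record_trace: bool = True,
) -> tuple[ActivityState, list[ActivityState]]:
    """Run ``n_clamped`` clamped steps from a supplied (free-phase) state."""
    net.check_finite()
    _check_state(net, initial)
    y = np.atleast_2d(np.asarray(target, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite values in target")
    if net.activation == "sigmoid" and (np.any(y < 0) or np.any(y > 1)):
        raise ValidationError("targets must lie in [0, 1] for sigmoid networks")
    state = initial
    trace = [state]
    for t in range(schedule.n_clamped):
        state = clamped_step(net, state, y, schedule, t)
        if record_trace:
            trace.append(state)
    if not record_trace:
        trace = [trace[0], state]
    return state, trace


def run_adaptation(
    clamped: ActivityState,
    free_ss: ActivityState,
    schedule: PhaseSchedule,
    record_trace: bool = True,
) -> tuple[ActivityState, list[ActivityState]]:
    """Relax the clamped state toward the free steady state.

    Every non-input unit follows ``x <- (1 - c) * x + c * x_free`` for
    ``n_adapt`` steps; no other dynamics run.  The closed form is
    ``x_free + (1 - c)**n_adapt * (x_clamped - x_free)``.
    """
    if clamped.layer_sizes != free_ss.layer_sizes:
        raise StructuralError(
            f"clamped and free states disagree: {clamped.layer_sizes} vs {free_ss.layer_sizes}"
        )
    c = schedule.c
    state = clamped
    trace = [state]
    for _ in range(schedule.n_adapt):
        new_layers = [state.layers[0]]
        for x, xf in zip(state.layers[1:], free_ss.layers[1:]):
            new_layers.append((1.0 - c) * x + c * xf)
        state = ActivityState(new_layers)
        if record_trace:
            trace.append(state)
    if not record_trace:
        trace = [trace[0], state]
    return state, trace


def run_phases(
    net: LayeredNetwork,
    inputs: np.ndarray,
    targets: np.ndarray,
    schedule: PhaseSchedule,
    record_traces: bool = False,
) -> PhaseResult:
    """Full free -> clamped -> adaptation pass for one (mini-batch of) input.

    The clamped phase starts from the final free state, or from the
    free-phase state recorded at ``schedule.clamp_init_step`` when that is
    set (the convolutional model's snapshot initialisation).
    """
    free_state, free_trace = run_free_phase(
        net, inputs, schedule, record_trace=record_traces or schedule.clamp_init_step is not None
    )
    if schedule.clamp_init_step is not None:
        clamp_init = free_trace[schedule.clamp_init_step]
    else:
        clamp_init = free_state
    clamped_state, clamped_trace = run_clamped_phase(
        net, clamp_init, targets, schedule, record_trace=record_traces
    )
    adapted_state, adapt_trace = run_adaptation(
        clamped_state, free_state, schedule, record_trace=record_traces
    )
    traces = None
    if record_traces:
        traces = {"free": free_trace, "clamped": clamped_trace, "adaptation": adapt_trace}
    return PhaseResult(
        free_state=free_state,
        clamped_state=clamped_state,
        adapted_state=adapted_state,
        schedule=schedule,
        traces=traces,
    )
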