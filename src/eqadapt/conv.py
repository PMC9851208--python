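"""Convolutional equilibrium propagation with adaptation.

Same two-phase relaxation as the dense networks, with the weighted sums
replaced by stride-1 "same" convolutions and the top-down feedback realised
as the transposed convolution of the forward kernels (no pooling; the
activation is the hard sigmoid throughout, with Euler step h = 1 the
relaxation reduces to a damped synchronous map).  The clamped phase is
soft-clamp only (EP) and starts from the free-phase state recorded at
``schedule.clamp_init_step``, which plays the role of the dense models'
teaching-signal delay.  Updates follow the predictive EP rule with one
learning rate per parameter stage and no optimizer.

A convolution with 1x1 kernels on a 1x1 image is exactly a dense layer, so
the dense dynamics serve as a bit-for-bit oracle for this module (covered in
the test suite).
"""

from __future__ import annotations

import dataclasses
import time
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, StructuralError, ValidationError
from .network import PhaseSchedule, activation_fn

__all__ = ["ConvNetwork", "ConvState", "conv_free_phase", "conv_clamped_phase",
           "conv_adaptation", "conv_predictive_update", "conv_train", "conv_error"]


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding k-by-k windows of a (B, C, H, W) tensor, "same" zero padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return sliding_window_view(xp, (k, k), axis=(2, 3))


def conv_same(x: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Stride-1 same-padding cross-correlation; K is (out, in, k, k)."""
    return np.einsum("bchwuv,ocuv->bohw", _windows(x, K.shape[-1]), K)


def conv_transpose_same(y: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`conv_same` (spatially flipped kernels)."""
    Kf = K[:, :, ::-1, ::-1]
    return np.einsum("bohwuv,ocuv->bchw", _windows(y, K.shape[-1]), Kf)


@dataclasses.dataclass
class ConvState:
    """Activities of one step: input image, feature maps, output vector."""

    layers: list[np.ndarray]  # [(B,C,H,W), (B,F1,H,W), ..., (B,k)]

    def copy(self) -> "ConvState":
        return ConvState([a.copy() for a in self.layers])


class ConvNetwork:
    """Convolutional stages plus one dense readout, hard-sigmoid activation.

    Kernels are ``(out_channels, in_channels, k, k)`` with odd ``k``; every
    stage keeps the spatial size (stride 1, zero "same" padding).  Feedback
    between conv stages is the transposed convolution of the forward kernel
    scaled by ``feedback_gain``; the last stage receives dense feedback from
    the output layer.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        kernels: Sequence[np.ndarray],
        stage_biases: Sequence[np.ndarray],
        dense_weight: np.ndarray,
        dense_bias: np.ndarray,
        feedback_gain: float = 1.0,
        seed: int | None = None,
    ) -> None:
        self.input_shape = tuple(int(s) for s in input_shape)
        self.kernels = [np.asarray(k, dtype=float) for k in kernels]
        self.stage_biases = [np.asarray(b, dtype=float) for b in stage_biases]
        self.dense_weight = np.asarray(dense_weight, dtype=float)
        self.dense_bias = np.asarray(dense_bias, dtype=float)
        self.feedback_gain = float(feedback_gain)
        self.activation = "hard_sigmoid"
        self.seed = seed
        self._validate()

    def _validate(self) -> None:
        C, H, W = self.input_shape
        in_ch = C
        for i, (K, b) in enumerate(zip(self.kernels, self.stage_biases)):
            if K.ndim != 4 or K.shape[1] != in_ch or K.shape[2] != K.shape[3] or K.shape[2] % 2 == 0:
                raise StructuralError(
                    f"kernel {i} has shape {K.shape}; expected (out, {in_ch}, k, k) with odd k"
                )
            if b.shape != (K.shape[0],):
                raise StructuralError(f"stage bias {i} has shape {b.shape}, expected ({K.shape[0]},)")
            if not np.all(np.isfinite(K)):
                raise ValidationError(f"non-finite entries in kernel {i}")
            in_ch = K.shape[0]
        flat = in_ch * H * W
        if self.dense_weight.shape[0] != flat:
            raise StructuralError(
                f"dense weight expects {self.dense_weight.shape[0]} inputs, "
                f"feature maps flatten to {flat}"
            )
        if self.dense_bias.shape != (self.dense_weight.shape[1],):
            raise StructuralError("dense bias shape mismatch")

    @classmethod
    def initialize(
        cls,
        input_shape: tuple[int, int, int],
        stage_filters: Sequence[int],
        n_classes: int,
        kernel_size: int = 3,
        feedback_gain: float = 1.0,
        seed: int = 0,
    ) -> "ConvNetwork":
        rng = np.random.default_rng(seed)
        C, H, W = input_shape
        kernels, biases = [], []
        in_ch = C
        for f in stage_filters:
            fan_in = in_ch * kernel_size**2
            fan_out = f * kernel_size**2
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            kernels.append(rng.uniform(-limit, limit, size=(f, in_ch, kernel_size, kernel_size)))
            biases.append(np.zeros(f))
            in_ch = f
        flat = in_ch * H * W
        limit = np.sqrt(6.0 / (flat + n_classes))
        dense_w = rng.uniform(-limit, limit, size=(flat, n_classes))
        return cls(input_shape, kernels, biases, dense_w, np.zeros(n_classes),
                   feedback_gain=feedback_gain, seed=seed)

    # ------------------------------------------------------------------
    @property
    def n_stages(self) -> int:
        return len(self.kernels)

    def initial_state(self, images: np.ndarray) -> ConvState:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise StructuralError(f"images have shape {x.shape[1:]}, expected {self.input_shape}")
        if not np.all(np.isfinite(x)):
            raise ValidationError("non-finite values in images")
        B = x.shape[0]
        _, H, W = self.input_shape
        layers = [x]
        for K in self.kernels:
            layers.append(np.zeros((B, K.shape[0], H, W)))
        layers.append(np.zeros((B, self.dense_bias.shape[0])))
        return ConvState(layers)

    def copy(self) -> "ConvNetwork":
        return ConvNetwork(
            self.input_shape,
            [k.copy() for k in self.kernels],
            [b.copy() for b in self.stage_biases],
            self.dense_weight.copy(),
            self.dense_bias.copy(),
            feedback_gain=self.feedback_gain,
            seed=self.seed,
        )


# ----------------------------------------------------------------------
# Dynamics
# ----------------------------------------------------------------------

def _preactivations(net: ConvNetwork, layers: list[np.ndarray]) -> list[np.ndarray]:
    S = net.n_stages
    B = layers[0].shape[0]
    zs = []
    for s in range(S):
        z = conv_same(layers[s], net.kernels[s]) + net.stage_biases[s][None, :, None, None]
        if s < S - 1:
            z = z + net.feedback_gain * conv_transpose_same(layers[s + 2], net.kernels[s + 1])
        else:
            fb = layers[S + 1] @ net.dense_weight.T
            z = z + net.feedback_gain * fb.reshape(layers[S].shape)
        zs.append(z)
    z_out = layers[S].reshape(B, -1) @ net.dense_weight + net.dense_bias
    zs.append(z_out)
    return zs


def _free_step(net: ConvNetwork, state: ConvState, h: float) -> ConvState:
    act = activation_fn(net.activation)
    zs = _preactivations(net, state.layers)
    new = [state.layers[0]]
    for x, z in zip(state.layers[1:], zs):
        new.append(x + h * (-x + act(z)))
    return ConvState(new)


def _clamped_step(
    net: ConvNetwork, state: ConvState, y: np.ndarray, schedule: PhaseSchedule, step_index: int
) -> ConvState:
    if step_index < schedule.teach_delay:
        return _free_step(net, state, schedule.h)
    act = activation_fn(net.activation)
    h = schedule.h
    zs = _preactivations(net, state.layers)
    new = [state.layers[0]]
    for x, z in zip(state.layers[1:-1], zs[:-1]):
        new.append(x + h * (-x + act(z)))
    x_o = state.layers[-1]
    new.append(x_o + h * (-x_o + act(zs[-1]) + schedule.beta * (y - x_o)))
    return ConvState(new)


def conv_free_phase(
    net: ConvNetwork, images: np.ndarray, schedule: PhaseSchedule, record_trace: bool = True
) -> tuple[ConvState, list[ConvState]]:
    """Free relaxation from zero feature maps; returns final state and trace.

    When ``record_trace`` is False the trace holds only the initial state,
    the snapshot at ``schedule.clamp_init_step`` (if configured), and the
    final state — full traces of large feature maps are expensive.
    """
    state = net.initial_state(images)
    trace = [state]
    snapshot = state if schedule.clamp_init_step == 0 else None
    for t in range(schedule.n_free):
        state = _free_step(net, state, schedule.h)
        if record_trace:
            trace.append(state)
        if schedule.clamp_init_step is not None and t + 1 == schedule.clamp_init_step:
            snapshot = state
    if not record_trace:
        trace = [trace[0]] + ([snapshot] if snapshot is not None else []) + [state]
    return state, trace


def conv_clamped_phase(
    net: ConvNetwork,
    initial: ConvState,
    targets: np.ndarray,
    schedule: PhaseSchedule,
    record_trace: bool = False,
) -> tuple[ConvState, list[ConvState]]:
    """Soft-clamped relaxation from a supplied (snapshot) state."""
    if schedule.clamp_mode != "soft":
        raise ConfigurationError("the convolutional model supports soft clamping (EP) only")
    y = np.atleast_2d(np.asarray(targets, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite values in target")
    state = initial
    trace = [state]
    for t in range(schedule.n_clamped):
        state = _clamped_step(net, state, y, schedule, t)
        if record_trace:
            trace.append(state)
    if not record_trace:
        trace = [trace[0], state]
    return state, trace


def conv_adaptation(
    clamped: ConvState, free_ss: ConvState, schedule: PhaseSchedule
) -> ConvState:
    """Relax every non-input tensor toward the free steady state.

    Same geometric relaxation as the dense case:
    ``x <- (1 - c) * x + c * x_free`` for ``n_adapt`` steps.
    """
    c = schedule.c
    state = clamped
    for _ in range(schedule.n_adapt):
        new = [state.layers[0]]
        for x, xf in zip(state.layers[1:], free_ss.layers[1:]):
            new.append((1.0 - c) * x + c * xf)
        state = ConvState(new)
    return state


# ----------------------------------------------------------------------
# Updates and training
# ----------------------------------------------------------------------

@dataclasses.dataclass
class ConvUpdateSet:
    """Per-tensor deltas: conv kernels, stage biases, dense weight/bias."""

    kernels: list[np.ndarray]
    stage_biases: list[np.ndarray]
    dense_weight: np.ndarray
    dense_bias: np.ndarray


def conv_predictive_update(
    hat: ConvState, free: ConvState, net: ConvNetwork, alphas: Sequence[float], beta: float
) -> ConvUpdateSet:
    """Predictive EP rule generalised to shared kernels.

    The kernel delta correlates the clamped presynaptic map with the
    clamped-minus-free postsynaptic gap, summed over spatial positions
    (weight sharing) and averaged over the batch; scale is ``alpha / beta``
    per stage.
    """
    if not beta > 0:
        raise ConfigurationError("predictive EP update requires beta > 0")
    alphas = list(alphas)
    if len(alphas) != net.n_stages + 1:
        raise ConfigurationError(
            f"need {net.n_stages + 1} learning rates (stages + dense), got {len(alphas)}"
        )
    B = hat.layers[0].shape[0]
    dK, db = [], []
    for s in range(net.n_stages):
        scale = alphas[s] / beta
        pre = hat.layers[s]
        diff = hat.layers[s + 1] - free.layers[s + 1]
        w = _windows(pre, net.kernels[s].shape[-1])
        dK.append(scale * np.einsum("bchwuv,bohw->ocuv", w, diff) / B)
        db.append(scale * np.einsum("bohw->o", diff) / B)
    scale = alphas[-1] / beta
    pre = hat.layers[net.n_stages].reshape(B, -1)
    diff = hat.layers[-1] - free.layers[-1]
    dW = scale * (pre.T @ diff) / B
    dB = scale * np.mean(diff, axis=0)
    return ConvUpdateSet(dK, db, dW, dB)


def _apply(net: ConvNetwork, upd: ConvUpdateSet) -> None:
    for K, d in zip(net.kernels, upd.kernels):
        K += d
    for b, d in zip(net.stage_biases, upd.stage_biases):
        b += d
    net.dense_weight += upd.dense_weight
    net.dense_bias += upd.dense_bias


def conv_error(net: ConvNetwork, X: np.ndarray, Y: np.ndarray, schedule: PhaseSchedule,
               batch_size: int = 64) -> float:
    """Free-phase argmax classification error, evaluated in chunks."""
    wrong = 0
    n = X.shape[0]
    for start in range(0, n, batch_size):
        state, _ = conv_free_phase(net, X[start : start + batch_size], schedule, record_trace=False)
        pred = np.argmax(state.layers[-1], axis=1)
        truth = np.argmax(Y[start : start + batch_size], axis=1)
        wrong += int(np.sum(pred != truth))
    return wrong / n


def conv_train(
    net: ConvNetwork, dataset, schedule: PhaseSchedule, config
) -> tuple[ConvNetwork, pd.DataFrame]:
    """Mini-batch training of the convolutional EP model.

    Per batch: free phase, soft-clamped phase initialised from the recorded
    free-phase snapshot, adaptation, predictive EP update applied directly
    (no optimizer, per the model's design).  Hard clamping is rejected.
    """
    if schedule.clamp_mode != "soft":
        raise ConfigurationError("conv_train is EP-only: set clamp_mode='soft'")
    if config.optimizer != "none":
        raise ConfigurationError("the convolutional model uses no optimizer")
    Xtr, Ytr, Xte, Yte = dataset.train_test()
    if Xtr.shape[0] == 0:
        raise ValidationError("training set is empty")
    alphas = np.atleast_1d(np.asarray(config.learning_rates, dtype=float))
    if alphas.size == 1:
        alphas = np.full(net.n_stages + 1, alphas[0])
    rng = np.random.default_rng(config.seed)
    rows = []
    for epoch in range(config.n_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(Xtr.shape[0])
        for start in range(0, Xtr.shape[0], config.batch_size):
            idx = order[start : start + config.batch_size]
            free_final, trace = conv_free_phase(net, Xtr[idx], schedule, record_trace=False)
            clamp_init = trace[1] if schedule.clamp_init_step is not None else free_final
            clamped, _ = conv_clamped_phase(net, clamp_init, Ytr[idx], schedule)
            adapted = conv_adaptation(clamped, free_final, schedule)
            upd = conv_predictive_update(adapted, free_final, net, alphas, schedule.beta)
            _apply(net, upd)
        row = {
            "epoch": epoch,
            "train_error": conv_error(net, Xtr, Ytr, schedule),
            "test_error": conv_error(net, Xte, Yte, schedule) if len(Xte) else np.nan,
        }
        row["wall_time_s"] = time.perf_counter() - t0
        rows.append(row)
    return net, pd.DataFrame(rows)
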