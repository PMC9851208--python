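"""Gradient-alignment diagnostics against backpropagation.

The two-phase rules never compute gradients, so the natural question is how
close their updates come to the gradient a conventional feedforward network
would follow.  This module provides:

* :func:`bp_reference_gradient` — the exact squared-error gradient of the
  feedforward skeleton ``x_{l+1} = p(W_l x_l + b_l)`` sharing the network's
  weights (feedback gain and lateral terms excluded: they have no standard
  feedforward counterpart), returned with descent polarity so it can be
  *added* to the parameters like every rule's update;
* :func:`gradient_angle` — the per-weight-matrix angle
  ``theta = arccos(|a . b| / (|a| |b|))`` in degrees between two flattened
  update sets.  The absolute value in the numerator folds opposing vectors
  to 0 degrees, so angles live in [0, 90]; an opt-in signed mode is
  available for debugging but is never the default;
* :func:`angle_curve` — tracks the mean per-layer angle between a rule's raw
  (pre-optimizer) updates and the BP reference over training, for variants
  with and without adaptation started from identical initial weights.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .learning import RULES, TrainConfig, UpdateSet, train
from .network import ActivityState, LayeredNetwork, PhaseResult, PhaseSchedule, activation_fn, run_phases

__all__ = [
    "AngleReport",
    "VARIANTS",
    "angle_curve",
    "bp_reference_gradient",
    "gradient_angle",
    "plot_angle_curves",
]

VARIANTS = ("with_adaptation", "without_adaptation")


def _activation_derivative(name: str, z: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        s = activation_fn("sigmoid")(z)
        return s * (1.0 - s)
    if name == "hard_sigmoid":
        # subgradient: 0.5 strictly inside (-1, 1), 0 outside and at the kinks
        return np.where((z > -1.0) & (z < 1.0), 0.5, 0.0)
    activation_fn(name)  # raises
    raise AssertionError("unreachable")


def _feedforward(net: LayeredNetwork, X: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Activities and pre-activations of the pure feedforward skeleton."""
    act = activation_fn(net.activation)
    xs = [np.atleast_2d(np.asarray(X, dtype=float))]
    zs = []
    for W, b in zip(net.weights, net.biases):
        z = xs[-1] @ W + b
        zs.append(z)
        xs.append(act(z))
    return xs, zs


def _bp_deltas(net: LayeredNetwork, X: np.ndarray, Y: np.ndarray):
    """Per-sample backpropagated error signals for the squared-error loss."""
    xs, zs = _feedforward(net, X)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    deltas = [None] * len(net.weights)
    deltas[-1] = (xs[-1] - Y) * _activation_derivative(net.activation, zs[-1])
    for l in range(len(net.weights) - 2, -1, -1):
        deltas[l] = (deltas[l + 1] @ net.weights[l + 1].T) * _activation_derivative(
            net.activation, zs[l]
        )
    return xs, deltas


def bp_reference_gradient(net: LayeredNetwork, X: np.ndarray, Y: np.ndarray) -> UpdateSet:
    """Exact gradient of the loss ``0.5 * ||x_out - y||^2``, descent polarity.

    The returned deltas are the *negative* gradient averaged over the batch,
    matching the additive polarity of the contrastive rules.  Lateral
    matrices receive zero deltas (the feedforward reference has none).
    """
    xs, deltas = _bp_deltas(net, X, Y)
    B = xs[0].shape[0]
    dW = [-(xs[l].T @ deltas[l]) / B for l in range(len(net.weights))]
    db = [-np.mean(d, axis=0) for d in deltas]
    dL = {k: np.zeros_like(v) for k, v in net.lateral_weights.items()}
    return UpdateSet(dW, db, dL, alpha=[1.0] * len(net.weights), beta=None)


def _bp_per_sample_weight_grads(net: LayeredNetwork, X: np.ndarray, Y: np.ndarray) -> list[np.ndarray]:
    """Per-sample descent directions, one ``(B, n_pre, n_post)`` array per W."""
    xs, deltas = _bp_deltas(net, X, Y)
    return [-np.einsum("bi,bj->bij", xs[l], deltas[l]) for l in range(len(net.weights))]


def _rule_per_sample_weight_deltas(
    result: PhaseResult, net: LayeredNetwork, rule: str
) -> list[np.ndarray]:
    """Per-sample weight deltas of a contrastive rule, unscaled.

    Positive per-layer scale factors (alpha, 1/beta) are omitted: the angle
    statistic is invariant to them.
    """
    hat, free = result.adapted_state, result.free_state
    out = []
    for i in range(len(net.weights)):
        if rule in ("predictive_ep", "predictive_chl"):
            d = np.einsum("bi,bj->bij", hat.layers[i], hat.layers[i + 1] - free.layers[i + 1])
        else:
            d = np.einsum("bi,bj->bij", hat.layers[i], hat.layers[i + 1]) - np.einsum(
                "bi,bj->bij", free.layers[i], free.layers[i + 1]
            )
        out.append(d)
    return out


@dataclasses.dataclass
class AngleReport:
    """Per-weight-matrix angles (degrees) between two update sets."""

    angles_deg: dict[str, float]
    epoch: int | None = None
    rule_a: str = ""
    rule_b: str = "bp"

    def mean(self) -> float:
        vals = [v for v in self.angles_deg.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def _angle_deg(a: np.ndarray, b: np.ndarray, signed: bool) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    cos = float(np.dot(a, b) / (na * nb))
    if not signed:
        cos = abs(cos)
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def gradient_angle(a: UpdateSet, b: UpdateSet, signed: bool = False, epoch: int | None = None) -> AngleReport:
    """Angle between two update sets, per weight matrix, in degrees.

    A layer whose delta is all-zero in either set has no defined direction;
    it is reported as NaN with a warning.
    """
    if len(a.weights) != len(b.weights):
        raise ValidationError("update sets have different numbers of weight matrices")
    angles = {}
    for i, (wa, wb) in enumerate(zip(a.weights, b.weights)):
        if wa.shape != wb.shape:
            raise ValidationError(f"weight delta {i} shapes differ: {wa.shape} vs {wb.shape}")
        theta = _angle_deg(wa.ravel(), wb.ravel(), signed)
        if np.isnan(theta):
            warnings.warn(f"zero-norm delta for W{i + 1}; angle undefined", stacklevel=2)
        angles[f"W{i + 1}"] = theta
    return AngleReport(angles, epoch=epoch)


def _batch_mean_angles(
    net: LayeredNetwork,
    X: np.ndarray,
    Y: np.ndarray,
    schedule: PhaseSchedule,
    rule: str,
) -> dict[str, tuple[float, float]]:
    """Mean and SD over the batch of per-sample per-layer angles to BP."""
    result = run_phases(net, X, Y, schedule)
    rule_ds = _rule_per_sample_weight_deltas(result, net, rule)
    bp_ds = _bp_per_sample_weight_grads(net, X, Y)
    out = {}
    B = X.shape[0]
    for i, (rd, bd) in enumerate(zip(rule_ds, bp_ds)):
        thetas = np.array([_angle_deg(rd[b].ravel(), bd[b].ravel(), signed=False) for b in range(B)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[f"W{i + 1}"] = (float(np.nanmean(thetas)), float(np.nanstd(thetas)))
    return out


def angle_curve(
    net: LayeredNetwork,
    dataset,
    schedule: PhaseSchedule,
    config: TrainConfig,
    rule_variants=VARIANTS,
    eval_batch_size: int = 32,
) -> pd.DataFrame:
    """Track the rule-vs-BP angle over training for adaptation variants.

    Each variant trains its own copy of ``net`` (identical initial weights)
    under ``config``; ``without_adaptation`` runs the same schedule with
    ``n_adapt = 0``.  At epoch 0 (before training) and after every epoch the
    rule's raw per-sample updates and the BP reference are computed on a
    shared evaluation batch — the optimizer never touches these diagnostics
    — and per-sample angles are averaged.  Returns a long-format table
    ``(epoch, layer, variant, mean_angle_deg, sd)``.
    """
    variants = list(rule_variants)
    if not variants:
        raise ValidationError("rule_variants must be non-empty")
    unknown = set(variants) - set(VARIANTS)
    if unknown:
        raise ValidationError(f"unknown variants: {sorted(unknown)}; choose from {VARIANTS}")

    Xtr, Ytr, _, _ = dataset.train_test()
    n = Xtr.shape[0]
    # shared evaluation batches so both variants see identical data
    eval_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    eval_idx = [
        eval_rng.choice(n, size=min(eval_batch_size, n), replace=False)
        for _ in range(config.n_epochs + 1)
    ]

    rows: list[dict] = []

    def record(variant: str, sched: PhaseSchedule, epoch: int, current: LayeredNetwork) -> None:
        idx = eval_idx[epoch]
        stats = _batch_mean_angles(current, Xtr[idx], Ytr[idx], sched, config.rule)
        for layer, (m, s) in stats.items():
            rows.append(
                {
                    "epoch": epoch,
                    "layer": layer,
                    "variant": variant,
                    "mean_angle_deg": m,
                    "sd": s,
                }
            )

    for variant in variants:
        sched = (
            schedule
            if variant == "with_adaptation"
            else dataclasses.replace(schedule, n_adapt=0)
        )
        net_v = net.copy()
        record(variant, sched, 0, net_v)
        train(
            net_v,
            dataset,
            sched,
            config,
            epoch_callback=lambda epoch, cur, v=variant, s=sched: record(v, s, epoch + 1, cur),
        )
    return pd.DataFrame(rows)


def plot_angle_curves(df: pd.DataFrame, path) -> None:
    """Render per-layer angle curves (one panel per weight matrix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layers = sorted(df["layer"].unique())
    fig, axes = plt.subplots(1, len(layers), figsize=(4.5 * len(layers), 3.5), squeeze=False)
    for ax, layer in zip(axes[0], layers):
        sub = df[df["layer"] == layer]
        for variant, grp in sub.groupby("variant"):
            grp = grp.sort_values("epoch")
            ax.plot(grp["epoch"], grp["mean_angle_deg"], label=variant)
            ax.fill_between(
                grp["epoch"],
                grp["mean_angle_deg"] - grp["sd"],
                grp["mean_angle_deg"] + grp["sd"],
                alpha=0.2,
            )
        ax.set_title(layer)
        ax.set_xlabel("epoch")
        ax.set_ylabel("angle to BP (deg)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
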