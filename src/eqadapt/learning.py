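"""Local learning rules, AdaGrad, and the two-phase training loop.

All rules turn a :class:`~eqadapt.network.PhaseResult` into an
:class:`UpdateSet` of per-parameter deltas built from products of pre- and
post-synaptic activities:

* equilibrium propagation (soft clamp):
  ``dw = (alpha / beta) * (x^_pre x^_post - xv_pre xv_post)``
* contrastive Hebbian learning (hard clamp): the same without ``1/beta``;
* the predictive rule: ``dw = scale * x^_pre * (x^_post - xv_post)`` with
  the *clamped* presynaptic activity in both terms (``scale`` includes
  ``1/beta`` for the EP flavour only).

``x^`` is the clamped-phase activity — the adapted state when adaptation
steps were run — and ``xv`` the free-phase steady state.  Biases are treated
as weights from a constant-1 presynaptic unit; lateral matrices use the same
rule with pre and post both in their layer and the diagonal re-zeroed.

Deltas are *added* to the parameters (the rules' polarity already points
toward reducing the free/clamped gap) and are averaged over the mini-batch,
so learning rates are on a per-example scale.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError, ValidationError
from .network import ActivityState, LayeredNetwork, PhaseResult, PhaseSchedule, run_free_phase, run_phases

__all__ = [
    "AdaGradState",
    "RULES",
    "TrainConfig",
    "UpdateSet",
    "adagrad_apply",
    "apply_updates",
    "chl_update",
    "classification_error",
    "ep_update",
    "predictive_update",
    "train",
]


@dataclasses.dataclass
class UpdateSet:
    """Proposed parameter changes, one array per parameter tensor.

    ``alpha`` and ``beta`` record the scale factors already folded into the
    deltas, so the optimizer can recover the unscaled pseudo-gradient.
    ``alpha`` is per weight matrix; bias and lateral deltas share the rate
    of their layer's weight matrix.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    laterals: dict[int, np.ndarray]
    alpha: list[float]
    beta: float | None = None

    def __post_init__(self) -> None:
        for arrs in (self.weights, self.biases, list(self.laterals.values())):
            for a in arrs:
                if not np.all(np.isfinite(a)):
                    raise ValidationError("non-finite entries in update set")

    def check_matches(self, net: LayeredNetwork) -> None:
        if len(self.weights) != len(net.weights) or any(
            d.shape != w.shape for d, w in zip(self.weights, net.weights)
        ):
            raise StructuralError("update weight shapes do not mirror the network")
        if len(self.biases) != len(net.biases) or any(
            d.shape != b.shape for d, b in zip(self.biases, net.biases)
        ):
            raise StructuralError("update bias shapes do not mirror the network")
        if set(self.laterals) != set(net.lateral_weights) or any(
            self.laterals[k].shape != v.shape for k, v in net.lateral_weights.items()
        ):
            raise StructuralError("update lateral shapes do not mirror the network")

    def scaled(self, factor: float) -> "UpdateSet":
        return UpdateSet(
            [factor * w for w in self.weights],
            [factor * b for b in self.biases],
            {k: factor * v for k, v in self.laterals.items()},
            alpha=list(self.alpha),
            beta=self.beta,
        )

    def norms(self) -> list[float]:
        """Frobenius norm of each weight-matrix delta (W1, W2, ...)."""
        return [float(np.linalg.norm(w)) for w in self.weights]


@dataclasses.dataclass
class TrainConfig:
    """Run configuration for the mini-batch training loop.

    ``learning_rates`` is a single rate applied to every parameter tensor,
    or one rate per weight matrix (the convolutional model uses
    0.21 / 0.021 / 0.021 for its three stages).
    """

    rule: str = "predictive_chl"
    learning_rates: float | Sequence[float] = 0.1
    optimizer: str = "adagrad"
    adagrad_epsilon: float = 1e-8
    batch_size: int = 20
    n_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ConfigurationError(f"unknown rule {self.rule!r}; choose from {sorted(RULES)}")
        if self.optimizer not in ("none", "adagrad"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        rates = np.atleast_1d(np.asarray(self.learning_rates, dtype=float))
        if np.any(rates <= 0):
            raise ConfigurationError("all learning rates must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")

    def rates_for(self, net: LayeredNetwork) -> list[float]:
        """Resolve the learning-rate setting to one alpha per weight matrix."""
        rates = np.atleast_1d(np.asarray(self.learning_rates, dtype=float))
        n = len(net.weights)
        if rates.size == 1:
            return [float(rates[0])] * n
        if rates.size != n:
            raise ConfigurationError(
                f"got {rates.size} learning rates for a network with {n} weight matrices"
            )
        return [float(r) for r in rates]


# ----------------------------------------------------------------------
# Update rules
# ----------------------------------------------------------------------

def _clamped_activities(result: PhaseResult) -> ActivityState:
    # The adapted state *is* the clamped state when no adaptation ran.
    return result.adapted_state


def _contrastive_deltas(
    hat: ActivityState, free: ActivityState, net: LayeredNetwork, scale: list[float]
) -> tuple[list[np.ndarray], list[np.ndarray], dict[int, np.ndarray]]:
    """Batch-averaged x^_pre x^_post - xv_pre xv_post per parameter tensor."""
    B = hat.batch_size
    dW, db, dL = [], [], {}
    for i in range(len(net.weights)):
        pre_h, post_h = hat.layers[i], hat.layers[i + 1]
        pre_f, post_f = free.layers[i], free.layers[i + 1]
        dW.append(scale[i] * (pre_h.T @ post_h - pre_f.T @ post_f) / B)
        db.append(scale[i] * np.mean(post_h - post_f, axis=0))
    for layer in net.lateral_weights:
        xh, xf = hat.layers[layer], free.layers[layer]
        d = scale[layer - 1] * (xh.T @ xh - xf.T @ xf) / B
        np.fill_diagonal(d, 0.0)
        dL[layer] = d
    return dW, db, dL


def _predictive_deltas(
    hat: ActivityState, free: ActivityState, net: LayeredNetwork, scale: list[float]
) -> tuple[list[np.ndarray], list[np.ndarray], dict[int, np.ndarray]]:
    """Batch-averaged x^_pre (x^_post - xv_post) per parameter tensor."""
    B = hat.batch_size
    dW, db, dL = [], [], {}
    for i in range(len(net.weights)):
        pre_h = hat.layers[i]
        diff = hat.layers[i + 1] - free.layers[i + 1]
        dW.append(scale[i] * (pre_h.T @ diff) / B)
        db.append(scale[i] * np.mean(diff, axis=0))
    for layer in net.lateral_weights:
        xh = hat.layers[layer]
        diff = hat.layers[layer] - free.layers[layer]
        d = scale[layer - 1] * (xh.T @ diff) / B
        np.fill_diagonal(d, 0.0)
        dL[layer] = d
    return dW, db, dL


def ep_update(result: PhaseResult, net: LayeredNetwork, config: TrainConfig) -> UpdateSet:
    """Equilibrium-propagation update (soft clamp, 1/beta normaliser)."""
    beta = result.schedule.beta
    if not beta > 0:
        raise ConfigurationError("EP update requires beta > 0")
    alphas = config.rates_for(net)
    scale = [a / beta for a in alphas]
    dW, db, dL = _contrastive_deltas(_clamped_activities(result), result.free_state, net, scale)
    return UpdateSet(dW, db, dL, alpha=alphas, beta=beta)


def chl_update(result: PhaseResult, net: LayeredNetwork, config: TrainConfig) -> UpdateSet:
    """Contrastive Hebbian update (hard clamp, no 1/beta factor)."""
    alphas = config.rates_for(net)
    dW, db, dL = _contrastive_deltas(_clamped_activities(result), result.free_state, net, alphas)
    return UpdateSet(dW, db, dL, alpha=alphas, beta=None)


def predictive_update(
    result: PhaseResult, net: LayeredNetwork, config: TrainConfig, divide_beta: bool | None = None
) -> UpdateSet:
    """Predictive rule: clamped presynaptic activity times the post gap.

    ``divide_beta`` selects the EP flavour (with 1/beta) or the CHL flavour
    (without); by default it follows ``config.rule``.
    """
    if divide_beta is None:
        divide_beta = config.rule == "predictive_ep"
    alphas = config.rates_for(net)
    beta = result.schedule.beta
    if divide_beta:
        if not beta > 0:
            raise ConfigurationError("predictive EP update requires beta > 0")
        scale = [a / beta for a in alphas]
    else:
        scale = list(alphas)
    dW, db, dL = _predictive_deltas(_clamped_activities(result), result.free_state, net, scale)
    return UpdateSet(dW, db, dL, alpha=alphas, beta=beta if divide_beta else None)


RULES: dict[str, Callable[[PhaseResult, LayeredNetwork, TrainConfig], UpdateSet]] = {
    "ep": ep_update,
    "chl": chl_update,
    "predictive_ep": lambda r, n, c: predictive_update(r, n, c, divide_beta=True),
    "predictive_chl": lambda r, n, c: predictive_update(r, n, c, divide_beta=False),
}


# ----------------------------------------------------------------------
# Optimizer
# ----------------------------------------------------------------------

@dataclasses.dataclass
class AdaGradState:
    """Squared pseudo-gradient accumulators mirroring the parameters."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    laterals: dict[int, np.ndarray]

    @classmethod
    def zeros_like(cls, net: LayeredNetwork) -> "AdaGradState":
        return cls(
            [np.zeros_like(w) for w in net.weights],
            [np.zeros_like(b) for b in net.biases],
            {k: np.zeros_like(v) for k, v in net.lateral_weights.items()},
        )


def adagrad_apply(
    updates: UpdateSet, accumulator: AdaGradState, config: TrainConfig
) -> tuple[UpdateSet, AdaGradState]:
    """Rescale an update set by the AdaGrad recursion.

    The rule's delta already carries the learning rate alpha; AdaGrad is
    applied to the unscaled pseudo-gradient ``g = delta / alpha``:
    the accumulator gains ``g**2`` and the effective parameter increment is
    ``alpha * g / (sqrt(accumulator) + eps)``.  Returns the effective
    increments and the updated accumulator; both inputs are left untouched.
    """
    eps = config.adagrad_epsilon

    def one(delta: np.ndarray, acc: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        if delta.shape != acc.shape:
            raise StructuralError(
                f"accumulator shape {acc.shape} does not match update shape {delta.shape}"
            )
        g = delta / alpha
        new_acc = acc + g * g
        return alpha * g / (np.sqrt(new_acc) + eps), new_acc

    eff_w, acc_w = [], []
    for d, a, al in zip(updates.weights, accumulator.weights, updates.alpha):
        e, na = one(d, a, al)
        eff_w.append(e)
        acc_w.append(na)
    eff_b, acc_b = [], []
    for d, a, al in zip(updates.biases, accumulator.biases, updates.alpha):
        e, na = one(d, a, al)
        eff_b.append(e)
        acc_b.append(na)
    eff_l, acc_l = {}, {}
    for k, d in updates.laterals.items():
        e, na = one(d, accumulator.laterals[k], updates.alpha[k - 1])
        eff_l[k] = e
        acc_l[k] = na
    effective = UpdateSet(eff_w, eff_b, eff_l, alpha=list(updates.alpha), beta=updates.beta)
    return effective, AdaGradState(acc_w, acc_b, acc_l)


def apply_updates(net: LayeredNetwork, updates: UpdateSet) -> None:
    """Add the deltas to the parameters in place; lateral diagonals re-zeroed."""
    updates.check_matches(net)
    for w, d in zip(net.weights, updates.weights):
        w += d
    for b, d in zip(net.biases, updates.biases):
        b += d
    for k, d in net.lateral_weights.items():
        d += updates.laterals[k]
        np.fill_diagonal(d, 0.0)


# ----------------------------------------------------------------------
# Training loop
# ----------------------------------------------------------------------

def classification_error(
    net: LayeredNetwork, X: np.ndarray, Y: np.ndarray, schedule: PhaseSchedule
) -> float:
    """Fraction of examples whose free-phase output argmax misses the target."""
    state, _ = run_free_phase(net, X, schedule, record_trace=False)
    pred = np.argmax(state.layers[-1], axis=1)
    truth = np.argmax(np.atleast_2d(Y), axis=1)
    return float(np.mean(pred != truth))


def train(
    net: LayeredNetwork,
    dataset,
    schedule: PhaseSchedule,
    config: TrainConfig,
    epoch_callback: Callable | None = None,
) -> tuple[LayeredNetwork, pd.DataFrame]:
    """Mini-batch two-phase training; returns the net and a metrics table.

    Per mini-batch: free phase, clamped phase, adaptation (when
    ``n_adapt > 0``), the configured rule's batch-averaged update, then the
    optimizer.  The metrics table has one row per epoch with train/test
    error, the mean per-layer update norms, and wall time; everything except
    wall time is reproducible bit-for-bit from the seed.

    ``epoch_callback(epoch, net)`` — if given — runs after each epoch's
    parameter updates (used by the gradient-angle diagnostics).
    """
    Xtr, Ytr, Xte, Yte = dataset.train_test()
    n = Xtr.shape[0]
    if n == 0:
        raise ValidationError("training set is empty")
    rng = np.random.default_rng(config.seed)
    rule = RULES[config.rule]
    opt_state = AdaGradState.zeros_like(net) if config.optimizer == "adagrad" else None

    rows = []
    layer_names = [f"W{i + 1}" for i in range(len(net.weights))]
    for epoch in range(config.n_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        norms = np.zeros(len(net.weights))
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            result = run_phases(net, Xtr[idx], Ytr[idx], schedule)
            updates = rule(result, net, config)
            if opt_state is not None:
                updates, opt_state = adagrad_apply(updates, opt_state, config)
            apply_updates(net, updates)
            norms += updates.norms()
            n_batches += 1
        train_err = classification_error(net, Xtr, Ytr, schedule)
        test_err = classification_error(net, Xte, Yte, schedule) if len(Xte) else np.nan
        row = {"epoch": epoch, "train_error": train_err, "test_error": test_err}
        for name, s in zip(layer_names, norms):
            row[f"mean_update_norm_{name}"] = s / n_batches
        row["wall_time_s"] = time.perf_counter() - t0
        rows.append(row)
        if epoch_callback is not None:
            epoch_callback(epoch, net)
    return net, pd.DataFrame(rows)
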