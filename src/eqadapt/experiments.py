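"""Desk-scale replication experiments.

Bundles the study configurations used by the test suite and the
reproduction script so both run exactly the same computation:

* :func:`adaptation_comparison` — train matched with/without-adaptation
  models (identical initial weights) on a synthetic blob task and collect,
  per seed, the final test error, the epoch-to-epoch test-error
  variability, and the mean per-layer angle between the rule's raw updates
  and the backpropagation reference.  This is the desk-scale analogue of
  the benchmark comparison and the angle-curve analysis.
* :func:`ep_bp_angle_sweep` — the small-nudging equilibrium-propagation
  limit: per-layer angle between EP updates and the BP gradient on random
  3-4-2 networks across nudging strengths.

Study conditions
----------------
The blob task is deliberately non-trivial (4 Gaussian classes in 8
dimensions, centroid spacing ~3 noise SD, so classes overlap) and the
trainer uses plain rule updates without an optimizer: AdaGrad normalises
update magnitudes away, which at this problem size masks the very effect
adaptation is designed to produce — tempering large free/clamped activity
gaps into smaller, steadier weight changes.  With 20 adaptation steps at
c = 0.1 the adapted updates are scaled by (1 - c)^20 ~ 0.12, so the base
rate 1.0 gives the adapted model an effective per-example rate of ~0.1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import make_blobs
from .diagnostics import _batch_mean_angles, bp_reference_gradient, gradient_angle
from .learning import TrainConfig, ep_update, train
from .network import LayeredNetwork, PhaseSchedule, run_phases

__all__ = ["BLOB_TASK", "adaptation_comparison", "ep_bp_angle_sweep"]

#: generator settings of the desk-scale benchmark task
BLOB_TASK = dict(n=800, d=8, k=4, separation=3.0, noise_sd=0.35)

_SCHEDULE = dict(
    n_free=120, n_clamped=120, teach_delay=12, n_adapt=20, h=0.1, c=0.1, clamp_mode="hard"
)
_HIDDEN = 16
_GAMMA = 0.5


def adaptation_comparison(
    seeds=range(5),
    n_epochs: int = 30,
    eval_batch: int = 32,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Matched comparison of adaptation vs no adaptation on the blob task.

    For each seed the two variants share initial weights and data; the
    without-adaptation variant runs the identical schedule with
    ``n_adapt = 0``.  Returns one row per (seed, variant) with the final
    test error, mean absolute epoch-to-epoch change in test error, and the
    mean over epochs of batch-mean per-layer angles to the BP reference
    (computed on the raw rule updates, before any optimizer).
    """
    rows = []
    for s in seeds:
        seed = int(base_seed) + int(s)
        ds = make_blobs(seed=seed, **BLOB_TASK)
        schedule = PhaseSchedule(**_SCHEDULE)
        config = TrainConfig(
            rule="predictive_chl",
            learning_rates=1.0,
            optimizer="none",
            batch_size=20,
            n_epochs=n_epochs,
            seed=seed,
        )
        net0 = LayeredNetwork.initialize(
            [BLOB_TASK["d"], _HIDDEN, BLOB_TASK["k"]], seed=seed, feedback_gain=_GAMMA
        )
        Xtr, Ytr, _, _ = ds.train_test()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA17]))
        eval_idx = [
            rng.choice(Xtr.shape[0], size=min(eval_batch, Xtr.shape[0]), replace=False)
            for _ in range(n_epochs)
        ]
        for variant, n_adapt in (("with_adaptation", schedule.n_adapt), ("without_adaptation", 0)):
            sched = dataclasses.replace(schedule, n_adapt=n_adapt)
            angle_log: list[dict[str, float]] = []

            def record(epoch: int, current: LayeredNetwork, sched=sched) -> None:
                stats = _batch_mean_angles(
                    current, Xtr[eval_idx[epoch]], Ytr[eval_idx[epoch]], sched, config.rule
                )
                angle_log.append({k: v[0] for k, v in stats.items()})

            _, metrics = train(net0.copy(), ds, sched, config, epoch_callback=record)
            te = metrics["test_error"].to_numpy()
            row = {
                "seed": seed,
                "variant": variant,
                "final_test_error": float(te[-1]),
                "final_train_error": float(metrics["train_error"].iloc[-1]),
                "test_error_variability": float(np.mean(np.abs(np.diff(te)))),
            }
            for layer in angle_log[0]:
                row[f"mean_angle_{layer}"] = float(np.mean([a[layer] for a in angle_log]))
            rows.append(row)
    return pd.DataFrame(rows)


def ep_bp_angle_sweep(
    betas=(1e-3, 1e-1, 1.0),
    n_seeds: int = 20,
    base_seed: int = 0,
    layer_sizes=(3, 4, 2),
    feedback_gain: float = 0.05,
    n_steps: int = 300,
    h: float = 0.5,
) -> pd.DataFrame:
    """Per-layer EP-vs-BP angle on random small networks across beta.

    Free and clamped phases run ``n_steps`` Euler steps (contraction factor
    ``1 - h`` per step makes that far beyond numerical convergence), the EP
    update is compared against the feedforward BP gradient on one random
    input/target pair per seed.  Small feedback gain keeps the free fixed
    point near the feedforward pass, the regime in which the
    EP-backpropagation correspondence holds.
    """
    rows = []
    for s in range(n_seeds):
        seed = int(base_seed) + s
        net = LayeredNetwork.initialize(
            list(layer_sizes), seed=seed, feedback_gain=feedback_gain, activation="sigmoid"
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEB]))
        x = rng.uniform(0.0, 1.0, size=(1, layer_sizes[0]))
        y = np.zeros((1, layer_sizes[-1]))
        y[0, rng.integers(layer_sizes[-1])] = 1.0
        bp = bp_reference_gradient(net, x, y)
        for beta in betas:
            sched = PhaseSchedule(
                n_free=n_steps,
                n_clamped=n_steps,
                teach_delay=0,
                n_adapt=0,
                h=h,
                beta=float(beta),
                clamp_mode="soft",
            )
            result = run_phases(net, x, y, sched)
            upd = ep_update(result, net, TrainConfig(rule="ep", optimizer="none", seed=seed))
            report = gradient_angle(upd, bp)
            for layer, theta in report.angles_deg.items():
                rows.append({"seed": seed, "beta": float(beta), "layer": layer, "angle_deg": theta})
    return pd.DataFrame(rows)
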