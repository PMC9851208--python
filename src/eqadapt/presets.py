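"""Named experiment presets.

Each preset is a full run configuration with four sections — ``network``,
``schedule``, ``train``, ``data`` — resolvable by the CLI.  The MNIST
multilayer-perceptron presets use hard clamping (contrastive Hebbian) with
the predictive rule, a 12-step teaching delay, 120-step free and clamped
phases, Euler step 0.1, and AdaGrad; the ``-adp`` variants add 20
adaptation steps with c = 0.1.  Learning rate is 0.1 except for the
1000-hidden-unit models (0.03).  The CIFAR-10 convolutional presets use
soft clamping (EP) with beta = 0.18, 130/30 steps with the clamped phase
initialised from the free-phase state at step 110, h = 1, per-stage rates
0.21/0.021/0.021, and no optimizer; the ``-adp`` variant adds 10 adaptation
steps with c = 0.1.

External-data presets never download anything: set ``data.path`` to a local
MNIST IDX directory or CIFAR-10 batch directory.
"""

from __future__ import annotations

import copy

__all__ = ["PRESETS", "get_preset", "LR_CONTROL_RATES"]

#: learning rates of the no-adaptation control sweep
LR_CONTROL_RATES = (0.05, 0.01, 0.001)


def _mlp_preset(hidden: int, adapt: bool, lateral: int = 0, alpha: float = 0.1) -> dict:
    lateral_layers = {0: [], 1: [1], 2: [1, 2]}[lateral]
    return {
        "network": {
            "kind": "mlp",
            "layer_sizes": [784, hidden, 10],
            "feedback_gain": 0.5,
            "activation": "sigmoid",
            "lateral_layers": lateral_layers,
        },
        "schedule": {
            "n_free": 120,
            "n_clamped": 120,
            "teach_delay": 12,
            "n_adapt": 20 if adapt else 0,
            "h": 0.1,
            "beta": 1.0,
            "c": 0.1,
            "clamp_mode": "hard",
        },
        "train": {
            "rule": "predictive_chl",
            "learning_rates": alpha,
            "optimizer": "adagrad",
            "batch_size": 20,
            "n_epochs": 30,
        },
        "data": {"kind": "mnist", "path": None},
    }


def _cnn_preset(adapt: bool) -> dict:
    return {
        "network": {
            "kind": "cnn",
            "input_shape": [3, 32, 32],
            # stride 1, zero "same" padding, no pooling; see the config notes
            "stage_filters": [256, 512],
            "kernel_size": 3,
            "n_classes": 10,
            "feedback_gain": 1.0,
        },
        "schedule": {
            "n_free": 130,
            "n_clamped": 30,
            "teach_delay": 0,
            "clamp_init_step": 110,
            "n_adapt": 10 if adapt else 0,
            "h": 1.0,
            "beta": 0.18,
            "c": 0.1,
            "clamp_mode": "soft",
        },
        "train": {
            "rule": "predictive_ep",
            "learning_rates": [0.21, 0.021, 0.021],
            "optimizer": "none",
            "batch_size": 20,
            "n_epochs": 50,
        },
        "data": {"kind": "cifar10", "path": None},
    }


def _blobs_preset(adapt: bool) -> dict:
    # the desk-scale benchmark conditions of eqadapt.experiments
    return {
        "network": {
            "kind": "mlp",
            "layer_sizes": [8, 16, 4],
            "feedback_gain": 0.5,
            "activation": "sigmoid",
            "lateral_layers": [],
        },
        "schedule": {
            "n_free": 120,
            "n_clamped": 120,
            "teach_delay": 12,
            "n_adapt": 20 if adapt else 0,
            "h": 0.1,
            "beta": 1.0,
            "c": 0.1,
            "clamp_mode": "hard",
        },
        "train": {
            "rule": "predictive_chl",
            "learning_rates": 1.0,
            "optimizer": "none",
            "batch_size": 20,
            "n_epochs": 30,
        },
        "data": {
            "kind": "blobs",
            "n": 800,
            "d": 8,
            "k": 4,
            "separation": 3.0,
            "noise_sd": 0.35,
        },
    }


PRESETS: dict[str, dict] = {}
for _hidden, _alpha in ((6, 0.1), (50, 0.1), (1000, 0.03)):
    for _lat in (0, 1, 2):
        if _hidden == 6 and _lat:
            continue  # the smallest model ships without lateral variants
        _suffix = {0: "", 1: "-lateral1", 2: "-lateral2"}[_lat]
        for _adapt in (False, True):
            name = f"mlp-784-{_hidden}-10{_suffix}" + ("-adp" if _adapt else "")
            PRESETS[name] = _mlp_preset(_hidden, _adapt, _lat, _alpha)
PRESETS["cnn-cifar"] = _cnn_preset(False)
PRESETS["cnn-cifar-adp"] = _cnn_preset(True)
PRESETS["blobs-demo"] = _blobs_preset(False)
PRESETS["blobs-demo-adp"] = _blobs_preset(True)

# no-adaptation control: reduced learning rates on the smallest MLP
for _r in LR_CONTROL_RATES:
    _p = _mlp_preset(6, adapt=False)
    _p["train"]["learning_rates"] = _r
    PRESETS[f"lr-control-{_r}"] = _p
PRESETS["lr-control"] = {"sweep": [f"lr-control-{r}" for r in LR_CONTROL_RATES]}


def get_preset(name: str) -> dict:
    """Deep copy of a named preset; raises KeyError with suggestions."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return copy.deepcopy(PRESETS[name])
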