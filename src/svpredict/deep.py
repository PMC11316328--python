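"""Network architectures and hyperparameter search for genomic prediction.

Three architectures are used: a multilayer perceptron over a marker (or
principal-component) matrix, a 1-D convolutional network over markers
ordered by genome coordinate, and a six-branch multi-input network taking
one principal-component block per marker class. All hyperparameters are
drawn from fixed grids:

========================  =====================================
first-layer units/filters  16, 38, 64, 128
hidden dense layers        MLP: 0-3; CNN: 1-3
hidden-layer units         2, 4, 8, 16
activation                 relu, tanh, linear
optimizer                  adam, rmsprop, sgd
dropout rate               0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3
L1 / L2 penalty weight     0 (off), 0.001, 0.01, 0.1
========================  =====================================

The output layer is a single unit, linear for quantitative traits and
sigmoid for binary traits. L1+L2 penalties act on the hidden dense layers
and a dropout layer sits just before the output. Hyperparameter search is
successive halving (the mechanism inside Hyperband): many configurations
are trained for a few epochs, the best half is promoted with a multiplied
epoch budget, down to a single survivor which is then retrained in full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nnet import (Conv1D, Dense, Dropout, Flatten, MaxPool1D,
                   MultiInputNetwork, Network, TrainedModel, fit_network)

GRID_FIRST_UNITS = (16, 38, 64, 128)
GRID_HIDDEN_MLP = (0, 1, 2, 3)
GRID_HIDDEN_CNN = (1, 2, 3)
GRID_HIDDEN_UNITS = (2, 4, 8, 16)
GRID_ACTIVATIONS = ("relu", "tanh", "linear")
GRID_OPTIMIZERS = ("adam", "rmsprop", "sgd")
GRID_DROPOUT = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
GRID_PENALTY = (0.0, 0.001, 0.01, 0.1)  # 0 switches the regularizer off

ARCHS = ("mlp", "cnn", "multi_input")


@dataclass(frozen=True)
class NetworkSpec:
    """One point in the hyperparameter grid."""

    arch: str = "mlp"
    first_units: int = 16
    n_hidden: int = 1
    hidden_units: int = 8
    activation: str = "relu"
    optimizer: str = "adam"
    dropout: float = 0.0
    l1: float = 0.0
    l2: float = 0.0
    out_activation: str = "linear"
    # CNN extras (widths are package defaults; the grids above do not cover them)
    kernel_width: int = 3
    stride: int = 1
    pool_width: int = 2
    pool_stride: int | None = None
    branch_units: int | None = None  # multi-input branch width; None -> first_units

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"unknown architecture {self.arch!r}")
        hidden_grid = GRID_HIDDEN_CNN if self.arch == "cnn" else GRID_HIDDEN_MLP
        checks = [
            (self.first_units, GRID_FIRST_UNITS, "first_units"),
            (self.n_hidden, hidden_grid, "n_hidden"),
            (self.hidden_units, GRID_HIDDEN_UNITS, "hidden_units"),
            (self.activation, GRID_ACTIVATIONS, "activation"),
            (self.optimizer, GRID_OPTIMIZERS, "optimizer"),
            (self.dropout, GRID_DROPOUT, "dropout"),
            (self.l1, GRID_PENALTY, "l1"),
            (self.l2, GRID_PENALTY, "l2"),
        ]
        for value, grid, name in checks:
            if value not in grid:
                raise ValueError(f"{name}={value!r} outside the search grid {grid}")
        if self.out_activation not in ("linear", "sigmoid"):
            raise ValueError("output activation must be linear or sigmoid")

    @property
    def trait_kind(self) -> str:
        return "binary" if self.out_activation == "sigmoid" else "quantitative"


def random_spec(rng: np.random.Generator, arch: str = "mlp",
                out_activation: str = "linear") -> NetworkSpec:
    """Sample one configuration uniformly from the grids."""
    hidden_grid = GRID_HIDDEN_CNN if arch == "cnn" else GRID_HIDDEN_MLP
    return NetworkSpec(
        arch=arch,
        first_units=int(rng.choice(GRID_FIRST_UNITS)),
        n_hidden=int(rng.choice(hidden_grid)),
        hidden_units=int(rng.choice(GRID_HIDDEN_UNITS)),
        activation=str(rng.choice(GRID_ACTIVATIONS)),
        optimizer=str(rng.choice(GRID_OPTIMIZERS)),
        dropout=float(rng.choice(GRID_DROPOUT)),
        l1=float(rng.choice(GRID_PENALTY)),
        l2=float(rng.choice(GRID_PENALTY)),
        out_activation=out_activation,
    )


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_mlp(spec: NetworkSpec, n_features: int, seed: int = 0) -> Network:
    """Fully connected stack: first layer, hidden layers with L1+L2
    penalties, dropout before the single-unit output."""
    if spec.arch != "mlp":
        raise ValueError("spec.arch must be 'mlp'")
    layers = [Dense(spec.first_units, spec.activation, l1=spec.l1, l2=spec.l2)]
    for _ in range(spec.n_hidden):
        layers.append(Dense(spec.hidden_units, spec.activation, l1=spec.l1, l2=spec.l2))
    layers.append(Dropout(spec.dropout))
    layers.append(Dense(1, spec.out_activation))
    return Network(layers).build((n_features,), seed=seed)


def build_cnn(spec: NetworkSpec, n_features: int, seed: int = 0) -> Network:
    """1-D convolution + max-pool over coordinate-ordered markers, then
    flatten, hidden dense layers, dropout, single-unit output."""
    if spec.arch != "cnn":
        raise ValueError("spec.arch must be 'cnn'")
    layers: list = [
        Conv1D(spec.first_units, spec.kernel_width, spec.stride,
               spec.activation, l1=spec.l1, l2=spec.l2),
        MaxPool1D(spec.pool_width, spec.pool_stride),
        Flatten(),
    ]
    for _ in range(spec.n_hidden):
        layers.append(Dense(spec.hidden_units, spec.activation, l1=spec.l1, l2=spec.l2))
    layers.append(Dropout(spec.dropout))
    layers.append(Dense(1, spec.out_activation))
    return Network(layers).build((n_features, 1), seed=seed)


def build_multi_input(spec: NetworkSpec, block_widths: list[int],
                      seed: int = 0) -> MultiInputNetwork:
    """Six parallel dense branches (one per marker class) concatenated into
    a shared hidden/dropout/output trunk."""
    if spec.arch != "multi_input":
        raise ValueError("spec.arch must be 'multi_input'")
    if len(block_widths) != 6:
        raise ValueError(f"expected 6 input blocks, got {len(block_widths)}")
    width = spec.branch_units if spec.branch_units is not None else spec.first_units
    branches = [[Dense(width, spec.activation, l1=spec.l1, l2=spec.l2)]
                for _ in block_widths]
    trunk: list = []
    for _ in range(spec.n_hidden):
        trunk.append(Dense(spec.hidden_units, spec.activation, l1=spec.l1, l2=spec.l2))
    trunk.append(Dropout(spec.dropout))
    trunk.append(Dense(1, spec.out_activation))
    net = MultiInputNetwork(branches, trunk)
    return net.build([(w,) for w in block_widths], seed=seed)


def build_network(spec: NetworkSpec, input_shape, seed: int = 0):
    if spec.arch == "mlp":
        return build_mlp(spec, int(input_shape), seed=seed)
    if spec.arch == "cnn":
        return build_cnn(spec, int(input_shape), seed=seed)
    return build_multi_input(spec, list(input_shape), seed=seed)


def _prep_input(spec: NetworkSpec, X):
    if spec.arch == "cnn":
        return np.asarray(X)[:, :, None]
    return X


def train(spec: NetworkSpec, X, y, X_val=None, y_val=None, *, epochs: int = 100,
          batch_size: int = 32, patience: int = 10, seed: int = 0) -> TrainedModel:
    """Build and train a network for this spec; see :func:`nnet.fit_network`."""
    shape = [x.shape[1] for x in X] if spec.arch == "multi_input" else X.shape[1]
    model = build_network(spec, shape, seed=seed)
    Xt = _prep_input(spec, X)
    Xv = None if X_val is None else _prep_input(spec, X_val)
    return fit_network(model, Xt, y, Xv, y_val, kind=spec.trait_kind,
                       optimizer=spec.optimizer, epochs=epochs,
                       batch_size=batch_size, patience=patience, seed=seed)


# ---------------------------------------------------------------------------
# successive halving search
# ---------------------------------------------------------------------------

@dataclass
class SearchSettings:
    n_configs: int = 8
    halving_factor: int = 2
    min_epochs: int = 2
    batch_size: int = 32
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.halving_factor < 2:
            raise ValueError("halving factor must be >= 2")
        if self.min_epochs < 1:
            raise ValueError("budget must allow at least one epoch per config")


@dataclass
class SearchResult:
    best_spec: NetworkSpec
    best_loss: float
    log: pd.DataFrame  # round, config_id, epochs, val_loss


def hyperband_search(configs, settings: SearchSettings, train_fn=None, *,
                     X=None, y=None, X_val=None, y_val=None) -> SearchResult:
    """Successive-halving search over explicit or sampled configurations.

    ``configs`` is either a list of :class:`NetworkSpec` or an ``(arch,
    out_activation)`` pair from which ``settings.n_configs`` specs are
    sampled. Each round trains every surviving config for the current epoch
    budget and promotes the top half (by validation loss) with the budget
    multiplied by the halving factor, ending in a final single-survivor
    round. ``train_fn(config, epochs) -> val_loss`` may replace the default
    trainer (used for deterministic cross-checks).
    """
    rng = np.random.default_rng(settings.seed)
    if isinstance(configs, tuple) and len(configs) == 2 and isinstance(configs[0], str):
        arch, out_act = configs
        configs = [random_spec(rng, arch, out_act) for _ in range(settings.n_configs)]
    configs = list(configs)
    if not configs:
        raise ValueError("no configurations to search")

    if train_fn is None:
        if X is None or y is None or X_val is None or y_val is None:
            raise ValueError("default trainer needs X, y, X_val, y_val")

        def train_fn(config, epochs):
            fitted = train(config, X, y, X_val, y_val, epochs=epochs,
                           batch_size=settings.batch_size,
                           patience=max(settings.patience, epochs),
                           seed=settings.seed)
            return fitted.best_val_loss

    survivors = list(range(len(configs)))
    epochs = settings.min_epochs
    rows = []
    round_id = 0
    while True:
        losses = {}
        for i in survivors:
            loss = train_fn(configs[i], epochs)
            losses[i] = loss
            rows.append({"round": round_id, "config_id": i, "epochs": epochs,
                         "val_loss": loss})
        survivors.sort(key=lambda i: (losses[i], i))
        if len(survivors) == 1:
            break
        survivors = survivors[:max(1, len(survivors) // settings.halving_factor)]
        epochs *= settings.halving_factor
        round_id += 1
    best = survivors[0]
    return SearchResult(best_spec=configs[best], best_loss=losses[best],
                        log=pd.DataFrame(rows))
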