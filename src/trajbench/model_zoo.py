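"""The nine-classifier zoo and the shared training protocol.

Architectures (all ending in a 2-unit softmax whose class-1 probability is
the reported score):

* ``MLP`` — three 500-unit ReLU hidden layers, dropout 0.1/0.2/0.3 before
  each hidden layer, on the raw (z-scored) series.
* ``FCNN`` — three stride-1 'same' convolution blocks with 128/256/128
  filters of lengths 8/5/3 and ReLU, global average pooling (GAP).
* ``TSF-MLP`` — the MLP on time-series-forest interval features.
* ``TSF-CNN`` — six 1-D convolutions (32,32,32,32,64,128 filters, length
  3), max-pool stride 2 after layers 2 and 4, GAP; input is the 3-channel
  TSF feature sequence ordered by interval start.
* ``GAF-CNN`` — six 3x3 2-D convolutions (same filter plan), pooling after
  layers 2 and 4, GAP; input is the Gramian angular field image of the
  min-max rescaled series.
* ``ResNet`` — three residual blocks of three convolutions (lengths 8/5/3,
  64/128/128 filters) with batch norm and shortcut additions, GAP.
* ``RNN-FCN`` — an LSTM branch and an FCN branch (128/256/128, lengths
  8/5/3, batch norm + ReLU, GAP) in parallel, concatenated.
* ``C-RNN`` — convolutions with 32 then 64 filters (lengths 5 and 3)
  feeding a 64-unit LSTM with dropouts 0.1 and 0.5.
* ``Transformer`` — a stack of 4 identical encoder layers (multi-head
  self-attention + feed-forward, residual connections, layer norm,
  dropout) over the embedded, position-encoded series, then GAP.

The shared optimization protocol: Adam (binary cross-entropy via the
2-unit softmax), initial learning rate 1e-3, learning rate multiplied by
0.92 whenever the training loss fails to improve for three consecutive
epochs, early stopping after 15 epochs without validation-AUC improvement,
hard cap 500 epochs, best-validation weights restored.  Hyperparameters
are searched with a successive-halving bandit on the 20% tuning subset.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from trajbench.benchmark_stats import roc_auc, threshold_metrics
from trajbench.cohort_simulator import Cohort, CohortSpec, simulate
from trajbench.nn import autograd as ag
from trajbench.nn import layers as L
from trajbench.nn.autograd import Tensor
from trajbench.nn.optim import Adadelta, Adam
from trajbench.preprocessing import (
    locf_impute,
    minmax_normalize,
    partition,
    zscore_normalize,
)
from trajbench.reference_profiles import ReferenceTrajectory
from trajbench.series_transforms import TSFConfig, gaf_transform, sample_intervals, tsf_transform

ARCH_NAMES = (
    "MLP",
    "FCNN",
    "TSF-MLP",
    "TSF-CNN",
    "GAF-CNN",
    "ResNet",
    "RNN-FCN",
    "C-RNN",
    "Transformer",
)


@dataclass
class TrainPolicy:
    """The shared optimization protocol."""

    optimizer: str = "adam"
    initial_lr: float = 1e-3
    max_epochs: int = 500
    lr_decay_factor: float = 0.92
    lr_patience: int = 3
    early_stop_patience: int = 15
    batch_size: int = 64
    seed: int = 0

    def scaled(self, max_epochs: int, early_stop_patience: int | None = None) -> "TrainPolicy":
        return replace(
            self,
            max_epochs=max_epochs,
            early_stop_patience=early_stop_patience or self.early_stop_patience,
        )


@dataclass
class FitResult:
    """Outcome of one training run."""

    arch: str
    epochs_run: int
    wall_time: float
    history: dict
    hyperparams: dict
    train_scores: np.ndarray
    val_scores: np.ndarray
    train_auc: float
    val_auc: float


class Model:
    """A forward function plus its trainable layers."""

    def __init__(self, forward: Callable[[Tensor, bool], Tensor], layers: list[L.Layer]):
        self._forward = forward
        self.layers = layers

    def params(self) -> list[Tensor]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> Tensor:
        return self._forward(Tensor(x, requires_grad=False), train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class-1 softmax probability per sample (inference mode)."""
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            probs.append(ag.softmax_probs(logits.data)[:, 1])
        return np.concatenate(probs)

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p.data[...] = w


@dataclass
class ArchSpec:
    """Declarative description of one architecture."""

    name: str
    input_transform: str  # raw | tsf | gaf
    builder: Callable  # (input_shape, hyperparams, rng) -> Model
    tunable: dict[str, Sequence] = field(default_factory=dict)
    defaults: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# builders


def _mlp_stack(rng, in_dim, widths, dropouts):
    layers = []
    dims = [in_dim] + list(widths)
    for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
        layers.append(L.Dropout(dropouts[i], rng))
        layers.append(L.Dense(a, b, rng))
    out = L.Dense(dims[-1], 2, rng)
    layers.append(out)

    def forward(x: Tensor, train: bool) -> Tensor:
        h = x.reshape(x.shape[0], -1) if x.ndim > 2 else x
        for drop, dense in zip(layers[0:-1:2], layers[1:-1:2]):
            h = drop(h, train)
            h = dense(h, train).relu()
        return out(h, train)

    return Model(forward, layers)


def build_mlp(input_shape, hp, rng):
    width = hp.get("dense_size", 500)
    in_dim = int(np.prod(input_shape))
    return _mlp_stack(rng, in_dim, [width] * 3, [0.1, 0.2, 0.3])


def build_fcnn(input_shape, hp, rng):
    T = input_shape[0]
    C = input_shape[1] if len(input_shape) > 1 else 1
    filters = hp.get("filters", (128, 256, 128))
    kernels = hp.get("kernels", (8, 5, 3))
    convs = [L.Conv1D(c_in, c_out, k, rng)
             for c_in, c_out, k in zip((C,) + tuple(filters[:-1]), filters, kernels)]
    head = L.Dense(filters[-1], 2, rng)

    def forward(x: Tensor, train: bool) -> Tensor:
        h = x.reshape(x.shape[0], T, C) if x.ndim == 2 else x
        for conv in convs:
            h = conv(h, train).relu()
        return head(L.gap1d(h), train)

    return Model(forward, convs + [head])


def _tsf_cnn_trunk(rng, C, filters, kernel):
    convs = []
    c_in = C
    for f in filters:
        convs.append(L.Conv1D(c_in, f, kernel, rng))
        c_in = f
    return convs


def build_tsf_cnn(input_shape, hp, rng):
    T, C = input_shape
    kernel = hp.get("kernel_size", 3)
    filters = hp.get("filters", (32, 32, 32, 32, 64, 128))
    convs = _tsf_cnn_trunk(rng, C, filters, kernel)
    head = L.Dense(filters[-1], 2, rng)

    def forward(x: Tensor, train: bool) -> Tensor:
        h = x
        for i, conv in enumerate(convs):
            h = conv(h, train).relu()
            if i in (1, 3):
                h = ag.maxpool1d(h, 2)
        return head(L.gap1d(h), train)

    return Model(forward, convs + [head])


def build_gaf_cnn(input_shape, hp, rng):
    H, W = input_shape[:2]
    kernel = hp.get("kernel_size", 3)
    filters = hp.get("filters", (32, 32, 32, 32, 64, 128))
    convs = []
    c_in = 1
    for f in filters:
        convs.append(L.Conv2D(c_in, f, kernel, rng))
        c_in = f
    head = L.Dense(filters[-1], 2, rng)

    def forward(x: Tensor, train: bool) -> Tensor:
        h = x.reshape(x.shape[0], H, W, 1) if x.ndim == 3 else x
        for i, conv in enumerate(convs):
            h = conv(h, train).relu()
            if i in (1, 3):
                h = ag.maxpool2d(h, 2)
        return head(L.gap2d(h), train)

    return Model(forward, convs + [head])


def build_resnet(input_shape, hp, rng):
    T = input_shape[0]
    C = input_shape[1] if len(input_shape) > 1 else 1
    block_filters = hp.get("filters", (64, 128, 128))
    kernels = (8, 5, 3)
    blocks = []
    c_in = C
    for f in block_filters:
        convs = []
        bns = []
        cc = c_in
        for k in kernels:
            convs.append(L.Conv1D(cc, f, k, rng))
            bns.append(L.BatchNorm(f))
            cc = f
        shortcut = L.Conv1D(c_in, f, 1, rng) if c_in != f else None
        sc_bn = L.BatchNorm(f) if shortcut is not None else None
        blocks.append((convs, bns, shortcut, sc_bn))
        c_in = f
    head = L.Dense(block_filters[-1], 2, rng)

    all_layers: list[L.Layer] = [head]
    for convs, bns, shortcut, sc_bn in blocks:
        all_layers.extend(convs)
        all_layers.extend(bns)
        if shortcut is not None:
            all_layers.extend([shortcut, sc_bn])

    def forward(x: Tensor, train: bool) -> Tensor:
        h = x.reshape(x.shape[0], T, C) if x.ndim == 2 else x
        for convs, bns, shortcut, sc_bn in blocks:
            res = h if shortcut is None else sc_bn(shortcut(h, train), train)
            for i, (conv, bn) in enumerate(zip(convs, bns)):
                h = bn(conv(h, train), train)
                if i < len(convs) - 1:
                    h = h.relu()
            h = (h + res).relu()
        return head(L.gap1d(h), train)

    return Model(forward, all_layers)


def build_rnn_fcn(input_shape, hp, rng):
    T = input_shape[0]
    C = input_shape[1] if len(input_shape) > 1 else 1
    lstm_units = hp.get("lstm_size", 64)
    drop_rate = hp.get("dropout", 0.2)
    lstm = L.LSTM(C, lstm_units, rng)
    drop = L.Dropout(drop_rate, rng)
    filters = (128, 256, 128)
    kernels = (8, 5, 3)
    convs, bns = [], []
    c_in = C
    for f, k in zip(filters, kernels):
        convs.append(L.Conv1D(c_in, f, k, rng))
        bns.append(L.BatchNorm(f))
        c_in = f
    head = L.Dense(lstm_units + filters[-1], 2, rng)

    def forward(x: Tensor, train: bool) -> Tensor:
        h = x.reshape(x.shape[0], T, C) if x.ndim == 2 else x
        r = drop(lstm(h, train), train)
        f = h
        for conv, bn in zip(convs, bns):
            f = bn(conv(f, train), train).relu()
        return head(ag.concat([r, L.gap1d(f)], axis=-1), train)

    return Model(forward, [lstm] + convs + bns + [head])


def build_crnn(input_shape, hp, rng):
    T = input_shape[0]
    C = input_shape[1] if len(input_shape) > 1 else 1
    lstm_units = hp.get("lstm_size", 64)
    conv1 = L.Conv1D(C, 32, hp.get("kernel1", 5), rng)
    conv2 = L.Conv1D(32, 64, hp.get("kernel2", 3), rng)
    drop1 = L.Dropout(0.1, rng)
    drop2 = L.Dropout(0.5, rng)
    lstm = L.LSTM(64, lstm_units, rng)
    head = L.Dense(lstm_units, 2, rng)

    def forward(x: Tensor, train: bool) -> Tensor:
        h = x.reshape(x.shape[0], T, C) if x.ndim == 2 else x
        h = conv1(h, train).relu()
        h = conv2(h, train).relu()
        h = drop1(h, train)
        h = lstm(h, train)
        h = drop2(h, train)
        return head(h, train)

    return Model(forward, [conv1, conv2, lstm, head])


def _positional_encoding(T: int, d: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


def build_transformer(input_shape, hp, rng):
    T = input_shape[0]
    C = input_shape[1] if len(input_shape) > 1 else 1
    heads = hp.get("heads", 4)
    head_size = hp.get("head_size", 8)
    ff_units = hp.get("ff_units", 64)
    drop_rate = hp.get("dropout", 0.1)
    n_layers = 4
    d_model = heads * head_size
    embed = L.Dense(C, d_model, rng)
    pe = Tensor(_positional_encoding(T, d_model))
    enc_layers = []
    for _ in range(n_layers):
        enc_layers.append(
            {
                "mha": L.MultiHeadAttention(d_model, heads, head_size, rng),
                "ln1": L.LayerNorm(d_model),
                "ff1": L.Dense(d_model, ff_units, rng),
                "ff2": L.Dense(ff_units, d_model, rng),
                "ln2": L.LayerNorm(d_model),
                "drop1": L.Dropout(drop_rate, rng),
                "drop2": L.Dropout(drop_rate, rng),
            }
        )
    head = L.Dense(d_model, 2, rng)
    flat_layers: list[L.Layer] = [embed, head]
    for lay in enc_layers:
        flat_layers.extend(
            [lay["mha"], lay["ln1"], lay["ff1"], lay["ff2"], lay["ln2"]]
        )

    def forward(x: Tensor, train: bool) -> Tensor:
        h = x.reshape(x.shape[0], T, C) if x.ndim == 2 else x
        h = embed(h, train) + pe
        for lay in enc_layers:
            a = lay["drop1"](lay["mha"](h, train), train)
            h = lay["ln1"](h + a, train)
            f = lay["ff2"](lay["ff1"](h, train).relu(), train)
            f = lay["drop2"](f, train)
            h = lay["ln2"](h + f, train)
        return head(h.mean(axis=1), train)

    return Model(forward, flat_layers)


ARCHS: dict[str, ArchSpec] = {
    "MLP": ArchSpec(
        "MLP", "raw", build_mlp,
        tunable={"dense_size": (250, 500, 750), "batch_size": (32, 64, 128)},
    ),
    "FCNN": ArchSpec(
        "FCNN", "raw", build_fcnn,
        tunable={"batch_size": (32, 64, 128)},
    ),
    "TSF-MLP": ArchSpec(
        "TSF-MLP", "tsf", build_mlp,
        tunable={"dense_size": (250, 500, 750), "batch_size": (32, 64, 128)},
    ),
    "TSF-CNN": ArchSpec(
        "TSF-CNN", "tsf", build_tsf_cnn,
        tunable={"kernel_size": (3, 5), "batch_size": (32, 64, 128)},
    ),
    "GAF-CNN": ArchSpec(
        "GAF-CNN", "gaf", build_gaf_cnn,
        tunable={"kernel_size": (3, 5), "batch_size": (32, 64, 128)},
    ),
    "ResNet": ArchSpec(
        "ResNet", "raw", build_resnet,
        tunable={"batch_size": (32, 64, 128)},
    ),
    "RNN-FCN": ArchSpec(
        "RNN-FCN", "raw", build_rnn_fcn,
        tunable={"lstm_size": (32, 64, 128), "dropout": (0.1, 0.2, 0.5),
                 "batch_size": (32, 64, 128)},
    ),
    "C-RNN": ArchSpec(
        "C-RNN", "raw", build_crnn,
        tunable={"lstm_size": (32, 64, 128), "batch_size": (32, 64, 128)},
    ),
    "Transformer": ArchSpec(
        "Transformer", "raw", build_transformer,
        tunable={"heads": (2, 4, 8), "head_size": (8, 16, 32),
                 "ff_units": (32, 64, 128), "dropout": (0.0, 0.1, 0.2),
                 "lr": (1e-3, 3e-3), "batch_size": (32, 64, 128)},
    ),
}


def build_model(
    arch: ArchSpec | str,
    input_shape: tuple[int, ...],
    hyperparams: dict | None = None,
    seed: int = 0,
) -> Model:
    """Instantiate one architecture for a given input shape."""
    if isinstance(arch, str):
        arch = ARCHS[arch]
    hp = dict(arch.defaults)
    hp.update(hyperparams or {})
    expected_ndim = {"raw": (1, 2), "tsf": (2,), "gaf": (2, 3)}[arch.input_transform]
    if len(input_shape) not in expected_ndim:
        raise ValueError(
            f"{arch.name} expects a '{arch.input_transform}' input; "
            f"got per-sample shape {input_shape}"
        )
    rng = np.random.default_rng(seed)
    return arch.builder(input_shape, hp, rng)


# ---------------------------------------------------------------------------
# training engine


def train(
    model: Model,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    policy: TrainPolicy,
    arch_name: str = "",
    hyperparams: dict | None = None,
) -> FitResult:
    """Run the shared optimization protocol on prepared inputs.

    The learning rate decays by ``lr_decay_factor`` after ``lr_patience``
    consecutive epochs without training-loss improvement; early stopping
    fires after ``early_stop_patience`` epochs without validation-AUC
    improvement; the best-validation weights are restored at the end.
    """
    hyperparams = hyperparams or {}
    lr = hyperparams.get("lr", policy.initial_lr)
    batch_size = int(hyperparams.get("batch_size", policy.batch_size))
    params = model.params()
    if policy.optimizer == "adam":
        opt = Adam(params, lr=lr)
    elif policy.optimizer == "adadelta":
        opt = Adadelta(params, lr=lr)
    else:
        raise ValueError(f"unknown optimizer '{policy.optimizer}'")
    rng = np.random.default_rng(policy.seed)
    n = len(x_train)
    best_val = -np.inf
    best_weights = model.get_weights()
    best_loss = np.inf
    loss_stall = 0
    val_stall = 0
    history = {"train_loss": [], "val_auc": [], "lr": []}
    t0 = time.perf_counter()
    epochs_run = 0
    for epoch in range(policy.max_epochs):
        epochs_run = epoch + 1
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            logits = model.forward(x_train[idx], train=True)
            loss = ag.softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} ({arch_name})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))
        val_auc = roc_auc(model.predict_proba(x_val), y_val)
        history["train_loss"].append(train_loss)
        history["val_auc"].append(val_auc)
        history["lr"].append(opt.lr)
        # lr schedule on training loss
        if train_loss < best_loss - 1e-6:
            best_loss = train_loss
            loss_stall = 0
        else:
            loss_stall += 1
            if loss_stall >= policy.lr_patience:
                opt.lr *= policy.lr_decay_factor
                loss_stall = 0
        # early stopping / model selection on validation AUC
        if val_auc > best_val + 1e-6:
            best_val = val_auc
            best_weights = model.get_weights()
            val_stall = 0
        else:
            val_stall += 1
            if val_stall >= policy.early_stop_patience:
                break
    model.set_weights(best_weights)
    wall = time.perf_counter() - t0
    train_scores = model.predict_proba(x_train)
    val_scores = model.predict_proba(x_val)
    return FitResult(
        arch=arch_name,
        epochs_run=epochs_run,
        wall_time=wall,
        history=history,
        hyperparams=hyperparams,
        train_scores=train_scores,
        val_scores=val_scores,
        train_auc=roc_auc(train_scores, y_train),
        val_auc=roc_auc(val_scores, y_val),
    )


def tune(
    arch: ArchSpec | str,
    x_tune: np.ndarray,
    y_tune: np.ndarray,
    policy: TrainPolicy,
    budget: int = 100,
    seed: int = 0,
    initial_epochs: int = 3,
    eta: int = 3,
) -> dict:
    """Successive-halving hyperparameter search on the tuning subset.

    Up to ``budget`` sampled configurations are trained briefly on 80% of
    the tuning subset and scored on the held-out 20%; the top 1/eta survive
    to the next round with eta-fold more epochs.  Returns the best
    configuration (architecture defaults when nothing is tunable).
    """
    if isinstance(arch, str):
        arch = ARCHS[arch]
    if not arch.tunable:
        return dict(arch.defaults)
    rng = np.random.default_rng(seed)
    n_configs = min(budget, int(np.prod([len(v) for v in arch.tunable.values()])))
    configs = []
    seen = set()
    while len(configs) < n_configs:
        cfg = {k: v[rng.integers(len(v))] for k, v in arch.tunable.items()}
        key = tuple(sorted(cfg.items()))
        if key not in seen:
            seen.add(key)
            configs.append(cfg)
    # stratified 80/20 split of the tuning subset
    order = rng.permutation(len(x_tune))
    n_val = max(2, len(order) // 5)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    epochs = initial_epochs
    input_shape = x_tune.shape[1:]
    while len(configs) > 1:
        scored = []
        for i, cfg in enumerate(configs):
            model = build_model(arch, input_shape, cfg, seed=seed + i)
            sub_policy = replace(policy, max_epochs=epochs, early_stop_patience=epochs)
            fit = train(
                model, x_tune[tr_idx], y_tune[tr_idx], x_tune[val_idx], y_tune[val_idx],
                sub_policy, arch_name=arch.name, hyperparams=cfg,
            )
            scored.append((fit.val_auc, i, cfg))
        scored.sort(key=lambda t: (-t[0], t[1]))
        configs = [cfg for _, _, cfg in scored[: max(1, len(scored) // eta)]]
        epochs *= eta
    return configs[0]


# ---------------------------------------------------------------------------
# benchmark orchestration


def make_inputs(
    transform: str,
    series: np.ndarray,
    train_idx: np.ndarray,
    tsf_config: TSFConfig | None = None,
) -> np.ndarray:
    """Transform a complete cohort's series into one architecture's input tensor.

    Normalization statistics come from the training rows only: z-score for
    raw/TSF inputs, min-max to [-1, 1] for the angular-field image encoder.
    """
    if transform in ("raw", "tsf"):
        values = zscore_normalize(series, train_idx)
        if transform == "raw":
            return values.astype(np.float32)
        cfg = tsf_config or TSFConfig()
        intervals = sample_intervals(series.shape[1], cfg)
        return tsf_transform(values, intervals).astype(np.float32)
    if transform == "gaf":
        # [0, 1] keeps the angular encoding injective: the summation field is
        # invariant to a global sign flip, so a symmetric [-1, 1] rescale
        # would alias trajectories mirrored around zero
        values = minmax_normalize(series, train_idx, target_range=(0.0, 1.0))
        return gaf_transform(values).astype(np.float32)
    raise ValueError(f"unknown transform '{transform}'")


def evaluate_arch_on_cohort(
    arch: ArchSpec | str,
    cohort: Cohort,
    policy: TrainPolicy,
    fold_count: int = 3,
    seed: int = 0,
    tune_budget: int = 0,
    tsf_config: TSFConfig | None = None,
) -> list[dict]:
    """Preprocess, transform, (optionally) tune, and k-fold train one architecture.

    Returns one metric row per fold with train/validation/test AUCs.
    """
    if isinstance(arch, str):
        arch = ARCHS[arch]
    complete = locf_impute(cohort.series)
    imputed = Cohort(
        spec=cohort.spec, series=complete, labels=cohort.labels,
        observed_mask=np.ones_like(complete, dtype=bool), overlap=cohort.overlap,
    )
    split = partition(imputed, fold_count=fold_count, seed=seed)
    x = make_inputs(arch.input_transform, complete, split.train_idx, tsf_config)
    y = cohort.labels
    hp: dict = dict(arch.defaults)
    if tune_budget > 0:
        tune_idx = split.tuning_idx
        hp = tune(arch, x[tune_idx], y[tune_idx], policy, budget=tune_budget, seed=seed)
    rows = []
    for fold in range(fold_count):
        tr, val = split.fold_split(fold)
        model = build_model(arch, x.shape[1:], hp, seed=seed + fold)
        fit = train(
            model, x[tr], y[tr], x[val], y[val],
            replace(policy, seed=seed + fold), arch_name=arch.name, hyperparams=hp,
        )
        test_scores = model.predict_proba(x[split.test_idx])
        extras = threshold_metrics(test_scores, y[split.test_idx])
        rows.append(
            {
                "arch": arch.name,
                "fold": fold,
                "train_auc": fit.train_auc,
                "val_auc": fit.val_auc,
                "test_auc": roc_auc(test_scores, y[split.test_idx]),
                "f1": extras["f1"],
                "precision": extras["precision"],
                "recall": extras["recall"],
                "specificity": extras["specificity"],
                "epochs": fit.epochs_run,
                "duration": fit.wall_time,
                "overlap": cohort.overlap,
            }
        )
    return rows


def run_benchmark(
    specs: Sequence[CohortSpec],
    archs: Sequence[str],
    policy: TrainPolicy,
    references: Sequence[ReferenceTrajectory],
    fold_count: int = 3,
    tune_budget: int = 0,
) -> pd.DataFrame:
    """Simulate every cohort and train every architecture on it.

    References seed cohorts round-robin.  Individual failures are recorded
    as error rows and the run continues.
    """
    all_rows = []
    for c_idx, spec in enumerate(specs):
        reference = references[c_idx % len(references)]
        cohort = simulate(reference, spec)
        for arch in archs:
            try:
                rows = evaluate_arch_on_cohort(
                    arch, cohort, policy,
                    fold_count=fold_count, seed=spec.seed, tune_budget=tune_budget,
                )
            except Exception as exc:  # noqa: BLE001 - per-row failure logging
                all_rows.append(
                    {"cohort_id": c_idx, "arch": str(arch), "error": repr(exc)}
                )
                continue
            for row in rows:
                row["cohort_id"] = c_idx
                row["variation"] = cohort.spec.variation.value
                row["effect_size"] = cohort.spec.effect_size
                row["dispersion"] = cohort.spec.dispersion
                row["missing_rate"] = cohort.spec.missing_rate
                row["imbalance_ratio"] = cohort.spec.imbalance_ratio
                all_rows.append(row)
    return pd.DataFrame(all_rows)
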