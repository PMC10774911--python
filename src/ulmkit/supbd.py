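"""Supervised residual-learning super-resolution localizer (SupBD-net).

An 80 x 80 native CEUS window maps to a 240 x 240 center-likelihood map
(three-fold resolution gain, lambda/14 pitch).  The architecture is a
residual super-resolution network adapted to single-image enhancement:

    ConvBlock(9x9) -> ConvBlock(3x3) -> 4 x ResBlock(3x3)
    -> global skip add (output of the 2nd ConvBlock)
    -> transposed convolution (stride 3) -> IN -> LeakyReLU
    -> Conv(9x9) -> sigmoid

Instance normalization replaces batch normalization so the network learns
instance-invariant trace-to-center structure regardless of per-frame
intensity and noise statistics; leaky rectifiers (slope 0.2) avoid dead
units on the dark background.  Training minimizes pixelwise MSE against
blurred reference center maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .detections import DetectionSet, extract_centers_from_map
from .grids import GridSpec
from .nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    InstanceNorm,
    LeakyReLU,
    ResBlock,
    Sequential,
    Sigmoid,
)
from .training_data import TrainingSet


@dataclass(frozen=True)
class SupBDSpec:
    """Architecture hyper-parameters."""

    n_conv_blocks: int = 2
    n_res_blocks: int = 4
    feature_channels: int = 64
    first_last_kernel: int = 9
    inner_kernel: int = 3
    leaky_slope: float = 0.2
    upscale: int = 3

    def __post_init__(self) -> None:
        if self.upscale != 3:
            raise ValueError("the default heads implement a fixed x3 upscale")


@dataclass(frozen=True)
class SupTrainConfig:
    """Optimization schedule for supervised training."""

    minibatch: int = 16
    lr: float = 1e-3
    lr_decay: float = 0.1
    lr_decay_every: int = 5  # epochs
    patience: int = 5  # epochs without validation improvement
    max_epochs: int = 50
    val_fraction: float = 0.3
    seed: int = 0


def _conv_block(c_in: int, c_out: int, kernel: int, slope: float, rng) -> Sequential:
    return Sequential(Conv2d(c_in, c_out, kernel, rng), InstanceNorm(c_out), LeakyReLU(slope))


class SupBDNet:
    """Residual super-resolution localizer with explicit backprop."""

    def __init__(self, spec: SupBDSpec, rng: np.random.Generator):
        self.spec = spec
        c = spec.feature_channels
        self.stage1 = Sequential(
            _conv_block(1, c, spec.first_last_kernel, spec.leaky_slope, rng),
            _conv_block(c, c, spec.inner_kernel, spec.leaky_slope, rng),
        )
        self.body = Sequential(
            *[ResBlock(c, spec.inner_kernel, rng, spec.leaky_slope) for _ in range(spec.n_res_blocks)]
        )
        self.tail = Sequential(
            ConvTranspose2d(c, c, spec.upscale, rng),
            InstanceNorm(c),
            LeakyReLU(spec.leaky_slope),
            Conv2d(c, 1, spec.first_last_kernel, rng),
            Sigmoid(),
        )

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, H, W) or (N, 1, H, W) input -> (N, 3H, 3W) output in (0, 1)."""
        if x.ndim == 3:
            x = x[:, None]
        x = x.astype(np.float32, copy=False)
        s1 = self.stage1.forward(x, train=train)
        b = self.body.forward(s1, train=train)
        out = self.tail.forward(b + s1, train=train)
        return out[:, 0]

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        df = self.tail.backward(dout[:, None].astype(np.float32, copy=False))
        db = self.body.backward(df)
        return self.stage1.backward(df + db)

    # -- parameter plumbing -------------------------------------------------

    def _groups(self):
        return (("stage1", self.stage1), ("body", self.body), ("tail", self.tail))

    def param_items(self):
        items = []
        for gname, group in self._groups():
            for layer_idx, layer in enumerate(group.layers):
                if hasattr(layer, "param_items"):
                    items.extend(layer.param_items(f"{gname}.{layer_idx}."))
                else:
                    for name, p in layer.P.items():
                        items.append((f"{gname}.{layer_idx}.{name}", p, layer.G[name]))
        return items

    def tail_param_items(self):
        """Parameters downstream of the global residual addition."""
        return [it for it in self.param_items() if it[0].startswith("tail.")]

    def zero_grad(self) -> None:
        for _, group in self._groups():
            group.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.param_items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.param_items():
            p[...] = state[name]

    def layer_summary(self) -> list[tuple[str, int | None]]:
        """(layer type, kernel size) pairs in execution order, for audits."""
        out: list[tuple[str, int | None]] = []

        def visit(layer):
            if isinstance(layer, Sequential):
                for sub in layer.layers:
                    visit(sub)
            elif isinstance(layer, ResBlock):
                for sub in layer.body.layers:
                    visit(sub)
            else:
                k = getattr(layer, "k", getattr(layer, "s", None))
                out.append((type(layer).__name__, k))

        for _, group in self._groups():
            visit(group)
        return out


def build_supbd(spec: SupBDSpec | None = None, seed: int = 0) -> SupBDNet:
    spec = spec or SupBDSpec()
    return SupBDNet(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# training


def _mse_and_grad(pred: np.ndarray, ref: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - ref
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff


def _val_loss(model: SupBDNet, inputs: np.ndarray, refs: np.ndarray, batch: int) -> float:
    losses = []
    for i in range(0, len(inputs), batch):
        pred = model.forward(inputs[i : i + batch], train=False)
        losses.append(np.mean((pred - refs[i : i + batch]) ** 2) * len(pred))
    return float(np.sum(losses) / len(inputs))


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None
    best_epoch: int | None = None


def train_supbd(
    model: SupBDNet,
    dataset: TrainingSet,
    config: SupTrainConfig | None = None,
) -> tuple[SupBDNet, TrainHistory]:
    """Train with Adam, stepped learning-rate decay, and early stopping.

    The data are split 70/30 into training and validation, reshuffled every
    epoch; training stops once the validation loss has not improved for
    ``patience`` epochs and the best-validated parameters are restored.
    """
    config = config or SupTrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("dataset too small to split")
    x_val = dataset.inputs[val_idx].astype(np.float32)
    r_val = dataset.references[val_idx].astype(np.float32)
    x_tr = dataset.inputs[train_idx].astype(np.float32)
    r_tr = dataset.references[train_idx].astype(np.float32)

    opt = Adam(model.param_items(), lr=config.lr)
    history = TrainHistory()
    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0
    for epoch in range(config.max_epochs):
        opt.lr = config.lr * (config.lr_decay ** (epoch // config.lr_decay_every))
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), config.minibatch):
            idx = order[i : i + config.minibatch]
            model.zero_grad()
            pred = model.forward(x_tr[idx], train=True)
            loss, dpred = _mse_and_grad(pred, r_tr[idx])
            model.backward(dpred.astype(np.float32))
            opt.step()
            losses.append(loss * len(idx))
        history.train_loss.append(float(np.sum(losses) / len(order)))
        vloss = _val_loss(model, x_val, r_val, config.minibatch)
        history.val_loss.append(vloss)
        history.lr.append(opt.lr)
        if vloss < best_val - 1e-12:
            best_val = vloss
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                history.stopped_epoch = epoch
                break
    model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# inference


def infer_map(model: SupBDNet, frame: np.ndarray) -> np.ndarray:
    """Center-likelihood map for one native-resolution frame."""
    return model.forward(frame[None], train=False)[0]


def net_extract_centers(
    map240: np.ndarray,
    grid: GridSpec | None = None,
    min_peak: float = 0.5,
    frame: int | None = None,
) -> DetectionSet:
    """Centers from a network output map on the lambda/14 grid.

    8-connected clusters above ``min_peak`` are reduced to intensity-
    weighted centroids in microns.
    """
    grid = grid or GridSpec()
    return extract_centers_from_map(
        np.asarray(map240, dtype=float), grid.superres_pixel_um, min_peak, frame=frame
    )


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: SupBDNet, path: str | Path) -> None:
    """Write parameters (.npz) plus a JSON architecture sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    spec = {k: getattr(model.spec, k) for k in model.spec.__dataclass_fields__}
    path.with_suffix(".json").write_text(json.dumps(spec, indent=2))


def load_checkpoint(path: str | Path) -> SupBDNet:
    path = Path(path)
    spec = SupBDSpec(**json.loads(path.with_suffix(".json").read_text()))
    model = build_supbd(spec)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
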