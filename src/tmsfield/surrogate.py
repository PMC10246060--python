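"""Multi-scale 3D Res-UNet surrogate for fast E-field prediction.

Maps the 9-channel volumetric input (6 conductivity-tensor components followed
by the 3 dA/dt components, on the reduced field of view) to the 3-component
E-field. The network is a residual encoder–decoder with skip connections and
deep supervision: auxiliary 1x1x1 heads predict the field at the coarser
decoder scales and enter a weighted multi-scale mean-squared-error loss
against average-pooled targets. Training uses Adam with linear warmup and
cosine learning-rate decay; inputs are z-scored per channel and targets scaled
by their global RMS, with the statistics stored in the checkpoint.

The quality metric is the normalized root-mean-square error

    NE = sqrt( sum_mask ||E_pred - E_true||^2 / sum_mask ||E_true||^2 ),

which is 0 for a perfect prediction and exactly 1 for the zero predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .fieldsolver import TrainingSample
from .geometry import VolumeGrid

__all__ = [
    "SurrogateConfig",
    "TrainedSurrogate",
    "EvalReport",
    "train_surrogate",
    "predict_efield",
    "ne_metric",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass
class SurrogateConfig:
    levels: int = 3                 # resolution depths (encoder stages)
    base_channels: int = 8          # channels at full resolution
    epochs: int = 100
    batch_size: int = 4
    learning_rate: float = 2e-3
    warmup_frac: float = 0.05       # fraction of steps spent in linear warmup
    loss_weights: tuple[float, ...] = (1.0, 0.5, 0.25)  # fine -> coarse scales
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if len(self.loss_weights) < self.levels:
            # pad by halving: weight per extra coarse scale
            w = list(self.loss_weights)
            while len(w) < self.levels:
                w.append(w[-1] / 2.0)
            self.loss_weights = tuple(w)


class _ResUNet:
    """Residual encoder-decoder with deep-supervision heads at every scale.

    The 3x3x3 convolutional trunk runs at half resolution and below (a
    stride-2 stem), which keeps CPU training tractable; a pointwise
    full-resolution stage refines the upsampled features concatenated with
    the raw 9-channel input (the full-resolution skip). Deep-supervision
    heads emit predictions at every scale, finest first.
    """

    def __init__(self, config: SurrogateConfig, in_channels: int = 9,
                 out_channels: int = 3):
        rng = np.random.default_rng(config.seed)
        L = config.levels
        n_enc = L - 1                       # stride-2 encoder stages
        c = [config.base_channels * 2**l for l in range(n_enc)]
        self.config = config
        self.in_channels = in_channels
        self.n_enc = n_enc
        self.c = c
        self.enc_in, self.enc_relu, self.enc_res = [], [], []
        for l in range(n_enc):
            cin = in_channels if l == 0 else c[l - 1]
            self.enc_in.append(_nn.Conv3d(rng, cin, c[l], stride=2))
            self.enc_relu.append(_nn.ReLU())
            self.enc_res.append(_nn.ResBlock(rng, c[l]))
        self.up, self.up_conv, self.up_relu = [], [], []
        self.merge_conv, self.merge_relu, self.dec_res = [], [], []
        for l in range(n_enc - 2, -1, -1):
            self.up.append(_nn.Upsample2())
            self.up_conv.append(_nn.Conv3d(rng, c[l + 1], c[l]))
            self.up_relu.append(_nn.ReLU())
            self.merge_conv.append(_nn.Conv3d(rng, 2 * c[l], c[l]))
            self.merge_relu.append(_nn.ReLU())
            self.dec_res.append(_nn.ResBlock(rng, c[l]))
        # full-resolution pointwise refinement over (upsampled features, input)
        self.up_full = _nn.Upsample2()
        self.refine_conv = _nn.Conv3d(rng, c[0] + in_channels, c[0], kernel=1)
        self.refine_relu = _nn.ReLU()
        # heads[0] = full resolution ... heads[L-1] = bottleneck scale
        self.heads = [_nn.Conv3d(rng, c[0], out_channels, kernel=1)]
        for l in range(n_enc):
            self.heads.append(_nn.Conv3d(rng, c[l], out_channels, kernel=1))

    @property
    def params(self):
        ps = []
        for lay in (*self.enc_in, *self.enc_res, *self.up_conv,
                    *self.merge_conv, *self.dec_res,
                    self.refine_conv, *self.heads):
            ps += lay.params
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> list[np.ndarray]:
        """Return per-scale predictions, finest first."""
        L = self.config.levels
        n_enc = self.n_enc
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        h = x
        for l in range(n_enc):
            h = self.enc_relu[l].forward(self.enc_in[l].forward(h, train), train)
            h = self.enc_res[l].forward(h, train)
            skips.append(h)
        outs = [None] * L
        outs[L - 1] = self.heads[L - 1].forward(h, train)
        self._concat_split = []
        for i, l in enumerate(range(n_enc - 2, -1, -1)):
            h = self.up_relu[i].forward(
                self.up_conv[i].forward(self.up[i].forward(h, train), train), train
            )
            cat = np.concatenate([h, skips[l]], axis=-1)
            self._concat_split.append(h.shape[-1])
            h = self.merge_relu[i].forward(self.merge_conv[i].forward(cat, train), train)
            h = self.dec_res[i].forward(h, train)
            outs[l + 1] = self.heads[l + 1].forward(h, train)
        hu = self.up_full.forward(h, train)
        catf = np.concatenate([hu, x], axis=-1)
        f = self.refine_relu.forward(self.refine_conv.forward(catf, train), train)
        outs[0] = self.heads[0].forward(f, train)
        return outs

    def backward(self, douts: list[np.ndarray]) -> None:
        """Backprop given per-scale loss gradients (finest first)."""
        L = self.config.levels
        n_enc = self.n_enc
        c0 = self.c[0]
        dskips = [None] * n_enc
        d = self.heads[0].backward(douts[0])
        d = self.refine_conv.backward(self.refine_relu.backward(d))
        dh = self.up_full.backward(d[..., :c0])  # input-skip gradient discarded
        n_dec = n_enc - 1
        for i in range(n_dec - 1, -1, -1):  # reverse of decoder loop
            l = n_enc - 2 - i
            d = self.heads[l + 1].backward(douts[l + 1]) + dh
            d = self.dec_res[i].backward(d)
            dcat = self.merge_conv[i].backward(self.merge_relu[i].backward(d))
            nsplit = self._concat_split[i]
            dskips[l] = dcat[..., nsplit:]
            dh = self.up[i].backward(
                self.up_conv[i].backward(self.up_relu[i].backward(dcat[..., :nsplit]))
            )
        d = self.heads[L - 1].backward(douts[L - 1]) + dh
        for l in range(n_enc - 1, -1, -1):
            if dskips[l] is not None:
                d = d + dskips[l]
            d = self.enc_res[l].backward(d)
            d = self.enc_in[l].backward(self.enc_relu[l].backward(d))
        # d is dLoss/dinput; discarded


@dataclass
class TrainedSurrogate:
    """Weights + config + input-normalization statistics + training history."""

    net: _ResUNet
    config: SurrogateConfig
    in_mean: np.ndarray        # (9,) per-channel mean of training inputs
    in_std: np.ndarray         # (9,)
    target_scale: float        # RMS of training targets (V/m)
    history: list[dict] = field(default_factory=list)  # per-epoch loss / NE

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.in_mean)) and np.all(np.isfinite(self.in_std))):
            raise ValueError("normalization statistics must be finite")


@dataclass
class EvalReport:
    per_case_ne: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_case_ne))

    @property
    def std(self) -> float:
        return float(np.std(self.per_case_ne, ddof=1)) if len(self.per_case_ne) > 1 else 0.0


def ne_metric(pred, truth, mask=None) -> float:
    """Normalized RMS error between two vector fields over a mask.

    Accepts arrays shaped (..., 3) or 3-component VolumeGrids. Raises on a
    truth field with zero energy over the mask (metric undefined).
    """
    p = pred.values if isinstance(pred, VolumeGrid) else np.asarray(pred)
    t = truth.values if isinstance(truth, VolumeGrid) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("pred and truth shapes differ")
    if mask is not None:
        m = (mask.values if isinstance(mask, VolumeGrid) else np.asarray(mask)) > 0
        p, t = p[m], t[m]
    den = float(np.sum(t.astype(np.float64) ** 2))
    if den == 0.0:
        raise ValueError("truth field has zero energy over the mask; NE undefined")
    num = float(np.sum((p.astype(np.float64) - t.astype(np.float64)) ** 2))
    return float(np.sqrt(num / den))


def _stack_inputs(samples: list[TrainingSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.input for s in samples])  # (B, X, Y, Z, C) channels-last
    y = np.stack([s.target for s in samples])
    return x.astype(np.float32), y.astype(np.float32)


def _check_shape(shape: tuple[int, ...], levels: int) -> None:
    f = 2 ** (levels - 1)
    if any(s % f for s in shape):
        raise ValueError(f"spatial shape {shape} must be divisible by {f} "
                         f"for a {levels}-level network (pad the FOV)")


def train_surrogate(dataset: list[TrainingSample],
                    config: SurrogateConfig | None = None) -> TrainedSurrogate:
    """Train the multi-scale Res-UNet on ground-truth cases.

    Deterministic for a fixed config (the seed drives weight initialization
    and batch shuffling). Raises on inconsistent shapes or a non-finite loss.
    """
    config = config or SurrogateConfig()
    if len(dataset) < 2:
        raise ValueError("need at least 2 training samples")
    shapes = {s.input.shape for s in dataset}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent sample shapes: {shapes}")
    _check_shape(dataset[0].input.shape[:3], config.levels)

    x, y = _stack_inputs(dataset)
    in_mean = x.mean(axis=(0, 1, 2, 3))
    in_std = np.maximum(x.std(axis=(0, 1, 2, 3)), 1e-12)
    target_scale = float(max(np.sqrt(np.mean(y.astype(np.float64) ** 2)), 1e-30))
    xn = (x - in_mean) / in_std
    yn = y / np.float32(target_scale)

    net = _ResUNet(config)
    opt = _nn.Adam(net.params)
    rng = np.random.default_rng(config.seed + 1)
    n = len(dataset)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    weights = config.loss_weights[:config.levels]

    history = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ne_num = 0.0
        ne_den = 0.0
        for bi in range(steps_per_epoch):
            sel = order[bi * config.batch_size:(bi + 1) * config.batch_size]
            xb, yb = xn[sel], yn[sel]
            outs = net.forward(xb, train=True)
            opt.zero_grad()
            douts = []
            loss = 0.0
            for s_idx, (w, out) in enumerate(zip(weights, outs)):
                tgt = yb if s_idx == 0 else _nn.avg_pool(yb, 2**s_idx)
                diff = out - tgt
                loss += w * float(np.mean(diff.astype(np.float64) ** 2))
                douts.append((2.0 * w / diff.size) * diff)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {bi}: {loss}")
            net.backward(douts)
            lr = _nn.cosine_lr(step, total_steps, config.learning_rate,
                               config.warmup_frac)
            opt.step(lr)
            step += 1
            ep_loss += loss
            ne_num += float(np.sum((outs[0] - yb).astype(np.float64) ** 2))
            ne_den += float(np.sum(yb.astype(np.float64) ** 2))
        history.append({
            "epoch": epoch,
            "loss": ep_loss / steps_per_epoch,
            "train_ne": float(np.sqrt(ne_num / max(ne_den, 1e-300))),
        })
    return TrainedSurrogate(net=net, config=config, in_mean=in_mean,
                            in_std=in_std, target_scale=target_scale,
                            history=history)


def _predict_array(model: TrainedSurrogate, x9: np.ndarray) -> np.ndarray:
    """Inference on a (X,Y,Z,9) input; returns (X,Y,Z,3), padding as needed."""
    if x9.ndim != 4 or x9.shape[3] != 9:
        raise ValueError(f"expected 9 input channels, got shape {x9.shape}")
    f = 2 ** (model.config.levels - 1)
    shape = x9.shape[:3]
    padded = tuple(int(np.ceil(s / f)) * f for s in shape)
    xb = np.zeros((1,) + padded + (9,), dtype=np.float32)
    xb[0, :shape[0], :shape[1], :shape[2]] = x9
    xb = (xb - model.in_mean) / model.in_std
    out = model.net.forward(xb, train=False)[0]
    out = out[0, :shape[0], :shape[1], :shape[2]]
    return (out * model.target_scale).astype(np.float32)


def predict_efield(model: TrainedSurrogate, sigma, dadt) -> tuple[VolumeGrid, VolumeGrid]:
    """Predict the E-field and its magnitude for a (conductivity, dA/dt) pair.

    ``sigma``: 6-component VolumeGrid (or array); ``dadt``: 3-component
    VolumeGrid (or array) on the same FOV grid. Returns the 3-component vector
    prediction and the per-voxel Euclidean-norm magnitude volume (the
    1-channel image the streaming loop sends to a viewer).
    """
    sv = sigma.values if isinstance(sigma, VolumeGrid) else np.asarray(sigma)
    dv = dadt.values if isinstance(dadt, VolumeGrid) else np.asarray(dadt)
    affine = dadt.affine if isinstance(dadt, VolumeGrid) else np.eye(4)
    x9 = np.concatenate([sv, dv], axis=3)
    vec = _predict_array(model, x9)
    mag = np.linalg.norm(vec, axis=3).astype(np.float32)
    return VolumeGrid(vec, np.asarray(affine).copy()), VolumeGrid(mag, np.asarray(affine).copy())


def evaluate(model: TrainedSurrogate, samples: list[TrainingSample]) -> EvalReport:
    """Per-case NE of the surrogate against ground truth, over each case's mask."""
    nes = []
    for s in samples:
        pred = _predict_array(model, s.input)
        nes.append(ne_metric(pred, s.target, s.mask))
    return EvalReport(per_case_ne=nes)


# --------------------------------------------------------------------------- #
# checkpoint I/O: single .npz archive with weights, config, stats, history
# --------------------------------------------------------------------------- #


def save_model(model: TrainedSurrogate, path: str | Path) -> None:
    arrays = {}
    for i, (p, _) in enumerate(model.net.params):
        arrays[f"param_{i:04d}"] = p
    arrays["in_mean"] = model.in_mean
    arrays["in_std"] = model.in_std
    arrays["target_scale"] = np.array(model.target_scale)
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    arrays["history_json"] = np.frombuffer(
        json.dumps(model.history).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_model(path: str | Path) -> TrainedSurrogate:
    with np.load(str(path)) as z:
        cfg_d = json.loads(bytes(z["config_json"]).decode())
        cfg_d["loss_weights"] = tuple(cfg_d["loss_weights"])
        config = SurrogateConfig(**cfg_d)
        net = _ResUNet(config)
        for i, (p, _) in enumerate(net.params):
            p[...] = z[f"param_{i:04d}"]
        return TrainedSurrogate(
            net=net,
            config=config,
            in_mean=z["in_mean"],
            in_std=z["in_std"],
            target_scale=float(z["target_scale"]),
            history=json.loads(bytes(z["history_json"]).decode()),
        )
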