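"""The two learned stages and their training regimes.

Stage one, *virtual uncovering*: a 3D U-Net f maps the binary occupancy
volume of a covered patient (bed included) to a per-voxel probability
volume of the uncovered patient's surface, trained with voxel-wise
binary cross-entropy against patient-segmented uncovered targets.

Stage two, *weight regression*: a compact 3D CNN g maps an occupancy (or
probability) volume to the weight in kg, trained with mean squared
error.  Three regimes are supported:

* ``two-stage`` — g is trained on the frozen f's soft output (the
  primary pipeline; f's parameters are verifiably untouched);
* ``plain``     — g consumes raw occupancy volumes directly;
* ``e2e``       — the composition g(f(.)) is trained on the weight loss
  only, without the intermediate uncovering supervision.

The same CNN with a logistic head doubles as the cover-condition
classifier that routes inputs to the appropriate regime.  Default
schedules: U-Net 50 epochs (lr /10 after 30); regressor 120 epochs
(lr /10 at 60 and 100); classifier 10 epochs (lr /10 after 5 and 8);
Adam, lr 0.001, batch 16 throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "TrainConfig",
    "UncoverModel",
    "WeightModel",
    "build_unet",
    "build_weight_cnn",
    "ce_loss",
    "mse_loss",
    "train_uncover",
    "train_weight",
    "predict_weight",
    "train_cover_classifier",
    "classify_cover",
    "route_and_predict",
    "save_checkpoint",
    "load_checkpoint",
]

# re-export the losses at the model surface
ce_loss = nn.ce_loss
mse_loss = nn.mse_loss


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule: Adam at ``learning_rate``, divided by 10 at
    each milestone epoch (0-based)."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 120
    milestones: tuple[int, ...] = (60, 100)
    seed: int = 0

    def __post_init__(self):
        if any(m >= self.epochs for m in self.milestones) and self.epochs > 0:
            raise ValueError(f"milestones {self.milestones} must lie below epoch count {self.epochs}")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")

    @classmethod
    def unet(cls, seed: int = 0, epochs: int = 50, milestones: tuple[int, ...] = (30,), **kw) -> "TrainConfig":
        return cls(epochs=epochs, milestones=milestones, seed=seed, **kw)

    @classmethod
    def regressor(cls, seed: int = 0, epochs: int = 120, milestones: tuple[int, ...] = (60, 100), **kw) -> "TrainConfig":
        return cls(epochs=epochs, milestones=milestones, seed=seed, **kw)

    @classmethod
    def classifier(cls, seed: int = 0, epochs: int = 10, milestones: tuple[int, ...] = (5, 8), **kw) -> "TrainConfig":
        return cls(epochs=epochs, milestones=milestones, seed=seed, **kw)

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "milestones": list(self.milestones),
            "seed": self.seed,
        }


def _block(c_in: int, c_out: int, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv3d(c_in, c_out, 3, padding=1, rng=rng),
        nn.BatchNorm3d(c_out),
        nn.ReLU(),
        nn.Conv3d(c_out, c_out, 3, padding=1, rng=rng),
        nn.BatchNorm3d(c_out),
        nn.ReLU(),
    )


class UncoverModel(nn.Module):
    """3D U-Net f: encoder and decoder with four resolution levels.

    Downsampling by 2x2x2 max pooling, upsampling by transposed
    convolutions, skip connections concatenating equal-resolution
    encoder features before the merging convolutions; base channels
    double per level; the final 1x1x1 convolution yields per-voxel
    logits (probabilities after the logistic).
    """

    def __init__(self, resolution: tuple[int, int, int], levels: int = 4,
                 base_channels: int = 32, seed: int = 0):
        factor = 2 ** (levels - 1)
        if any(r % factor != 0 for r in resolution):
            raise ValueError(
                f"input resolution {resolution} must be divisible by {factor} for {levels} levels"
            )
        rng = np.random.default_rng(seed)
        self.resolution = tuple(int(r) for r in resolution)
        self.levels = levels
        self.base_channels = base_channels
        chans = [base_channels * 2**i for i in range(levels)]  # last = bottleneck

        self.encoders = [_block(1 if i == 0 else chans[i - 1], chans[i], rng) for i in range(levels - 1)]
        self.pools = [nn.MaxPool3d() for _ in range(levels - 1)]
        self.bottleneck = _block(chans[levels - 2], chans[levels - 1], rng)
        self.ups = [nn.ConvTranspose3d(chans[i + 1], chans[i], rng=rng) for i in range(levels - 1)]
        self.decoders = [_block(2 * chans[i], chans[i], rng) for i in range(levels - 1)]
        self.head = nn.Conv3d(chans[0], 1, 1, rng=rng)
        self.bottleneck_shape: tuple[int, ...] | None = None
        self.train_log: list[tuple[int, float, float]] = []

    @property
    def descriptor(self) -> dict:
        return {
            "kind": "unet",
            "resolution": list(self.resolution),
            "levels": self.levels,
            "base_channels": self.base_channels,
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Volumes in, per-voxel logits out (same spatial shape)."""
        skips = []
        h = x
        for enc, pool in zip(self.encoders, self.pools):
            h = enc(h)
            skips.append(h)
            h = pool(h)
        h = self.bottleneck(h)
        self.bottleneck_shape = h.shape[2:]
        for i in reversed(range(len(self.decoders))):
            h = self.ups[i](h)
            h = np.concatenate([skips[i], h], axis=1)
            h = self.decoders[i](h)
        return self.head(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head.backward(dout)
        d_skips: list[np.ndarray | None] = [None] * len(self.decoders)
        for i in range(len(self.decoders)):
            d = self.decoders[i].backward(d)
            split = self.decoders[i].layers[0].in_channels // 2
            d_skips[i] = d[:, :split]
            d = self.ups[i].backward(np.ascontiguousarray(d[:, split:]))
        d = self.bottleneck.backward(d)
        for i in reversed(range(len(self.encoders))):
            d = self.pools[i].backward(d) + d_skips[i]
            d = self.encoders[i].backward(d)
        return d

    def predict_proba(self, volumes: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Per-voxel uncovered-surface probabilities, eval mode."""
        self.eval()
        x = _as_batch(volumes, self.resolution)
        out = np.empty_like(x)
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size])
            out[i : i + batch_size] = 1.0 / (1.0 + np.exp(-logits))
        return out


class WeightModel(nn.Module):
    """3D CNN g for weight regression or cover classification.

    A k=5, stride-2 convolution followed by alternating k=3 convolutions
    and 2x2x2 max pools drives the volume down by a factor of
    ``2^(number of convolutions)`` per axis while the channel count grows
    along ``channel_schedule``; each convolution is followed by batch
    normalization and a ReLU.  The flattened features pass a
    fully connected layer, ReLU, dropout, and a single output neuron —
    linear for regression (kg), logistic for the cover classifier.
    """

    def __init__(self, resolution: tuple[int, int, int],
                 channel_schedule: tuple[int, ...] = (16, 24, 32, 48, 64),
                 head_width: int = 128, dropout: float = 0.8,
                 mode: str = "regression", seed: int = 0):
        if mode not in ("regression", "classifier"):
            raise ValueError(f"unknown mode {mode!r}")
        if any(a > b for a, b in zip(channel_schedule, channel_schedule[1:])):
            raise ValueError("channel schedule must be nondecreasing")
        rng = np.random.default_rng(seed)
        self.resolution = tuple(int(r) for r in resolution)
        self.channel_schedule = tuple(channel_schedule)
        self.head_width = head_width
        self.dropout = dropout
        self.mode = mode

        layers: list[nn.Module] = []
        shape = np.asarray(self.resolution)
        c_in = 1
        for i, c_out in enumerate(channel_schedule):
            if i == 0:
                layers.append(nn.Conv3d(c_in, c_out, 5, stride=2, padding=2, rng=rng))
                shape = (shape + 2 * 2 - 5) // 2 + 1
            else:
                layers.append(nn.Conv3d(c_in, c_out, 3, stride=1, padding=1, rng=rng))
            layers += [nn.BatchNorm3d(c_out), nn.ReLU()]
            if i < len(channel_schedule) - 1:
                layers.append(nn.MaxPool3d())
                shape = shape // 2
            if np.any(shape < 1):
                raise ValueError(
                    f"input {resolution} too small for {len(channel_schedule)} downsampling stages"
                )
            c_in = c_out
        self.feature_shape = tuple(int(s) for s in shape)
        flat = int(channel_schedule[-1] * np.prod(shape))
        layers += [
            nn.Flatten(),
            nn.Linear(flat, head_width, rng=rng),
            nn.ReLU(),
            nn.Dropout(dropout),
            nn.Linear(head_width, 1, rng=rng),
        ]
        self.stack = nn.Sequential(*layers)
        self.train_log: list[tuple[int, float, float]] = []

    @property
    def downsampling_factor(self) -> int:
        """Cumulative spatial downsampling of the convolutional stack."""
        return 2 ** len(self.channel_schedule)

    @property
    def final_channels(self) -> int:
        return self.channel_schedule[-1]

    @property
    def descriptor(self) -> dict:
        return {
            "kind": "weight_cnn",
            "resolution": list(self.resolution),
            "channel_schedule": list(self.channel_schedule),
            "head_width": self.head_width,
            "dropout": self.dropout,
            "mode": self.mode,
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.stack(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.stack.backward(dout)

    def predict(self, volumes: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Scalar output per volume: kg (regression) or P(covered)."""
        self.eval()
        x = _as_batch(volumes, self.resolution)
        out = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            z = self.forward(x[i : i + batch_size])[:, 0]
            out[i : i + batch_size] = 1.0 / (1.0 + np.exp(-z)) if self.mode == "classifier" else z
        return out


def build_unet(resolution: tuple[int, int, int] = (48, 96, 32), levels: int = 4,
               base_channels: int = 32, seed: int = 0) -> UncoverModel:
    """Construct the uncovering U-Net (resolution must divide 2^(levels-1))."""
    return UncoverModel(resolution, levels=levels, base_channels=base_channels, seed=seed)


def build_weight_cnn(resolution: tuple[int, int, int] = (48, 96, 32),
                     channel_schedule: tuple[int, ...] = (16, 24, 32, 48, 64),
                     head_width: int = 128, dropout: float = 0.8,
                     mode: str = "regression", seed: int = 0) -> WeightModel:
    """Construct the weight-regression / cover-classification 3D CNN."""
    return WeightModel(resolution, channel_schedule, head_width, dropout, mode, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _as_batch(volumes: np.ndarray, resolution: tuple[int, ...]) -> np.ndarray:
    """(n, h, w, d) or (h, w, d) float volumes -> (n, 1, h, w, d) float32."""
    x = np.asarray(volumes, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or tuple(x.shape[1:]) != tuple(resolution):
        raise ValueError(f"volume shape {x.shape} does not match model resolution {resolution}")
    return x[:, None]


def _epoch_lr(cfg: TrainConfig, epoch: int) -> float:
    drops = sum(1 for m in cfg.milestones if epoch >= m)
    return cfg.learning_rate / (10.0**drops)


def train_uncover(covered: np.ndarray, targets: np.ndarray,
                  config: TrainConfig | None = None,
                  model: UncoverModel | None = None,
                  base_channels: int = 32, levels: int = 4) -> UncoverModel:
    """Fit the uncovering U-Net on (covered volume, uncovered-patient
    target) pairs by voxel-wise binary cross-entropy.

    Targets are the binary grids of patient-segmented uncovered clouds.
    Deterministic given ``config.seed``; the per-epoch mean loss and
    learning rate are recorded on ``model.train_log``.
    """
    config = config if config is not None else TrainConfig.unet()
    covered = np.asarray(covered, dtype=np.float32)
    targets = np.asarray(targets, dtype=np.float32)
    if len(covered) == 0:
        raise ValueError("empty training set")
    if covered.shape != targets.shape:
        raise ValueError("covered and target volumes must align")
    if model is None:
        model = build_unet(covered.shape[1:], levels=levels, base_channels=base_channels,
                           seed=config.seed)
        # prior initialization: start the output at the target occupancy
        # rate so optimization skips the learn-to-predict-background phase
        prevalence = float(np.clip(targets.mean(), 1e-4, 1 - 1e-4))
        model.head.bias.data[:] = np.float32(np.log(prevalence / (1 - prevalence)))
    x = _as_batch(covered, model.resolution)
    t = _as_batch(targets, model.resolution)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    model.set_rng(rng)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    model.train()
    for epoch in range(config.epochs):
        opt.lr = _epoch_lr(config, epoch)
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(x[idx])
            loss, grad = nn.bce_with_logits(logits, t[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        model.train_log.append((epoch, float(np.mean(losses)), opt.lr))
    model.eval()
    return model


def train_weight(volumes: np.ndarray, weights: np.ndarray, mode: str = "plain",
                 uncover_model: UncoverModel | None = None,
                 config: TrainConfig | None = None,
                 model: WeightModel | None = None,
                 **arch_kwargs):
    """Fit the weight CNN in one of the three regimes.

    ``volumes`` are covered inputs for ``two-stage``/``e2e`` and raw
    (covered or uncovered) inputs for ``plain``; ``weights`` in kg.

    * ``two-stage``: requires a trained ``uncover_model``; g is trained
      on f's soft (probability) output and f stays bitwise frozen.
    * ``plain``: g is trained on the volumes directly.
    * ``e2e``: the composition is trained on the MSE weight loss alone;
      returns ``(weight_model, uncover_model)`` with both updated.

    The output bias is initialized to the mean training weight so the
    optimizer fits residuals around a sensible operating point.
    """
    if mode not in ("plain", "two-stage", "e2e"):
        raise ValueError(f"unknown training mode {mode!r}")
    config = config if config is not None else TrainConfig.regressor()
    y = np.asarray(weights, dtype=np.float64).ravel()
    vols = np.asarray(volumes, dtype=np.float32)
    if len(vols) == 0 or len(vols) != len(y):
        raise ValueError("volumes and weights must be nonempty and aligned")

    if mode == "two-stage":
        if uncover_model is None:
            raise ValueError("two-stage training requires a trained uncover model")
        vols = uncover_model.predict_proba(vols)[:, 0]  # frozen f, soft output
    if mode == "e2e" and uncover_model is None:
        uncover_model = build_unet(vols.shape[1:], base_channels=arch_kwargs.pop("base_channels", 32),
                                   seed=config.seed + 1)

    if model is None:
        model = build_weight_cnn(vols.shape[1:], seed=config.seed, **arch_kwargs)
    if model.mode != "regression":
        raise ValueError("weight training requires a regression-mode model")
    # operating-point initialization of the output neuron
    model.stack.layers[-1].bias.data[:] = np.float32(y.mean())

    x = _as_batch(vols, model.resolution)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    model.set_rng(rng)
    params = model.parameters()
    if mode == "e2e":
        params = params + uncover_model.parameters()
    opt = nn.Adam(params, lr=config.learning_rate)

    model.train()
    if mode == "e2e":
        uncover_model.train()
        uncover_model.set_rng(rng)
    for epoch in range(config.epochs):
        opt.lr = _epoch_lr(config, epoch)
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = x[idx]
            if mode == "e2e":
                logits = uncover_model.forward(xb)
                probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
                xb = probs.astype(np.float32)
            pred = model.forward(xb)[:, 0]
            losses.append(nn.mse_loss(pred, y[idx]))
            grad = (2.0 * (pred - y[idx]) / len(idx)).astype(np.float32)[:, None]
            dx = model.backward(grad)
            if mode == "e2e":
                dlogits = dx * (probs * (1.0 - probs)).astype(np.float32)
                uncover_model.backward(dlogits)
            opt.step()
        model.train_log.append((epoch, float(np.mean(losses)), opt.lr))
    model.eval()
    if mode == "e2e":
        uncover_model.eval()
        return model, uncover_model
    return model


def predict_weight(covered_volume: np.ndarray, uncover_model: UncoverModel,
                   weight_model: WeightModel) -> tuple[float, np.ndarray]:
    """Two-stage inference: y = g(f(X^c)).

    Returns the weight in kg together with the intermediate uncovered
    probability volume (the interpretable by-product of the pipeline).
    """
    if tuple(uncover_model.resolution) != tuple(weight_model.resolution):
        raise ValueError(
            f"grid mismatch: uncover {uncover_model.resolution} vs weight {weight_model.resolution}"
        )
    proba = uncover_model.predict_proba(covered_volume)
    w = weight_model.predict(proba[:, 0])
    vol = proba[0, 0]
    return float(w[0]), vol


def train_cover_classifier(volumes: np.ndarray, covered_labels: np.ndarray,
                           config: TrainConfig | None = None,
                           **arch_kwargs) -> WeightModel:
    """Train the baseline CNN as a binary covered/uncovered classifier.

    ``covered_labels`` is 1 for covered (thin and thick pooled) and 0
    for uncovered; both classes must be present.
    """
    config = config if config is not None else TrainConfig.classifier()
    y = np.asarray(covered_labels, dtype=np.float64).ravel()
    vols = np.asarray(volumes, dtype=np.float32)
    if len(vols) == 0 or len(vols) != len(y):
        raise ValueError("volumes and labels must be nonempty and aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("classifier training requires both classes")

    model = build_weight_cnn(vols.shape[1:], mode="classifier", seed=config.seed, **arch_kwargs)
    x = _as_batch(vols, model.resolution)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    model.set_rng(rng)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    model.train()
    for epoch in range(config.epochs):
        opt.lr = _epoch_lr(config, epoch)
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(x[idx])[:, 0]
            loss, grad = nn.bce_with_logits(logits, y[idx])
            model.backward(grad[:, None].astype(np.float32))
            opt.step()
            losses.append(loss)
        model.train_log.append((epoch, float(np.mean(losses)), opt.lr))
    model.eval()
    return model


def classify_cover(volume: np.ndarray, classifier: WeightModel) -> str:
    """'covered' iff P(covered) > 0.5; exact ties resolve to 'uncovered'."""
    if classifier.mode != "classifier":
        raise ValueError("model was not built in classifier mode")
    p = float(classifier.predict(volume)[0])
    return "covered" if p > 0.5 else "uncovered"


def route_and_predict(volume: np.ndarray, classifier: WeightModel,
                      uncover_model: UncoverModel, two_stage_regressor: WeightModel,
                      plain_regressor: WeightModel) -> tuple[float, str]:
    """Fully automatic pipeline: classify the cover condition, then send
    covered inputs through uncover+regress and uncovered inputs through
    the plain regressor.  Returns (weight kg, detected condition)."""
    label = classify_cover(volume, classifier)
    if label == "covered":
        w, _ = predict_weight(volume, uncover_model, two_stage_regressor)
    else:
        w = float(plain_regressor.predict(volume)[0])
    return w, label


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UncoverModel | WeightModel, path,
                    train_config: TrainConfig | None = None) -> None:
    """Write architecture descriptor + parameters (+ config) to an .npz."""
    meta = {"descriptor": model.descriptor}
    if train_config is not None:
        meta["train_config"] = train_config.to_dict()
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    desc = meta["descriptor"]
    if desc["kind"] == "unet":
        model: UncoverModel | WeightModel = build_unet(
            tuple(desc["resolution"]), levels=desc["levels"], base_channels=desc["base_channels"]
        )
    elif desc["kind"] == "weight_cnn":
        model = build_weight_cnn(
            tuple(desc["resolution"]), tuple(desc["channel_schedule"]),
            desc["head_width"], desc["dropout"], desc["mode"],
        )
    else:
        raise ValueError(f"unknown checkpoint kind {desc['kind']!r}")
    current = model.state_arrays()
    if len(current) != len(arrays):
        raise ValueError("checkpoint does not match the rebuilt architecture")
    for dst, src in zip(current, arrays):
        dst[...] = src
    model.eval()
    return model
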