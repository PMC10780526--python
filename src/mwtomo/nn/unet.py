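"""Encoder-decoder (U-net style) permittivity reconstruction network.

Architecture at defaults: depth 5, two same-padded 5x5 convolutions with
ReLU per level, 2x2 max pooling between encoder levels, channels growing
8 -> 16 -> 32 -> 64 -> 128 (so a 256x256 input reaches a 16x16x128
bottleneck), a decoder mirroring with 2x2-stride-2 transposed convolutions
and skip concatenation, and a final linear 1x1 convolution to one channel.
Trained with Adam (lr 5e-4), MSE loss, batch size 32 on labels affinely
scaled from the permittivity design range [10, 80] to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ..config import ConfigError
from .layers import Adam, Concat, Conv2d, ConvTranspose2, Layer, MaxPool2, ReLU


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class NetworkConfig:
    depth: int = 5
    convs_per_level: int = 2
    kernel_size: int = 5
    encoder_channels: tuple[int, ...] = (8, 16, 32, 64, 128)
    pool_size: int = 2
    upconv_size: int = 2
    upconv_stride: int = 2
    output_channels: int = 1
    skip_connections: bool = True
    input_channels: int = 1

    def __post_init__(self) -> None:
        if len(self.encoder_channels) != self.depth:
            raise ConfigError("encoder_channels length must equal depth")
        if self.pool_size != 2 or self.upconv_size != 2 or self.upconv_stride != 2:
            raise ConfigError("only 2x2 pooling / stride-2 upconvolution supported")

    def encoder_sizes(self, input_size: int) -> list[int]:
        """Spatial side length at each encoder level (256 -> ... -> 16)."""
        if input_size % 2 ** (self.depth - 1) != 0:
            raise ConfigError(
                f"input side {input_size} not divisible by 2^{self.depth - 1}"
            )
        return [input_size // 2**lvl for lvl in range(self.depth)]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 32
    loss: str = "mean_squared_error"
    optimizer: str = "adaptive_moment_estimation"
    n_steps: int = 2000
    seed: int = 0
    # affine map permittivity -> [0, 1]: scaled = (eps - lo) / (hi - lo)
    label_scaling: tuple[float, float] = (10.0, 80.0)

    def scale_labels(self, eps: np.ndarray) -> np.ndarray:
        lo, hi = self.label_scaling
        return (np.asarray(eps, dtype=float) - lo) / (hi - lo)

    def unscale(self, y: np.ndarray) -> np.ndarray:
        lo, hi = self.label_scaling
        return np.asarray(y, dtype=float) * (hi - lo) + lo


class UNet:
    """The reconstruction network with explicit forward/backward passes."""

    def __init__(
        self, cfg: NetworkConfig | None = None, seed: int = 0, dtype=np.float32
    ) -> None:
        self.cfg = cfg or NetworkConfig()
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = self.cfg
        ch = c.encoder_channels
        k = c.kernel_size

        def block(c_in: int, c_out: int) -> list[Layer]:
            layers: list[Layer] = []
            for i in range(c.convs_per_level):
                layers.append(Conv2d(c_in if i == 0 else c_out, c_out, k, rng, dtype))
                layers.append(ReLU())
            return layers

        self.enc_blocks = [block(c.input_channels if l == 0 else ch[l - 1], ch[l])
                           for l in range(c.depth)]
        self.pools = [MaxPool2() for _ in range(c.depth - 1)]
        self.upconvs = [ConvTranspose2(ch[l + 1], ch[l], rng, dtype)
                        for l in reversed(range(c.depth - 1))]
        self.up_relus = [ReLU() for _ in range(c.depth - 1)]
        self.concats = [Concat() for _ in range(c.depth - 1)]
        dec_in = [(2 * ch[l] if c.skip_connections else ch[l]) for l in reversed(range(c.depth - 1))]
        self.dec_blocks = [block(cin, ch[l])
                           for cin, l in zip(dec_in, reversed(range(c.depth - 1)))]
        self.head = Conv2d(ch[0], c.output_channels, 1, rng, dtype)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in self.enc_blocks:
            out.extend(blk)
        out.extend(self.pools)
        for up, relu, cat, blk in zip(
            self.upconvs, self.up_relus, self.concats, self.dec_blocks
        ):
            out.append(up)
            out.append(relu)
            out.append(cat)
            out.extend(blk)
        out.append(self.head)
        return out

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads]

    # -- passes -------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, H, W) or (N, H, W) -> (N, 1, H, W)."""
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != x.shape[3]:
            raise ConfigError("inputs must be square")
        self.cfg.encoder_sizes(x.shape[2])  # divisibility check
        x = np.ascontiguousarray(x, dtype=self.dtype)

        skips = []
        for lvl, blk in enumerate(self.enc_blocks):
            for layer in blk:
                x = layer.forward(x)
            if lvl < self.cfg.depth - 1:
                skips.append(x)
                x = self.pools[lvl].forward(x)
        self.bottleneck_shape = x.shape[1:]

        for i, (up, relu, cat, blk) in enumerate(
            zip(self.upconvs, self.up_relus, self.concats, self.dec_blocks)
        ):
            x = relu.forward(up.forward(x))
            if self.cfg.skip_connections:
                x = cat.forward(x, skips[-(i + 1)])
            for layer in blk:
                x = layer.forward(x)
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.head.backward(dy)
        dskips: list[np.ndarray | None] = [None] * (self.cfg.depth - 1)
        for i in reversed(range(len(self.dec_blocks))):
            for layer in reversed(self.dec_blocks[i]):
                dx = layer.backward(dx)
            if self.cfg.skip_connections:
                dx, dskip = self.concats[i].backward(dx)
                dskips[-(i + 1)] = dskip
            dx = self.upconvs[i].backward(self.up_relus[i].backward(dx))
        for lvl in reversed(range(self.cfg.depth)):
            if lvl < self.cfg.depth - 1:
                dx = self.pools[lvl].backward(dx)
                if self.cfg.skip_connections:
                    dx = dx + dskips[lvl]
            for layer in reversed(self.enc_blocks[lvl]):
                dx = layer.backward(dx)
        return dx


def train(
    net: UNet,
    inputs: np.ndarray,
    labels_eps: np.ndarray,
    cfg: TrainConfig | None = None,
) -> list[float]:
    """Minimize MSE between network output and [0,1]-scaled labels.

    ``inputs``: (N, H, W) normalized input maps; ``labels_eps``: (N, H, W)
    permittivity labels in native units. Returns the per-step loss history.
    Seeded and deterministic on one platform.
    """
    cfg = cfg or TrainConfig()
    n = len(inputs)
    if n == 0:
        raise ConfigError("empty training dataset")
    x_all = np.ascontiguousarray(inputs, dtype=net.dtype)[:, None]
    y_all = np.ascontiguousarray(cfg.scale_labels(labels_eps), dtype=net.dtype)[:, None]

    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    order = np.array([], dtype=int)
    for step_i in range(cfg.n_steps):
        if len(order) < cfg.batch_size:
            order = np.concatenate([order, rng.permutation(n)])
        batch, order = order[: cfg.batch_size], order[cfg.batch_size :]
        xb, yb = x_all[batch], y_all[batch]
        out = net.forward(xb)
        diff = out - yb
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at step {step_i}")
        history.append(loss)
        net.backward((2.0 / diff.size) * diff.astype(net.dtype))
        opt.step(net.gradients())
    return history


def predict(net: UNet, input_map: np.ndarray, cfg: TrainConfig | None = None) -> np.ndarray:
    """Forward pass + inverse label scaling back to permittivity units.

    Accepts one (H, W) map or a batch (N, H, W); returns the same leading
    shape with a permittivity image per case.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(input_map)
    single = x.ndim == 2
    if single:
        x = x[None]
    out = net.forward(x)[:, 0]
    out = cfg.unscale(out)
    if not np.isfinite(out).all():
        raise DivergenceError("non-finite prediction")
    return out[0] if single else out


def save_loss_history(history: list[float], path) -> None:
    """Training loss as CSV (step, loss)."""
    with open(path, "w") as fh:
        fh.write("step,loss\n")
        for i, loss in enumerate(history):
            fh.write(f"{i},{loss:.8g}\n")


def save_checkpoint(net: UNet, path) -> None:
    """Parameters + serialized NetworkConfig in one ``.npz`` file."""
    arrays = {f"p{i}": p for i, p in enumerate(net.parameters())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(net.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path, dtype=np.float32) -> UNet:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        cfg_dict["encoder_channels"] = tuple(cfg_dict["encoder_channels"])
        net = UNet(NetworkConfig(**cfg_dict), seed=0, dtype=dtype)
        for p, key in zip(net.parameters(), (f"p{i}" for i in range(10**6))):
            p[...] = data[key].astype(dtype)
    return net
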