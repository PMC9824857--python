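"""The Hyper3DNetReg 3D-2D convolutional regression network.

The network maps a normalized 5 x 5 x n covariate data cube to an N x N
patch of predicted yield (N in {5, 3, 1}). It has two modules:

* a **3-D feature extractor** — four Conv3D(32, 3x3x3, padding 1) + ReLU +
  BN blocks with dense skip connections that concatenate the outputs of the
  two preceding layers along the channel axis (widths 32 -> 64 -> 32 -> 96
  -> 32 -> 128), so spectral-spatial interactions between covariates are
  captured without any downsampling;
* a **2-D encoder** — the extractor output reshaped to (5, 5, 128*n)
  followed by five SepConv2D + ReLU + BN blocks (512, 320, 256, 128, 32
  channels, 3x3 kernels, stride 1, padding 1) with Dropout(0.5) before the
  first and after the second and third blocks.

The head depends on the output size: N = 5 uses Conv2D(1, 3x3, padding 1) +
ReLU; N = 3 the same without padding; N = 1 applies the unpadded Conv2D +
ReLU, flattens the 3 x 3 result and maps it to a scalar with a bias-free
fully connected layer (9 parameters). Every tensor between the input and
the head keeps the 5 x 5 spatial footprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .raster_core import NormalizationParams

__all__ = [
    "ModelConfig",
    "Hyper3DNetReg",
    "build_model",
    "count_parameters",
    "forward",
    "fc_alternative_param_count",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    W is the input window size, n the number of covariate channels and N the
    output window size. ``conv3d_filters`` and ``sep_channels`` reproduce
    the published layer widths by default.
    """

    W: int = 5
    n: int = 8
    N: int = 5
    conv3d_filters: int = 32
    sep_channels: tuple[int, ...] = (512, 320, 256, 128, 32)
    dropout_p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.N not in (5, 3, 1):
            raise ValueError(f"output size N must be 5, 3 or 1, got {self.N}")
        if self.W != 5:
            raise ValueError("the published architecture uses W = 5")
        if self.conv3d_filters < 1 or any(c < 1 for c in self.sep_channels):
            raise ValueError("channel counts must be positive")


class Hyper3DNetReg:
    """Model state: layer graph, trainable weights and training mode."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.conv3d_filters
        n = config.n

        self.conv3d_blocks = []
        in_ch = 1
        for i in range(4):
            conv = _nn.Conv3D(f"conv3d_{i + 1}", in_ch, f, rng=rng)
            block = (conv, _nn.ReLU(f"relu3d_{i + 1}"),
                     _nn.BatchNorm(f"bn3d_{i + 1}", f))
            self.conv3d_blocks.append(block)
            # input widths along the dense chain: 1, 32, 64, 96 (concat adds f)
            in_ch = f * (i + 1)

        self.dropout_in = _nn.Dropout("dropout_in", config.dropout_p, rng)
        self.sep_blocks = []
        self.dropouts = {}
        in2d = 4 * f * n                       # reshaped extractor output
        for i, out_ch in enumerate(config.sep_channels):
            block = (_nn.SepConv2D(f"sep2d_{i + 1}", in2d, out_ch, rng=rng),
                     _nn.ReLU(f"relu2d_{i + 1}"),
                     _nn.BatchNorm(f"bn2d_{i + 1}", out_ch))
            self.sep_blocks.append(block)
            if i in (1, 2):                    # Dropout after blocks 2 and 3
                self.dropouts[i] = _nn.Dropout(f"dropout_{i + 1}",
                                               config.dropout_p, rng)
            in2d = out_ch

        last = config.sep_channels[-1]
        if config.N == 5:
            self.head_conv = _nn.Conv2D("head_conv2d", last, 1, pad=1, rng=rng)
            self.head_fc = None
        else:                                  # N = 3 and N = 1 share pad 0
            self.head_conv = _nn.Conv2D("head_conv2d", last, 1, pad=0, rng=rng)
            self.head_fc = _nn.Dense("head_fc", 9, 1, bias=False, rng=rng) \
                if config.N == 1 else None
        self.head_relu = _nn.ReLU("head_relu")
        self.training_mode = False

    # -- bookkeeping --------------------------------------------------------

    def layers(self) -> list[_nn.Layer]:
        out = []
        for block in self.conv3d_blocks:
            out.extend(block)
        out.append(self.dropout_in)
        for i, block in enumerate(self.sep_blocks):
            out.extend(block)
            if i in self.dropouts:
                out.append(self.dropouts[i])
        out.append(self.head_conv)
        out.append(self.head_relu)
        if self.head_fc is not None:
            out.append(self.head_fc)
        return out

    # -- forward / backward -------------------------------------------------

    def forward(self, batch: np.ndarray, train: bool | None = None) -> np.ndarray:
        """Run the network on a batch of normalized covariate patches.

        ``batch`` is (B, W, W, n) (a squeezed trailing singleton axis from
        the (B, W, W, n, 1) data-cube convention is accepted). Returns
        (B, N, N) predictions, or (B,) scalars for N = 1; outputs are
        nonnegative because of the final ReLU. Evaluation-mode passes are
        deterministic: dropout is inactive and batch normalization uses its
        running statistics.
        """
        cfg = self.config
        train = self.training_mode if train is None else train
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 5 and batch.shape[-1] == 1:
            batch = batch[..., 0]
        if batch.ndim != 4 or batch.shape[1:] != (cfg.W, cfg.W, cfg.n):
            raise ValueError(
                f"expected batch shaped (B, {cfg.W}, {cfg.W}, {cfg.n}), "
                f"got {batch.shape}")
        B = batch.shape[0]
        # (B, W, W, n) -> (B, D=n, H, W, C=1)
        x = np.moveaxis(batch, 3, 1)[..., None]

        self._tape = []
        feats = None
        for i, block in enumerate(self.conv3d_blocks):
            h = x if i == 0 else feats
            for ly in block:
                h = ly.forward(h, train)
            if i == 0:
                feats = h
            else:
                self._tape.append(("concat", h.shape[-1]))
                feats = np.concatenate([h, feats], axis=-1)

        # (B, n, 5, 5, 128) -> (B, 5, 5, 128*n)
        shape3d = feats.shape
        h = np.moveaxis(feats, 1, -1).reshape(
            B, cfg.W, cfg.W, shape3d[-1] * shape3d[1])
        h = self.dropout_in.forward(h, train)
        for i, block in enumerate(self.sep_blocks):
            for ly in block:
                h = ly.forward(h, train)
            if i in self.dropouts:
                h = self.dropouts[i].forward(h, train)
        h = self.head_conv.forward(h, train)
        h = self.head_relu.forward(h, train)
        if cfg.N == 1:
            h = self.head_fc.forward(h.reshape(B, 9), train)
            out = h[:, 0]
        else:
            out = h[..., 0]
        self._shape3d = shape3d
        return out.astype(np.float64)

    def backward(self, dout: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output); fills every layer's ``grads``."""
        cfg = self.config
        B = dout.shape[0]
        if cfg.N == 1:
            d = self.head_fc.backward(dout[:, None].astype(np.float32))
            d = d.reshape(B, 3, 3, 1)
        else:
            d = dout[..., None].astype(np.float32)
        d = self.head_relu.backward(d)
        d = self.head_conv.backward(d)
        for i in range(len(self.sep_blocks) - 1, -1, -1):
            if i in self.dropouts:
                d = self.dropouts[i].backward(d)
            for ly in reversed(self.sep_blocks[i]):
                d = ly.backward(d)
        d = self.dropout_in.backward(d)
        # (B, 5, 5, 128*n) -> (B, n, 5, 5, 128)
        s3 = self._shape3d
        d = np.moveaxis(d.reshape(B, cfg.W, cfg.W, s3[-1], s3[1]), -1, 1)
        d = np.ascontiguousarray(d)

        # reverse the dense-concatenation chain
        for i in range(len(self.conv3d_blocks) - 1, 0, -1):
            _, width = self._tape[i - 1]
            d_new, d = d[..., :width], d[..., width:]
            for ly in reversed(self.conv3d_blocks[i]):
                d_new = ly.backward(d_new)
            d = d + d_new
        for ly in reversed(self.conv3d_blocks[0]):
            d = ly.backward(d)


def build_model(cfg: ModelConfig) -> Hyper3DNetReg:
    """Construct the network with seeded Glorot-uniform initialization."""
    return Hyper3DNetReg(cfg)


def forward(model: Hyper3DNetReg, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward pass (deterministic)."""
    return model.forward(batch, train=False)


def count_parameters(model: Hyper3DNetReg, scope: str = "all") -> int:
    """Exact trainable-parameter count.

    ``scope`` selects layers by exact name or name prefix ("all" counts the
    whole model); e.g. ``count_parameters(m, "head_conv2d")`` gives the 289
    parameters of the N = 5 output head (3*3*32 weights + 1 bias) and
    ``count_parameters(m, "head_fc")`` the 9 bias-free weights of the N = 1
    head.
    """
    layers = model.layers()
    if scope == "all":
        selected = layers
    else:
        selected = [ly for ly in layers if ly.name == scope or
                    ly.name.startswith(scope)]
        if not selected:
            raise ValueError(f"unknown scope '{scope}'")
    return sum(ly.param_count() for ly in selected)


def fc_alternative_param_count(spatial: int = 5, channels: int = 32,
                               outputs: int = 25, bias: bool = True) -> int:
    """Parameter count of the fully connected head the Conv2D head replaces.

    Flattening the final (spatial, spatial, channels) encoder tensor into an
    FC layer with ``outputs`` units would cost
    ``spatial**2 * channels * outputs (+ outputs biases)`` parameters —
    20,025 for the 5 x 5 x 32 encoder output and 25 outputs, versus 289 for
    the convolutional head.
    """
    return spatial * spatial * channels * outputs + (outputs if bias else 0)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: Hyper3DNetReg, path: str | Path,
                    norm: NormalizationParams | None = None) -> Path:
    """Serialize weights, running statistics, ModelConfig and (optionally)
    the normalization parameters to a single .npz checkpoint."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for ly in model.layers():
        for k, v in ly.params.items():
            arrays[f"param/{ly.name}/{k}"] = v
        if isinstance(ly, _nn.BatchNorm):
            arrays[f"stat/{ly.name}/mean"] = ly.running_mean
            arrays[f"stat/{ly.name}/var"] = ly.running_var
    cfg = model.config
    meta = {"version": CHECKPOINT_VERSION, "W": cfg.W, "n": cfg.n, "N": cfg.N,
            "conv3d_filters": cfg.conv3d_filters,
            "sep_channels": list(cfg.sep_channels),
            "dropout_p": cfg.dropout_p, "seed": cfg.seed}
    arrays["meta"] = np.bytes_(json.dumps(meta).encode())
    if norm is not None:
        arrays["norm/mins"] = norm.mins
        arrays["norm/maxs"] = norm.maxs
        arrays["norm/fitted_on"] = np.bytes_(norm.fitted_on.encode())
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path,
                    ) -> tuple[Hyper3DNetReg, NormalizationParams | None]:
    """Rebuild a model (and normalization parameters, if stored) from a
    checkpoint written by :func:`save_checkpoint`."""
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = ModelConfig(W=meta["W"], n=meta["n"], N=meta["N"],
                          conv3d_filters=meta["conv3d_filters"],
                          sep_channels=tuple(meta["sep_channels"]),
                          dropout_p=meta["dropout_p"], seed=meta["seed"])
        model = Hyper3DNetReg(cfg)
        for ly in model.layers():
            for k in ly.params:
                ly.params[k] = z[f"param/{ly.name}/{k}"].copy()
            if isinstance(ly, _nn.BatchNorm):
                ly.running_mean = z[f"stat/{ly.name}/mean"].copy()
                ly.running_var = z[f"stat/{ly.name}/var"].copy()
        norm = None
        if "norm/mins" in z:
            norm = NormalizationParams(
                z["norm/mins"], z["norm/maxs"],
                fitted_on=bytes(z["norm/fitted_on"]).decode())
    return model, norm
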