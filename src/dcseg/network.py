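"""Encoder--decoder segmentation backbone with deep supervision.

The network is a light U-Net: four encoder blocks, each a 3x3
convolution + ReLU followed by 2x2 max-pooling, a bottleneck block, and
four decoder stages that bilinearly upsample, concatenate the skip
features and convolve back down.  Deep supervision attaches a prediction
head (dropout -> 1x1 convolution -> upsample -> softmax) to each of the
``head_levels`` deepest decoder stages, producing the coarse-to-fine
probability maps [p_1 ... p_S]; p_1 comes from the deepest (coarsest)
stage.  A multi-scale convolution (MSC) module fuses shallow and deep
decoder features through parallel pooling at several window sizes and
emits the fine-grained map p_0.

All probability maps are returned at full input resolution with a
channel-wise softmax applied, so every map is a valid per-pixel
categorical distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["NetworkConfig", "FeaturePyramid", "MultiLevelPrediction",
           "SegNet", "msc_forward"]


@dataclass
class NetworkConfig:
    in_channels: int = 3
    n_classes: int = 2
    base_width: int = 16
    encoder_depth: int = 4
    dropout_rate: float = 0.3
    head_levels: int = 4          # S: number of deeply supervised heads
    msc_kernels: tuple = (1, 2, 3, 5)
    msc_pool: str = "avg"         # "avg" or "max"
    upsample_mode: str = "bilinear"
    use_msc: bool = True          # when False the fine head p_0 is absent

    def __post_init__(self):
        if self.head_levels > self.encoder_depth:
            raise ValueError("head_levels cannot exceed encoder_depth")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not self.msc_kernels or any(k < 1 for k in self.msc_kernels):
            raise ValueError("msc_kernels must be nonempty, each >= 1")
        self.msc_kernels = tuple(int(k) for k in self.msc_kernels)


@dataclass
class FeaturePyramid:
    """Decoder features ordered shallow -> deep (spatial size halves per stage)."""
    decoder_features: list


@dataclass
class MultiLevelPrediction:
    """Probability maps [p_0, p_1, ..., p_S], all at full input resolution.

    ``maps[0]`` is the MSC-fused fine map p_0 (or ``None`` without MSC);
    ``maps[1]`` is the coarsest deeply supervised head p_1.
    """
    maps: list

    @property
    def p0(self):
        return self.maps[0]

    def heads(self):
        """The deeply supervised maps p_1..p_S (excludes p_0)."""
        return self.maps[1:]

    def all_valid(self):
        return [m for m in self.maps if m is not None]


def _he_conv(rng, cout, cin, k):
    std = np.sqrt(2.0 / (cin * k * k))
    return Tensor(rng.normal(0.0, std, (cout, cin, k, k)).astype(np.float32),
                  requires_grad=True)


def msc_forward(x: Tensor, weights: dict, prefix: str, kernels,
                pool: str = "avg", mode: str = "bilinear") -> Tensor:
    """Multi-scale convolution: parallel pooling branches, re-upsampled,
    concatenated, then fused by a 3x3 convolution.

    Window-1 pooling is the identity, so ``kernels=(1,)`` reduces the module
    to a plain 3x3 convolution of the input.
    """
    n, c, h, w = x.data.shape
    if min(h, w) < max(kernels):
        raise ValueError(
            f"spatial size {h}x{w} smaller than largest pooling window "
            f"{max(kernels)}")
    pool_fn = nn.avg_pool2d if pool == "avg" else nn.max_pool2d
    branches = [nn.resize2d(pool_fn(x, k), h, w, mode=mode) for k in kernels]
    cat = nn.concat(branches, axis=1)
    return nn.relu(nn.conv2d(cat, weights[prefix + ".fuse.w"],
                             weights[prefix + ".fuse.b"], padding=1))


class SegNet:
    """U-Net with multi-level prediction heads and an optional MSC fine head."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])
        self._build(np.random.default_rng(seed))

    # -- construction ---------------------------------------------------
    def _build(self, rng):
        cfg = self.config
        w = cfg.base_width
        depth = cfg.encoder_depth
        enc_ch = [w * (2 ** i) for i in range(depth)]          # e.g. 16,32,64,128
        self._enc_ch = enc_ch
        cin = cfg.in_channels
        for i, cout in enumerate(enc_ch):
            self._add_conv(rng, f"enc{i}", cout, cin, 3)
            cin = cout
        bott = enc_ch[-1]
        self._add_conv(rng, "bott", bott, bott, 3)
        # decoder stages deep -> shallow; dec_ch[j] is the output width of
        # the stage whose skip is enc stage (depth-1-j)
        dec_ch = []
        prev = bott
        for j in range(depth):
            skip = enc_ch[depth - 1 - j]
            cout = max(enc_ch[depth - 1 - j] // 2, w)
            self._add_conv(rng, f"dec{j}", cout, prev + skip, 3)
            dec_ch.append(cout)
            prev = cout
        self._dec_ch = dec_ch
        for s in range(1, cfg.head_levels + 1):      # p_s head on stage s-1 (deep first)
            self._add_conv(rng, f"head{s}", cfg.n_classes, dec_ch[s - 1], 1)
        if cfg.use_msc:
            fuse_in = dec_ch[-1] + dec_ch[-2] + dec_ch[-3]
            self._add_conv(rng, "msc.reduce", w, fuse_in, 1)
            self._add_conv(rng, "msc.fuse", w, w * len(cfg.msc_kernels), 3)
            self._add_conv(rng, "fine", cfg.n_classes, w, 1)

    def _add_conv(self, rng, name, cout, cin, k):
        self.params[name + ".w"] = _he_conv(rng, cout, cin, k)
        self.params[name + ".b"] = Tensor(np.zeros(cout, dtype=np.float32),
                                          requires_grad=True)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward --------------------------------------------------------
    def _conv(self, name, x, padding):
        return nn.conv2d(x, self.params[name + ".w"], self.params[name + ".b"],
                         padding=padding)

    def forward(self, image, train_mode: bool = False
                ) -> tuple[MultiLevelPrediction, FeaturePyramid]:
        """Run the network on an (N,3,H,W) or (3,H,W) or (H,W,3) image array."""
        cfg = self.config
        x = image.data if isinstance(image, Tensor) else np.asarray(image, np.float32)
        if x.ndim == 3 and x.shape[-1] == cfg.in_channels:
            x = x.transpose(2, 0, 1)
        if x.ndim == 3:
            x = x[None]
        n, c, h, w = x.shape
        div = 2 ** cfg.encoder_depth
        if h % div or w % div:
            raise ValueError(
                f"input height and width must be divisible by {div} "
                f"(got {h}x{w})")
        x = Tensor(x)
        mode = cfg.upsample_mode
        skips = []
        for i in range(cfg.encoder_depth):
            x = nn.relu(self._conv(f"enc{i}", x, 1))
            skips.append(x)
            x = nn.max_pool2d(x, 2)
        x = nn.relu(self._conv("bott", x, 1))
        dec = []
        for j in range(cfg.encoder_depth):
            skip = skips[cfg.encoder_depth - 1 - j]
            x = nn.resize2d(x, skip.shape[2], skip.shape[3], mode=mode)
            x = nn.relu(self._conv(f"dec{j}", nn.concat([x, skip], axis=1), 1))
            dec.append(x)                                  # deep -> shallow
        heads = []
        for s in range(1, cfg.head_levels + 1):
            f = nn.dropout(dec[s - 1], cfg.dropout_rate, self._dropout_rng,
                           train_mode)
            logits = self._conv(f"head{s}", f, 0)
            heads.append(nn.softmax(nn.resize2d(logits, h, w, mode=mode), axis=1))
        p0 = None
        if cfg.use_msc:
            shallow = dec[-1]
            fused = nn.concat(
                [shallow,
                 nn.resize2d(dec[-2], h, w, mode=mode),
                 nn.resize2d(dec[-3], h, w, mode=mode)], axis=1)
            fused = nn.relu(self._conv("msc.reduce", fused, 0))
            msc = msc_forward(fused, self.params, "msc", cfg.msc_kernels,
                              pool=cfg.msc_pool, mode=mode)
            p0 = nn.softmax(self._conv("fine", msc, 0), axis=1)
        pyramid = FeaturePyramid(decoder_features=list(reversed(dec)))
        return MultiLevelPrediction(maps=[p0] + heads), pyramid

    def predict(self, image) -> np.ndarray:
        """Label map from the finest available head (p_0, else p_S)."""
        preds, _ = self.forward(image, train_mode=False)
        m = preds.p0 if preds.p0 is not None else preds.maps[-1]
        return m.data.argmax(axis=1).squeeze()

    def predict_proba(self, image) -> np.ndarray:
        preds, _ = self.forward(image, train_mode=False)
        m = preds.p0 if preds.p0 is not None else preds.maps[-1]
        return m.data

    # -- checkpointing --------------------------------------------------
    def save(self, path):
        arrays = {k: p.data for k, p in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SegNet":
        with np.load(path) as z:
            cfg = json.loads(bytes(z["__config__"]).decode())
            cfg["msc_kernels"] = tuple(cfg["msc_kernels"])
            net = cls(NetworkConfig(**cfg))
            for k in net.params:
                net.params[k].data = z[k].astype(np.float32)
        return net
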