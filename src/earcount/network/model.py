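"""The hybrid local/global density-estimation network.

Architecture
------------
* A four-stage cross-stage-partial (CSP) convolutional backbone.  Each stage
  enters with a stride-2 CBS convolution, so a H x W input yields a feature
  pyramid at strides 2/4/8/16 with channel widths 64/256/512/512 by default.
* A pyramid-pooling transformer (P2T) encoder on the coarsest (stride-16)
  grid: 1x1 patch embedding, then multi-head self-attention whose keys and
  values are pyramid-pooled token sets, preserving the grid resolution while
  adding global context.
* Top-down attentional feature fusion (AFF): the transformer output is fused
  with the stride-8 features, the result is reduced/upsampled and fused with
  stride-4, then stride-2.
* A decoder of parallel dilated 3x3 convolutions whose concatenation is
  projected to two channels: a non-negative density map (whose integral is
  the predicted ear count) and a sigmoid attention probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (AFF, CBS, Conv2d, CSPStage, Module, P2TEncoder)


@dataclass
class ModelConfig:
    """All architecture knobs; defaults give the full-size network."""

    stage_channels: tuple = (64, 256, 512, 512)
    csp_blocks_per_stage: tuple = (1, 2, 2, 1)
    p2t_depth: int = 2
    p2t_heads: int = 8
    p2t_pool_bins: tuple = (1, 2, 3, 6)
    p2t_ffn_expansion: int = 4
    decoder_dilations: tuple = (1, 2, 3)
    output_stride: int = 1
    attention_gating: bool = False
    density_activation: str = "abs"  # or "relu"

    def __post_init__(self):
        self.stage_channels = tuple(self.stage_channels)
        self.csp_blocks_per_stage = tuple(self.csp_blocks_per_stage)
        self.p2t_pool_bins = tuple(self.p2t_pool_bins)
        self.decoder_dilations = tuple(self.decoder_dilations)
        if len(self.stage_channels) != 4 or len(self.csp_blocks_per_stage) != 4:
            raise ValueError("the backbone has exactly four stages")
        if self.output_stride not in (1, 2, 4, 8):
            raise ValueError("output_stride must be one of 1, 2, 4, 8")
        if any(d < 1 for d in self.decoder_dilations):
            raise ValueError("decoder dilations must be >= 1")
        if self.stage_channels[3] % self.p2t_heads:
            raise ValueError("stage-4 channels must be divisible by p2t_heads")
        if self.density_activation not in ("abs", "relu"):
            raise ValueError("density_activation must be 'abs' or 'relu'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def tiny_config(**overrides) -> ModelConfig:
    """A reduced desk-scale configuration (used by the smoke training runs)."""
    base = dict(stage_channels=(16, 32, 64, 64), csp_blocks_per_stage=(1, 1, 1, 1),
                p2t_depth=1, p2t_heads=4, p2t_ffn_expansion=2)
    base.update(overrides)
    return ModelConfig(**base)


@dataclass
class PredictionPair:
    """The network's two outputs for a batch: density and attention maps."""

    density: Tensor     # (N, 1, H', W'), >= 0
    attention: Tensor   # (N, 1, H', W'), strictly in (0, 1)

    def counts(self) -> np.ndarray:
        """Predicted count per image = integral of the density map."""
        return self.density.data.sum(axis=(1, 2, 3))


class Decoder(Module):
    """Parallel dilated branches -> fuse -> two-channel head."""

    def __init__(self, c, dilations, gating, density_activation, rng=None):
        super().__init__()
        self.gating = gating
        self.density_activation = density_activation
        self.branches = [CBS(c, c, 3, dilation=d, rng=rng) for d in dilations]
        self.fuse = CBS(c * len(dilations), c, 1, rng=rng)
        self.att_head = Conv2d(c, 1, 1, rng=rng)
        self.den_head = Conv2d(c, 1, 1, rng=rng)
        # density values are tiny (a Gaussian bump integrates to 1), so the
        # head starts near zero instead of at the He-init output scale
        self.den_head.weight.data *= 0.01
        self.att_head.weight.data *= 0.1

    def forward(self, x):
        feats = self.fuse(ag.concat([b(x) for b in self.branches], axis=1))
        att_logit = self.att_head(feats)
        att = ag.sigmoid(att_logit)
        if self.gating:
            feats = feats * att
        den_raw = self.den_head(feats)
        if self.density_activation == "abs":
            den = ag.absolute(den_raw)
        else:
            den = ag.relu(den_raw)
        return den, att


class EarDensityNet(Module):
    """Hybrid CSP + pyramid-pooling-transformer counting network."""

    def __init__(self, config: ModelConfig | None = None,
                 rng: np.random.Generator | int | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        c1, c2, c3, c4 = self.config.stage_channels
        n1, n2, n3, n4 = self.config.csp_blocks_per_stage
        self.stage1 = CSPStage(3, c1, n1, rng=rng)
        self.stage2 = CSPStage(c1, c2, n2, rng=rng)
        self.stage3 = CSPStage(c2, c3, n3, rng=rng)
        self.stage4 = CSPStage(c3, c4, n4, rng=rng)
        self.p2t = P2TEncoder(c4, depth=self.config.p2t_depth,
                              heads=self.config.p2t_heads,
                              pool_bins=self.config.p2t_pool_bins,
                              ffn_expansion=self.config.p2t_ffn_expansion, rng=rng)
        self.fuse3 = AFF(c3, rng=rng)
        self.reduce32 = CBS(c3, c2, 1, rng=rng)
        self.fuse2 = AFF(c2, rng=rng)
        self.reduce21 = CBS(c2, c1, 1, rng=rng)
        self.fuse1 = AFF(c1, rng=rng)
        self.align43 = (CBS(c4, c3, 1, rng=rng) if c4 != c3 else None)
        self.decoder = Decoder(c1, self.config.decoder_dilations,
                               self.config.attention_gating,
                               self.config.density_activation, rng=rng)

    # -- pieces --------------------------------------------------------------
    def extract_pyramid(self, x) -> list[Tensor]:
        """Backbone features at strides 2, 4, 8, 16."""
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        return [f1, f2, f3, f4]

    @staticmethod
    def _validate(x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N,3,H,W) input, got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            ph, pw = (-h) % 16, (-w) % 16
            raise ValueError(
                f"input sides must be divisible by 16, got {h}x{w}; "
                f"pad by {ph} rows and {pw} columns")
        return x

    def forward(self, x) -> PredictionPair:
        x = self._validate(x)
        f1, f2, f3, f4 = self.extract_pyramid(x)
        g = self.p2t(f4)
        if self.align43 is not None:
            g = self.align43(g)
        d3 = self.fuse3(ag.upsample_nearest(g, 2), f3)
        d2 = self.fuse2(ag.upsample_nearest(self.reduce32(d3), 2), f2)
        d1 = self.fuse1(ag.upsample_nearest(self.reduce21(d2), 2), f1)
        den, att = self.decoder(d1)
        os = self.config.output_stride
        if os == 1:
            den = ag.upsample_nearest(den, 2)
            att = ag.upsample_nearest(att, 2)
        elif os > 2:
            f = os // 2
            n, _, h, w = den.shape
            den = ag.adaptive_avg_pool2d(den, (h // f, w // f))
            att = ag.adaptive_avg_pool2d(att, (h // f, w // f))
        return PredictionPair(density=den, attention=att)

    def predict_density(self, image: np.ndarray) -> np.ndarray:
        """Inference on a single (H,W,3) float image in [0,1].

        Pads reflectively to a multiple of 16, runs the network in eval mode
        without recording gradients, and crops back to the image size.
        """
        was_training = self.training
        self.eval()
        try:
            h, w = image.shape[:2]
            ph, pw = (-h) % 16, (-w) % 16
            img = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect") \
                if (ph or pw) else image
            x = normalize_image(img).transpose(2, 0, 1)[None]
            with ag.no_grad():
                pair = self.forward(x)
            den = pair.density.data[0, 0]
            os = self.config.output_stride
            return den[:h // os + (1 if h % os else 0), :w // os + (1 if w % os else 0)] \
                if os > 1 else den[:h, :w]
        finally:
            self.train(was_training)

    def predict_count(self, image: np.ndarray) -> float:
        return float(self.predict_density(image).sum())


# -- image normalisation shared by training and inference --------------------
_IMG_MEAN = 0.5
_IMG_STD = 0.25


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Map a float [0,1] RGB image to the network's input scale."""
    return ((image - _IMG_MEAN) / _IMG_STD).astype(np.float32)
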