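"""W-shaped dual-decoder network with lesion-prior cross-attention (LPCA).

One encoder, two heads: a segmentation decoder that reconstructs a lesion
probability map at input resolution, and a classification branch that grades
severity into five classes.  Skip connections pass through LPCA modules that
fuse encoder features F with the classical lesion-prior stack P:

    gate  g   = sigma(W_a [F || P])              (1x1 convolution)
    Q = W_q F,  K = W_k P,  V = W_v F            (projections)
    Phi = g * softmax(Q K^T / sqrt(d)) V + (1 - g) * F

Attention over flattened spatial positions is memory-bounded by average
pooling both streams to a grid of at most ``attention_grid_max`` per side and
nearest-upsampling the attended output back to the skip resolution.  The
gate is always computed at full skip resolution.

Spatial bookkeeping: the working size 644 is not repeatedly halvable, so
pooling uses ceil mode (644 -> 322 -> 161 -> 81 -> 41) and each decoder stage
doubles the size and center-crops/pads to match its skip.  Channel widths
default to 128/256/512 with a 1024-channel context stage.

Ablation variants: ``baseline_unet`` (plain skips, no pixel attention),
``no_lpca`` (plain skips, pixel attention kept), ``lpca_spatial_only``
(gate-only re-weighting, Phi = F + g * F), and ``full``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .priors import resize_prior_stack

VARIANTS = ("baseline_unet", "no_lpca", "lpca_spatial_only", "full")

__all__ = ["WNetConfig", "WNetOutput", "LPCA", "WNet", "count_parameters", "pixel_attention"]


@dataclass
class WNetConfig:
    input_size: int = 644
    input_channels: int = 3
    encoder_channels: tuple = (128, 256, 512)
    context_channels: int = 1024
    conv_kernel: int = 3
    pool: int = 2
    num_classes: int = 5
    dropout: float = 0.75
    fc_width: int = 256
    prior_channels: int = 4
    variant: str = "full"
    attention_mode: str = "spatial"   # "spatial" (QK^T) or "pooled" (GAP descriptor)
    attention_grid_max: int = 48
    use_recon: bool = True
    leaky_relu: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.num_classes != 5:
            raise ValueError("the grading head is five-class (ICDR 0-4)")
        if list(self.encoder_channels) != sorted(self.encoder_channels) or len(
            set(self.encoder_channels)
        ) != len(self.encoder_channels):
            raise ValueError("encoder_channels must be strictly increasing")

    def tiny(self, input_size: int = 128) -> "WNetConfig":
        """A reduced-width preset for CPU-scale experiments and tests."""
        return WNetConfig(
            input_size=input_size,
            input_channels=self.input_channels,
            encoder_channels=(8, 16, 32),
            context_channels=64,
            num_classes=self.num_classes,
            dropout=self.dropout,
            fc_width=self.fc_width,  # the high dropout rate needs wide FC layers
            prior_channels=self.prior_channels,
            variant=self.variant,
            attention_mode=self.attention_mode,
            attention_grid_max=16,
            use_recon=self.use_recon,
            seed=self.seed,
        )


@dataclass
class WNetOutput:
    """Forward-pass results (numpy views plus live Tensors for training)."""

    seg_prob_t: Tensor
    class_logits_t: Tensor
    attention_maps_t: list
    recon_t: Tensor | None = None

    @property
    def seg_prob(self) -> np.ndarray:
        """H x W x 1 lesion probability map (first batch element)."""
        return np.moveaxis(self.seg_prob_t.data[0], 0, -1)

    @property
    def class_prob(self) -> np.ndarray:
        """Length-5 probability vector (first batch element)."""
        logits = self.class_logits_t.data
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        return (e / e.sum(axis=-1, keepdims=True))[0]

    @property
    def class_prob_batch(self) -> np.ndarray:
        logits = self.class_logits_t.data
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    @property
    def attention_maps(self) -> list:
        return [t.data[:, 0] for t in self.attention_maps_t]


def _layer_norm(h: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample channel normalization (no learnable affine)."""
    mu = h.mean(axis=-1, keepdims=True)
    var = ((h - mu) ** 2).mean(axis=-1, keepdims=True)
    return (h - mu) * ((var + eps) ** -0.5)


def pixel_attention(f: Tensor, w_conv) -> Tensor:
    """F_pa = sigma(W_p * F) (elementwise) F — pixel-wise attention gate."""
    return w_conv(f).sigmoid() * f


class LPCA(nn.Module):
    """Lesion-Prior Cross Attention for one skip scale."""

    def __init__(self, c_feat, c_prior, rng, mode="spatial", grid_max=48):
        self.c_feat = c_feat
        self.mode = mode
        self.grid_max = grid_max
        self.gate_conv = nn.Conv2d(c_feat + c_prior, 1, k=1, pad=0, rng=rng)  # W_a
        self.q_conv = nn.Conv2d(c_feat, c_feat, k=1, pad=0, rng=rng)          # W_q
        self.k_conv = nn.Conv2d(c_prior, c_feat, k=1, pad=0, rng=rng)         # W_k
        # 2x2 local-detail projection for V, cropped back to the skip size
        self.v_conv = nn.Conv2d(c_feat, c_feat, k=2, pad=1, rng=rng)          # W_v

    def gate(self, f: Tensor, p: Tensor) -> Tensor:
        return self.gate_conv(nn.concat([f, p], axis=1)).sigmoid()

    def _attend_spatial(self, f: Tensor, p: Tensor) -> Tensor:
        n, c, h, w = f.shape
        k_pool = max(1, math.ceil(h / self.grid_max))
        fp = nn.avgpool2d(f, k_pool) if k_pool > 1 else f
        pp = nn.avgpool2d(p, k_pool) if k_pool > 1 else p
        g = fp.shape[2]
        gw = fp.shape[3]
        d = self.c_feat
        q = self.q_conv(fp).reshape(n, d, g * gw).transpose(0, 2, 1)   # N x L x d
        k = self.k_conv(pp).reshape(n, d, g * gw).transpose(0, 2, 1)
        v = nn.crop_or_pad(self.v_conv(fp), g, gw)
        v = v.reshape(n, d, g * gw).transpose(0, 2, 1)
        attn = (q @ k.transpose(0, 2, 1) * (1.0 / math.sqrt(d))).softmax(axis=-1)
        out = attn @ v                                                  # N x L x d
        out = out.transpose(0, 2, 1).reshape(n, d, g, gw)
        if k_pool > 1:
            out = nn.crop_or_pad(nn.upsample_nearest(out, k_pool), h, w)
        return out

    def _attend_pooled(self, f: Tensor, p: Tensor) -> Tensor:
        # Fig-4 granularity: GAP descriptor from the prior path drives a
        # channel-attention weighting of the local-detail projection.
        n, c, h, w = f.shape
        d = self.c_feat
        q = nn.global_avg_pool(self.q_conv(f))          # N x d
        kd = nn.global_avg_pool(self.k_conv(p))         # N x d
        weights = (q * kd * (1.0 / math.sqrt(d))).softmax(axis=-1)
        v = nn.crop_or_pad(self.v_conv(f), h, w)
        return v * weights.reshape(n, d, 1, 1) * float(d)

    def __call__(self, f: Tensor, p: Tensor, spatial_only: bool = False):
        """Returns ``(fused, gate_map)``; ``p`` must match ``f`` spatially."""
        if f.shape[2:] != p.shape[2:]:
            raise ValueError(
                f"feature/prior spatial mismatch: {f.shape} vs {p.shape}"
            )
        g = self.gate(f, p)
        if spatial_only:
            return f + g * f, g
        if self.mode == "pooled":
            attn_out = self._attend_pooled(f, p)
        else:
            attn_out = self._attend_spatial(f, p)
        return g * attn_out + (1.0 - g) * f, g


class WNet(nn.Module):
    """The dual-decoder network; see the module docstring for the layout."""

    def __init__(self, config: WNetConfig | None = None):
        self.config = config or WNetConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        k = cfg.conv_kernel
        chans = list(cfg.encoder_channels) + [cfg.context_channels]
        self.enc = [
            nn.Conv2d(cin, cout, k=k, rng=rng)
            for cin, cout in zip([cfg.input_channels] + chans[:-1], chans)
        ]
        self.lpca = [
            LPCA(c, cfg.prior_channels, rng, mode=cfg.attention_mode,
                 grid_max=cfg.attention_grid_max)
            for c in cfg.encoder_channels
        ]
        # segmentation decoder: context-skip stage, then encoder skips
        # deep-to-shallow
        self.deconv = []
        self.dec_conv = []
        prev = chans[-1]
        self.deconv.append(nn.ConvTranspose2d(prev, chans[-1] // 2, rng=rng))
        self.dec_conv.append(
            nn.Conv2d(chans[-1] // 2 + chans[-1], chans[-2], k=k, rng=rng)
        )
        prev = chans[-2]
        for c_skip in chans[:-1][::-1]:
            up_out = max(prev // 2, 8)
            self.deconv.append(nn.ConvTranspose2d(prev, up_out, rng=rng))
            self.dec_conv.append(nn.Conv2d(up_out + c_skip, max(c_skip // 2, 8), k=k, rng=rng))
            prev = max(c_skip // 2, 8)
        self.pa_conv = nn.Conv2d(prev, prev, k=1, pad=0, rng=rng)  # W_p
        self.seg_head = nn.Conv2d(prev, 1, k=1, pad=0, rng=rng)
        # classification branch pools the deepest LPCA-fused skip together
        # with the lesion-prior channels at that scale: the priors carry the
        # grade-determining signal (lesion burden) explicitly
        self.cls_conv = nn.Conv2d(
            cfg.encoder_channels[-1] + cfg.prior_channels, cfg.fc_width, k=k, rng=rng
        )
        self.fc1 = nn.Linear(cfg.fc_width, cfg.fc_width, rng=rng)
        self.fc2 = nn.Linear(cfg.fc_width, cfg.fc_width, rng=rng)
        self.fc_out = nn.Linear(cfg.fc_width, cfg.num_classes, rng=rng)
        # reconstruction head for the consistency term
        if cfg.use_recon:
            self.recon_conv = nn.Conv2d(chans[-1], cfg.input_channels, k=1, pad=0, rng=rng)

    # -----------------------------------------------------------------
    def _act(self, t: Tensor) -> Tensor:
        return t.leaky_relu(0.01) if self.config.leaky_relu else t.relu()

    def forward(
        self,
        x: np.ndarray | Tensor,
        priors: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> WNetOutput:
        """Run the network.

        ``x`` is (H, W, 3) or (N, H, W, 3) in [0, 1]; ``priors`` is the
        matching (H, W, K) or (N, H, W, K) prior stack.  Dropout is active
        only when ``train`` is True (supply ``rng`` for reproducibility).
        """
        cfg = self.config
        if isinstance(x, Tensor):
            xt = x
        else:
            x = np.asarray(x, dtype=np.float32)
            if x.ndim == 3:
                x = x[None]
            xt = Tensor(np.moveaxis(x, -1, 1))
        pr = np.asarray(priors, dtype=np.float32)
        if pr.ndim == 3:
            pr = pr[None]
        n, _, h0, w0 = xt.shape
        if h0 != cfg.input_size:
            raise ValueError(f"expected input size {cfg.input_size}, got {h0}")
        rng = rng or np.random.default_rng(0)

        # encoder
        skips = []
        cur = xt
        for conv in self.enc:
            feat = self._act(conv(cur))
            skips.append(feat)
            cur = nn.maxpool2d(feat, cfg.pool)
        bottleneck = cur

        # LPCA-gated skips (per variant)
        gates: list[Tensor] = []
        fused = list(skips)
        if cfg.variant in ("full", "lpca_spatial_only"):
            for i, lpca in enumerate(self.lpca):
                f = skips[i]
                pt = Tensor(self._resize_priors(pr, f.shape[2], f.shape[3]))
                phi, g = lpca(f, pt, spatial_only=cfg.variant == "lpca_spatial_only")
                fused[i] = phi
                gates.append(g)

        # classification branch (upper decoder): global pooling of the
        # deepest LPCA-fused skip, then the fully connected stack with
        # dropout.  Lesion activations are spatially sparse, so each channel's
        # spatial mean (the background common mode) is removed before
        # averaging the positive residual, and the pooled vector is
        # layer-normalized — otherwise sample-to-sample differences are
        # orders of magnitude smaller than the shared background response.
        deepest = fused[len(cfg.encoder_channels) - 1]
        p_deep = Tensor(self._resize_priors(pr, deepest.shape[2], deepest.shape[3]))
        cls = self._act(self.cls_conv(nn.concat([deepest, p_deep], axis=1)))
        cls = (cls - cls.mean(axis=(2, 3), keepdims=True)).relu()
        hvec = _layer_norm(nn.global_avg_pool(cls))
        hvec = nn.dropout(self._act(self.fc1(hvec)), cfg.dropout, rng, train)
        hvec = nn.dropout(self._act(self.fc2(hvec)), cfg.dropout, rng, train)
        class_logits = self.fc_out(hvec)

        # segmentation decoder (lower branch)
        cur = bottleneck
        dec_skips = [skips[-1]] + fused[:-1][::-1]
        for i, (up, conv) in enumerate(zip(self.deconv, self.dec_conv)):
            skip = dec_skips[i]
            cur = nn.crop_or_pad(up(cur), skip.shape[2], skip.shape[3])
            cur = self._act(conv(nn.concat([cur, skip], axis=1)))
        if cfg.variant != "baseline_unet":
            cur = pixel_attention(cur, self.pa_conv)
        seg_prob = self.seg_head(cur).sigmoid()

        recon = None
        if cfg.use_recon:
            r = self.recon_conv(bottleneck)
            factor = math.ceil(h0 / r.shape[2])
            recon = nn.crop_or_pad(nn.upsample_nearest(r, factor), h0, w0)

        return WNetOutput(
            seg_prob_t=seg_prob,
            class_logits_t=class_logits,
            attention_maps_t=gates,
            recon_t=recon,
        )

    __call__ = forward

    @staticmethod
    def _resize_priors(pr: np.ndarray, h: int, w: int) -> np.ndarray:
        """(N, H, W, K) -> (N, K, h, w) float32, values clamped to [0, 1]."""
        out = np.empty((pr.shape[0], pr.shape[-1], h, w), dtype=np.float32)
        for i in range(pr.shape[0]):
            resized = resize_prior_stack(pr[i], h)
            out[i] = np.moveaxis(resized, -1, 0)
        return out

    # -----------------------------------------------------------------
    def save(self, path: str) -> None:
        state = self.state_dict()
        np.savez_compressed(
            path, __config__=json.dumps(asdict(self.config)), **state
        )

    @classmethod
    def load(cls, path: str) -> "WNet":
        archive = np.load(path, allow_pickle=False)
        cfg_dict = json.loads(str(archive["__config__"]))
        for key in ("encoder_channels",):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(WNetConfig(**cfg_dict))
        model.load_state_dict(
            {k: archive[k] for k in archive.files if k != "__config__"}
        )
        return model


def count_parameters(config: WNetConfig) -> int:
    """Total trainable parameter count for a configuration."""
    return WNet(config).count_parameters()
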