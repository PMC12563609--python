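"""Composite training objective.

    L = lambda_seg * L_seg + lambda_cls * L_cls
      + lambda_align * L_align + lambda_cons * L_cons

* ``L_seg`` — hybrid Dice + binary cross-entropy per lesion class, weighted
  by ``w_k`` and scaled by ``beta`` on the BCE term, with smoothing ``eps``.
* ``L_cls`` — inverse-frequency weighted cross-entropy (``omega_c = N/N_c``).
* ``L_align`` — KL divergence aligning the attention gate maps with the
  lesion priors; each map is normalized to a spatial probability
  distribution (uniform fallback for an all-zero map), KL(prior || attention)
  so attention is penalized for missing prior mass, averaged over scales.
* ``L_cons`` — mean squared reconstruction consistency against the input.

Default weights: lambda_seg = lambda_cls = 1.0, lambda_align = lambda_cons
= 0.5.  Every function accepts either numpy arrays (returns a float) or
autograd Tensors (returns a Tensor), so the same formulas drive both
evaluation and training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .priors import resize_prior_stack

__all__ = [
    "LossWeights",
    "ClassWeights",
    "LossBreakdown",
    "class_weights",
    "seg_loss",
    "cls_loss",
    "cls_loss_from_logits",
    "align_loss",
    "cons_loss",
    "total_loss",
]

_EPS_PROB = 1e-12


@dataclass
class LossWeights:
    lambda_seg: float = 1.0
    lambda_cls: float = 1.0
    lambda_align: float = 0.5
    lambda_cons: float = 0.5
    beta: float = 1.0          # BCE scaling factor inside L_seg
    epsilon: float = 1e-6      # Dice smoothing constant
    w_k: tuple | None = None   # per-lesion-class weights (default: all 1)

    def __post_init__(self):
        for name in ("lambda_seg", "lambda_cls", "lambda_align", "lambda_cons", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ClassWeights:
    """Inverse-frequency class weights omega_c = N / N_c."""

    omega: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=np.float64)


@dataclass
class LossBreakdown:
    seg: float
    cls: float
    align: float
    cons: float
    total: float

    def as_dict(self) -> dict:
        return {
            "seg": self.seg,
            "cls": self.cls,
            "align": self.align,
            "cons": self.cons,
            "total": self.total,
        }


def class_weights(counts) -> ClassWeights:
    """omega_c = (sum of counts) / counts_c for the five severity classes."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts <= 0):
        raise ValueError(
            "every class must have at least one sample; merge sparse grades "
            "or resample before computing inverse-frequency weights"
        )
    return ClassWeights(omega=counts.sum() / counts)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _maybe_float(value: Tensor, tensor_inputs: bool):
    return value if tensor_inputs else float(value.data)


def seg_loss(s_hat, m, weights: LossWeights | None = None):
    """Hybrid Dice + beta-scaled BCE, summed over lesion classes.

    ``s_hat`` and ``m`` are (K, H, W) stacks (or single (H, W) maps);
    predictions in (0, 1), masks binary.
    """
    weights = weights or LossWeights()
    tensor_inputs = isinstance(s_hat, Tensor) or isinstance(m, Tensor)
    s = _as_tensor(s_hat)
    t = _as_tensor(m)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {t.shape}")
    if len(s.shape) == 2:
        s = s.reshape(1, *s.shape)
        t = t.reshape(1, *t.shape)
    k = s.shape[0]
    w_k = np.ones(k) if weights.w_k is None else np.asarray(weights.w_k, dtype=np.float64)
    eps = weights.epsilon
    total = None
    for i in range(k):
        si, ti = s[i], t[i]
        inter = (si * ti).sum()
        dice_term = 1.0 - (2.0 * inter + eps) / (si.sum() + ti.sum() + eps)
        term = dice_term
        if weights.beta > 0:
            bce = -(
                ti * si.log(_EPS_PROB) + (1.0 - ti) * (1.0 - si).log(_EPS_PROB)
            ).mean()
            term = term + weights.beta * bce
        term = float(w_k[i]) * term
        total = term if total is None else total + term
    return _maybe_float(total, tensor_inputs)


def cls_loss(p_hat, y, omega: ClassWeights):
    """Weighted cross-entropy -omega_c log p_hat_c for the true class c.

    ``y`` may be a one-hot vector or an integer class index; probabilities
    are clamped at 1e-12.
    """
    p = np.asarray(p_hat, dtype=np.float64)
    if np.isscalar(y) or np.asarray(y).ndim == 0:
        c = int(y)
    else:
        c = int(np.argmax(y))
    return float(-omega.omega[c] * np.log(max(p[c], _EPS_PROB)))


def cls_loss_from_logits(logits: Tensor, y_idx, omega: ClassWeights) -> Tensor:
    """Differentiable batched version operating on raw logits."""
    y_idx = np.atleast_1d(np.asarray(y_idx, dtype=int))
    ls = logits.log_softmax(axis=-1)
    onehot = np.zeros(ls.shape, dtype=np.float32)
    onehot[np.arange(len(y_idx)), y_idx] = 1.0
    w = omega.omega[y_idx].astype(np.float32)
    per_sample = -(ls * Tensor(onehot)).sum(axis=-1)
    return (per_sample * Tensor(w)).mean()


def _normalize_map(x, uniform_shape=None):
    """Normalize a non-negative map to a probability distribution (numpy)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    s = x.sum()
    if s <= 0:
        return np.full(x.size, 1.0 / x.size)
    return x / s


def align_loss(gate_maps, prior_stack, lesion_channels=(1, 2, 3)):
    """KL(prior || attention), averaged over scales.

    ``gate_maps``: list of per-scale attention maps (numpy arrays or
    Tensors, any spatial size).  ``prior_stack``: H x W x K prior tensor; the
    prior saliency is the maximum over the lesion channels, resized to each
    gate's resolution.  Empty gate list -> 0.
    """
    if not gate_maps:
        return 0.0
    prior_stack = np.asarray(prior_stack, dtype=np.float64)
    saliency = prior_stack[..., list(lesion_channels)].max(axis=-1)
    tensor_inputs = any(isinstance(g, Tensor) for g in gate_maps)
    total = None
    for gmap in gate_maps:
        g = gmap if isinstance(gmap, Tensor) else _as_tensor(gmap)
        if len(g.shape) > 2:  # (N, 1, H, W) or (N, H, W): use first element
            g = g.reshape(-1, g.shape[-2], g.shape[-1])[0]
        h, w = g.shape
        p = _normalize_map(
            resize_prior_stack(saliency[..., None], h)[..., 0]
        )
        flat = g.reshape(h * w)
        s = float(flat.data.sum())
        if s <= 0:
            a = Tensor(np.full(h * w, 1.0 / (h * w), dtype=np.float32))
        else:
            a = flat / flat.sum()
        pt = Tensor(p.astype(np.float32))
        kl = (pt * (Tensor(np.log(p + _EPS_PROB).astype(np.float32)) - a.log(_EPS_PROB))).sum()
        total = kl if total is None else total + kl
    total = total * (1.0 / len(gate_maps))
    return _maybe_float(total, tensor_inputs)


def cons_loss(recon, x):
    """Mean squared discrepancy between the reconstruction and the input."""
    tensor_inputs = isinstance(recon, Tensor) or isinstance(x, Tensor)
    r = _as_tensor(recon)
    t = _as_tensor(x)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {t.shape}")
    out = ((r - t) ** 2).mean()
    return _maybe_float(out, tensor_inputs)


def total_loss(seg, cls, align, cons, weights: LossWeights | None = None):
    """lambda-weighted sum of the four components -> LossBreakdown.

    Accepts floats (evaluation) or Tensors (training); Tensor inputs return
    ``(breakdown, total_tensor)``.
    """
    weights = weights or LossWeights()
    parts = {"seg": seg, "cls": cls, "align": align, "cons": cons}
    floats = {}
    for name, value in parts.items():
        v = float(value.data) if isinstance(value, Tensor) else float(value)
        if not np.isfinite(v):
            raise ValueError(f"loss component {name!r} is not finite")
        if v < 0:
            raise ValueError(f"loss component {name!r} is negative ({v})")
        floats[name] = v
    total = (
        weights.lambda_seg * floats["seg"]
        + weights.lambda_cls * floats["cls"]
        + weights.lambda_align * floats["align"]
        + weights.lambda_cons * floats["cons"]
    )
    breakdown = LossBreakdown(
        seg=floats["seg"],
        cls=floats["cls"],
        align=floats["align"],
        cons=floats["cons"],
        total=total,
    )
    if any(isinstance(v, Tensor) for v in parts.values()):
        zero = Tensor(np.float32(0.0))
        tt = zero
        for lam, value in (
            (weights.lambda_seg, seg),
            (weights.lambda_cls, cls),
            (weights.lambda_align, align),
            (weights.lambda_cons, cons),
        ):
            if isinstance(value, Tensor):
                tt = tt + value * float(lam)
            else:
                tt = tt + float(lam) * float(value)
        return breakdown, tt
    return breakdown
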