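"""The composite counting objective.

Three components are combined as ``L = L_den + L_c + alpha * L_att``:

* ``L_den`` — pixel-wise Euclidean loss between predicted and true density
  maps (per-image squared norm divided by the pixel count, averaged over
  the batch, so the magnitude is resolution independent).
* ``L_c = 1 - SSIM`` — local pattern-consistency loss.  SSIM compares local
  means, variances and covariances inside a sliding window:

      SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
             / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

  with the unbiased 1/(M-1) variance/covariance estimator (M = window pixel
  count) and small constants C1, C2 guarding the denominators.
* ``L_att`` — mean binary cross-entropy between the predicted attention
  probabilities and the binary attention ground truth, weighted by
  ``alpha`` (default 0.1).

Every component is differentiable through the autograd engine, so the same
functions serve both evaluation (NumPy in, float out) and training (Tensor
in, Tensor out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import autograd as ag
from .network.autograd import Tensor

DEFAULT_ALPHA = 0.1
_BCE_EPS = 1e-7


@dataclass(frozen=True)
class SSIMConfig:
    """Window and stabilisation constants for the SSIM index.

    The default is the standard 11x11 Gaussian window (sigma 1.5) with
    C1 = 0.01^2 and C2 = 0.03^2 on a unit dynamic range.  ``scale``
    multiplies both maps before comparison (SSIM is scale sensitive and
    density values are small).
    """

    window_radius: int = 5
    window: str = "gaussian"   # or "uniform"
    window_sigma: float = 1.5
    c1: float = 1e-4
    c2: float = 9e-4
    scale: float = 1.0

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("C1 and C2 must be positive")
        if self.window not in ("gaussian", "uniform"):
            raise ValueError("window must be 'gaussian' or 'uniform'")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")

    def weights(self) -> np.ndarray:
        """Unit-sum window weights, shape (2r+1, 2r+1)."""
        r = self.window_radius
        if self.window == "uniform":
            w = np.ones((2 * r + 1, 2 * r + 1))
        else:
            ax = np.arange(-r, r + 1, dtype=np.float64)
            w = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2)
                       / (2.0 * self.window_sigma ** 2))
        return w / w.sum()

    @property
    def n_pixels(self) -> int:
        """M, the number of pixels in the window."""
        return (2 * self.window_radius + 1) ** 2


@dataclass(frozen=True)
class LossBreakdown:
    """Per-component values of the combined objective (for logging)."""

    l_den: float
    l_c: float
    l_att: float
    alpha: float
    total: float


def _as_batch(x) -> Tensor:
    """Coerce (H,W), (N,H,W) or (N,1,H,W) input to an (N,1,H,W) Tensor."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    if t.ndim == 2:
        t = t.reshape((1, 1) + t.shape)
    elif t.ndim == 3:
        t = t.reshape((t.shape[0], 1) + t.shape[1:])
    elif t.ndim != 4:
        raise ValueError(f"expected a 2-D map or batch of maps, got shape {t.shape}")
    return t


def _check_same_shape(a: Tensor, b: Tensor):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def density_loss(pred, target):
    """Mean over images of ||pred - target||^2 / n_pixels."""
    p, t = _as_batch(pred), _as_batch(target)
    _check_same_shape(p, t)
    out = ((p - t) ** 2).mean()
    return out if isinstance(pred, Tensor) or isinstance(target, Tensor) else out.item()


def ssim_map(x, y, config: SSIMConfig | None = None):
    """Pointwise SSIM map between two maps (or batches); shape (N,1,H,W).

    Returns a Tensor if either input is one, else a NumPy array.
    """
    config = config or SSIMConfig()
    tensor_in = isinstance(x, Tensor) or isinstance(y, Tensor)
    xb, yb = _as_batch(x), _as_batch(y)
    _check_same_shape(xb, yb)
    if config.scale != 1.0:
        xb = xb * config.scale
        yb = yb * config.scale
    w = Tensor(config.weights()[None, None])  # constant (1,1,k,k) window
    r = config.window_radius
    m = config.n_pixels
    bessel = m / (m - 1.0)

    mu_x = ag.conv2d(xb, w, padding=r)
    mu_y = ag.conv2d(yb, w, padding=r)
    # windowed second moments; the Bessel factor reproduces the 1/(M-1)
    # sample estimator exactly for the uniform window
    var_x = (ag.conv2d(xb * xb, w, padding=r) - mu_x * mu_x) * bessel
    var_y = (ag.conv2d(yb * yb, w, padding=r) - mu_y * mu_y) * bessel
    cov = (ag.conv2d(xb * yb, w, padding=r) - mu_x * mu_y) * bessel

    num = (2.0 * mu_x * mu_y + config.c1) * (2.0 * cov + config.c2)
    den = (mu_x * mu_x + mu_y * mu_y + config.c1) * (var_x + var_y + config.c2)
    out = num / den
    return out if tensor_in else out.data


def ssim_index(x, y, config: SSIMConfig | None = None):
    """Mean SSIM between two maps (or batches of maps); result in [-1, 1]."""
    out = ssim_map(x, y, config)
    if isinstance(out, Tensor):
        return out.mean()
    return float(out.mean())


def consistency_loss(pred, target, config: SSIMConfig | None = None):
    """Local pattern-consistency loss 1 - SSIM, in [0, 2]."""
    return 1.0 - ssim_index(pred, target, config)


def attention_loss(pred_prob, target):
    """Mean binary cross-entropy of attention probabilities vs a binary mask."""
    p, t = _as_batch(pred_prob), _as_batch(target)
    _check_same_shape(p, t)
    tdata = t.data
    if not np.all((tdata == 0) | (tdata == 1)):
        raise ValueError("attention ground truth must be binary (0/1)")
    pc = ag.clip(p, _BCE_EPS, 1.0 - _BCE_EPS)
    out = -(t * ag.log(pc) + (1.0 - t) * ag.log(1.0 - pc)).mean()
    return out if isinstance(pred_prob, Tensor) else out.item()


def total_loss(l_den: float, l_c: float, l_att: float,
               alpha: float = DEFAULT_ALPHA) -> LossBreakdown:
    """Combine the three components: total = l_den + l_c + alpha * l_att."""
    for name, v in (("l_den", l_den), ("l_c", l_c), ("l_att", l_att)):
        if not np.isfinite(v):
            raise ValueError(f"{name} is not finite: {v}")
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return LossBreakdown(l_den=float(l_den), l_c=float(l_c), l_att=float(l_att),
                         alpha=float(alpha),
                         total=float(l_den) + float(l_c) + float(alpha) * float(l_att))


def combined_loss(pred_density: Tensor, pred_attention: Tensor,
                  gt_density, gt_attention,
                  alpha: float = DEFAULT_ALPHA,
                  ssim_config: SSIMConfig | None = None):
    """Differentiable total loss for a training step.

    Returns ``(loss_tensor, LossBreakdown)``; the breakdown holds the
    detached component values for the training log.
    """
    l_den = density_loss(pred_density, _as_batch(gt_density).detach())
    l_c = consistency_loss(pred_density, _as_batch(gt_density).detach(), ssim_config)
    l_att = attention_loss(pred_attention, _as_batch(gt_attention).detach())
    loss = l_den + l_c + alpha * l_att
    # float32 rounding can push SSIM a hair past 1; clamp for the log only
    breakdown = total_loss(l_den.item(), max(l_c.item(), 0.0), l_att.item(), alpha)
    return loss, breakdown
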