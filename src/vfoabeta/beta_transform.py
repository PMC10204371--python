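"""Normalized incomplete-Beta gray-level transfer curve and variance fitness.

The transfer curve is the regularized incomplete Beta function — the CDF
of a Beta(α, β) distribution — applied to gray values rescaled to [0, 1]:

    F(u; α, β) = B(α, β)^{-1} ∫_0^u t^{α−1} (1 − t)^{β−1} dt

With 0 < α, β < 10 this single family reproduces the classic square,
logarithmic, gamma and sigmoid enhancement curves: α < β bends the curve
upward (brightening dark images), α > β bends it downward, α = β = 1 is
the identity.

The enhancement objective is the gray-level variance of the transformed
image — mean of squared pixels minus squared mean — negated so that the
minimizing optimizer maximizes contrast/content richness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import DegenerateImageError, InvalidInputError

__all__ = [
    "BetaParams",
    "TransferCurve",
    "NormalizedImage",
    "beta_complete",
    "beta_cdf",
    "build_lut",
    "normalize_image",
    "apply_transform",
    "denormalize_image",
    "image_variance",
    "fitness",
    "round_half_up",
]


@dataclass(frozen=True)
class BetaParams:
    """Transfer-curve parameters, both strictly inside (0, 10)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not 0.0 < v < 10.0:
                raise InvalidInputError(f"{name} must lie strictly in (0, 10), got {v}")

    @classmethod
    def identity(cls) -> "BetaParams":
        return cls(1.0, 1.0)


@dataclass(frozen=True)
class TransferCurve:
    """Discretized transfer curve: lut[k] = F(k/(levels−1))."""

    levels: int
    lut: np.ndarray


@dataclass(frozen=True)
class NormalizedImage:
    """Gray values rescaled to [0, 1] with the original span recorded."""

    values: np.ndarray
    gmin: int
    gmax: int


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (values here are non-negative).

    A fixed rule so normalize → identity transform → denormalize is a
    bit-exact round trip regardless of platform banker's rounding.
    """
    return np.floor(np.asarray(x) + 0.5)


def _check_gray(img) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError(f"expected a non-empty 2-D gray image, got shape {img.shape}")
    return img


def beta_complete(alpha: float, beta: float) -> float:
    """Complete Beta integral B(α, β) = Γ(α)Γ(β)/Γ(α+β)."""
    if alpha <= 0 or beta <= 0:
        raise InvalidInputError("beta_complete requires alpha, beta > 0")
    return float(special.beta(alpha, beta))


def beta_cdf(u, params: BetaParams):
    """Regularized incomplete Beta F(u; α, β), the transfer curve itself.

    Accepts a scalar or array ``u`` in [0, 1]; strictly increasing in u.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0.0) or np.any(u_arr > 1.0):
        raise InvalidInputError("beta_cdf argument must lie in [0, 1]")
    out = special.betainc(params.alpha, params.beta, u_arr)
    return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out


def build_lut(params: BetaParams, levels: int = 256) -> TransferCurve:
    """Tabulate the transfer curve on an evenly spaced [0, 1] grid.

    lut[k] = F(k/(levels−1)); endpoints are exactly 0 and 1 and the table
    is non-decreasing.  Routing 8-bit pixels through the table is exactly
    equivalent to per-pixel evaluation because both compute F at the same
    float arguments.
    """
    if levels < 2:
        raise InvalidInputError("levels must be >= 2")
    grid = np.arange(levels, dtype=float) / (levels - 1)
    return TransferCurve(levels=levels, lut=beta_cdf(grid, params))


def normalize_image(img) -> NormalizedImage:
    """Rescale gray values to [0, 1] by the image's own min/max span."""
    img = _check_gray(img)
    gmin = int(img.min())
    gmax = int(img.max())
    if gmax == gmin:
        raise DegenerateImageError("constant image: min/max normalization undefined")
    values = (img.astype(float) - gmin) / (gmax - gmin)
    return NormalizedImage(values=values, gmin=gmin, gmax=gmax)


def apply_transform(n: NormalizedImage, params: BetaParams) -> NormalizedImage:
    """Apply the transfer curve element-wise, preserving the span metadata.

    Images coming from 8-bit sources hold at most 256 distinct values, so
    the curve is evaluated once per distinct value and broadcast back —
    identical results to per-pixel evaluation, at LUT cost.
    """
    uniq, inverse = np.unique(n.values, return_inverse=True)
    mapped = beta_cdf(uniq, params)
    out = mapped[inverse].reshape(n.values.shape)
    return NormalizedImage(values=out, gmin=n.gmin, gmax=n.gmax)


def denormalize_image(n: NormalizedImage) -> np.ndarray:
    """Map [0, 1] values back onto the original span as 8-bit pixels."""
    raw = n.gmin + np.asarray(n.values, dtype=float) * (n.gmax - n.gmin)
    return np.clip(round_half_up(raw), 0, 255).astype(np.uint8)


def image_variance(img) -> float:
    """Gray-level variance: mean of squared pixels minus squared mean."""
    img = _check_gray(img).astype(float)
    m = img.mean()
    return float((img * img).mean() - m * m)


def fitness(img) -> float:
    """Enhancement objective: negative gray-level variance (minimized)."""
    return -image_variance(img)
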