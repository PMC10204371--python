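"""Image quality metrics: MSE/PSNR, global SSIM, and the natural-scene-
statistics building blocks of no-reference assessment (MSCN coefficients,
AGGD moment fits, the NIQE Mahalanobis distance).

Full-reference metrics compare an enhanced image against its original.
The no-reference machinery implements the feature pipeline of the
BRISQUE/NIQE family — local mean-subtracted contrast-normalized (MSCN)
coefficients, asymmetric generalized Gaussian fits, and the Mahalanobis
distance between multivariate Gaussian feature summaries — without any
pretrained corpus model, which is out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, special

from .errors import InvalidInputError

__all__ = [
    "QualityReport",
    "MSCNField",
    "AGGDParams",
    "GaussianModel",
    "mse",
    "psnr",
    "ssim_global",
    "gaussian_window",
    "local_stats",
    "mscn",
    "fit_aggd",
    "niqe_distance",
    "quality_report",
]


@dataclass(frozen=True)
class QualityReport:
    mse: float
    psnr: float
    ssim: float
    niqe_distance: float | None = None


@dataclass(frozen=True)
class MSCNField:
    coefficients: np.ndarray
    window: np.ndarray
    C: float


@dataclass(frozen=True)
class AGGDParams:
    """Asymmetric generalized Gaussian: shape ν and per-side scales.

    ``left_scale == right_scale`` reduces to the symmetric GGD; shape 2 is
    Gaussian, shape 1 Laplacian.
    """

    shape: float
    left_scale: float
    right_scale: float


@dataclass(frozen=True)
class GaussianModel:
    """Multivariate Gaussian summary (mean vector, covariance matrix)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise InvalidInputError("covariance shape must match the mean vector")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise InvalidInputError("covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise InvalidInputError("empty images")
    return a, b


def mse(a, b) -> float:
    """Mean squared pixel difference."""
    a, b = _pair(a, b)
    d = a - b
    return float(np.mean(d * d))


def psnr(a, b, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10·log10(MAX²/MSE) in dB (inf if equal)."""
    err = mse(a, b)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value * max_value / err))


def ssim_global(a, b, k1: float = 0.01, k2: float = 0.03, L: float = 255.0) -> float:
    """Single-window SSIM over the whole image.

    Means, variances and the covariance are taken over all pixels
    (population moments); c1 = (k1·L)², c2 = (k2·L)².
    """
    a, b = _pair(a, b)
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a = a.var()
    var_b = b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def gaussian_window(size: int = 7, sigma: float = 7.0 / 6.0) -> np.ndarray:
    """Normalized 2-D Gaussian weight window (default 7×7, σ = 7/6)."""
    if size < 1 or size % 2 == 0:
        raise InvalidInputError("window size must be a positive odd integer")
    half = size // 2
    coords = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(coords**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def local_stats(img, window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted local mean and standard deviation fields.

    Uses symmetric boundary extension.  The window must be normalized
    (weights summing to 1) and no larger than the image.
    """
    img = np.asarray(img, dtype=float)
    window = np.asarray(window, dtype=float)
    if img.ndim != 2 or window.ndim != 2:
        raise InvalidInputError("local_stats expects 2-D image and window")
    if window.shape[0] > img.shape[0] or window.shape[1] > img.shape[1]:
        raise InvalidInputError("window larger than image")
    if abs(window.sum() - 1.0) > 1e-8:
        raise InvalidInputError("window weights must sum to 1")
    mean = ndimage.correlate(img, window, mode="reflect")
    mean_sq = ndimage.correlate(img * img, window, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return mean, np.sqrt(var)


def mscn(img, C: float = 1.0, window: np.ndarray | None = None) -> MSCNField:
    """Mean-subtracted contrast-normalized coefficients (I − μ)/(σ + C)."""
    if window is None:
        window = gaussian_window()
    mean, std = local_stats(img, window)
    coeff = (np.asarray(img, dtype=float) - mean) / (std + C)
    return MSCNField(coefficients=coeff, window=window, C=float(C))


# shape-parameter grid of the standard AGGD moment-matching estimator
_GAMMA_GRID = np.arange(0.2, 10.001, 0.001)
_RHO_GRID = special.gamma(2.0 / _GAMMA_GRID) ** 2 / (
    special.gamma(1.0 / _GAMMA_GRID) * special.gamma(3.0 / _GAMMA_GRID)
)


def fit_aggd(sample) -> AGGDParams:
    """Moment-matching fit of an asymmetric generalized Gaussian.

    The standard estimator: per-side root-mean-squares give the asymmetry
    ratio, the (mean |x|)²/mean x² ratio gives the generalized kurtosis,
    and the shape is read off a precomputed ρ(ν) grid.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 100:
        raise InvalidInputError("fit_aggd needs at least 100 samples")
    if np.all(x == x[0]):
        raise InvalidInputError("degenerate sample: all values equal")
    left = x[x < 0]
    right = x[x >= 0]
    if left.size == 0 or right.size == 0:
        raise InvalidInputError("sample must contain values on both sides of zero")
    sigma_l = np.sqrt(np.mean(left * left))
    sigma_r = np.sqrt(np.mean(right * right))
    if sigma_l == 0 or sigma_r == 0:
        raise InvalidInputError("degenerate one-sided sample")
    gamma_hat = sigma_l / sigma_r
    r_hat = np.mean(np.abs(x)) ** 2 / np.mean(x * x)
    R_hat = r_hat * (gamma_hat**3 + 1) * (gamma_hat + 1) / (gamma_hat**2 + 1) ** 2
    shape = float(_GAMMA_GRID[np.argmin((_RHO_GRID - R_hat) ** 2)])
    conv = np.sqrt(special.gamma(1.0 / shape) / special.gamma(3.0 / shape))
    return AGGDParams(
        shape=shape,
        left_scale=float(sigma_l * conv),
        right_scale=float(sigma_r * conv),
    )


def niqe_distance(m1: GaussianModel, m2: GaussianModel) -> float:
    """Mahalanobis-type distance between two Gaussian feature summaries:

        sqrt((v1 − v2)ᵀ ((Σ1 + Σ2)/2)⁻¹ (v1 − v2))

    Zero iff the mean vectors coincide; smaller means the two feature
    distributions are more alike.
    """
    if m1.mean.size != m2.mean.size:
        raise InvalidInputError("model dimensions disagree")
    diff = m1.mean - m2.mean
    pooled = (m1.cov + m2.cov) / 2.0
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; using pseudo-inverse", stacklevel=2)
        sol = np.linalg.pinv(pooled) @ diff
    return float(np.sqrt(max(diff @ sol, 0.0)))


def quality_report(original, enhanced, niqe: float | None = None) -> QualityReport:
    """Bundle the full-reference metrics for one original/enhanced pair."""
    return QualityReport(
        mse=mse(original, enhanced),
        psnr=psnr(original, enhanced),
        ssim=ssim_global(original, enhanced),
        niqe_distance=niqe,
    )
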