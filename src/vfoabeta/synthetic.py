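"""Seeded synthetic scenes: low-contrast and reference fixtures.

Real enhancement benchmarks use photographs (street scenes, endoscopy
frames, ...).  These generators emulate the properties that matter to the
pipeline — compressed dark histograms, smooth structure with blobs, exact
two-level patterns — so every stage is testable without downloads.  No
claim of photographic realism is made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError

__all__ = ["SceneSpec", "make_scene", "histogram"]

_KINDS = ("gradient", "gamma_dark", "blobs", "checker")


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene.

    ``gamma`` darkens the base scene (values^gamma on the [0, 1] scale;
    gamma > 1 compresses the histogram into the dark end, the typical
    under-exposed/endoscopic situation).  ``noise_sigma`` is the standard
    deviation of additive Gaussian pixel noise on the 0–255 scale.
    """

    kind: str
    width: int = 256
    height: int = 256
    gamma: float = 2.5
    n_blobs: int = 6
    noise_sigma: float = 2.0
    seed: int = 0
    rgb: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidInputError(f"unknown scene kind {self.kind!r}; choose from {_KINDS}")
        if self.width < 8 or self.height < 8:
            raise InvalidInputError("width and height must be >= 8")
        if self.gamma <= 0:
            raise InvalidInputError("gamma must be > 0")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")


def _base_scene(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Blobby textured scene on [0, 1]: smooth background + Gaussian bumps."""
    h, w = spec.height, spec.width
    background = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=min(h, w) / 8)
    span = background.max() - background.min()
    # dark scenes have no saturated whites: cap the base below ~0.8 so a
    # gamma of 2.5 compresses the histogram into less than 60% of the levels
    background = 0.05 + 0.35 * (background - background.min()) / (span if span else 1.0)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sy = rng.uniform(min(h, w) / 20, min(h, w) / 6)
        sx = rng.uniform(min(h, w) / 20, min(h, w) / 6)
        amp = rng.uniform(0.15, 0.4)
        background = background + amp * np.exp(
            -((yy - cy) ** 2 / (2 * sy**2) + (xx - cx) ** 2 / (2 * sx**2))
        )
    return np.clip(background, 0.0, 0.78)


def _finalize(values01: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    pixels = values01 * 255.0
    if spec.noise_sigma > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sigma, pixels.shape)
    gray = np.clip(np.floor(pixels + 0.5), 0, 255).astype(np.uint8)
    if not spec.rgb:
        return gray
    # hue-tinted channels around the gray scene, warm-dark palette
    gains = (1.0, 0.82, 0.65)
    rgbim = np.stack(
        [np.clip(np.floor(gray * g + 0.5), 0, 255).astype(np.uint8) for g in gains],
        axis=-1,
    )
    return rgbim


def make_scene(spec: SceneSpec) -> np.ndarray:
    """Render a scene as an 8-bit array, bit-reproducible under its seed.

    * ``gradient`` — full-range horizontal linear ramp.
    * ``gamma_dark`` — the blob scene raised to ``gamma`` (darkened,
      histogram compressed toward 0).
    * ``blobs`` — textured background with Gaussian blobs plus noise.
    * ``checker`` — exact two-level {0, 255} parity pattern (no noise).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gradient":
        ramp = np.linspace(0.0, 1.0, spec.width)
        values = np.tile(ramp, (spec.height, 1))
        return _finalize(values, spec, rng)
    if spec.kind == "checker":
        yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
        gray = (((yy + xx) % 2) * 255).astype(np.uint8)
        if spec.rgb:
            return np.stack([gray] * 3, axis=-1)
        return gray
    base = _base_scene(spec, rng)
    if spec.kind == "gamma_dark":
        base = base**spec.gamma
    return _finalize(base, spec, rng)


def histogram(img) -> np.ndarray:
    """256-bin gray-level histogram; counts sum to the pixel count."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise InvalidInputError("histogram expects an 8-bit image")
    return np.bincount(img.ravel(), minlength=256)
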