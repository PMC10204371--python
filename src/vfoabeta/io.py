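"""Pixel-exact 8-bit image reading and writing (PNG, PGM/PPM) and run reports.

The whole pipeline is 8-bit by design (256-entry transfer tables,
MAX = 255 in PSNR), so higher bit depths are rejected rather than
silently rescaled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import InvalidInputError

__all__ = ["read_image", "write_image", "RunReport"]

_OK_MODES = {"L", "RGB"}
# modes Pillow uses for >8-bit or float data
_DEEP_MODES = {"I", "I;16", "I;16B", "I;16L", "I;16N", "F"}


def read_image(path) -> np.ndarray:
    """Load an 8-bit grayscale or RGB image as a uint8 array.

    Accepts PNG and both binary and ASCII PGM/PPM dialects.  Palette
    images are expanded to RGB; 16-bit and float inputs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            if im.mode in _DEEP_MODES:
                raise InvalidInputError(
                    f"{path}: {im.mode}-mode image is deeper than 8 bits; "
                    "this pipeline is 8-bit only"
                )
            if im.mode == "P":
                im = im.convert("RGB")
            if im.mode == "LA" or im.mode == "RGBA":
                raise InvalidInputError(f"{path}: alpha channels are not supported")
            if im.mode not in _OK_MODES:
                raise InvalidInputError(f"{path}: unsupported image mode {im.mode!r}")
            return np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise InvalidInputError(f"{path}: not a recognized image file") from exc
    except OSError as exc:
        raise InvalidInputError(f"{path}: unreadable or truncated image ({exc})") from exc


def write_image(path, img) -> None:
    """Write a uint8 gray or RGB array losslessly (format from extension)."""
    img = np.asarray(img)
    if img.dtype != np.uint8 or img.ndim not in (2, 3):
        raise InvalidInputError("write_image expects a uint8 MxN or MxNx3 array")
    Image.fromarray(img).save(Path(path))


@dataclass
class RunReport:
    """JSON-serializable record of one enhancement run."""

    config: dict
    alpha: float
    beta: float
    original_variance: float
    enhanced_variance: float
    fitness_trace: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    wall_time_s: float = 0.0
    seed: int = 0
    version: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))
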