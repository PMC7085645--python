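"""Raw pocket image → prefilter verdict + fixed-length byte feature vector.

The camera frame is nominally 176×144 pixels of 8-bit grayscale.  The
pipeline is: crop a region of interest (ROI) around the pocket, divert
pockets that the pixel-area prefilter recognises as *double* (two olives or
two substantial fragments) or *small part* (a fragment below a minimum
area) — those never reach the neural network — and downscale the rest to a
square low-resolution raster (16×16 for the 256-byte network profile,
11×11 for the 128-byte one) flattened row-major into a byte vector.

Downscaling is exact box (area) averaging with round-half-up to integer, so
feature vectors are reproducible bit-for-bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

from .rce import NetworkProfile

__all__ = [
    "PocketImage",
    "RoiSpec",
    "ResolutionProfile",
    "PrefilterConfig",
    "PrefilterResult",
    "load_image",
    "crop_roi",
    "binarize",
    "to_feature_vector",
    "prefilter",
]

FRAME_WIDTH = 176
FRAME_HEIGHT = 144


@dataclass
class PocketImage:
    """8-bit grayscale raster with optional ground-truth annotation."""

    pixels: np.ndarray  # (height, width) uint8
    case: Optional[str] = None
    angle: Optional[float] = None
    source: Optional[str] = None
    converted_from_color: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(
                f"PocketImage expects a 2-D grayscale raster, got shape {px.shape}; "
                "convert color input to luminance first"
            )
        self.pixels = px.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RoiSpec:
    """Half-open pixel rectangle [x0, x1) × [y0, y1), origin top-left."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValueError(f"degenerate ROI {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height


# Default ROI: the pocket interior of the synthetic scene (the chain walls
# confine the olive along X, so the X bounds are fixed; Y is stable because
# the chain geometry seats the fruit).  Override via config for real rigs.
DEFAULT_ROI = RoiSpec(x0=28, y0=16, x1=148, y1=128)


@dataclass(frozen=True)
class ResolutionProfile:
    """Output raster size for feature vectors, tied to a network profile."""

    out_w: int
    out_h: int
    network: str = "cm1k"

    def __post_init__(self) -> None:
        if self.out_w < 1 or self.out_h < 1:
            raise ValueError("output dimensions must be positive")
        cap = NetworkProfile.builtin(self.network).vector_len
        if self.vector_len > cap:
            raise ValueError(
                f"{self.out_w}x{self.out_h} = {self.vector_len} bytes exceeds the "
                f"{self.network!r} profile's {cap}-byte input vector"
            )

    @property
    def vector_len(self) -> int:
        return self.out_w * self.out_h


@dataclass(frozen=True)
class PrefilterConfig:
    """Pixel-area rules that divert doubles and small parts off the network.

    ``threshold`` is ``"otsu"`` or a fixed integer gray level.  A pocket is a
    *double* when at least ``double_min_components`` connected foreground
    components each reach ``component_min_area`` pixels; it is a *small part*
    when foreground is present but totals below ``small_max_area``.  Doubles
    are tested first.
    """

    threshold: str | int = "otsu"
    min_contrast: int = 50  # gray levels; below this the scene is all background
    component_min_area: int = 250
    small_max_area: int = 500
    min_olive_area: int = 700
    max_olive_area: int = 3000
    double_min_components: int = 2

    def __post_init__(self) -> None:
        if min(self.component_min_area, self.small_max_area,
               self.min_olive_area, self.max_olive_area) <= 0:
            raise ValueError("all area thresholds must be positive")
        if self.small_max_area >= self.min_olive_area:
            raise ValueError(
                "small_max_area must stay below the minimum single-olive area"
            )


@dataclass(frozen=True)
class PrefilterResult:
    verdict: str  # "pass" | "double" | "small_part"
    total_area: int
    component_areas: tuple[int, ...]


def load_image(path: str | Path) -> PocketImage:
    """Read a PNG/PGM pocket image; color inputs are converted by luminance."""
    with Image.open(path) as im:
        converted = im.mode not in ("L", "I;16", "1")
        gray = im.convert("L")
        return PocketImage(
            np.asarray(gray, dtype=np.uint8),
            source=str(path),
            converted_from_color=converted,
        )


def crop_roi(image: PocketImage, roi: RoiSpec) -> PocketImage:
    """Crop the ROI out of the frame, preserving pixel values."""
    if roi.x1 > image.width or roi.y1 > image.height:
        raise ValueError(
            f"ROI {roi} exceeds image bounds {image.width}x{image.height}"
        )
    return PocketImage(
        image.pixels[roi.y0:roi.y1, roi.x0:roi.x1].copy(),
        case=image.case,
        angle=image.angle,
        source=image.source,
        converted_from_color=image.converted_from_color,
    )


def binarize(image: PocketImage, cfg: PrefilterConfig | None = None) -> np.ndarray:
    """Foreground mask of the pocket interior.

    With ``threshold="otsu"`` the Otsu level is used, but the mask is declared
    empty when the resulting foreground/background mean separation stays below
    ``min_contrast`` — Otsu always splits something, even pure sensor noise,
    and an empty pocket must binarize to an empty mask.
    """
    cfg = cfg or PrefilterConfig()
    px = image.pixels
    if isinstance(cfg.threshold, (int, np.integer)) and not isinstance(cfg.threshold, bool):
        return px > int(cfg.threshold)
    if px.min() == px.max():
        return np.zeros_like(px, dtype=bool)
    t = threshold_otsu(px)
    mask = px > t
    if not mask.any() or mask.all():
        return np.zeros_like(px, dtype=bool)
    if px[mask].mean() - px[~mask].mean() < cfg.min_contrast:
        return np.zeros_like(px, dtype=bool)
    return mask


_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def prefilter(image: PocketImage, cfg: PrefilterConfig | None = None) -> PrefilterResult:
    """Divert doubles and small parts before the network sees the pocket.

    Expects the ROI crop.  All-background images pass (deciding "empty" is
    the network's job, not the prefilter's).
    """
    cfg = cfg or PrefilterConfig()
    mask = binarize(image, cfg)
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    areas = tuple(
        sorted((int(a) for a in ndimage.sum_labels(mask, labels, range(1, n + 1))),
               reverse=True)
    )
    total = int(mask.sum())
    big = [a for a in areas if a >= cfg.component_min_area]
    if len(big) >= cfg.double_min_components:
        return PrefilterResult("double", total, areas)
    if 0 < total < cfg.small_max_area:
        return PrefilterResult("small_part", total, areas)
    return PrefilterResult("pass", total, areas)


def _box_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) row-stochastic matrix of exact box-overlap weights."""
    w = np.zeros((n_out, n_in))
    step = n_in / n_out
    for i in range(n_out):
        lo, hi = i * step, (i + 1) * step
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / step


def to_feature_vector(image: PocketImage, profile: ResolutionProfile) -> np.ndarray:
    """Area-mean downscale to the profile raster, flattened row-major.

    Each output component is the exact box average of the source pixels it
    covers, rounded half-up to an integer in [0, 255].  An image already at
    the target size maps to itself.
    """
    px = image.pixels.astype(np.float64)
    wy = _box_weights(px.shape[0], profile.out_h)
    wx = _box_weights(px.shape[1], profile.out_w)
    means = wy @ px @ wx.T
    out = np.floor(means + 0.5).astype(np.int64)
    return np.clip(out, 0, 255).astype(np.uint8).ravel()
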