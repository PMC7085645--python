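"""Ground-truth labelling: olive orientation and angle-to-class mapping.

An olive seated correctly for the punch needles has its major axis along the
pocket's seating axis; that direction is 0°.  A "boat" lies roughly
perpendicular (|angle| >= 80°) and would be pitted through its side.  The
angle is estimated from the binarized pocket mask as the principal axis of
the largest foreground component, via central second moments.

Angles are reported in degrees in [-90, 90], positive counterclockwise with
the y axis pointing up (i.e. the usual mathematical convention applied to
the image).  Three class schemes of increasing coarseness exist:

* ``degrees`` — |angle| binned into nine 10° bins, sign kept for the eight
  sub-boat bins; the [80, 90] bin is the single class ``boat``; plus
  ``empty``.  18 classes in total.
* ``intermediate`` — ``normal`` (|angle| < 10), ``boat`` (|angle| >= 80),
  ``intermediate`` otherwise, plus ``empty``.
* ``simple`` — ``normal`` / ``boat`` / ``empty`` only; intermediate-range
  angles are rejected by default (they can be coerced to the nearer class
  with ``policy="coerce"``).

Bin edges are half-open below ([a, b)) with the top bin closed at 90 so the
mapping is total and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .preprocess import (
    DEFAULT_ROI,
    PocketImage,
    PrefilterConfig,
    RoiSpec,
    binarize,
    crop_roi,
)

__all__ = [
    "SCHEMES",
    "AngleLabel",
    "LabelerConfig",
    "SchemeError",
    "scheme_classes",
    "estimate_orientation",
    "angle_to_class",
    "label_image",
]

SCHEMES = ("degrees", "intermediate", "simple")

BIN_EDGES = tuple(range(0, 100, 10))  # 0,10,...,90
BOAT_MIN_ABS = 80.0
NORMAL_MAX_ABS = 10.0


class SchemeError(ValueError):
    """An angle or class that the requested scheme cannot express."""


@dataclass(frozen=True)
class AngleLabel:
    """Classification ground truth for one pocket image."""

    angle: Optional[float]  # degrees in [-90, 90]; None for an empty pocket
    scheme: str
    label: str
    degenerate: bool = False  # near-circular blob: angle defaulted to 0


@dataclass(frozen=True)
class LabelerConfig:
    """Binarization + orientation settings for ground-truth generation."""

    roi: RoiSpec = DEFAULT_ROI
    prefilter: PrefilterConfig = field(default_factory=PrefilterConfig)
    empty_threshold: float = 0.01  # foreground fraction of the ROI below which
    # the pocket counts as empty
    anisotropy_tol: float = 1e-3  # |mu20-mu02|, |mu11| below this (normalised)
    # flag the component as degenerate (near-circular)


def _degrees_bins() -> list[str]:
    names = []
    for lo in range(0, 80, 10):
        names.append(f"deg+{lo:02d}_{lo + 10:02d}")
        names.append(f"deg-{lo:02d}_{lo + 10:02d}")
    return names


def scheme_classes(scheme: str, include_empty: bool = True) -> list[str]:
    """The class labels of a scheme, in canonical order."""
    if scheme == "degrees":
        names = _degrees_bins() + ["boat"]
    elif scheme == "intermediate":
        names = ["normal", "intermediate", "boat"]
    elif scheme == "simple":
        names = ["normal", "boat"]
    else:
        raise SchemeError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    return names + (["empty"] if include_empty else [])


def estimate_orientation(
    mask: np.ndarray, cfg: LabelerConfig | None = None
) -> tuple[Optional[float], bool]:
    """Principal-axis angle of the largest foreground component.

    Returns ``(angle_degrees, degenerate)``; angle is ``None`` when the
    foreground area is below ``empty_threshold`` of the mask.  A component
    with no moment anisotropy (near-circular) gets angle 0 and the
    degeneracy flag.
    """
    cfg = cfg or LabelerConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < cfg.empty_threshold * mask.size:
        return None, False
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n > 1:
        areas = ndimage.sum_labels(mask, labels, range(1, n + 1))
        mask = labels == (int(np.argmax(areas)) + 1)
    rows, cols = np.nonzero(mask)
    x = cols.astype(np.float64)
    y = -rows.astype(np.float64)  # y up: counterclockwise-positive angles
    x -= x.mean()
    y -= y.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    norm = mu20 + mu02
    if norm <= 0 or max(abs(mu20 - mu02), abs(mu11)) / norm < cfg.anisotropy_tol:
        return 0.0, True
    angle = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle), False


def angle_to_class(
    angle: Optional[float], scheme: str, policy: str = "reject"
) -> str:
    """Map an angle (or None = empty pocket) to a class of the scheme."""
    if scheme not in SCHEMES:
        raise SchemeError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    if angle is None:
        return "empty"
    if not -90.0 <= angle <= 90.0:
        raise ValueError(f"angle {angle} outside [-90, 90]")
    a = abs(angle)
    if scheme == "degrees":
        if a >= BOAT_MIN_ABS:
            return "boat"
        lo = int(a // 10) * 10
        sign = "-" if angle < 0 else "+"
        return f"deg{sign}{lo:02d}_{lo + 10:02d}"
    if scheme == "intermediate":
        if a < NORMAL_MAX_ABS:
            return "normal"
        if a >= BOAT_MIN_ABS:
            return "boat"
        return "intermediate"
    # simple
    if a < NORMAL_MAX_ABS:
        return "normal"
    if a >= BOAT_MIN_ABS:
        return "boat"
    if policy == "coerce":
        return "normal" if a < 45.0 else "boat"
    raise SchemeError(
        f"angle {angle:.1f}° is intermediate; the simple scheme has no class "
        "for it (policy='coerce' maps it to the nearer of normal/boat)"
    )


def label_image(
    image: PocketImage,
    cfg: LabelerConfig | None = None,
    scheme: str = "intermediate",
    policy: str = "reject",
) -> AngleLabel:
    """Binarize → estimate orientation → map to a class. Deterministic."""
    cfg = cfg or LabelerConfig()
    roi = crop_roi(image, cfg.roi) if (
        image.width > cfg.roi.x1 or image.height > cfg.roi.y1
    ) else image
    mask = binarize(roi, cfg.prefilter)
    angle, degenerate = estimate_orientation(mask, cfg)
    return AngleLabel(
        angle=angle,
        scheme=scheme,
        label=angle_to_class(angle, scheme, policy=policy),
        degenerate=degenerate,
    )
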