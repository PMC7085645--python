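"""Synthetic pocket-scene renderer emulating the feed-chain camera.

Real training data for this system is a camera feed of feed-chain pockets:
176×144-pixel 8-bit grayscale frames, one olive (or none, or two, or a
fragment, or a foreign object) per pocket, LED-lit against a dark chain.
This module renders labelled stand-ins for that feed: a bright filled
ellipse (the olive) between mid-gray pocket walls that confine it along X,
with centre jitter, additive Gaussian sensor noise and a linear illumination
ramp.  Every scene is deterministic given its seed, and dataset generation
derives one child seed per image from the master seed, so any single image
can be re-rendered without re-running the whole set.

The renderer makes no attempt at photorealism — shapes are minimal, chosen
to exercise every prefilter rule and class: doubles are two stacked
ellipses, small parts a sub-threshold fragment, anomalies a thin branch-like
bar or a small high-contrast stone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .labeler import LabelerConfig, SCHEMES, label_image, scheme_classes
from .preprocess import FRAME_HEIGHT, FRAME_WIDTH, PocketImage

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "Sample",
    "CASES",
    "render_scene",
    "sample_angle",
    "generate_dataset",
    "write_dataset",
    "read_sidecar",
]

CASES = ("empty", "olive", "double", "small_part", "anomaly")

# Geometry/intensity defaults, qualitatively matching LED-lit chain scenes:
# dark background, mid-gray pocket walls, bright fruit.
WALL_WIDTH = 20


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one rendered pocket scene."""

    case: str = "olive"
    angle: float = 0.0  # major-axis angle, degrees in [-90, 90]
    semi_major: float = 26.0  # olive semi-axes, pixels
    semi_minor: float = 18.0
    center_jitter: float = 6.0  # uniform ± pixels, both axes
    background: int = 30
    wall: int = 90
    olive: int = 200
    noise_sigma: float = 8.0  # gray levels
    illumination_gradient: float = 0.15  # gray levels per pixel along X
    pit_hole: bool = False  # small dark spot at the fruit centre
    seed: int = 0
    width: int = FRAME_WIDTH
    height: int = FRAME_HEIGHT

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValueError(f"unknown case {self.case!r}; one of {CASES}")
        if not -90.0 <= self.angle <= 90.0:
            raise ValueError(f"angle {self.angle} outside [-90, 90]")
        if self.olive - self.background < 3 * self.noise_sigma:
            raise ValueError(
                "olive/background contrast must exceed 3x noise_sigma for "
                "binarization to be well-posed"
            )
        cx = self.width / 2
        reach = self.semi_major + self.center_jitter
        if cx - reach < WALL_WIDTH or cx + reach > self.width - WALL_WIDTH:
            raise ValueError("olive does not fit between the pocket walls")
        if self.semi_major + self.center_jitter > self.height / 2:
            raise ValueError("olive does not fit in the frame vertically")


@dataclass(frozen=True)
class GroundTruth:
    case: str
    angle: Optional[float]  # None for empty/double/small_part/anomaly scenes


@dataclass(frozen=True)
class Sample:
    """One generated image with its ground truth and scheme class."""

    id: str
    image: PocketImage
    case: str
    angle: Optional[float]
    label: str


def _ellipse_mask(h: int, w: int, cx: float, cy: float, a: float, b: float,
                  angle_deg: float) -> np.ndarray:
    """Filled ellipse, major semi-axis a along `angle_deg` (CCW, y up)."""
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols - cx
    y = -(rows - cy)  # y up, so positive angles are counterclockwise
    t = np.radians(angle_deg)
    xr = x * np.cos(t) + y * np.sin(t)
    yr = -x * np.sin(t) + y * np.cos(t)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _bar_mask(h: int, w: int, cx: float, cy: float, half_len: float,
              half_wid: float, angle_deg: float) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols - cx
    y = -(rows - cy)
    t = np.radians(angle_deg)
    xr = x * np.cos(t) + y * np.sin(t)
    yr = -x * np.sin(t) + y * np.cos(t)
    return (np.abs(xr) <= half_len) & (np.abs(yr) <= half_wid)


def render_scene(spec: SceneSpec) -> tuple[PocketImage, GroundTruth]:
    """Render one 8-bit grayscale pocket scene; deterministic for a seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.full((h, w), float(spec.background))
    img[:, :WALL_WIDTH] = spec.wall
    img[:, w - WALL_WIDTH:] = spec.wall

    cx = w / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter)
    cy = h / 2 + rng.uniform(-spec.center_jitter, spec.center_jitter)
    truth_angle: Optional[float] = None

    if spec.case == "olive":
        mask = _ellipse_mask(h, w, cx, cy, spec.semi_major, spec.semi_minor,
                             spec.angle)
        img[mask] = spec.olive
        if spec.pit_hole:
            img[_ellipse_mask(h, w, cx, cy, 3.0, 3.0, 0.0)] = spec.wall
        truth_angle = spec.angle
    elif spec.case == "double":
        # two smaller fruit stacked along Y (the walls confine X)
        gap = 26.0
        for dy in (-gap, gap):
            ang = rng.uniform(-20.0, 20.0)
            img[_ellipse_mask(h, w, cx, cy + dy, 16.0, 11.0, ang)] = spec.olive
    elif spec.case == "small_part":
        ang = rng.uniform(-90.0, 90.0)
        img[_ellipse_mask(h, w, cx, cy, 8.0, 5.0, ang)] = spec.olive
    elif spec.case == "anomaly":
        if rng.random() < 0.5:  # branch / leaf stem
            ang = rng.uniform(-90.0, 90.0)
            img[_bar_mask(h, w, cx, cy, 30.0, 2.0, ang)] = spec.olive
        else:  # stone: small, brighter than fruit
            img[_ellipse_mask(h, w, cx, cy, 9.0, 9.0, 0.0)] = min(
                255, spec.olive + 30
            )
    # case "empty": background and walls only

    img += spec.illumination_gradient * (np.arange(w) - w / 2)[None, :]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    image = PocketImage(pixels, case=spec.case, angle=truth_angle)
    return image, GroundTruth(spec.case, truth_angle)


_DIVERTED = ("double", "small_part", "anomaly")


def sample_angle(class_name: str, scheme: str, rng: np.random.Generator,
                 margin: float = 0.0) -> Optional[float]:
    """Draw a uniform angle inside the class's bin; None for non-olive classes.

    ``margin`` shrinks the bin symmetrically — used for noise-free closure
    checks that need angles away from bin edges.
    """
    def u(lo: float, hi: float) -> float:
        return float(rng.uniform(lo + margin, hi - margin))

    if class_name in ("empty",) + _DIVERTED:
        return None
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if class_name == "normal":
        return sign * u(0.0, 10.0)
    if class_name == "boat":
        return sign * u(80.0, 90.0)
    if class_name == "intermediate":
        return sign * u(10.0, 80.0)
    if class_name.startswith("deg"):
        sign = -1.0 if class_name[3] == "-" else 1.0
        lo, hi = class_name[4:].split("_")
        return sign * u(float(lo), float(hi))
    raise ValueError(f"unknown class {class_name!r} for scheme {scheme!r}")


def generate_dataset(
    n_per_case: dict[str, int],
    scheme: str = "simple",
    seed: int = 0,
    spec_defaults: SceneSpec | None = None,
    angle_margin: float = 0.0,
) -> list[Sample]:
    """Render a labelled dataset; reproducible from (n_per_case, scheme, seed).

    Keys of ``n_per_case`` are scheme class names (``normal``, ``boat``,
    ``empty``, …) plus optionally the prefilter-diverted cases ``double``,
    ``small_part`` and ``anomaly``.  Each image gets its own child seed
    derived from ``seed`` and its index, so regeneration is piecewise.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    valid = set(scheme_classes(scheme)) | set(_DIVERTED)
    plan: list[str] = []
    for cls, n in n_per_case.items():
        if cls not in valid:
            raise ValueError(f"class {cls!r} is not valid for scheme {scheme!r}")
        if n < 0:
            raise ValueError(f"negative count for class {cls!r}")
        plan.extend([cls] * n)

    base = spec_defaults or SceneSpec()
    samples: list[Sample] = []
    for i, cls in enumerate(plan):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        angle = sample_angle(cls, scheme, rng, margin=angle_margin)
        case = cls if cls in _DIVERTED else ("empty" if cls == "empty" else "olive")
        spec = SceneSpec(
            **{
                **asdict(base),
                "case": case,
                "angle": angle if angle is not None else 0.0,
                "seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
        image, truth = render_scene(spec)
        samples.append(Sample(f"img{i:05d}", image, case, truth.angle, cls))
    return samples


def _sidecar_frame(samples: Sequence[Sample],
                   estimate: bool = False,
                   labeler_cfg: LabelerConfig | None = None) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {
            "image_id": s.id,
            "case": s.case,
            "true_angle": "" if s.angle is None else round(s.angle, 3),
            "label": s.label,
        }
        if estimate:
            est = label_image(s.image, labeler_cfg)
            row["estimated_angle"] = "" if est.angle is None else round(est.angle, 3)
        rows.append(row)
    cols = ["image_id", "case", "true_angle", "label"] + (
        ["estimated_angle"] if estimate else []
    )
    return pd.DataFrame(rows, columns=cols)


def write_dataset(
    samples: Sequence[Sample],
    out_dir: str | Path,
    manifest: dict | None = None,
    estimate: bool = False,
) -> Path:
    """Write PNGs + tabular sidecar (+ JSON manifest); returns the sidecar path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        Image.fromarray(s.image.pixels, mode="L").save(out / f"{s.id}.png")
    sidecar = out / "labels.csv"
    _sidecar_frame(samples, estimate=estimate).to_csv(sidecar, index=False)
    if manifest is not None:
        import json

        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True) + "\n")
    return sidecar


def read_sidecar(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)
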