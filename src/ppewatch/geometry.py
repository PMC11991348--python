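"""Landmark-driven region-of-interest geometry.

A person is described by the 17-keypoint COCO skeleton.  Three kinds of
square regions are derived from it with simple Euclidean rules:

* **face** — a square centred on the nose, sized by the mean ear-to-nose
  distance times a coefficient (default 1.2);
* **palm** — the palm centre is extrapolated from the elbow through the
  wrist by half the elbow–wrist distance, and the square side is 1.6
  times that distance;
* **torso** — centred on the centroid of shoulders and hips, sized by
  0.83 times the distance from the centroid to the furthest of the four
  landmarks.

Degenerate geometry (zero measurement scale, window fully outside the
frame, missing or low-confidence landmarks) is signalled by returning
``None`` — a live monitoring loop must never crash on a bad pose, it
simply treats the region as not visible in that frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from PIL import Image

#: Canonical COCO-17 keypoint names, in storage order.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

_KP_INDEX = {name: i for i, name in enumerate(COCO_KEYPOINTS)}

#: Region kinds produced by this module.
REGION_KINDS: tuple[str, ...] = ("face", "torso", "left_palm", "right_palm")

#: Landmarks each region requires above the confidence threshold.
REGION_LANDMARKS: dict[str, tuple[str, ...]] = {
    "face": ("nose", "left_ear", "right_ear"),
    "torso": ("left_shoulder", "right_shoulder", "left_hip", "right_hip"),
    "left_palm": ("left_elbow", "left_wrist"),
    "right_palm": ("right_elbow", "right_wrist"),
}


@dataclass(frozen=True)
class LandmarkSet:
    """17 anatomical keypoints with pixel coordinates and confidences.

    Coordinates use image convention: origin at the top-left corner,
    ``x`` increasing rightward and ``y`` downward.  Points may lie
    outside the frame — that encodes "out of field".
    """

    coords: np.ndarray  # (17, 2) float
    confidence: np.ndarray  # (17,) float in [0, 1]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        conf = np.asarray(self.confidence, dtype=float)
        if coords.shape != (17, 2):
            raise ValueError(f"coords must have shape (17, 2), got {coords.shape}")
        if conf.shape != (17,):
            raise ValueError(f"confidence must have shape (17,), got {conf.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("landmark coordinates must be finite")
        if np.any(conf < 0) or np.any(conf > 1):
            raise ValueError("confidences must lie in [0, 1]")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "confidence", conf)

    def point(self, name: str) -> np.ndarray:
        return self.coords[_KP_INDEX[name]]

    def conf(self, name: str) -> float:
        return float(self.confidence[_KP_INDEX[name]])

    @classmethod
    def from_points(
        cls,
        points: Mapping[str, Sequence[float]],
        default_confidence: float = 1.0,
    ) -> "LandmarkSet":
        """Build a set from ``{name: (x, y)}`` or ``{name: (x, y, conf)}``.

        Keypoints absent from *points* get coordinate (0, 0) and
        confidence 0 (i.e. undetected).
        """
        coords = np.zeros((17, 2))
        conf = np.zeros(17)
        for name, val in points.items():
            i = _KP_INDEX[name]
            coords[i] = val[:2]
            conf[i] = val[2] if len(val) > 2 else default_confidence
        return cls(coords, conf)

    @classmethod
    def all_undetected(cls) -> "LandmarkSet":
        """A pose with every confidence 0 — 'no person found'."""
        return cls(np.zeros((17, 2)), np.zeros(17))

    def to_json_dict(self, frame_id: str = "") -> dict:
        return {
            "frame_id": frame_id,
            "keypoints": [
                {
                    "name": name,
                    "x": float(self.coords[i, 0]),
                    "y": float(self.coords[i, 1]),
                    "confidence": float(self.confidence[i]),
                }
                for i, name in enumerate(COCO_KEYPOINTS)
            ],
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "LandmarkSet":
        kps = d["keypoints"]
        if len(kps) != 17:
            raise ValueError(f"expected 17 keypoints, got {len(kps)}")
        points = {kp["name"]: (kp["x"], kp["y"], kp["confidence"]) for kp in kps}
        if set(points) != set(COCO_KEYPOINTS):
            raise ValueError("keypoint names do not match the COCO-17 skeleton")
        return cls.from_points(points)

    def save_json(self, path, frame_id: str = "") -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(frame_id), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass(frozen=True)
class SquareRegion:
    """An axis-aligned square window in frame coordinates."""

    center_x: float
    center_y: float
    side: float
    kind: Literal["face", "torso", "left_palm", "right_palm"]

    def __post_init__(self) -> None:
        if not self.side > 0:
            raise ValueError("region side must be > 0")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.center_x, self.center_y])


SideConvention = Literal["half", "full"]


@dataclass(frozen=True)
class GeometryConfig:
    """Coefficients and conventions for region extraction.

    ``*_side_convention`` records whether the coefficient scales a
    half-width ("half": side = 2 × coeff × scale) or the full side
    ("full": side = coeff × scale).  Defaults: palm uses the full-side
    reading (1.6 × the elbow–wrist distance spans a palm), face and
    torso use half-side (1.2 × the ear–nose distance as a full side
    would not contain a face).
    """

    face_coeff: float = 1.2
    palm_offset_coeff: float = 0.5
    palm_side_coeff: float = 1.6
    torso_coeff: float = 0.83
    face_side_convention: SideConvention = "half"
    palm_side_convention: SideConvention = "full"
    torso_side_convention: SideConvention = "half"
    visibility_confidence_threshold: float = 0.3
    crop_out_size: int = 224
    resample: Literal["nearest", "bilinear"] = "bilinear"

    def __post_init__(self) -> None:
        for name in ("face_coeff", "palm_offset_coeff", "palm_side_coeff", "torso_coeff"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.crop_out_size < 8:
            raise ValueError("crop_out_size must be >= 8")

    def with_(self, **kw) -> "GeometryConfig":
        return replace(self, **kw)


def _side(scale: float, coeff: float, convention: SideConvention) -> float:
    return (2.0 if convention == "half" else 1.0) * coeff * scale


def _confident(lm: LandmarkSet, names: Iterable[str], thr: float) -> bool:
    return all(lm.conf(n) >= thr for n in names)


def face_region(lm: LandmarkSet, cfg: GeometryConfig | None = None) -> SquareRegion | None:
    """Square around the nose, sized by the mean ear-to-nose distance.

    Returns ``None`` when the nose or an ear is missing/low-confidence
    or when the measurement scale is degenerate (ears on the nose).
    """
    cfg = cfg or GeometryConfig()
    if not _confident(lm, REGION_LANDMARKS["face"], cfg.visibility_confidence_threshold):
        return None
    nose = lm.point("nose")
    scale = 0.5 * (
        np.linalg.norm(lm.point("right_ear") - nose)
        + np.linalg.norm(lm.point("left_ear") - nose)
    )
    side = _side(scale, cfg.face_coeff, cfg.face_side_convention)
    if side <= 0:
        return None
    return SquareRegion(float(nose[0]), float(nose[1]), float(side), "face")


def palm_region(
    lm: LandmarkSet,
    side: Literal["left", "right"],
    cfg: GeometryConfig | None = None,
) -> SquareRegion | None:
    """Square at the extrapolated palm centre.

    The palm centre lies on the elbow→wrist line, ``palm_offset_coeff``
    times the elbow–wrist distance beyond the wrist; the square side is
    ``palm_side_coeff`` times that distance.
    """
    cfg = cfg or GeometryConfig()
    kind = f"{side}_palm"
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if not _confident(lm, REGION_LANDMARKS[kind], cfg.visibility_confidence_threshold):
        return None
    elbow = lm.point(f"{side}_elbow")
    wrist = lm.point(f"{side}_wrist")
    vec = wrist - elbow
    scale = float(np.linalg.norm(vec))
    if scale <= 0:
        return None
    center = wrist + cfg.palm_offset_coeff * vec  # == wrist + coeff*scale*unit(vec)
    side_px = _side(scale, cfg.palm_side_coeff, cfg.palm_side_convention)
    return SquareRegion(float(center[0]), float(center[1]), float(side_px), kind)  # type: ignore[arg-type]


def torso_region(lm: LandmarkSet, cfg: GeometryConfig | None = None) -> SquareRegion | None:
    """Square at the shoulders/hips centroid, sized by the furthest landmark."""
    cfg = cfg or GeometryConfig()
    if not _confident(lm, REGION_LANDMARKS["torso"], cfg.visibility_confidence_threshold):
        return None
    pts = np.stack([lm.point(n) for n in REGION_LANDMARKS["torso"]])
    center = pts.mean(axis=0)
    scale = float(np.max(np.linalg.norm(pts - center, axis=1)))
    if scale <= 0:
        return None
    side = _side(scale, cfg.torso_coeff, cfg.torso_side_convention)
    return SquareRegion(float(center[0]), float(center[1]), float(side), "torso")


_REGION_BUILDERS = {
    "face": lambda lm, cfg: face_region(lm, cfg),
    "torso": lambda lm, cfg: torso_region(lm, cfg),
    "left_palm": lambda lm, cfg: palm_region(lm, "left", cfg),
    "right_palm": lambda lm, cfg: palm_region(lm, "right", cfg),
}


def build_region(kind: str, lm: LandmarkSet, cfg: GeometryConfig | None = None) -> SquareRegion | None:
    """Dispatch to the region constructor for *kind*."""
    try:
        builder = _REGION_BUILDERS[kind]
    except KeyError:
        raise ValueError(f"unknown region kind {kind!r}") from None
    return builder(lm, cfg or GeometryConfig())


@dataclass(frozen=True)
class Crop:
    """A resampled square crop plus its provenance."""

    image: np.ndarray  # (out, out, 3) uint8
    region: SquareRegion
    inside_fraction: float  # fraction of the window overlapping the frame


def crop(image: np.ndarray, region: SquareRegion, cfg: GeometryConfig | None = None) -> Crop | None:
    """Extract *region* from *image*, zero-pad out-of-frame parts, resample.

    Zero padding (rather than clamping the window) preserves the
    region's geometric centre so the object stays centred for the
    classifier.  Returns ``None`` when the window rounds to less than
    one pixel or lies entirely outside the frame.
    """
    cfg = cfg or GeometryConfig()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an (H, W, 3) array")
    h, w = img.shape[:2]
    size = int(round(region.side))
    if size < 1:
        return None
    x0 = int(round(region.center_x - region.side / 2.0))
    y0 = int(round(region.center_y - region.side / 2.0))
    x1, y1 = x0 + size, y0 + size
    ox0, oy0 = max(x0, 0), max(y0, 0)
    ox1, oy1 = min(x1, w), min(y1, h)
    if ox0 >= ox1 or oy0 >= oy1:
        return None
    window = np.zeros((size, size, 3), dtype=img.dtype)
    window[oy0 - y0 : oy1 - y0, ox0 - x0 : ox1 - x0] = img[oy0:oy1, ox0:ox1]
    inside = (ox1 - ox0) * (oy1 - oy0) / float(size * size)
    out = cfg.crop_out_size
    if size == out:
        resized = window
    else:
        method = Image.NEAREST if cfg.resample == "nearest" else Image.BILINEAR
        resized = np.asarray(
            Image.fromarray(window.astype(np.uint8)).resize((out, out), method)
        )
    return Crop(resized.astype(np.uint8), region, float(inside))


def visible_regions(
    lm: LandmarkSet,
    frame_size: tuple[int, int],
    cfg: GeometryConfig | None = None,
) -> set[str]:
    """Region kinds assessable in this frame.

    A region is visible iff all its required landmarks pass the
    confidence threshold, and additionally for palms the wrist lies
    inside the frame (the "wrist out of the image field" cleaning rule)
    — the nose-confidence requirement on the face acts as a
    back-of-head proxy.  ``frame_size`` is (width, height).
    """
    cfg = cfg or GeometryConfig()
    w, h = frame_size
    thr = cfg.visibility_confidence_threshold
    out: set[str] = set()
    for kind, names in REGION_LANDMARKS.items():
        if not _confident(lm, names, thr):
            continue
        if kind.endswith("palm"):
            wrist = lm.point(kind.split("_")[0] + "_wrist")
            if not (0 <= wrist[0] < w and 0 <= wrist[1] < h):
                continue
        out.add(kind)
    return out
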