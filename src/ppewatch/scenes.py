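"""Synthetic schematic-person scenes with known landmarks and PPE state.

The renderer draws a stick/ellipse figure on a parametric background and
encodes each PPE item as a distinct colour patch: a pale-blue mask over
the lower face (nose-anchored), blue-violet glove discs at the palm
centres, and a yellow gown panel over the torso.  Within-class hue
jitter and additive Gaussian noise make classification learnable but not
trivial.

This is deliberately a schematic emulation, not photorealism: it gives
the geometry, training, pipeline and evaluation code a fully controlled,
downloadable-nothing test surface where every landmark coordinate and
every label is known exactly.  Accuracy on these scenes demonstrates
that the pipeline mechanics are correct; it says nothing about accuracy
on real hospital imagery.

Confounder tags (clothing, scenery, height class, sex proxy) are
attached to every scene so stratified accuracy analyses run end-to-end.
An optional "white coat" clothing mode gives casual clothing a
near-gown hue, reproducing the known failure mode where white coats are
mistaken for single-use gowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .geometry import (
    COCO_KEYPOINTS,
    GeometryConfig,
    LandmarkSet,
    build_region,
    crop as crop_region,
)

# Canonical standing-figure landmark offsets in units of the figure scale
# (x rightward, y downward, nose at (0, -1)).
_LAYOUT: dict[str, tuple[float, float]] = {
    "nose": (0.00, -1.00),
    "left_eye": (0.07, -1.06),
    "right_eye": (-0.07, -1.06),
    "left_ear": (0.18, -1.00),
    "right_ear": (-0.18, -1.00),
    "left_shoulder": (0.35, -0.60),
    "right_shoulder": (-0.35, -0.60),
    "left_elbow": (0.55, -0.15),
    "right_elbow": (-0.55, -0.15),
    "left_wrist": (0.62, 0.28),
    "right_wrist": (-0.62, 0.28),
    "left_hip": (0.22, 0.25),
    "right_hip": (-0.22, 0.25),
    "left_knee": (0.25, 0.85),
    "right_knee": (-0.25, 0.85),
    "left_ankle": (0.25, 1.45),
    "right_ankle": (-0.25, 1.45),
}

# Base palette.  PPE hues are far from skin/clothing hues so that a
# colour rule separates classes perfectly at zero jitter.
COLORS = {
    "skin": (224, 172, 105),
    "mask": (120, 170, 220),
    "glove": (90, 70, 200),
    "gown": (235, 200, 40),
    "scrubs": (60, 130, 90),
    "casual": (150, 60, 60),
    "white_coat": (230, 205, 70),  # near-gown hue: the confusable case
    "pants": (70, 70, 80),
    "bg_hospital": (202, 208, 214),
    "bg_regular": (208, 196, 176),
}

#: Jitter amplitudes below this keep every class colour-separable by the
#: oracle colour rule (patch hues stay within `_ORACLE_TOL` of their base).
SEPARABLE_JITTER = 0.2
_ORACLE_TOL = 70.0
_ORACLE_MIN_FRACTION = 0.02

#: Median figure scale used to tag height above/below median.
MEDIAN_SCALE = 54.0


@dataclass(frozen=True)
class PPEState:
    """Which protective items the figure wears."""

    mask: bool = True
    gown: bool = True
    glove_left: bool = True
    glove_right: bool = True

    def labels(self) -> dict[str, bool]:
        return {
            "mask": self.mask,
            "gown": self.gown,
            "glove_left": self.glove_left,
            "glove_right": self.glove_right,
        }

    @staticmethod
    def permutations() -> list["PPEState"]:
        """All 8 mask x gloves x gown permutations (gloves as a pair).

        Ordered so consecutive pairs are complements: any even-length
        prefix contains both classes of every item, which keeps small
        cycled event batches trainable.
        """
        half = [(True, True, True), (True, False, False), (False, True, False), (False, False, True)]
        ordered = []
        for m, gl, g in half:
            ordered.append((m, gl, g))
            ordered.append((not m, not gl, not g))
        return [
            PPEState(mask=m, gown=g, glove_left=gl, glove_right=gl)
            for m, gl, g in ordered
        ]


@dataclass(frozen=True)
class SceneSpec:
    """Full generative description of one synthetic frame."""

    frame_size: tuple[int, int] = (256, 256)  # (width, height)
    center: tuple[float, float] = (128.0, 110.0)
    scale: float = 54.0
    ppe: PPEState = field(default_factory=PPEState)
    hidden: tuple[str, ...] = ()  # landmark names flagged hidden (confidence 0)
    clothing: str = "scrubs"  # scrubs | casual
    scenery: str = "hospital"  # hospital | regular
    background_style: int = 0
    jitter: float = 0.1  # within-class hue jitter amplitude in [0, 1]
    noise_sigma: float = 4.0  # additive Gaussian pixel noise
    white_coat: bool = False  # casual clothing takes a near-gown hue
    seed: int = 0

    def layout(self) -> LandmarkSet:
        """Ground-truth landmarks: exact coordinates, confidence 1
        except joints flagged hidden (confidence 0)."""
        cx, cy = self.center
        pts = {}
        for name, (ox, oy) in _LAYOUT.items():
            conf = 0.0 if name in self.hidden else 1.0
            pts[name] = (cx + ox * self.scale, cy + oy * self.scale, conf)
        return LandmarkSet.from_points(pts)

    def tags(self) -> dict[str, str]:
        return {
            "clothing": self.clothing,
            "scenery": self.scenery,
            "height": "above_median" if self.scale >= MEDIAN_SCALE else "below_median",
            "sex_proxy": "large_frame" if self.scale >= MEDIAN_SCALE else "small_frame",
        }


@dataclass(frozen=True)
class Scene:
    """A rendered frame with its ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    landmarks: LandmarkSet
    ppe: PPEState
    tags: dict[str, str]


def _jitter_color(base: tuple[int, int, int], rng: np.random.Generator, amp: float):
    c = np.asarray(base, dtype=float) + rng.uniform(-1, 1, 3) * amp * 255.0
    return tuple(int(v) for v in np.clip(c, 0, 255))


def render_scene(spec: SceneSpec) -> Scene:
    """Render one frame; deterministic given an identical spec."""
    w, h = spec.frame_size
    if w < 16 or h < 16:
        raise ValueError("frame must be at least 16x16")
    if not np.all(np.isfinite(spec.center)) or not np.isfinite(spec.scale) or spec.scale <= 0:
        raise ValueError("scene layout must have finite centre and positive scale")
    rng = np.random.default_rng(spec.seed)
    s = spec.scale
    lm = spec.layout()
    pt = {name: tuple(lm.point(name)) for name in COCO_KEYPOINTS}

    jit = spec.jitter
    bg = _jitter_color(COLORS["bg_hospital" if spec.scenery == "hospital" else "bg_regular"], rng, jit)
    skin = _jitter_color(COLORS["skin"], rng, jit)
    if spec.clothing == "scrubs":
        cloth = _jitter_color(COLORS["scrubs"], rng, jit)
    else:
        cloth = _jitter_color(COLORS["white_coat" if spec.white_coat else "casual"], rng, jit)
    gown_c = _jitter_color(COLORS["gown"], rng, jit)
    mask_c = _jitter_color(COLORS["mask"], rng, jit)
    glove_c = _jitter_color(COLORS["glove"], rng, jit)
    pants = _jitter_color(COLORS["pants"], rng, jit)

    img = Image.new("RGB", (w, h), bg)
    draw = ImageDraw.Draw(img)

    # background furniture: deterministic per style id, independent of seed
    style_rng = np.random.default_rng(1000 + spec.background_style)
    for _ in range(3):
        x0, y0 = style_rng.uniform(0, w), style_rng.uniform(0, h)
        bw, bh = style_rng.uniform(0.1, 0.4) * w, style_rng.uniform(0.05, 0.3) * h
        shade = tuple(int(np.clip(v + style_rng.uniform(-30, 30), 0, 255)) for v in bg)
        draw.rectangle([x0, y0, x0 + bw, y0 + bh], fill=shade)

    lw = max(2, int(0.12 * s))
    # legs
    for side in ("left", "right"):
        draw.line([pt[f"{side}_hip"], pt[f"{side}_knee"]], fill=pants, width=lw)
        draw.line([pt[f"{side}_knee"], pt[f"{side}_ankle"]], fill=pants, width=lw)
    # arms (sleeves follow the torso garment)
    sleeve = gown_c if spec.ppe.gown else cloth
    for side in ("left", "right"):
        draw.line([pt[f"{side}_shoulder"], pt[f"{side}_elbow"]], fill=sleeve, width=lw)
        draw.line([pt[f"{side}_elbow"], pt[f"{side}_wrist"]], fill=sleeve, width=lw)
    # torso panel spanning shoulders to hips
    x0 = min(pt["right_shoulder"][0], pt["right_hip"][0]) - 0.06 * s
    x1 = max(pt["left_shoulder"][0], pt["left_hip"][0]) + 0.06 * s
    y0 = pt["right_shoulder"][1] - 0.05 * s
    y1 = pt["right_hip"][1] + 0.12 * s
    draw.rectangle([x0, y0, x1, y1], fill=gown_c if spec.ppe.gown else cloth)
    # head
    hx, hy = pt["nose"]
    r = 0.28 * s
    draw.ellipse([hx - r, hy - r - 0.05 * s, hx + r, hy + r], fill=skin)
    # eyes
    er = max(1, int(0.03 * s))
    for eye in ("left_eye", "right_eye"):
        ex, ey = pt[eye]
        draw.ellipse([ex - er, ey - er, ex + er, ey + er], fill=(40, 30, 30))
    # mask over the lower face, anchored at the nose
    if spec.ppe.mask:
        draw.rectangle(
            [hx - 0.16 * s, hy - 0.03 * s, hx + 0.16 * s, hy + 0.20 * s], fill=mask_c
        )
    # hands at the extrapolated palm centres
    pr = 0.16 * s
    for side in ("left", "right"):
        elbow = np.asarray(pt[f"{side}_elbow"])
        wrist = np.asarray(pt[f"{side}_wrist"])
        palm = wrist + 0.5 * (wrist - elbow)
        gloved = spec.ppe.glove_left if side == "left" else spec.ppe.glove_right
        color = glove_c if gloved else skin
        draw.ellipse([palm[0] - pr, palm[1] - pr, palm[0] + pr, palm[1] + pr], fill=color)

    arr = np.asarray(img, dtype=np.float64)
    if spec.noise_sigma > 0:
        arr = arr + rng.normal(0.0, spec.noise_sigma, arr.shape)
    arr = np.clip(arr, 0, 255).astype(np.uint8)
    return Scene(arr, lm, spec.ppe, spec.tags())


# --- oracle colour rule -----------------------------------------------

_ITEM_COLOR = {"mask": "mask", "gloves": "glove", "gown": "gown"}


def ppe_color_fraction(crop_img: np.ndarray, item: str, tol: float = _ORACLE_TOL) -> float:
    """Fraction of crop pixels within *tol* (Euclidean RGB) of the item's hue."""
    base = np.asarray(COLORS[_ITEM_COLOR[item]], dtype=float)
    dist = np.linalg.norm(crop_img.astype(float) - base, axis=-1)
    return float(np.mean(dist < tol))


def oracle_color_rule(crop_img: np.ndarray, item: str) -> bool:
    """Deterministic colour-rule classifier: is the item's hue present?

    Perfect on renderer output below :data:`SEPARABLE_JITTER`; used as an
    independent check and as 'oracle head' in pipeline tests.
    """
    return ppe_color_fraction(crop_img, item) >= _ORACLE_MIN_FRACTION


# --- dataset generation ------------------------------------------------

_REGION_ITEM = {"face": "mask", "torso": "gown", "left_palm": "gloves", "right_palm": "gloves"}


def _random_spec(rng: np.random.Generator, ppe: PPEState, jitter: float, noise_sigma: float) -> SceneSpec:
    return SceneSpec(
        center=(128 + rng.uniform(-12, 12), 110 + rng.uniform(-8, 8)),
        scale=float(rng.uniform(46, 62)),
        ppe=ppe,
        clothing=str(rng.choice(["scrubs", "casual"])),
        scenery=str(rng.choice(["hospital", "regular"])),
        background_style=int(rng.integers(0, 4)),
        jitter=jitter,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n_per_class: int,
    region_kind: str,
    jitter: float = 0.1,
    noise_sigma: float = 4.0,
    seed: int = 0,
    geometry: GeometryConfig | None = None,
    out_dir=None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Balanced labelled crops for one region's item.

    ``region_kind`` is one of face, torso, left_palm, right_palm, or
    "palm" (alternating sides, mirroring that palm data comes from both
    hands).  Returns (crops (2n, 224, 224, 3), labels (2n,), manifest)
    where the manifest carries confounder tags per crop.  With
    ``out_dir`` set, crops are saved as PNGs and the manifest as CSV.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    cfg = geometry or GeometryConfig()
    rng = np.random.default_rng(seed)
    kinds = (
        ["left_palm", "right_palm"] if region_kind == "palm" else [region_kind]
    )
    if any(k not in _REGION_ITEM for k in kinds):
        raise ValueError(f"unknown region kind {region_kind!r}")
    crops, labels, rows = [], [], []
    total = 2 * n_per_class
    for i in range(total):
        label = i < n_per_class  # first half positive, balanced by construction
        kind = kinds[i % len(kinds)]
        item = _REGION_ITEM[kind]
        gl = bool(rng.integers(0, 2))
        state = {
            "mask": bool(rng.integers(0, 2)),
            "gown": bool(rng.integers(0, 2)),
            "glove_left": gl,
            "glove_right": gl,
        }
        if item == "gloves":
            state["glove_left" if kind == "left_palm" else "glove_right"] = label
        else:
            state[item] = label
        spec = _random_spec(rng, PPEState(**state), jitter, noise_sigma)
        scene = render_scene(spec)
        region = build_region(kind, scene.landmarks, cfg)
        assert region is not None, "canonical layout must yield a region"
        cr = crop_region(scene.image, region, cfg)
        assert cr is not None, "canonical layout crop must intersect the frame"
        crops.append(cr.image)
        labels.append(int(label))
        rows.append(
            {
                "crop_path": f"crop_{i:05d}_{kind}.png",
                "region_kind": kind,
                "label": int(label),
                "participant_id": int(i % 11),
                **scene.tags,
            }
        )
    manifest = pd.DataFrame(rows)
    X = np.stack(crops)
    y = np.asarray(labels)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for img, row in zip(X, manifest.itertuples()):
            Image.fromarray(img).save(os.path.join(out_dir, row.crop_path))
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return X, y, manifest


# --- events -------------------------------------------------------------

@dataclass(frozen=True)
class EventSpec:
    """A staged episode: one person walks laterally through the frame
    in a fixed PPE permutation."""

    n_frames: int = 25
    ppe: PPEState = field(default_factory=PPEState)
    start_x: float = 100.0
    end_x: float = 156.0
    center_y: float = 110.0
    scale: float = 54.0
    clothing: str = "scrubs"
    scenery: str = "hospital"
    background_style: int = 0
    jitter: float = 0.1
    noise_sigma: float = 4.0
    hidden: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("an event needs at least one frame")


def generate_event(spec: EventSpec) -> list[Scene]:
    """Ordered frames of one event; landmark trajectory is continuous."""
    rng = np.random.default_rng(spec.seed)
    xs = np.linspace(spec.start_x, spec.end_x, spec.n_frames)
    frames = []
    for x in xs:
        frames.append(
            render_scene(
                SceneSpec(
                    center=(float(x), spec.center_y),
                    scale=spec.scale,
                    ppe=spec.ppe,
                    hidden=spec.hidden,
                    clothing=spec.clothing,
                    scenery=spec.scenery,
                    background_style=spec.background_style,
                    jitter=spec.jitter,
                    noise_sigma=spec.noise_sigma,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
        )
    return frames
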