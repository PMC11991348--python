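"""End-to-end frame processing and run aggregation.

Per frame: pose -> region visibility -> square crops -> three binary
classifiers -> item verdicts.  Items map to regions as mask<-face,
gown<-torso, gloves<-both palms; the gloves verdict is true only if
*every visible* palm is predicted gloved (a single visible palm decides
alone), so mixed gloving counts as non-adherent.

Correctness of a frame follows the visible-regions rule: a frame is
"correct" (no misclassified regions) when every visible region's
prediction matches ground truth; the relaxed "no misclassified mask or
gown" variant restricts that to the face and torso regions, isolating
the weaker glove model's impact.

Event-level verdicts (majority vote over the sampled frames, ties
non-adherent) extend the frame-level protocol and are reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .classifiers import RandomProjectionFeatureExtractor, RegionPPEClassifier
from .geometry import GeometryConfig, REGION_KINDS
from .pose import PoseProvider
from .stats import ConfusionMatrix2x2

#: item assessed from each region kind
REGION_ITEM = {"face": "mask", "torso": "gown", "left_palm": "gloves", "right_palm": "gloves"}
ITEMS = ("mask", "gloves", "gown")

#: ground-truth label key per region kind
REGION_TRUTH_KEY = {
    "face": "mask",
    "torso": "gown",
    "left_palm": "glove_left",
    "right_palm": "glove_right",
}


@dataclass(frozen=True)
class RegionOutcome:
    """One region's classification within a frame."""

    kind: str
    visible: bool
    probability: float | None = None
    prediction: bool | None = None
    inside_fraction: float | None = None
    region: geometry.SquareRegion | None = None


@dataclass(frozen=True)
class FrameResult:
    """Visibility flags and per-region/per-item predictions for one frame."""

    frame_id: str
    regions: dict[str, RegionOutcome]
    items: dict[str, bool | None]  # None = not assessable in this frame

    def to_json_dict(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "regions": {
                k: {
                    "visible": r.visible,
                    "probability": r.probability,
                    "prediction": r.prediction,
                    "inside_fraction": r.inside_fraction,
                }
                for k, r in self.regions.items()
            },
            "items": dict(self.items),
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "FrameResult":
        regions = {
            k: RegionOutcome(
                kind=k,
                visible=r["visible"],
                probability=r.get("probability"),
                prediction=r.get("prediction"),
                inside_fraction=r.get("inside_fraction"),
            )
            for k, r in d["regions"].items()
        }
        return cls(d["frame_id"], regions, dict(d["items"]))


def sample_frames(frames: Sequence, ratio: int = 5) -> list:
    """Keep every *ratio*-th frame starting at index 0 (the 1:5 sampler)."""
    if ratio < 1:
        raise ValueError("sampling ratio denominator must be >= 1")
    return list(frames[::ratio])


def process_frame(
    image: np.ndarray,
    pose: PoseProvider,
    heads: Mapping[str, RegionPPEClassifier],
    extractor: RandomProjectionFeatureExtractor,
    cfg: GeometryConfig | None = None,
    frame_id: str = "",
) -> FrameResult:
    """Classify every visible region of one frame and aggregate to items."""
    cfg = cfg or GeometryConfig()
    missing = [i for i in ITEMS if i not in heads]
    if missing:
        raise ValueError(f"missing trained heads for items: {missing}")
    img = np.asarray(image)
    lm = pose.estimate(img, frame_id=frame_id)
    h, w = img.shape[:2]
    vis = geometry.visible_regions(lm, (w, h), cfg)

    regions: dict[str, RegionOutcome] = {}
    for kind in REGION_KINDS:
        if kind not in vis:
            regions[kind] = RegionOutcome(kind, visible=False)
            continue
        region = geometry.build_region(kind, lm, cfg)
        cr = geometry.crop(img, region, cfg) if region is not None else None
        if cr is None:  # degenerate geometry or window off-frame
            regions[kind] = RegionOutcome(kind, visible=False)
            continue
        feats = extractor.transform(cr.image)
        head = heads[REGION_ITEM[kind]]
        prob = float(head.predict_proba(feats))
        regions[kind] = RegionOutcome(
            kind,
            visible=True,
            probability=prob,
            prediction=bool(prob >= head.decision_threshold),
            inside_fraction=cr.inside_fraction,
            region=region,
        )

    items: dict[str, bool | None] = {}
    items["mask"] = regions["face"].prediction if regions["face"].visible else None
    items["gown"] = regions["torso"].prediction if regions["torso"].visible else None
    palms = [regions[k] for k in ("left_palm", "right_palm") if regions[k].visible]
    if not palms:
        items["gloves"] = None
    else:
        items["gloves"] = all(p.prediction for p in palms)
    return FrameResult(frame_id, regions, items)


@dataclass(frozen=True)
class FrameScore:
    """Correctness flags of one frame against ground truth.

    Flags are ``None`` when no region contributes to that definition
    (nothing visible), mirroring the manual cleaning of unassessable
    frames.
    """

    frame_id: str
    all_regions_correct: bool | None
    mask_gown_correct: bool | None
    region_correct: dict[str, bool]  # visible regions only
    tags: dict[str, str] = field(default_factory=dict)


def score_frame(
    result: FrameResult,
    truth: Mapping[str, bool],
    tags: Mapping[str, str] | None = None,
) -> FrameScore:
    """Compare visible-region predictions with ground truth.

    *truth* holds the item labels keyed mask/gown/glove_left/glove_right.
    Invisible regions are ignored — only visible regions count toward
    correctness.
    """
    region_correct: dict[str, bool] = {}
    for kind, outcome in result.regions.items():
        if not outcome.visible:
            continue
        key = REGION_TRUTH_KEY[kind]
        if key not in truth:
            raise ValueError(f"truth missing label {key!r} for visible region {kind}")
        region_correct[kind] = bool(outcome.prediction) == bool(truth[key])
    mg = {k: v for k, v in region_correct.items() if k in ("face", "torso")}
    return FrameScore(
        frame_id=result.frame_id,
        all_regions_correct=all(region_correct.values()) if region_correct else None,
        mask_gown_correct=all(mg.values()) if mg else None,
        region_correct=region_correct,
        tags=dict(tags or {}),
    )


@dataclass(frozen=True)
class RunSummary:
    """Aggregated accuracy table for a scored run."""

    counts: pd.DataFrame  # definition x (correct, incorrect, accuracy)
    region_confusions: dict[str, ConfusionMatrix2x2]
    strata: pd.DataFrame | None = None


def _accuracy_row(flags: list[bool]) -> dict:
    correct = int(sum(flags))
    incorrect = len(flags) - correct
    return {
        "correct": correct,
        "incorrect": incorrect,
        "accuracy": correct / len(flags) if flags else float("nan"),
    }


def aggregate_run(
    results: Sequence[FrameResult],
    truths: Sequence[Mapping[str, bool]],
    tags: Sequence[Mapping[str, str]] | None = None,
    stratify_by: Sequence[str] = (),
) -> RunSummary:
    """Counts of correct/incorrect frames per definition, per-region
    confusion matrices, and optional stratified counts by tag."""
    if len(results) != len(truths):
        raise ValueError("results and truths must align")
    if not results:
        raise ValueError("nothing to aggregate")
    tags = tags or [{}] * len(results)
    scores = [score_frame(r, t, g) for r, t, g in zip(results, truths, tags)]

    rows = {}
    for name, attr in (
        ("no_misclassified_regions", "all_regions_correct"),
        ("no_misclassified_mask_or_gown", "mask_gown_correct"),
    ):
        flags = [getattr(s, attr) for s in scores if getattr(s, attr) is not None]
        rows[name] = _accuracy_row(flags)
    counts = pd.DataFrame(rows).T

    confusions: dict[str, ConfusionMatrix2x2] = {}
    for kind in REGION_KINDS:
        key = REGION_TRUTH_KEY[kind]
        cells = {"a": 0, "b": 0, "c": 0, "d": 0}
        for res, truth in zip(results, truths):
            outcome = res.regions.get(kind)
            if outcome is None or not outcome.visible:
                continue
            t, p = bool(truth[key]), bool(outcome.prediction)
            cells["a" if (t and p) else "b" if t else "c" if p else "d"] += 1
        if sum(cells.values()):
            confusions[kind] = ConfusionMatrix2x2(**cells)

    strata_df = None
    if stratify_by:
        recs = []
        for tag in stratify_by:
            groups: dict[str, list[bool]] = {}
            for s in scores:
                if s.all_regions_correct is None:
                    continue
                g = s.tags.get(tag)
                if g is None:
                    raise ValueError(f"unknown stratum tag {tag!r} on frame {s.frame_id}")
                groups.setdefault(g, []).append(s.all_regions_correct)
            for g, flags in sorted(groups.items()):
                recs.append({"tag": tag, "group": g, **_accuracy_row(flags)})
        strata_df = pd.DataFrame(recs)
    return RunSummary(counts, confusions, strata_df)


@dataclass(frozen=True)
class EventResult:
    """Majority-vote item verdicts over an event's sampled frames."""

    event_id: str
    frame_results: list[FrameResult]
    verdicts: dict[str, bool | None]
    correct: dict[str, bool | None]


def aggregate_event(
    event_id: str,
    frame_results: Sequence[FrameResult],
    truth: Mapping[str, bool],
) -> EventResult:
    """Event verdict per item: majority vote over frames where the item
    was assessable; ties count as non-adherent; no assessable frame
    leaves the item undecided (None)."""
    verdicts: dict[str, bool | None] = {}
    correct: dict[str, bool | None] = {}
    item_truth = {
        "mask": bool(truth["mask"]),
        "gown": bool(truth["gown"]),
        "gloves": bool(truth["glove_left"]) and bool(truth["glove_right"]),
    }
    for item in ITEMS:
        votes = [r.items[item] for r in frame_results if r.items[item] is not None]
        if not votes:
            verdicts[item] = None
            correct[item] = None
            continue
        positive = sum(votes)
        verdicts[item] = positive * 2 > len(votes)  # tie -> non-adherent
        correct[item] = verdicts[item] == item_truth[item]
    return EventResult(event_id, list(frame_results), verdicts, correct)
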