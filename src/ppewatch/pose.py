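"""Pose-provider contract: image -> LandmarkSet.

The monitoring pipeline only needs landmark locations; it never trains
or evaluates the pose model itself.  Two providers are shipped:

* :class:`GroundTruthPoseProvider` — returns the known landmark layout
  of a synthetic scene (confidence 1 for rendered joints, 0 for joints
  flagged hidden).  This is the test surface.
* :class:`ExternalPoseModel` — an adapter slot for a real lightweight
  pose network supplied by the user as a callable; single-person only.

Both are deterministic: the same image (and frame id) always yields the
same landmark set.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Callable, Mapping

import numpy as np

from .geometry import LandmarkSet


class PoseProvider(ABC):
    """Maps an RGB image to a single person's 17-keypoint landmark set."""

    name: str = "abstract"
    kind: str = "abstract"

    @abstractmethod
    def estimate(self, image: np.ndarray, frame_id: str | None = None) -> LandmarkSet:
        """Estimate landmarks for the (single) person in *image*.

        When no person can be described, all confidences are 0 and
        downstream treats every region as not visible.
        """

    @staticmethod
    def _check_image(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image)
        if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
            raise ValueError("image must be RGB with positive dimensions")
        return img


class GroundTruthPoseProvider(PoseProvider):
    """Looks landmarks up from known per-frame ground truth.

    Built from a mapping ``frame_id -> LandmarkSet`` (as produced by the
    synthetic-scene renderer).  Frames without an entry return an
    all-undetected pose rather than raising.
    """

    name = "ground_truth"
    kind = "ground_truth"

    def __init__(self, landmarks: Mapping[str, LandmarkSet]):
        self._landmarks = dict(landmarks)

    def estimate(self, image: np.ndarray, frame_id: str | None = None) -> LandmarkSet:
        self._check_image(image)
        if frame_id is None or frame_id not in self._landmarks:
            return LandmarkSet.all_undetected()
        return self._landmarks[frame_id]


class ExternalPoseModel(PoseProvider):
    """Adapter for an external single-person pose network.

    *infer* is any callable ``image -> LandmarkSet`` (e.g. a wrapper
    around an exported lightweight pose model).  The adapter exists so a
    real detector can be dropped in without touching the pipeline; it is
    not exercised by the shipped tests.
    """

    kind = "external_model"

    def __init__(self, infer: Callable[[np.ndarray], LandmarkSet], name: str = "external"):
        if not callable(infer):
            raise TypeError("infer must be a callable image -> LandmarkSet")
        self._infer = infer
        self.name = name

    def estimate(self, image: np.ndarray, frame_id: str | None = None) -> LandmarkSet:
        img = self._check_image(image)
        lm = self._infer(img)
        if not isinstance(lm, LandmarkSet):
            raise TypeError("external pose model must return a LandmarkSet")
        return lm
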