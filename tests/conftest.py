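import numpy as np
import pytest

import ppewatch as pw

# Documented study-condition seeds for the synthetic training datasets.
HEAD_SEEDS = {"mask": 1, "gloves": 2, "gown": 3}
HEAD_REGIONS = {"mask": "face", "gloves": "palm", "gown": "torso"}
N_PER_CLASS = 200


@pytest.fixture(scope="session")
def extractor():
    return pw.RandomProjectionFeatureExtractor(seed=0).fit()


@pytest.fixture(scope="session")
def trained_heads(extractor):
    """The three region heads trained on 200 crops per class each."""
    heads = {}
    for item, rs in HEAD_SEEDS.items():
        X, y, _ = pw.generate_dataset(N_PER_CLASS, HEAD_REGIONS[item], seed=40 + rs)
        heads[item] = pw.RegionPPEClassifier(random_state=rs).fit(extractor.transform(X), y)
    return heads


@pytest.fixture
def cfg():
    return pw.GeometryConfig()


@pytest.fixture
def full_scene():
    """A full-PPE scene with every landmark visible."""
    return pw.render_scene(pw.SceneSpec(seed=7))


class IdentityExtractor:
    """Passes crops straight through so oracle heads can inspect pixels."""

    def transform(self, X):
        return X


class OracleHead:
    """Colour-rule 'classifier' — perfect on low-jitter synthetic crops."""

    decision_threshold = 0.5

    def __init__(self, item: str):
        self.item = item

    def predict_proba(self, crop_img):
        return 1.0 if pw.oracle_color_rule(np.asarray(crop_img), self.item) else 0.0


@pytest.fixture
def oracle_setup():
    heads = {item: OracleHead(item) for item in ("mask", "gloves", "gown")}
    return heads, IdentityExtractor()
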