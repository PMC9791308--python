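import numpy as np
import pytest

from histoweak.slide_io import FeatureBag, Manifest, SlideRecord, parse_label


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_manifest(n=12, labs=("lab1", "lab2", "lab3"), labels=None):
    """Small synthetic manifest cycling labels/labs deterministically."""
    label_cycle = labels or ["malignant", "benign_other", "insufficient"]
    records = []
    for i in range(n):
        records.append(
            SlideRecord(
                slide_id=f"s{i:03d}",
                image_uri=f"mem://{i}",
                label=parse_label(label_cycle[i % len(label_cycle)]),
                subcategory=f"sub{i % 2}",
                site=f"site{i % 2}",
                lab=labs[i % len(labs)],
            )
        )
    return Manifest(records)


@pytest.fixture
def small_manifest():
    return make_manifest()


def random_bag(rng, n=6, dim=16, slide_id="bag"):
    feats = rng.standard_normal((n, dim)).astype(np.float32)
    coords = np.stack(
        [np.arange(n) * 256, np.zeros(n, dtype=int)], axis=1
    ).astype(np.int64)
    return FeatureBag(slide_id, feats, coords, patch_size=256)


@pytest.fixture
def bag_factory(rng):
    def make(n=6, dim=16, slide_id="bag"):
        return random_bag(rng, n, dim, slide_id)

    return make
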