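import numpy as np
import pandas as pd
import pytest

from trapdiv.boxes import Box
from trapdiv.detect import Detection, GroundTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """Six traps x four taxa with heterogeneous totals."""
    return pd.DataFrame(
        {
            "Nematocera": [8, 5, 12, 0, 3, 7],
            "Ephemeroptera": [2, 1, 0, 4, 1, 2],
            "Coleoptera": [1, 3, 2, 1, 0, 1],
            "Hemiptera": [0, 2, 1, 2, 5, 1],
        },
        index=pd.Index([f"T{i}" for i in range(1, 7)], name="trap_id"),
    )


@pytest.fixture
def lifecycles():
    return {
        "Nematocera": "aquatic",
        "Ephemeroptera": "aquatic",
        "Trichoptera": "aquatic",
        "Coleoptera": "terrestrial",
        "Hemiptera": "terrestrial",
        "Brachycera": "terrestrial",
        "Hymenoptera": "terrestrial",
    }


def det(conf, x=0.0, y=0.0, w=10.0, h=10.0, fold=1, cls="Nematocera",
        image="T1_A", side="A"):
    return Detection(image, side, fold, cls, Box(x, y, w, h), conf)


def truth(x=0.0, y=0.0, w=10.0, h=10.0, cls="Nematocera", image="T1_A",
          side="A", tid=0):
    return GroundTruth(image, side, cls, Box(x, y, w, h), tid)


@pytest.fixture
def make_detection():
    return det


@pytest.fixture
def make_truth():
    return truth
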