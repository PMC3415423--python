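import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

from idrscape.records import (
    ModType,
    PredictorTrack,
    ProteinRecord,
    PTMSite,
    Region,
    RegionClass,
    TrackCategory,
)
from idrscape.synthetic import SyntheticConfig, generate_proteome


@pytest.fixture(scope="session")
def small_bundle():
    """A 5-protein noise-free synthetic bundle with planted truth."""
    cfg = SyntheticConfig(n_proteins=5, epsilon=0.0, seed=11)
    return generate_proteome(cfg)


@pytest.fixture
def tiny_proteome():
    return [
        ProteinRecord("p1", "MKR"),
        ProteinRecord("p2", "GGSA"),
    ]


def disorder_track(pid, values, predictor="d0"):
    return PredictorTrack(pid, predictor, TrackCategory.DISORDER, tuple(values))


def ss_track(pid, labels, predictor="s0"):
    return PredictorTrack(
        pid, predictor, TrackCategory.SECONDARY_STRUCTURE, tuple(labels)
    )


def binary_track(pid, category, values, predictor="b0"):
    return PredictorTrack(pid, predictor, category, tuple(values))


@pytest.fixture
def simple_regions():
    return [
        Region("p1", 1, 10, RegionClass.STRUCTURAL_ORDER),
        Region("p1", 11, 40, RegionClass.RS_LIKE, frozenset("RS")),
        Region("p1", 41, 60, RegionClass.OTHER_DISORDER),
    ]
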