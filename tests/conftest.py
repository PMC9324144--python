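import numpy as np
import pandas as pd
import pytest

from paleoresil.data_model import (
    BathymetryCensus,
    CommunityMatrix,
    SampleMetadata,
    SpeciesTraits,
)


@pytest.fixture
def small_cm():
    """Six samples (2 per interval) x 4 species, integer counts."""
    counts = pd.DataFrame(
        [
            [30, 5, 1, 0],
            [28, 6, 0, 2],
            [2, 10, 20, 8],
            [1, 12, 18, 9],
            [31, 4, 2, 1],
            [29, 7, 1, 0],
        ],
        index=["lig1", "lig2", "lg1", "lg2", "cig1", "cig2"],
        columns=["spA", "spB", "spC", "spD"],
        dtype=float,
    )
    return CommunityMatrix(counts)


@pytest.fixture
def small_meta():
    table = pd.DataFrame(
        {
            "interval": ["LIG", "LIG", "LG", "LG", "CIG", "CIG"],
            "core_id": ["c1", "c1", "c2", "c2", "c3", "c3"],
            "environment": ["nearshore"] * 6,
        },
        index=["lig1", "lig2", "lg1", "lg2", "cig1", "cig2"],
    )
    return SampleMetadata(table)


@pytest.fixture
def small_traits():
    table = pd.DataFrame(
        {
            "biogeo_class": ["MED/LUS", "WAF", "COS", "BOR"],
            "habitat": ["marine"] * 4,
        },
        index=["spA", "spB", "spC", "spD"],
    )
    return SpeciesTraits(table)


@pytest.fixture
def small_census():
    records = pd.DataFrame(
        {
            "species_id": ["spA", "spA", "spB", "spC", "spD"],
            "depth_m": [2.0, 5.0, 4.0, 8.0, 1.0],
            "live_abundance": [2, 1, 3, 0, 5],
            "dead_abundance": [0, 0, 1, 4, 0],
        }
    )
    return BathymetryCensus(records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
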