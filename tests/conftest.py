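import numpy as np
import pytest

from funred.core import (
    CommunityProfileSet,
    FunctionSet,
    GenomeCatalog,
    GenomeRecord,
    MetadataRecord,
)
from funred.mapping import OtuGenomeMap


@pytest.fixture
def cellulase_like() -> FunctionSet:
    return FunctionSet("cellulases", frozenset({"GH5", "GH6"}))


@pytest.fixture
def tiny_catalog() -> GenomeCatalog:
    """Three genomes: two in one genus, one in another; varied traits."""
    return GenomeCatalog(
        [
            GenomeRecord("G1", "pA", "pA.c1", "pA.c1.g1", 2, {"GH5": 4, "GH18": 1}),
            GenomeRecord("G2", "pA", "pA.c1", "pA.c1.g1", 1, {"GH5": 0, "GH18": 2}),
            GenomeRecord("G3", "pB", "pB.c1", "pB.c1.g2", 4, {"GH5": 2, "GH6": 1}),
        ]
    )


@pytest.fixture
def tiny_map() -> OtuGenomeMap:
    return OtuGenomeMap(
        assignments={"O1": "G1", "O2": "G2", "O3": "G3"},
        unassigned={"O4"},
    )


@pytest.fixture
def tiny_profileset() -> CommunityProfileSet:
    counts = np.array(
        [
            [100, 50, 0, 7],
            [0, 20, 30, 0],
        ]
    )
    meta = {
        "S1": MetadataRecord(environment_level1="free-living", ph=6.5),
        "S2": MetadataRecord(environment_level1="host-associated", ph=7.5),
    }
    return CommunityProfileSet(
        ["S1", "S2"], ["O1", "O2", "O3", "O4"], counts, meta
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240702)
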