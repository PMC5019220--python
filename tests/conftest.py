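import numpy as np
import pandas as pd
import pytest

from hv2pop import Alignment, PopulationMap, make_fixture_suite, read_alignment
from hv2pop.spatial import GeoLayout


@pytest.fixture
def toy_aln() -> Alignment:
    """Four 4-bp sequences: the worked example used throughout the suite."""
    return Alignment(["s1", "s2", "s3", "s4"], ["AAAA", "AAAT", "AATT", "AATT"])


@pytest.fixture
def toy_pm(toy_aln) -> PopulationMap:
    return PopulationMap(
        pd.DataFrame(
            {"sample_id": toy_aln.ids, "population": ["P1", "P1", "P2", "P2"]}
        )
    )


def _two_pop_map(ids, n1):
    return PopulationMap(
        pd.DataFrame(
            {
                "sample_id": ids,
                "population": ["P1"] * n1 + ["P2"] * (len(ids) - n1),
            }
        )
    )


@pytest.fixture
def fixed_diff_aln():
    """Two populations each fixed for a different haplotype."""
    aln = Alignment([f"s{i}" for i in range(8)], ["AAAA"] * 4 + ["AAAT"] * 4)
    return aln, _two_pop_map(aln.ids, 4)


@pytest.fixture
def shared_hap_aln():
    """pop1 = {h1,h1,h1,h2}, pop2 = {h2,h2,h2,h1}, d(h1,h2) = 1."""
    h1, h2 = "AAAA", "AAAT"
    aln = Alignment(
        [f"s{i}" for i in range(8)], [h1, h1, h1, h2, h2, h2, h2, h1]
    )
    return aln, _two_pop_map(aln.ids, 4)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out, seed=2024)


@pytest.fixture(scope="session")
def paper_shaped(fixture_suite):
    d = fixture_suite["paper_shaped"]
    aln, pm = read_alignment(d / "sequences.fasta", d / "popmap.tsv")
    layout = GeoLayout.from_tsv(d / "coords.tsv")
    return aln, pm, layout


@pytest.fixture(scope="session")
def barrier_dataset(fixture_suite):
    d = fixture_suite["barrier_2deme"]
    aln, pm = read_alignment(d / "sequences.fasta", d / "popmap.tsv")
    layout = GeoLayout.from_tsv(d / "coords.tsv")
    return aln, pm, layout
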