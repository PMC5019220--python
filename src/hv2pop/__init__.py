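"""hv2pop: population-genetic analysis of mtDNA HV2 control-region data.

Diversity and neutrality statistics, sudden-expansion mismatch dating,
K2P/PhiST differentiation with NJ and ordination, hierarchical AMOVA,
Mantel isolation-by-distance and Monmonier genetic barriers, plus a
coalescent generator for synthetic datasets.
"""

from importlib import resources as _resources

from .alignment import (
    Alignment,
    AlignmentError,
    MetadataError,
    PopulationMap,
    polymorphic_sites,
    read_alignment,
    write_fasta,
)
from .haplotypes import (
    HaplogroupMotifTable,
    HaplotypeTable,
    assign_all,
    assign_haplogroup,
    collapse_haplotypes,
)
from .diversity import (
    DiversitySummary,
    NeutralityResult,
    diversity_table,
    haplotype_diversity,
    pairwise_diff_stats,
    tajima_constants,
    tajima_d_from_summaries,
    tajimas_d,
)
from .mismatch import (
    DEFAULT_MU_SITE_PER_YEAR,
    ExpansionFit,
    MismatchObservation,
    expansion_time,
    expected_mismatch,
    fit_expansion,
    fit_population,
    gof_bootstrap,
    observed_mismatch,
    raggedness,
)
from .distance import (
    OrdinationResult,
    PopDistanceMatrix,
    SaturationError,
    TreeResult,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    ordinate,
    pairwise_phist,
    phist_from_d2,
    pop_distance_matrix,
)
from .amova import AmovaResult, GroupingScheme, amova
from .spatial import (
    BarrierResult,
    GeoLayout,
    MantelResult,
    TriangulationGraph,
    barrier_sides,
    barrier_significance,
    delaunay,
    geo_distance_matrix,
    haversine_km,
    mantel,
    monmonier_barriers,
)
from .simulate import (
    ConstantSize,
    SimulationConfig,
    SplitModel,
    SuddenExpansion,
    make_fixture_suite,
    simulate_sample,
)
from .pipeline import RunConfig, run_diversity, run_mismatch, run_structure

__version__ = "0.1.0"


def packaged_data(name: str):
    """Path to a packaged data table (coordinates, groupings, motifs)."""
    return _resources.files("hv2pop.data").joinpath(name)
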