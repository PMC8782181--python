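"""condensate-profiler: assignment of proteins to P-bodies and stress
granules from multi-fraction IP proteomics profiles, with set-overlap,
enrichment and RNA sequence-feature analyses."""

from importlib.resources import files as _files

from .design import SampleKey, SampleSet, StudyDesign, granule_ip_design
from .granule_clustering import (
    ClusterSelection,
    FuzzyModel,
    GranuleAssignment,
    assign_membership,
    estimate_fuzzifier,
    fuzzy_cmeans,
    select_cluster_count,
)
from .quant_ingest import (
    ProfileMatrix,
    QuantTable,
    elution_filter,
    impute_downshift,
    impute_qrilc,
    ingest_pipeline,
    ip_filter,
    normalize_and_split,
    read_quant_table,
    rollup_and_average,
)
from .set_analysis import (
    GeneSet,
    OverlapResult,
    hypergeom_enrich,
    s0_ttest,
    set_overlap,
)
from .seq_features import (
    CountMatrix,
    TranscriptRecord,
    base_content,
    composition_profile,
    mannwhitney_compare,
    normalize_counts,
    polya_tracts,
    select_utrs,
    transcript_features,
    translational_efficiency,
)
from .synthetic_data import (
    NoiseSpec,
    ProteomeSimSpec,
    RipseqSimSpec,
    TranscriptGroupSpec,
    TruthLabels,
    generate_quant_dataset,
    generate_ripseq_counts,
    generate_transcript_set,
)

__version__ = "0.1.0"


def packaged_gene_set(name: str):
    """Load one of the packaged interactor lists.

    Available names: pre_pb, pb, pre_sg, sg — the bait-interactor tables
    for Dcp1-myc (P-body) and Pbp1-myc (stress granule) before and after
    glucose depletion.
    """
    from .set_analysis import read_gene_list

    path = _files("condensate_profiler.data").joinpath(f"{name}_proteins.txt")
    return read_gene_list(str(path), name=name)
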