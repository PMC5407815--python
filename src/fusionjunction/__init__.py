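"""fusionjunction: CNV + RNA-seq fusion-gene discovery and quantification.

A reusable implementation of a combined copy-number / junction-read
pipeline for tandem-duplication driven gene fusions (the KIAA1549-BRAF
class of rearrangements in pilocytic astrocytoma): CNV segment filtering
and breakpoint-gene candidate enumeration, 600 bp junction template
construction, spanning/split read-support extraction, normalized fusion
expression, and fusion transcript/protein reconstruction, together with a
synthetic-data generator emulating a six-sample study.
"""

from .reference_io import (
    Genome,
    TranscriptModel,
    load_genome,
    load_annotation,
    write_annotation,
    transcript_sequence,
    reverse_complement,
)
from .cnv_candidates import (
    CnvSegment,
    SegmentFilterParams,
    FusionCandidate,
    FusionCallRecord,
    filter_segments,
    genes_at_breakpoints,
    enumerate_fusions,
    cross_validate,
    load_cnv_table,
    write_cnv_table,
)
from .junction_templates import (
    JunctionTemplate,
    build_wildtype_junction,
    build_fusion_junction,
    anchor_sequence,
    write_templates,
    load_templates,
)
from .read_support import (
    FilterParams,
    ReadMatch,
    SupportEvidence,
    TemplateIndex,
    match_read,
    classify_pair,
    collect_evidence,
    collect_evidence_from_fastq,
)
from .expression_quant import (
    ExpressionRecord,
    FoldChange,
    normalized_expression,
    fold_change,
    group_fold_change,
)
from .fusion_protein import (
    FusionTranscript,
    FusionProteinReport,
    DomainAnnotation,
    PrimerPair,
    assemble_fusion_cds,
    classify_frame,
    translate_fusion,
    in_silico_pcr,
)
from .pipeline import (
    FusionDef,
    SampleInput,
    PipelineConfig,
    PipelineResult,
    run_pipeline,
    breakpoints_to_exons,
    build_template_set,
)
from .synthetic_data import (
    SimConfig,
    PlantCounts,
    Scaffold,
    TruthManifest,
    build_scaffold,
    apply_rearrangement,
    simulate_sample,
    simulate_study,
    study_pipeline_config,
)

__version__ = "0.1.0"
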