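"""End-to-end orchestration: CNV candidates -> templates -> read support ->
expression -> fusion proteins -> per-sample summary.

The pipeline consumes a reference genome (FASTA), transcript models
(BED12), a CNV segment table (TSV) covering one or more samples, and one
paired FASTQ set per sample.  Besides CNV-derived candidates, a list of
*screened* fusions (known junctions assayed in every sample, the in-silico
analogue of a targeted qPCR panel) can be supplied; read support is
collected for both, and a coding fusion is stated for a sample only when a
CNV call and read support agree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cnv_candidates import (
    CnvSegment,
    FusionCandidate,
    FusionCallRecord,
    SegmentFilterParams,
    candidates_to_frame,
    enumerate_fusions,
    filter_segments,
    load_cnv_table,
)
from .expression_quant import ExpressionRecord, normalized_expression
from .fusion_protein import (
    DomainAnnotation,
    FusionProteinReport,
    PrimerPair,
    assemble_fusion_cds,
    in_silico_pcr,
    translate_fusion,
)
from .junction_templates import (
    JunctionTemplate,
    build_fusion_junction,
    build_wildtype_junction,
    write_templates,
)
from .read_support import (
    FilterParams,
    SupportEvidence,
    collect_evidence,
    iter_fastq_pairs,
)
from .reference_io import Genome, TranscriptModel, load_annotation, load_genome

logger = logging.getLogger(__name__)

__all__ = [
    "FusionDef",
    "SampleInput",
    "PipelineConfig",
    "SampleResult",
    "PipelineResult",
    "breakpoints_to_exons",
    "build_template_set",
    "run_pipeline",
]


@dataclass(frozen=True)
class FusionDef:
    """A concrete fusion junction: partners, exons, insert, overlap rule."""

    five_gene: str
    last_exon5: int
    three_gene: str
    first_exon3: int
    insert: str = ""
    min_breakpoint_overlap: int = 2

    @property
    def name(self) -> str:
        return f"{self.five_gene}-{self.three_gene}"

    @property
    def template_id(self) -> str:
        return f"{self.name}_e{self.last_exon5}-e{self.first_exon3}"


@dataclass(frozen=True)
class SampleInput:
    sample_id: str
    reads1: str
    reads2: str


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    cnv_table: str
    samples: list[SampleInput]
    screen_fusions: list[FusionDef] = field(default_factory=list)
    inserts: dict[str, str] = field(default_factory=dict)
    min_overlap: dict[str, int] = field(default_factory=dict)
    filter_params: FilterParams = field(default_factory=FilterParams)
    segment_filter: SegmentFilterParams = field(default_factory=SegmentFilterParams)
    domains: list[DomainAnnotation] = field(default_factory=list)
    primers: list[PrimerPair] = field(default_factory=list)
    out_dir: str | None = None


@dataclass
class SampleResult:
    sample_id: str
    candidates: list[FusionCandidate]
    fusion_defs: list[FusionDef]
    templates: list[JunctionTemplate]
    evidence: dict[str, SupportEvidence]
    total_raw_reads: int
    expression: list[ExpressionRecord]
    call_records: list[FusionCallRecord]
    protein_reports: dict[str, FusionProteinReport]
    pcr_products: dict[str, list[int]]


@dataclass
class PipelineResult:
    candidates: list[FusionCandidate]
    samples: dict[str, SampleResult]
    summary: pd.DataFrame


def _transcript_for(gene: str, annotation: Sequence[TranscriptModel]) -> TranscriptModel:
    for tx in annotation:
        if tx.gene_name == gene:
            return tx
    raise ValueError(f"no transcript model for gene {gene!r}")


def breakpoints_to_exons(
    candidate: FusionCandidate, annotation: Sequence[TranscriptModel]
) -> FusionDef:
    """Map a candidate's genomic breakpoints to fusion exon indices.

    The 5' partner keeps every exon transcribed before its breakpoint, the
    3' partner contributes every exon after its breakpoint.  Breakpoints
    must be intronic (or flanking) — a breakpoint inside an exon is an
    error, as exon-interrupting junctions are outside the splicing model.
    """
    tx5 = _transcript_for(candidate.five_gene, annotation)
    tx3 = _transcript_for(candidate.three_gene, annotation)

    def check_intronic(tx: TranscriptModel, pos: int):
        for a, b in tx.exons:
            if a <= pos < b:
                raise ValueError(
                    f"breakpoint {pos} lies inside an exon of {tx.gene_name}"
                )

    check_intronic(tx5, candidate.five_breakpoint)
    check_intronic(tx3, candidate.three_breakpoint)

    bp5 = candidate.five_breakpoint
    if tx5.strand == "+":
        retained5 = [i for i, (a, b) in enumerate(tx5.exons, 1) if b <= bp5]
    else:
        retained5 = [i for i, (a, b) in enumerate(tx5.exons, 1) if a >= bp5]
    if not retained5:
        raise ValueError(
            f"breakpoint {bp5} retains no exon of 5' partner {tx5.gene_name}"
        )
    last_exon5 = max(retained5)

    bp3 = candidate.three_breakpoint
    if tx3.strand == "+":
        retained3 = [i for i, (a, b) in enumerate(tx3.exons, 1) if a >= bp3]
    else:
        retained3 = [i for i, (a, b) in enumerate(tx3.exons, 1) if b <= bp3]
    if not retained3:
        raise ValueError(
            f"breakpoint {bp3} retains no exon of 3' partner {tx3.gene_name}"
        )
    first_exon3 = min(retained3)
    return FusionDef(
        five_gene=candidate.five_gene,
        last_exon5=last_exon5,
        three_gene=candidate.three_gene,
        first_exon3=first_exon3,
    )


def build_template_set(
    genome: Genome,
    annotation: Sequence[TranscriptModel],
    fusion_defs: Sequence[FusionDef],
) -> list[JunctionTemplate]:
    """Fusion templates plus the wild-type junction of each partner side.

    For a fusion joining exon i of the 5' gene to exon j of the 3' gene,
    the comparison wild-type junctions are (i, i+1) in the 5' gene and
    (j-1, j) in the 3' gene, when those exist.
    """
    templates: dict[str, JunctionTemplate] = {}
    for fd in fusion_defs:
        tx5 = _transcript_for(fd.five_gene, annotation)
        tx3 = _transcript_for(fd.three_gene, annotation)
        ft = build_fusion_junction(
            tx5,
            fd.last_exon5,
            tx3,
            fd.first_exon3,
            fd.insert,
            genome,
            min_breakpoint_overlap=fd.min_breakpoint_overlap,
        )
        templates.setdefault(ft.template_id, ft)
        if fd.last_exon5 < tx5.n_exons:
            wt = build_wildtype_junction(tx5, fd.last_exon5, genome)
            templates.setdefault(wt.template_id, wt)
        if fd.first_exon3 > 1:
            wt = build_wildtype_junction(tx3, fd.first_exon3 - 1, genome)
            templates.setdefault(wt.template_id, wt)
    return list(templates.values())


def _counting_pairs(path1: str, path2: str, counter: list[int]):
    for rid, s1, s2 in iter_fastq_pairs(path1, path2):
        counter[0] += 2
        yield rid, s1, s2


def _fusion_defs_for_sample(
    sample_candidates: Sequence[FusionCandidate],
    annotation: Sequence[TranscriptModel],
    config: PipelineConfig,
) -> list[FusionDef]:
    defs: dict[str, FusionDef] = {}
    for cand in sample_candidates:
        fd = breakpoints_to_exons(cand, annotation)
        fd = FusionDef(
            five_gene=fd.five_gene,
            last_exon5=fd.last_exon5,
            three_gene=fd.three_gene,
            first_exon3=fd.first_exon3,
            insert=config.inserts.get(fd.name, ""),
            min_breakpoint_overlap=config.min_overlap.get(
                fd.name, config.filter_params.default_min_breakpoint_overlap
            ),
        )
        defs.setdefault(fd.template_id, fd)
    for fd in config.screen_fusions:
        defs.setdefault(fd.template_id, fd)
    return list(defs.values())


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage for every sample and assemble the summary report."""
    logger.info(
        "filter params: min_matched=%d assumed_span=%d max_span=%d "
        "default_overlap=%d seed=%d | segment filter: min_length=%d "
        "min_markers=%d",
        config.filter_params.min_matched_bases,
        config.filter_params.assumed_read_span,
        config.filter_params.max_reference_span,
        config.filter_params.default_min_breakpoint_overlap,
        config.filter_params.seed_length,
        config.segment_filter.min_length,
        config.segment_filter.min_markers,
    )
    genome = load_genome(config.genome)
    annotation = load_annotation(config.annotation, genome)
    segments = load_cnv_table(config.cnv_table)
    kept = filter_segments(segments, config.segment_filter)
    logger.info("CNV segments: %d loaded, %d pass filters", len(segments), len(kept))
    candidates = enumerate_fusions(kept, annotation)

    kept_by_sample: dict[str, list[CnvSegment]] = {}
    for seg in kept:
        kept_by_sample.setdefault(seg.sample_id, []).append(seg)

    samples: dict[str, SampleResult] = {}
    summary_rows = []
    for sample in config.samples:
        sid = sample.sample_id
        sample_candidates = [c for c in candidates if c.sample_id == sid]
        fusion_defs = _fusion_defs_for_sample(sample_candidates, annotation, config)
        templates = build_template_set(genome, annotation, fusion_defs)
        logger.info(
            "%s: %d candidates, %d fusion defs, %d templates",
            sid, len(sample_candidates), len(fusion_defs), len(templates),
        )
        counter = [0]
        evidence = collect_evidence(
            _counting_pairs(sample.reads1, sample.reads2, counter),
            templates,
            config.filter_params,
        )
        total_raw_reads = counter[0]
        if total_raw_reads == 0:
            total_raw_reads = 1  # empty read set: keep expression defined (zero)
        expression = [
            normalized_expression(ev, total_raw_reads, sid, tid)
            for tid, ev in sorted(evidence.items())
        ]

        cnv_names = {c.name for c in sample_candidates}
        evidence_by_fusion = {
            fd.name: evidence[fd.template_id] for fd in fusion_defs
        }
        call_records = [
            FusionCallRecord(
                sample_id=sid,
                fusion=fd.name,
                cnv_called=fd.name in cnv_names,
                read_supported=evidence[fd.template_id].total_supporting >= 1,
            )
            for fd in fusion_defs
        ]

        protein_reports: dict[str, FusionProteinReport] = {}
        pcr_products: dict[str, list[int]] = {}
        primer_by_name = {p.name: p for p in config.primers}
        for fd in fusion_defs:
            tx5 = _transcript_for(fd.five_gene, annotation)
            tx3 = _transcript_for(fd.three_gene, annotation)
            ft = assemble_fusion_cds(
                tx5, fd.last_exon5, tx3, fd.first_exon3, fd.insert, genome
            )
            protein_reports[fd.name] = translate_fusion(
                ft, config.domains, genome=genome, fusion_id=fd.template_id
            )
            if fd.name in primer_by_name:
                pcr_products[fd.name] = in_silico_pcr(
                    ft.fused_cdna, primer_by_name[fd.name]
                )

        gains = [s for s in kept_by_sample.get(sid, []) if s.kind == "gain"]
        losses = [s for s in kept_by_sample.get(sid, []) if s.kind == "loss"]
        supported = sorted(r.fusion for r in call_records if r.read_supported)
        stated = sorted(r.fusion for r in call_records if r.stated)
        summary_rows.append(
            {
                "sample_id": sid,
                "gains": len(gains),
                "losses": len(losses),
                "breakpoint_fusions": ";".join(
                    sorted({c.name for c in sample_candidates})
                ),
                "read_supported": ";".join(supported),
                "stated": ";".join(stated),
            }
        )
        samples[sid] = SampleResult(
            sample_id=sid,
            candidates=sample_candidates,
            fusion_defs=fusion_defs,
            templates=templates,
            evidence=evidence,
            total_raw_reads=total_raw_reads,
            expression=expression,
            call_records=call_records,
            protein_reports=protein_reports,
            pcr_products=pcr_products,
        )

    summary = pd.DataFrame(summary_rows)
    result = PipelineResult(candidates=candidates, samples=samples, summary=summary)
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    candidates_to_frame(result.candidates).to_csv(
        out / "candidates.tsv", sep="\t", index=False
    )
    ev_rows, expr_rows, call_rows = [], [], []
    protein_json = {}
    for sid, sr in sorted(result.samples.items()):
        write_templates(
            sr.templates,
            out / f"{sid}.templates.fa",
            out / f"{sid}.templates.tsv",
        )
        for tid, ev in sorted(sr.evidence.items()):
            ev_rows.append(
                {
                    "sample_id": sid,
                    "template_id": tid,
                    "spanning": len(ev.spanning),
                    "split_pairs": len(ev.split_pairs),
                    "unique_count": ev.unique_count,
                    "ambiguous": ev.ambiguous_count,
                    "total_supporting": ev.total_supporting,
                }
            )
        for rec in sr.expression:
            expr_rows.append(
                {
                    "sample_id": rec.sample_id,
                    "junction_id": rec.junction_id,
                    "supporting_count": rec.supporting_count,
                    "total_raw_reads": rec.total_raw_reads,
                    "fpm": rec.fpm,
                    "log2_fpm": "" if rec.log2_fpm is None else rec.log2_fpm,
                }
            )
        for rec in sr.call_records:
            call_rows.append(
                {
                    "sample_id": rec.sample_id,
                    "fusion": rec.fusion,
                    "cnv_called": rec.cnv_called,
                    "read_supported": rec.read_supported,
                    "stated": rec.stated,
                }
            )
        protein_json[sid] = {
            name: {
                "fusion_id": rep.fusion_id,
                "frame": rep.frame,
                "coding": rep.coding,
                "protein_length": rep.protein_length,
                "new_aa_count": rep.new_aa_count,
                "five_breakpoint_aa": rep.five_breakpoint_aa,
                "three_breakpoint_aa": rep.three_breakpoint_aa,
                "retained_domains": list(rep.retained_domains),
                "truncated_domains": list(rep.truncated_domains),
                "runs_off_transcript": rep.runs_off_transcript,
                "pcr_products": sr.pcr_products.get(name, []),
            }
            for name, rep in sorted(sr.protein_reports.items())
        }
    pd.DataFrame(ev_rows).to_csv(out / "evidence.tsv", sep="\t", index=False)
    pd.DataFrame(expr_rows).to_csv(out / "expression.tsv", sep="\t", index=False)
    pd.DataFrame(call_rows).to_csv(out / "calls.tsv", sep="\t", index=False)
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    with open(out / "fusion_proteins.json", "w") as fh:
        json.dump(protein_json, fh, indent=2, sort_keys=True)
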