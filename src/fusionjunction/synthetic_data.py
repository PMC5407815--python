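"""Synthetic study generator.

Builds a deterministic toy genome carrying analogs of the five genes
involved in the study design this package targets — two adjacent
plus-strand genes (GTF2IRD1/GTF2I analogs), and three minus-strand genes
(KIAA1549/DENND2A/BRAF analogs) further along the contig — plants
duplication rearrangements with intronic breakpoints, and simulates
stranded 2 x 100 bp paired-end reads from a transcript pool with a truth
manifest, so every pipeline stage is testable without external data.

Two scenarios mirror the study samples:

* ``kiaa_braf_16_9`` — a single tandem duplication joining KIAA1549 exon
  16 to BRAF exon 9 (in frame).
* ``gtf2i_braf_pa3`` — two duplications joined by a circularization event
  (one segment inverted), yielding GTF2I-BRAF 19-10 with a 17 bp insert
  from BRAF intron 9 (in frame) and DENND2A-GTF2IRD1 14-2 (out of frame).

The generator's default plant counts reproduce the study's observed
support structure (109 fragments = 115 spanning reads + 9 split pairs for
GTF2I-BRAF, 11 for DENND2A-GTF2IRD1, low KIAA1549-BRAF counts with a
2-fold wild-type excess, and the wild-type expression ratios).  Planted
junction fragments are placed at distinct start-coordinate pairs and are
verified to be uniquely attributable to their intended template; ambiguous
placements are resampled.  Gene exons are generated long (>= ~610 bp) so
that no 600 bp junction template contains a second junction.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cnv_candidates import CnvSegment, SegmentFilterParams, write_cnv_table
from .fusion_protein import assemble_fusion_cds
from .junction_templates import JunctionTemplate
from .pipeline import (
    FusionDef,
    PipelineConfig,
    SampleInput,
    _fusion_defs_for_sample,
    build_template_set,
)
from .cnv_candidates import enumerate_fusions, filter_segments
from .read_support import FilterParams, TemplateIndex, assign_pair
from .reference_io import (
    Genome,
    TranscriptModel,
    reverse_complement,
    transcript_sequence,
    write_annotation,
)

__all__ = [
    "SimConfig",
    "PlantCounts",
    "Scaffold",
    "RearrangementEvent",
    "RearrangementResult",
    "TruthManifest",
    "build_scaffold",
    "apply_rearrangement",
    "scenario_events",
    "scenario_fusion_defs",
    "screen_fusion_defs",
    "default_plants",
    "simulated_filter_params",
    "simulated_segment_filter",
    "simulate_reads",
    "simulate_sample",
    "simulate_study",
    "study_pipeline_config",
    "STUDY_SAMPLES",
]

CONTIG = "sim7"
_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# scaffold


@dataclass
class Scaffold:
    genome: Genome
    annotation: list[TranscriptModel]
    transcripts: dict[str, TranscriptModel]
    insert_17bp: str  # last 17 bases of BRAF-analog intron 9 (sense)

    def intron_interval(self, gene: str, intron: int) -> tuple[int, int]:
        """Genomic interval of the intron after 1-based exon ``intron``."""
        tx = self.transcripts[gene]
        if not (1 <= intron < tx.n_exons):
            raise ValueError(f"intron {intron} out of range for {gene}")
        up = tx.exons[intron - 1]
        down = tx.exons[intron]
        if tx.strand == "+":
            return up[1], down[0]
        return down[1], up[0]

    def intron_midpoint(self, gene: str, intron: int) -> int:
        lo, hi = self.intron_interval(gene, intron)
        return (lo + hi) // 2


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


_STOP_ROWS = np.array([list(s.encode()) for s in _STOPS], dtype=np.uint8)


def _rand_cds(rng: np.random.Generator, n_codons: int) -> str:
    """n_codons - 1 random sense codons plus one stop codon."""
    rows: list[np.ndarray] = []
    need = n_codons - 1
    while need > 0:
        block = rng.choice(_BASES, size=(need + 16, 3))
        is_stop = (block[:, None, :] == _STOP_ROWS[None, :, :]).all(-1).any(-1)
        keep = block[~is_stop][:need]
        rows.append(keep)
        need -= len(keep)
    sense = np.concatenate(rows)
    stop = _STOPS[int(rng.integers(len(_STOPS)))]
    return sense.tobytes().decode("ascii") + stop


# (name, strand, number of exons) in layout order along the contig
_GENE_TABLE = (
    ("GTF2IRD1", "+", 5),
    ("GTF2I", "+", 20),
    ("HK1", "+", 3),
    ("KIAA1549", "-", 17),
    ("DENND2A", "-", 15),
    ("BRAF", "-", 12),
    ("HK2", "-", 3),
    ("HK3", "+", 3),
)

BACKGROUND_GENES = ("GTF2IRD1", "HK1", "HK2", "HK3")


def build_scaffold(seed: int) -> Scaffold:
    """Deterministic toy contig with the study's gene layout.

    Reading-frame phases are arranged so that the KIAA1549-BRAF 16-9
    junction and the GTF2I-BRAF 19-10 junction (through the 17 bp intron-9
    insert) are in frame, while DENND2A-GTF2IRD1 14-2 (which joins 6 bp
    upstream of the GTF2IRD1 start codon) is out of frame.
    """
    rng = np.random.default_rng([int(seed), 0xC0FFEE])
    exon_lens = {
        name: rng.integers(610, 700, size=n).tolist()
        for name, _, n in _GENE_TABLE
    }

    def boundary(gene: str, exon: int) -> int:
        return int(sum(exon_lens[gene][:exon]))

    cds_start: dict[str, int] = {}
    cds_start["BRAF"] = 90
    r3_10 = (cds_start["BRAF"] - boundary("BRAF", 9)) % 3
    r3_9 = (cds_start["BRAF"] - boundary("BRAF", 8)) % 3
    cds_start["GTF2I"] = 90 + (boundary("GTF2I", 19) + 17 + r3_10 - 90) % 3
    cds_start["KIAA1549"] = 90 + (boundary("KIAA1549", 16) + r3_9 - 90) % 3
    # +1 shifts the DENND2A 14-2 junction out of frame
    cds_start["DENND2A"] = 90 + (boundary("DENND2A", 14) + 6 + 1 - 90) % 3
    cds_start["GTF2IRD1"] = exon_lens["GTF2IRD1"][0] + 6
    for hk in ("HK1", "HK2", "HK3"):
        cds_start[hk] = 90

    spliced: dict[str, str] = {}
    for name, _, _n in _GENE_TABLE:
        total = int(sum(exon_lens[name]))
        start = cds_start[name]
        n_codons = (total - 60 - start) // 3
        if n_codons < 2:
            raise AssertionError("gene too short for a CDS")
        cds = _rand_cds(rng, n_codons)
        utr3 = total - start - len(cds)
        spliced[name] = _rand_bases(rng, start) + cds + _rand_bases(rng, utr3)
        assert len(spliced[name]) == total

    pieces: list[str] = []
    cursor = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        pieces.append(seq)
        start = cursor
        cursor += len(seq)
        return start, cursor

    emit(_rand_bases(rng, 1000))
    transcripts: dict[str, TranscriptModel] = {}
    for name, strand, n in _GENE_TABLE:
        lens = exon_lens[name]
        tx_pieces = [
            spliced[name][boundary(name, i) : boundary(name, i + 1)]
            for i in range(n)
        ]
        intron_lens = rng.integers(150, 400, size=n - 1).tolist()
        genomic_order = (
            list(range(n)) if strand == "+" else list(range(n - 1, -1, -1))
        )
        coords: dict[int, tuple[int, int]] = {}
        for idx, exon_i in enumerate(genomic_order):
            content = tx_pieces[exon_i]
            if strand == "-":
                content = reverse_complement(content)
            coords[exon_i] = emit(content)
            if idx < n - 1:
                emit(_rand_bases(rng, int(intron_lens[idx])))
        exons = tuple(coords[i] for i in range(n))
        total = int(sum(lens))
        n_codons = (total - 60 - cds_start[name]) // 3
        transcripts[name] = TranscriptModel(
            gene_name=name,
            transcript_accession=f"SIM_{name}",
            contig=CONTIG,
            strand=strand,
            exons=exons,
            cds_start=cds_start[name],
            cds_end=cds_start[name] + 3 * n_codons,
        )
        emit(_rand_bases(rng, int(rng.integers(800, 1500))))
    emit(_rand_bases(rng, 6000))

    genome = Genome({CONTIG: "".join(pieces)})
    annotation = [transcripts[name] for name, _, _ in _GENE_TABLE]
    for name in transcripts:
        assert transcript_sequence(genome, transcripts[name]) == spliced[name]

    lo, _hi = Scaffold(genome, annotation, transcripts, "").intron_interval("BRAF", 9)
    insert = reverse_complement(genome.fetch(CONTIG, lo, lo + 17))
    return Scaffold(genome, annotation, transcripts, insert)


# ---------------------------------------------------------------------------
# rearrangements


@dataclass(frozen=True)
class RearrangementEvent:
    mechanism: str  # "tandem_dup" | "circularized_pair"
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self):
        n = {"tandem_dup": 1, "circularized_pair": 2}.get(self.mechanism)
        if n is None:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if len(self.segments) != n:
            raise ValueError(f"{self.mechanism} takes {n} segment(s)")


@dataclass
class RearrangementResult:
    segments: list[CnvSegment]
    junction_sequences: dict[str, str]
    derived_allele: str


def apply_rearrangement(
    scaffold: Scaffold,
    event: RearrangementEvent,
    sample_id: str,
    *,
    marker_spacing: int = 150,
    junction_flank: int = 20,
) -> RearrangementResult:
    """Emit CNV gain segments, derived-allele sequence and junction DNA.

    Tandem duplications yield one junction and one gain; circularized
    pairs (second segment inverted, as required for opposite-strand
    partners) yield two junctions and two gains.  Breakpoints must be
    intronic or intergenic — a breakpoint inside an exon is an error.
    """
    contig_seq = scaffold.genome[CONTIG]
    for seg in event.segments:
        for pos in seg:
            for tx in scaffold.annotation:
                for a, b in tx.exons:
                    if a <= pos < b:
                        raise ValueError(
                            f"breakpoint {pos} inside an exon of {tx.gene_name}"
                        )

    def gain(lo: int, hi: int) -> CnvSegment:
        return CnvSegment(
            sample_id=sample_id,
            contig=CONTIG,
            start=lo,
            end=hi,
            kind="gain",
            marker_count=(hi - lo) // marker_spacing,
        )

    f = junction_flank
    if event.mechanism == "tandem_dup":
        (s, e) = event.segments[0]
        derived = contig_seq[:e] + contig_seq[s:e] + contig_seq[e:]
        junctions = {"dup_junction": contig_seq[e - f : e] + contig_seq[s : s + f]}
        segments = [gain(s, e)]
    else:
        (a1, a2), (b1, b2) = sorted(event.segments)
        derived = contig_seq[a1:a2] + reverse_complement(contig_seq[b1:b2])
        junctions = {
            "circle_junction_1": contig_seq[a2 - f : a2]
            + reverse_complement(contig_seq[b2 - f : b2]),
            "circle_junction_2": reverse_complement(contig_seq[b1 : b1 + f])
            + contig_seq[a1 : a1 + f],
        }
        segments = [gain(a1, a2), gain(b1, b2)]
    return RearrangementResult(
        segments=segments, junction_sequences=junctions, derived_allele=derived
    )


def scenario_events(scaffold: Scaffold, scenario: str) -> list[RearrangementEvent]:
    mid = scaffold.intron_midpoint
    if scenario == "kiaa_braf_16_9":
        return [
            RearrangementEvent(
                "tandem_dup",
                ((mid("KIAA1549", 16), mid("BRAF", 8)),),
            )
        ]
    if scenario == "gtf2i_braf_pa3":
        return [
            RearrangementEvent(
                "circularized_pair",
                (
                    (mid("GTF2IRD1", 1), mid("GTF2I", 19)),
                    (mid("DENND2A", 14), mid("BRAF", 9)),
                ),
            )
        ]
    if scenario == "flat":
        return []
    raise ValueError(f"unknown scenario {scenario!r}")


def scenario_fusion_defs(scaffold: Scaffold, scenario: str) -> list[FusionDef]:
    """The true planted fusions of a scenario."""
    if scenario == "kiaa_braf_16_9":
        return [FusionDef("KIAA1549", 16, "BRAF", 9)]
    if scenario == "gtf2i_braf_pa3":
        return [
            FusionDef("GTF2I", 19, "BRAF", 10, insert=scaffold.insert_17bp),
            FusionDef("DENND2A", 14, "GTF2IRD1", 2, min_breakpoint_overlap=5),
        ]
    if scenario == "flat":
        return []
    raise ValueError(f"unknown scenario {scenario!r}")


def screen_fusion_defs(scaffold: Scaffold) -> list[FusionDef]:
    """Known junctions screened in every sample (targeted-panel analogue)."""
    return [
        FusionDef("KIAA1549", 16, "BRAF", 9),
        FusionDef("GTF2I", 19, "BRAF", 10, insert=scaffold.insert_17bp),
        FusionDef("DENND2A", 14, "GTF2IRD1", 2, min_breakpoint_overlap=5),
    ]


# RT-PCR product sizes of the emulated assay, one junction-spanning
# amplicon per fusion
_PCR_SIZES = {
    "DENND2A-GTF2IRD1": 222,
    "GTF2I-BRAF": 291,
    "KIAA1549-BRAF": 249,
}


def study_primer_table(scaffold: Scaffold):
    """Junction-spanning primer pairs for the three study fusions.

    Each 22-mer pair is cut from the fused cDNA so that the amplicon
    crosses the fusion junction and has the assay's product size.
    """
    from .fusion_protein import PrimerPair

    primers = []
    for fd in screen_fusion_defs(scaffold):
        size = _PCR_SIZES[fd.name]
        ft = assemble_fusion_cds(
            scaffold.transcripts[fd.five_gene],
            fd.last_exon5,
            scaffold.transcripts[fd.three_gene],
            fd.first_exon3,
            fd.insert,
            scaffold.genome,
        )
        bp = ft.junction_offset
        arm5 = size // 2
        fwd_start = bp - arm5
        rev_end = fwd_start + size
        fwd = ft.fused_cdna[fwd_start : fwd_start + 22]
        rev_site = ft.fused_cdna[rev_end - 22 : rev_end]
        primers.append(
            PrimerPair(fd.name, fwd, reverse_complement(rev_site))
        )
    return primers


def decoy_segments(scaffold: Scaffold, sample_id: str) -> list[CnvSegment]:
    """Sub-threshold segments exercising both filter criteria."""
    n = len(scaffold.genome[CONTIG])
    return [
        CnvSegment(sample_id, CONTIG, n - 5900, n - 4700, "gain", 40),  # short
        CnvSegment(sample_id, CONTIG, n - 4500, n - 2000, "gain", 4),  # few markers
    ]


def simulated_filter_params(read_length: int = 100) -> FilterParams:
    """Read filters for the simulated 2 x ``read_length`` bp libraries.

    The identity floor stays at 70; the span cap scales with read length,
    keeping the 5-base slack of the 75 -> 80 rule.
    """
    return FilterParams(
        min_matched_bases=70,
        assumed_read_span=read_length,
        max_reference_span=read_length + 5,
    )


def simulated_segment_filter() -> SegmentFilterParams:
    """Segment thresholds scaled to the kb-scale toy duplications."""
    return SegmentFilterParams(min_length=2000, min_markers=10)


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class PlantCounts:
    """Planted support for one junction (fragments by category)."""

    single_spanning: int = 0
    double_spanning: int = 0
    split: int = 0

    @property
    def fragments(self) -> int:
        return self.single_spanning + self.double_spanning + self.split

    @property
    def spanning_reads(self) -> int:
        return self.single_spanning + 2 * self.double_spanning


@dataclass
class SimConfig:
    seed: int
    scenario: str = "gtf2i_braf_pa3"
    read_length: int = 100
    fragment_mean: int = 300
    fragment_sd: int = 30
    substitution_error_rate: float = 0.0
    per_junction_depth: dict[str, PlantCounts] | None = None
    total_background_reads: int = 600  # background fragments
    target_total_fragments: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.substitution_error_rate <= 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1]")
        if self.read_length < 20:
            raise ValueError("read_length too short")


def default_plants(scenario: str) -> dict[str, PlantCounts]:
    """Scenario plant tables emulating the study's observed support."""
    shared = {
        "GTF2I_e19-e20": PlantCounts(1942, 0, 20),  # 1962 fragments
        "BRAF_e9-e10": PlantCounts(196, 0, 4),  # 200
        "BRAF_e8-e9": PlantCounts(148, 0, 2),  # 150
    }
    if scenario == "kiaa_braf_16_9":
        return {
            "KIAA1549-BRAF_e16-e9": PlantCounts(9, 1, 1),  # 11 fragments
            "KIAA1549_e16-e17": PlantCounts(20, 0, 2),  # 22 = 2-fold wt excess
            "DENND2A_e14-e15": PlantCounts(60, 0, 0),
            **shared,
        }
    if scenario == "gtf2i_braf_pa3":
        return {
            # 109 fragments = 115 spanning reads + 9 split pairs
            "GTF2I-BRAF_e19-e10": PlantCounts(85, 15, 9),
            "DENND2A-GTF2IRD1_e14-e2": PlantCounts(11, 0, 0),
            "KIAA1549_e16-e17": PlantCounts(25, 0, 0),
            "DENND2A_e14-e15": PlantCounts(64, 0, 2),  # 66 = 6-fold wt excess
            **shared,
        }
    if scenario == "flat":
        return {
            "KIAA1549_e16-e17": PlantCounts(20, 0, 0),
            "DENND2A_e14-e15": PlantCounts(60, 0, 0),
            "GTF2I_e19-e20": PlantCounts(1942, 0, 20),
            "BRAF_e9-e10": PlantCounts(392, 0, 8),  # 400 = 2-fold excess
            "BRAF_e8-e9": PlantCounts(296, 0, 4),  # 300
        }
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass
class TruthManifest:
    scenario: str
    seed: int
    read_length: int
    fusions: list[dict]
    cnv_segments: list[dict]
    expected_support: dict[str, dict[str, int]]
    total_reads: int
    read_origins: dict[str, str]
    filter_params: dict
    segment_filter: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class _Junction:
    """Placement bookkeeping for one planted junction."""

    junction_id: str
    transcript: str  # pool key
    bp: int  # transcript offset of the classification breakpoint
    insert_len: int
    min_overlap: int


def _junction_catalog(
    scaffold: Scaffold, fusion_defs: Sequence[FusionDef], pool: Mapping[str, str]
) -> dict[str, _Junction]:
    cat: dict[str, _Junction] = {}
    for fd in fusion_defs:
        tx5 = scaffold.transcripts[fd.five_gene]
        bp = tx5.exon_end_offset(fd.last_exon5)
        cat[fd.template_id] = _Junction(
            fd.template_id,
            transcript=fd.template_id,
            bp=bp,
            insert_len=len(fd.insert),
            min_overlap=fd.min_breakpoint_overlap,
        )
    for gene, tx in scaffold.transcripts.items():
        for i in range(1, tx.n_exons):
            jid = f"{gene}_e{i}-e{i + 1}"
            cat[jid] = _Junction(
                jid, transcript=gene, bp=tx.exon_end_offset(i),
                insert_len=0, min_overlap=2,
            )
    return cat


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in _BASES.tolist() if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_reads(
    config: SimConfig,
    scaffold: Scaffold,
    fusion_defs: Sequence[FusionDef],
    plants: Mapping[str, PlantCounts],
    validation_templates: Sequence[JunctionTemplate],
    sample_id: str = "S",
) -> tuple[list[tuple[str, str, str]], dict[str, dict[str, int]], dict[str, str]]:
    """Generate read pairs for one sample.

    Returns (pairs, expected_support, read_origins) where ``pairs`` yields
    (read_id, mate1, mate2).  Planted fragments get distinct placement
    keys and are validated to be uniquely attributable to their intended
    template with their intended category; failing placements (sequence
    coincidences) are resampled.
    """
    rng = np.random.default_rng(
        [int(config.seed), zlib.crc32(sample_id.encode()) & 0x7FFFFFFF]
    )
    R = config.read_length
    rate = config.substitution_error_rate

    pool: dict[str, str] = {
        gene: transcript_sequence(scaffold.genome, tx)
        for gene, tx in scaffold.transcripts.items()
    }
    for fd in fusion_defs:
        ft = assemble_fusion_cds(
            scaffold.transcripts[fd.five_gene],
            fd.last_exon5,
            scaffold.transcripts[fd.three_gene],
            fd.first_exon3,
            fd.insert,
            scaffold.genome,
        )
        pool[fd.template_id] = ft.fused_cdna

    catalog = _junction_catalog(scaffold, fusion_defs, pool)
    params = simulated_filter_params(R)
    index = TemplateIndex(validation_templates, params)

    pairs: list[tuple[str, str, str]] = []
    origins: dict[str, str] = {}
    expected: dict[str, dict[str, int]] = {}
    counter = 0

    def emit_pair(seq: str, r1: int, r2: int, label: str) -> tuple[str, str, str]:
        nonlocal counter
        counter += 1
        rid = f"{sample_id}:{counter:06d}:{label}"
        m1 = _apply_errors(rng, seq[r1 : r1 + R], rate)
        m2 = _apply_errors(rng, reverse_complement(seq[r2 : r2 + R]), rate)
        return rid, m1, m2

    for jid, counts in sorted(plants.items()):
        if counts.fragments == 0:
            continue
        if jid not in catalog:
            raise ValueError(f"unknown junction {jid!r}")
        jc = catalog[jid]
        seq = pool[jc.transcript]
        bp, ins, mo = jc.bp, jc.insert_len, jc.min_overlap
        span_lo, span_hi = bp - R + mo + 1, bp - mo - 1  # spanning start range
        three_lo, three_hi = bp, bp + ins + 300 - R  # fully-3' start range
        five_lo, five_hi = bp - 300, bp - R  # fully-5' start range
        used: set[tuple[int, int]] = set()

        def plant(category: str, n: int) -> None:
            planted = 0
            attempts = 0
            while planted < n:
                attempts += 1
                if attempts > 200 * max(n, 1) + 1000:
                    raise RuntimeError(
                        f"could not place {n} {category} fragments on {jid}"
                    )
                if category == "single":
                    r1 = int(rng.integers(span_lo, span_hi + 1))
                    r2 = int(rng.integers(three_lo, three_hi + 1))
                elif category == "double":
                    r1 = int(rng.integers(span_lo, span_hi))
                    r2 = int(rng.integers(r1 + 1, span_hi + 1))
                else:  # split
                    r1 = int(rng.integers(five_lo, five_hi + 1))
                    r2 = int(rng.integers(three_lo, three_hi + 1))
                if (r1, r2) in used:
                    continue
                rid, m1, m2 = emit_pair(seq, r1, r2, jid)
                tid, cat, _matches, _tied = assign_pair(
                    index,
                    index.best_matches(m1, rid, 1),
                    index.best_matches(m2, rid, 2),
                    params,
                )
                want = "split_pair" if category == "split" else "spanning"
                if tid != jid or cat != want:
                    counter_rollback()
                    continue
                used.add((r1, r2))
                pairs.append((rid, m1, m2))
                origins[rid] = jid
                planted += 1

        def counter_rollback():
            nonlocal counter
            counter -= 1

        plant("single", counts.single_spanning)
        plant("double", counts.double_spanning)
        plant("split", counts.split)
        expected[jid] = {
            "spanning_reads": counts.spanning_reads,
            "split_pairs": counts.split,
            "unique_fragments": counts.fragments,
        }

    # background fragments from bystander transcripts
    n_planted = sum(c.fragments for c in plants.values())
    if config.target_total_fragments is not None:
        n_background = max(0, config.target_total_fragments - n_planted)
    else:
        n_background = config.total_background_reads
    bg_pool = [g for g in BACKGROUND_GENES if g in pool]
    lengths = np.array([len(pool[g]) for g in bg_pool], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(n_background):
        gene = bg_pool[int(rng.choice(len(bg_pool), p=weights))]
        seq = pool[gene]
        for _try in range(100):
            frag = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd),
                               R + 5, len(seq)))
            r1 = int(rng.integers(0, len(seq) - frag + 1))
            r2 = r1 + frag - R
            if r2 >= 0:
                break
        else:
            raise RuntimeError("could not draw a background fragment")
        rid, m1, m2 = emit_pair(seq, r1, r2, "background")
        pairs.append((rid, m1, m2))
        origins[rid] = "background"

    return pairs, expected, origins


def _write_fastq(pairs: Sequence[tuple[str, str, str]], p1: Path, p2: Path) -> None:
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rid, m1, m2 in pairs:
            f1.write(f"@{rid}/1\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{rid}/2\n{m2}\n+\n{'I' * len(m2)}\n")


@dataclass
class SampleSim:
    sample_id: str
    reads1: str
    reads2: str
    segments: list[CnvSegment]
    manifest: TruthManifest


def _sample_templates(
    scaffold: Scaffold,
    segments: Sequence[CnvSegment],
    fusion_defs: Sequence[FusionDef],
) -> list[JunctionTemplate]:
    """The template set the pipeline will build for this sample: CNV-derived
    candidates plus the screened fusions, each with partner wild-type
    junctions."""
    kept = filter_segments(list(segments), simulated_segment_filter())
    candidates = enumerate_fusions(kept, scaffold.annotation)
    cfg = PipelineConfig(
        genome="", annotation="", cnv_table="", samples=[],
        screen_fusions=list(fusion_defs),
        inserts={fd.name: fd.insert for fd in fusion_defs},
        min_overlap={fd.name: fd.min_breakpoint_overlap for fd in fusion_defs},
        filter_params=simulated_filter_params(),
    )
    defs = _fusion_defs_for_sample(candidates, scaffold.annotation, cfg)
    return build_template_set(scaffold.genome, scaffold.annotation, defs)


def _expected_frames(scaffold: Scaffold, fusion_defs: Sequence[FusionDef]) -> dict[str, bool]:
    """Design-side frame bookkeeping (phase arithmetic on the scaffold)."""
    out = {}
    for fd in fusion_defs:
        tx5 = scaffold.transcripts[fd.five_gene]
        tx3 = scaffold.transcripts[fd.three_gene]
        b5 = tx5.exon_end_offset(fd.last_exon5)
        o3 = tx3.exon_offset(fd.first_exon3)
        lead3 = (tx3.cds_start - o3) if o3 <= tx3.cds_start else (tx3.cds_start - o3) % 3
        out[fd.name] = (b5 - tx5.cds_start + len(fd.insert) + lead3) % 3 == 0
    return out


def simulate_sample(
    config: SimConfig,
    out_dir: str | Path,
    *,
    scaffold: Scaffold | None = None,
    sample_id: str = "S1",
    write_reference: bool = True,
) -> SampleSim:
    """Simulate one sample of the configured scenario into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scaffold is None:
        scaffold = build_scaffold(config.seed)
    if write_reference:
        _write_reference(scaffold, out)

    events = scenario_events(scaffold, config.scenario)
    segments: list[CnvSegment] = []
    for ev in events:
        segments.extend(
            apply_rearrangement(scaffold, ev, sample_id).segments
        )
    segments.extend(decoy_segments(scaffold, sample_id))

    fusion_defs = scenario_fusion_defs(scaffold, config.scenario)
    screen = screen_fusion_defs(scaffold)
    plants = (
        dict(config.per_junction_depth)
        if config.per_junction_depth is not None
        else default_plants(config.scenario)
    )
    templates = _sample_templates(scaffold, segments, screen)
    pairs, expected, origins = simulate_reads(
        config, scaffold, screen, plants, templates, sample_id
    )
    r1 = out / f"{sample_id}_R1.fastq"
    r2 = out / f"{sample_id}_R2.fastq"
    _write_fastq(pairs, r1, r2)
    write_cnv_table(segments, out / f"{sample_id}_cnv.tsv")

    frames = _expected_frames(scaffold, fusion_defs)
    manifest = TruthManifest(
        scenario=config.scenario,
        seed=config.seed,
        read_length=config.read_length,
        fusions=[
            {
                "name": fd.name,
                "template_id": fd.template_id,
                "five_gene": fd.five_gene,
                "last_exon5": fd.last_exon5,
                "three_gene": fd.three_gene,
                "first_exon3": fd.first_exon3,
                "insert": fd.insert,
                "min_breakpoint_overlap": fd.min_breakpoint_overlap,
                "expected_in_frame": frames[fd.name],
            }
            for fd in fusion_defs
        ],
        cnv_segments=[asdict(s) for s in segments],
        expected_support=expected,
        total_reads=2 * len(pairs),
        read_origins=origins,
        filter_params=asdict(simulated_filter_params(config.read_length)),
        segment_filter=asdict(simulated_segment_filter()),
    )
    manifest.to_json(out / f"{sample_id}_manifest.json")
    return SampleSim(
        sample_id=sample_id,
        reads1=str(r1),
        reads2=str(r2),
        segments=segments,
        manifest=manifest,
    )


def _write_reference(scaffold: Scaffold, out: Path) -> None:
    with open(out / "reference.fa", "w") as fh:
        seq = scaffold.genome[CONTIG]
        fh.write(f">{CONTIG}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    write_annotation(scaffold.annotation, out / "annotation.bed")


# ---------------------------------------------------------------------------
# six-sample study

# (scenario, fusion plant) per sample; wild-type plants follow the scenario
# table with per-sample overrides.  PA6 carries the fusion by orthogonal
# assay only: flat CNV profile and no supporting reads, with 2-fold
# elevated wild-type BRAF.
STUDY_SAMPLES = ("PA1", "PA2", "PA3", "PA4", "PA5", "PA6")

_STUDY_PLAN: dict[str, tuple[str, dict[str, PlantCounts]]] = {
    "PA1": ("kiaa_braf_16_9", {
        "KIAA1549-BRAF_e16-e9": PlantCounts(6, 0, 0),
        "KIAA1549_e16-e17": PlantCounts(12, 0, 0),
    }),
    "PA2": ("kiaa_braf_16_9", {
        "KIAA1549-BRAF_e16-e9": PlantCounts(7, 0, 0),
        "KIAA1549_e16-e17": PlantCounts(14, 0, 0),
    }),
    "PA3": ("gtf2i_braf_pa3", {}),
    "PA4": ("kiaa_braf_16_9", {
        "KIAA1549-BRAF_e16-e9": PlantCounts(8, 0, 1),
        "KIAA1549_e16-e17": PlantCounts(18, 0, 0),
    }),
    "PA5": ("kiaa_braf_16_9", {
        "KIAA1549-BRAF_e16-e9": PlantCounts(9, 1, 1),
        "KIAA1549_e16-e17": PlantCounts(22, 0, 0),
    }),
    "PA6": ("flat", {}),
}


@dataclass
class StudySim:
    out_dir: str
    scaffold: Scaffold
    samples: dict[str, SampleSim]
    cnv_table: str

    @property
    def manifests(self) -> dict[str, TruthManifest]:
        return {sid: s.manifest for sid, s in self.samples.items()}


def simulate_study(
    seed: int,
    out_dir: str | Path,
    *,
    scale: float = 1.0,
    substitution_error_rate: float = 0.0,
) -> StudySim:
    """Simulate the six-sample study (five KIAA1549-BRAF-like samples, one
    two-duplication sample, one read-negative/CNV-flat sample).

    ``scale`` < 1 shrinks every plant count proportionally (problem-size
    control for quick runs); ratios between junctions are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scaffold = build_scaffold(seed)
    _write_reference(scaffold, out)

    def scaled(counts: PlantCounts) -> PlantCounts:
        if scale == 1.0:
            return counts
        return PlantCounts(
            max(0, round(counts.single_spanning * scale)),
            max(0, round(counts.double_spanning * scale)),
            max(0, round(counts.split * scale)),
        )

    samples: dict[str, SampleSim] = {}
    all_segments: list[CnvSegment] = []
    for idx, sid in enumerate(STUDY_SAMPLES):
        scenario, overrides = _STUDY_PLAN[sid]
        plants = {**default_plants(scenario), **overrides}
        plants = {jid: scaled(c) for jid, c in plants.items()}
        config = SimConfig(
            seed=int(np.random.default_rng([int(seed), idx + 1]).integers(2**31)),
            scenario=scenario,
            substitution_error_rate=substitution_error_rate,
            per_junction_depth=plants,
            target_total_fragments=max(
                round(3400 * scale), sum(c.fragments for c in plants.values()) + 10
            ),
        )
        samples[sid] = simulate_sample(
            config, out, scaffold=scaffold, sample_id=sid, write_reference=False
        )
        all_segments.extend(samples[sid].segments)

    cnv_path = out / "cnv.tsv"
    write_cnv_table(all_segments, cnv_path)
    return StudySim(
        out_dir=str(out), scaffold=scaffold, samples=samples, cnv_table=str(cnv_path)
    )


def study_pipeline_config(
    study: StudySim, out_dir: str | None = None
) -> PipelineConfig:
    """Pipeline configuration matching a simulated study's conditions."""
    scaffold = study.scaffold
    screen = screen_fusion_defs(scaffold)
    return PipelineConfig(
        genome=str(Path(study.out_dir) / "reference.fa"),
        annotation=str(Path(study.out_dir) / "annotation.bed"),
        cnv_table=study.cnv_table,
        samples=[
            SampleInput(sid, s.reads1, s.reads2)
            for sid, s in sorted(study.samples.items())
        ],
        screen_fusions=screen,
        inserts={fd.name: fd.insert for fd in screen},
        min_overlap={fd.name: fd.min_breakpoint_overlap for fd in screen},
        filter_params=simulated_filter_params(),
        segment_filter=simulated_segment_filter(),
        primers=study_primer_table(scaffold),
        out_dir=out_dir,
    )
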