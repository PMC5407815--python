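"""Fusion transcript assembly, reading-frame analysis and translation.

The fused cDNA is the 5' partner's spliced sequence through its last
retained exon, an optional intronic insert, then the 3' partner's spliced
sequence from its first retained exon.  The junction is *in frame* when
the 3' partner's native codon phase is restored downstream of the insert:
(bases from the 5' CDS start to the junction + insert length + 3'-partner
bases preceding that partner's next native codon boundary) == 0 mod 3.

Translation runs from the 5' partner's start codon to the first stop.
Novel residues are those encoded by neither wild-type parent: the prefix
shared with the 5' protein and the suffix shared with the 3' protein are
subtracted from the fusion protein; out-of-frame fusions therefore count
every residue downstream of the junction-affected codon.  Domains wholly
inside a retained parental residue range are retained; domains cut by the
breakpoint are reported as truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .reference_io import Genome, TranscriptModel, reverse_complement, transcript_sequence

__all__ = [
    "FusionTranscript",
    "FusionProteinReport",
    "DomainAnnotation",
    "PrimerPair",
    "assemble_fusion_cds",
    "classify_frame",
    "translate_fusion",
    "in_silico_pcr",
    "load_domain_table",
    "load_primer_table",
]


@dataclass(frozen=True)
class FusionTranscript:
    five_tx: TranscriptModel
    three_tx: TranscriptModel
    last_exon5: int
    first_exon3: int
    insert: str
    fused_cdna: str
    junction_offset: int  # fused-cDNA offset of the 5'-prefix/insert boundary


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain (1-based inclusive residue coordinates)."""

    protein_accession: str
    domain_name: str
    aa_start: int
    aa_end: int

    def __post_init__(self):
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError("require 1 <= aa_start <= aa_end")


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        for seq in (self.forward, self.reverse):
            if not seq or set(seq.upper()) - set("ACGT"):
                raise ValueError("primers must be non-empty ACGT strings")


@dataclass(frozen=True)
class FusionProteinReport:
    fusion_id: str
    frame: str  # "in_frame" | "out_of_frame"
    coding: bool
    protein_length: int
    new_aa_count: int
    five_breakpoint_aa: int
    three_breakpoint_aa: int
    retained_domains: tuple[str, ...]
    truncated_domains: tuple[str, ...]
    runs_off_transcript: bool
    protein_sequence: str = ""


def assemble_fusion_cds(
    tx5: TranscriptModel,
    last_exon5: int,
    tx3: TranscriptModel,
    first_exon3: int,
    insert: str,
    genome: Genome,
) -> FusionTranscript:
    """Assemble the fused cDNA from its parts."""
    if not (1 <= last_exon5 <= tx5.n_exons):
        raise ValueError(f"last_exon5 {last_exon5} out of range")
    if not (1 <= first_exon3 <= tx3.n_exons):
        raise ValueError(f"first_exon3 {first_exon3} out of range")
    insert = insert.upper()
    prefix = transcript_sequence(genome, tx5)[: tx5.exon_end_offset(last_exon5)]
    suffix = transcript_sequence(genome, tx3)[tx3.exon_offset(first_exon3) :]
    return FusionTranscript(
        five_tx=tx5,
        three_tx=tx3,
        last_exon5=last_exon5,
        first_exon3=first_exon3,
        insert=insert,
        fused_cdna=prefix + insert + suffix,
        junction_offset=len(prefix),
    )


def _three_prime_entry(ft: FusionTranscript) -> tuple[int, int]:
    """(fused-cDNA offset, 3'-transcript offset) of the 3' partner's next
    native codon boundary at or after its entry point."""
    tx3 = ft.three_tx
    o3 = tx3.exon_offset(ft.first_exon3)
    if o3 <= tx3.cds_start:
        t0 = tx3.cds_start
    else:
        t0 = o3 + (tx3.cds_start - o3) % 3
    fused = ft.junction_offset + len(ft.insert) + (t0 - o3)
    return fused, t0


def classify_frame(ft: FusionTranscript) -> str:
    """'in_frame' iff the 3' partner's native codon phase is restored."""
    cds5 = ft.five_tx.cds_start
    if ft.junction_offset <= cds5:
        raise ValueError("junction precedes the 5' partner's CDS start")
    fused_boundary, _ = _three_prime_entry(ft)
    return "in_frame" if (fused_boundary - cds5) % 3 == 0 else "out_of_frame"


def _translate_to_stop(cdna: str, start: int) -> tuple[str, bool]:
    """Translate from ``start`` to the first stop; returns (protein,
    stopped)."""
    orf = cdna[start:]
    orf = orf[: len(orf) - len(orf) % 3]
    protein = str(Seq(orf).translate())
    if "*" in protein:
        return protein[: protein.index("*")], True
    return protein, False


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def translate_fusion(
    ft: FusionTranscript,
    domains: Sequence[DomainAnnotation] = (),
    *,
    genome: Genome | None = None,
    fusion_id: str | None = None,
) -> FusionProteinReport:
    """Translate the fused cDNA and report the protein consequences.

    ``domains`` are matched to the partners through their
    ``protein_accession`` equal to the partner transcript's accession.
    """
    tx5, tx3 = ft.five_tx, ft.three_tx
    if fusion_id is None:
        fusion_id = (
            f"{tx5.gene_name}-{tx3.gene_name}_e{ft.last_exon5}-e{ft.first_exon3}"
        )
    cds5 = tx5.cds_start
    if ft.junction_offset <= cds5:
        # junction upstream of the 5' start codon: no fusion ORF from the
        # 5' promoter; reported as non-coding rather than an error
        return FusionProteinReport(
            fusion_id=fusion_id,
            frame="out_of_frame",
            coding=False,
            protein_length=0,
            new_aa_count=0,
            five_breakpoint_aa=0,
            three_breakpoint_aa=0,
            retained_domains=(),
            truncated_domains=(),
            runs_off_transcript=False,
        )

    frame = classify_frame(ft)
    protein, stopped = _translate_to_stop(ft.fused_cdna, cds5)

    if genome is not None:
        spliced5 = transcript_sequence(genome, tx5)
        spliced3 = transcript_sequence(genome, tx3)
    else:
        # transcripts are only needed as sequences; require genome when the
        # caller has not pre-assembled them
        raise ValueError("genome is required to derive wild-type proteins")
    wt5, _ = _translate_to_stop(spliced5, tx5.cds_start)
    wt3, _ = _translate_to_stop(spliced3, tx3.cds_start)

    five_bp_aa = (ft.junction_offset - cds5) // 3
    if frame == "out_of_frame":
        # every residue from the junction-affected codon onward is novel
        new_aa = max(0, len(protein) - five_bp_aa)
    else:
        # hybrid junction codons encoding a residue matching neither parent
        shared5 = _common_prefix(protein, wt5)
        shared3 = _common_suffix(protein, wt3)
        new_aa = max(
            0, len(protein) - shared5 - min(shared3, len(protein) - shared5)
        )
    _, t0 = _three_prime_entry(ft)
    three_bp_aa = (t0 - tx3.cds_start) // 3 + 1

    retained: list[str] = []
    truncated: list[str] = []
    for dom in domains:
        if dom.protein_accession == tx5.transcript_accession:
            if dom.aa_end <= five_bp_aa:
                retained.append(dom.domain_name)
            elif dom.aa_start <= five_bp_aa:
                truncated.append(dom.domain_name)
        elif dom.protein_accession == tx3.transcript_accession:
            # 3' domains are retained only if the fusion reads them in frame
            if frame != "in_frame":
                continue
            if dom.aa_start >= three_bp_aa:
                retained.append(dom.domain_name)
            elif dom.aa_end >= three_bp_aa:
                truncated.append(dom.domain_name)
    return FusionProteinReport(
        fusion_id=fusion_id,
        frame=frame,
        coding=True,
        protein_length=len(protein),
        new_aa_count=new_aa,
        five_breakpoint_aa=five_bp_aa,
        three_breakpoint_aa=three_bp_aa,
        retained_domains=tuple(retained),
        truncated_domains=tuple(truncated),
        runs_off_transcript=not stopped,
        protein_sequence=protein,
    )


def in_silico_pcr(template: str, primers: PrimerPair) -> list[int]:
    """Exact-match PCR product sizes on a template.

    The forward primer binds the given strand; the reverse primer binds as
    its reverse complement downstream of the forward site.  Product length
    runs from the forward primer's 5' end through the reverse primer's 5'
    end, inclusive.  All products are reported; an empty list means no
    product.
    """
    template = template.upper()
    fwd = primers.forward.upper()
    rev_site = reverse_complement(primers.reverse.upper())

    def occurrences(needle: str) -> list[int]:
        out, start = [], 0
        while True:
            i = template.find(needle, start)
            if i == -1:
                return out
            out.append(i)
            start = i + 1

    products = []
    rev_positions = occurrences(rev_site)
    for f in occurrences(fwd):
        for r in rev_positions:
            if r >= f + len(fwd):
                products.append(r + len(rev_site) - f)
    return sorted(products)


def load_domain_table(path: str | Path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        DomainAnnotation(
            protein_accession=row.protein_accession,
            domain_name=row.domain_name,
            aa_start=int(row.aa_start),
            aa_end=int(row.aa_end),
        )
        for row in df.itertuples(index=False)
    ]


def load_primer_table(path: str | Path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        PrimerPair(name=row.name, forward=row.forward, reverse=row.reverse)
        for row in df.itertuples(index=False)
    ]
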