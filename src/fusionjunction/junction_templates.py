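"""Junction reference templates.

For every exon-exon junction of interest — wild-type or fusion — a template
of up to 600 bp is cut from the spliced mRNA: 300 bases upstream from the
5' side and 300 bases downstream from the 3' side.  Fusion templates may
carry an intronic insert between the two sides; the insert is counted with
the 3' side, so the breakpoint used for read classification sits at the
5'-partner/insert boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .reference_io import Genome, TranscriptModel, transcript_sequence

__all__ = [
    "JunctionTemplate",
    "DEFAULT_FLANK",
    "build_wildtype_junction",
    "build_fusion_junction",
    "anchor_sequence",
    "write_templates",
    "load_templates",
]

DEFAULT_FLANK = 300


@dataclass(frozen=True)
class JunctionTemplate:
    """A junction reference sequence with its breakpoint offset.

    ``breakpoint_offset`` is the number of bases contributed by the 5'
    side; the junction lies between template positions breakpoint_offset
    and breakpoint_offset + 1 (1-based display).
    """

    template_id: str
    five_label: str
    three_label: str
    sequence: str
    breakpoint_offset: int
    insert_length: int
    kind: str  # "wildtype_junction" | "fusion_junction"
    min_breakpoint_overlap: int = 2

    def __post_init__(self):
        if self.kind not in ("wildtype_junction", "fusion_junction"):
            raise ValueError(f"unknown template kind {self.kind!r}")
        if not (1 <= self.breakpoint_offset < len(self.sequence)):
            raise ValueError("breakpoint_offset must lie inside the sequence")
        if self.insert_length < 0:
            raise ValueError("insert_length must be >= 0")
        if self.kind == "wildtype_junction" and self.insert_length != 0:
            raise ValueError("wild-type junctions carry no insert")

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.five_label, self.three_label)


def build_wildtype_junction(
    tx: TranscriptModel,
    exon_index: int,
    genome: Genome,
    *,
    flank: int = DEFAULT_FLANK,
    min_breakpoint_overlap: int = 2,
) -> JunctionTemplate:
    """Template for the junction between exon ``exon_index`` and the next.

    ``exon_index`` is 1-based in transcript numbering.  Each side is
    truncated to what the transcript can supply (at most ``flank`` bases).
    """
    if not (1 <= exon_index < tx.n_exons):
        raise ValueError(
            f"exon_index must be in [1, {tx.n_exons - 1}], got {exon_index}"
        )
    spliced = transcript_sequence(genome, tx)
    boundary = tx.exon_end_offset(exon_index)
    five = spliced[max(0, boundary - flank) : boundary]
    three = spliced[boundary : boundary + flank]
    return JunctionTemplate(
        template_id=f"{tx.gene_name}_e{exon_index}-e{exon_index + 1}",
        five_label=tx.gene_name,
        three_label=tx.gene_name,
        sequence=five + three,
        breakpoint_offset=len(five),
        insert_length=0,
        kind="wildtype_junction",
        min_breakpoint_overlap=min_breakpoint_overlap,
    )


def build_fusion_junction(
    tx5: TranscriptModel,
    last_exon5: int,
    tx3: TranscriptModel,
    first_exon3: int,
    insert: str,
    genome: Genome,
    *,
    flank: int = DEFAULT_FLANK,
    min_breakpoint_overlap: int = 2,
    template_id: str | None = None,
) -> JunctionTemplate:
    """Template for a fusion junction joining two transcripts.

    The sequence is (last <= ``flank`` bases of the 5' transcript through
    exon ``last_exon5``) + insert + (first <= ``flank`` bases of the 3'
    transcript from exon ``first_exon3``).
    """
    if not (1 <= last_exon5 <= tx5.n_exons):
        raise ValueError(f"last_exon5 {last_exon5} out of range")
    if not (1 <= first_exon3 <= tx3.n_exons):
        raise ValueError(f"first_exon3 {first_exon3} out of range")
    insert = insert.upper()
    spliced5 = transcript_sequence(genome, tx5)
    spliced3 = transcript_sequence(genome, tx3)
    b5 = tx5.exon_end_offset(last_exon5)
    o3 = tx3.exon_offset(first_exon3)
    five = spliced5[max(0, b5 - flank) : b5]
    three = spliced3[o3 : o3 + flank]
    if template_id is None:
        template_id = (
            f"{tx5.gene_name}-{tx3.gene_name}_e{last_exon5}-e{first_exon3}"
        )
    return JunctionTemplate(
        template_id=template_id,
        five_label=tx5.gene_name,
        three_label=tx3.gene_name,
        sequence=five + insert + three,
        breakpoint_offset=len(five),
        insert_length=len(insert),
        kind="fusion_junction",
        min_breakpoint_overlap=min_breakpoint_overlap,
    )


def anchor_sequence(template: JunctionTemplate, side: str, k: int) -> str:
    """The ``k`` bases immediately adjacent to the junction on one side.

    The insert counts with the 3' side.  Used e.g. as a 30 bp match
    sequence to screen raw reads for a suspected junction.
    """
    bo = template.breakpoint_offset
    if side == "five":
        if k > bo:
            raise ValueError(f"only {bo} bases available on the 5' side")
        return template.sequence[bo - k : bo]
    if side == "three":
        avail = len(template.sequence) - bo
        if k > avail:
            raise ValueError(f"only {avail} bases available on the 3' side")
        return template.sequence[bo : bo + k]
    raise ValueError("side must be 'five' or 'three'")


def write_templates(
    templates: Sequence[JunctionTemplate],
    fasta_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Write templates as FASTA plus a sidecar TSV of junction metadata."""
    with open(fasta_path, "w") as fh:
        for t in templates:
            fh.write(f">{t.template_id}\n")
            for i in range(0, len(t.sequence), 80):
                fh.write(t.sequence[i : i + 80] + "\n")
    pd.DataFrame(
        [
            {
                "template_id": t.template_id,
                "five_label": t.five_label,
                "three_label": t.three_label,
                "breakpoint_offset": t.breakpoint_offset,
                "insert_length": t.insert_length,
                "kind": t.kind,
                "min_breakpoint_overlap": t.min_breakpoint_overlap,
            }
            for t in templates
        ]
    ).to_csv(tsv_path, sep="\t", index=False)


def load_templates(
    fasta_path: str | Path, tsv_path: str | Path
) -> list[JunctionTemplate]:
    from Bio import SeqIO

    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(tsv_path, sep="\t")
    templates = []
    for row in meta.itertuples(index=False):
        if row.template_id not in seqs:
            raise ValueError(f"template {row.template_id!r} missing from FASTA")
        templates.append(
            JunctionTemplate(
                template_id=row.template_id,
                five_label=row.five_label,
                three_label=row.three_label,
                sequence=seqs[row.template_id],
                breakpoint_offset=int(row.breakpoint_offset),
                insert_length=int(row.insert_length),
                kind=row.kind,
                min_breakpoint_overlap=int(row.min_breakpoint_overlap),
            )
        )
    return templates
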