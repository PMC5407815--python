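"""Reference sequence and transcript-model handling.

Coordinate conventions used throughout the package:

* External files keep their native standard (BED12 and FASTA are 0-based,
  half-open).
* All internal coordinates are 0-based, half-open.
* User-facing reports are 1-based inclusive.

Transcript (spliced) sequences are always stored in transcription
orientation; the genomic strand is metadata.  For a minus-strand transcript
the exon list is ordered 5'->3' along the mRNA, i.e. genomic start
coordinates strictly decrease along the list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Genome",
    "TranscriptModel",
    "load_genome",
    "load_annotation",
    "write_annotation",
    "transcript_sequence",
    "reverse_complement",
]

_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase, Ns preserved)."""
    return str(Seq(seq).reverse_complement())


class Genome:
    """A set of named contig sequences (uppercase A/C/G/T/N).

    Behaves like a read-only mapping from contig name to sequence string.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise ValueError("contig name must be non-empty")
            if name in self._sequences:
                raise ValueError(f"duplicate contig name: {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            self._sequences[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sequences

    def __iter__(self):
        return iter(self._sequences)

    def __len__(self) -> int:
        return len(self._sequences)

    def contigs(self) -> list[str]:
        return list(self._sequences)

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Subsequence [start, end) of a contig; bounds are checked."""
        seq = self._sequences[contig]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon/CDS gene model.

    ``exons`` are genomic half-open intervals ordered in transcription
    (5'->3') direction.  ``cds_start``/``cds_end`` are offsets into the
    spliced transcript (0-based, half-open); the CDS length, stop codon
    included, is a multiple of three.
    """

    gene_name: str
    transcript_accession: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        for a, b in exons:
            if not (0 <= a < b):
                raise ValueError(f"bad exon interval [{a}, {b})")
        genomic = sorted(exons)
        for (a1, b1), (a2, b2) in zip(genomic, genomic[1:]):
            if a2 < b1:
                raise ValueError("exons overlap on the genome")
        starts = [a for a, _ in exons]
        if self.strand == "+":
            if starts != sorted(starts):
                raise ValueError("plus-strand exons must ascend genomically")
        else:
            if starts != sorted(starts, reverse=True):
                raise ValueError(
                    "minus-strand exons must descend genomically in "
                    "transcription order"
                )
        n = self.spliced_length
        if not (0 <= self.cds_start < self.cds_end <= n):
            raise ValueError(
                f"CDS [{self.cds_start}, {self.cds_end}) outside spliced "
                f"transcript of length {n}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError("CDS length must be a multiple of 3")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def genomic_span(self) -> tuple[int, int]:
        """(min start, max end) over all exons — introns included."""
        return min(a for a, _ in self.exons), max(b for _, b in self.exons)

    def exon_offset(self, exon_number: int) -> int:
        """Spliced offset of the start of 1-based exon ``exon_number``."""
        if not (1 <= exon_number <= self.n_exons):
            raise ValueError(f"exon number {exon_number} out of range")
        return sum(self.exon_lengths[: exon_number - 1])

    def exon_end_offset(self, exon_number: int) -> int:
        """Spliced offset just past the end of 1-based exon ``exon_number``."""
        if not (1 <= exon_number <= self.n_exons):
            raise ValueError(f"exon number {exon_number} out of range")
        return sum(self.exon_lengths[:exon_number])


def load_genome(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Duplicate contig names and empty sequences are hard errors; lowercase
    input is uppercased.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate contig name: {record.id!r}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences)


def _parse_name(name: str) -> tuple[str, str]:
    """BED name field convention: 'GENE|ACCESSION', else both equal name."""
    if "|" in name:
        gene, acc = name.split("|", 1)
        return gene, acc
    return name, name


def load_annotation(path: str | Path, genome: Genome) -> list[TranscriptModel]:
    """Load transcript models from a BED12 file.

    blockSizes/blockStarts define exons; thickStart/thickEnd define the CDS.
    Exons are re-ordered into transcription order for minus-strand records
    and the CDS is converted to spliced-transcript coordinates.
    """
    transcripts: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom = fields[0]
            if chrom not in genome:
                raise ValueError(
                    f"{path}:{lineno}: unknown contig {chrom!r}"
                )
            chrom_start = int(fields[1])
            chrom_end = int(fields[2])
            gene, acc = _parse_name(fields[3])
            strand = fields[5]
            thick_start = int(fields[6])
            thick_end = int(fields[7])
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            blocks = [
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            for (a1, b1), (a2, b2) in zip(blocks, blocks[1:]):
                if a2 < b1:
                    raise ValueError(f"{path}:{lineno}: blocks overlap")
            if blocks[0][0] != chrom_start or blocks[-1][1] != chrom_end:
                raise ValueError(
                    f"{path}:{lineno}: blocks do not tile chromStart/chromEnd"
                )
            if thick_start >= thick_end:
                raise ValueError(f"{path}:{lineno}: transcript has no CDS")
            # genomic position -> plus-strand spliced offset
            def spliced_offset(pos: int, *, right: bool) -> int:
                acc_len = 0
                for a, b in blocks:
                    if (a <= pos < b) or (right and pos == b):
                        return acc_len + (pos - a)
                    acc_len += b - a
                raise ValueError(
                    f"{path}:{lineno}: thick boundary {pos} outside blocks"
                )

            cds_lo = spliced_offset(thick_start, right=False)
            cds_hi = spliced_offset(thick_end, right=True)
            total = sum(b - a for a, b in blocks)
            if strand == "-":
                exons = tuple(reversed(blocks))
                cds_start, cds_end = total - cds_hi, total - cds_lo
            else:
                exons = tuple(blocks)
                cds_start, cds_end = cds_lo, cds_hi
            transcripts.append(
                TranscriptModel(
                    gene_name=gene,
                    transcript_accession=acc,
                    contig=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    return transcripts


def write_annotation(
    transcripts: Iterable[TranscriptModel], path: str | Path
) -> None:
    """Write transcript models as BED12 (exact inverse of load_annotation)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            blocks = sorted(tx.exons)
            chrom_start = blocks[0][0]
            chrom_end = blocks[-1][1]
            # spliced CDS offsets -> genomic thick range
            if tx.strand == "-":
                total = tx.spliced_length
                lo, hi = total - tx.cds_end, total - tx.cds_start
            else:
                lo, hi = tx.cds_start, tx.cds_end

            def genomic_pos(offset: int, *, right: bool) -> int:
                # left boundaries snap to the next block's start, right
                # boundaries to the previous block's end
                acc_len = 0
                for a, b in blocks:
                    size = b - a
                    if offset < acc_len + size or (
                        right and offset == acc_len + size
                    ):
                        return a + (offset - acc_len)
                    acc_len += size
                raise ValueError("offset outside transcript")

            thick_start = genomic_pos(lo, right=False)
            thick_end = genomic_pos(hi, right=True)
            sizes = ",".join(str(b - a) for a, b in blocks)
            starts = ",".join(str(a - chrom_start) for a, b in blocks)
            name = (
                tx.gene_name
                if tx.gene_name == tx.transcript_accession
                else f"{tx.gene_name}|{tx.transcript_accession}"
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        tx.contig,
                        chrom_start,
                        chrom_end,
                        name,
                        0,
                        tx.strand,
                        thick_start,
                        thick_end,
                        "0,0,0",
                        len(blocks),
                        sizes,
                        starts,
                    )
                )
                + "\n"
            )


def transcript_sequence(genome: Genome, tx: TranscriptModel) -> str:
    """Spliced transcript sequence in transcription orientation.

    Exon sequences are concatenated in transcription order and
    reverse-complemented for minus-strand models.
    """
    if tx.contig not in genome:
        raise ValueError(f"contig {tx.contig!r} not in genome")
    pieces = []
    for a, b in sorted(tx.exons):
        pieces.append(genome.fetch(tx.contig, a, b))
    seq = "".join(pieces)
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return seq
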