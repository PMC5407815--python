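"""Shared fixtures and toy-model builders."""

from __future__ import annotations

import numpy as np
import pytest

from fusionjunction.reference_io import Genome, TranscriptModel, reverse_complement


def rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_gene(
    contig_parts: list[str],
    cursor: int,
    spliced: str,
    exon_lens: list[int],
    intron_lens: list[int],
    strand: str,
    gene: str,
    cds_start: int,
    cds_end: int,
    rng: np.random.Generator,
    accession: str | None = None,
) -> tuple[TranscriptModel, int]:
    """Place a spliced sequence on a growing contig as an exon/intron gene.

    Returns the transcript model and the new cursor.  ``contig_parts`` is
    mutated in place.
    """
    assert sum(exon_lens) == len(spliced)
    pieces, off = [], 0
    for L in exon_lens:
        pieces.append(spliced[off : off + L])
        off += L
    order = range(len(pieces)) if strand == "+" else range(len(pieces) - 1, -1, -1)
    coords = {}
    for idx, i in enumerate(order):
        content = pieces[i] if strand == "+" else reverse_complement(pieces[i])
        coords[i] = (cursor, cursor + len(content))
        contig_parts.append(content)
        cursor += len(content)
        if idx < len(pieces) - 1:
            gap = intron_lens[idx]
            contig_parts.append(rand_bases(rng, gap))
            cursor += gap
    tx = TranscriptModel(
        gene_name=gene,
        transcript_accession=accession or gene,
        contig="toy",
        strand=strand,
        exons=tuple(coords[i] for i in range(len(pieces))),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    return tx, cursor


def toy_genome(parts: list[str], pad: int = 50) -> Genome:
    return Genome({"toy": "A" * pad + "".join(parts) + "A" * pad})


def build_toy(
    rng: np.random.Generator,
    genes: list[dict],
) -> tuple[Genome, list[TranscriptModel]]:
    """Build a toy contig from gene specs.

    Each spec: dict(gene, strand, spliced, exon_lens, cds_start, cds_end,
    optional accession).  Genes are laid out left to right with 100 bp
    gaps.
    """
    parts: list[str] = []
    cursor = 50
    models = []
    for spec in genes:
        n = len(spec["exon_lens"])
        introns = [100] * (n - 1)
        tx, cursor = make_gene(
            parts,
            cursor,
            spec["spliced"],
            spec["exon_lens"],
            introns,
            spec["strand"],
            spec["gene"],
            spec["cds_start"],
            spec["cds_end"],
            rng,
            spec.get("accession"),
        )
        models.append(tx)
        parts.append(rand_bases(rng, 100))
        cursor += 100
    genome = toy_genome(parts)
    return genome, models


@pytest.fixture(scope="session")
def scaffold():
    from fusionjunction.synthetic_data import build_scaffold

    return build_scaffold(1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
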