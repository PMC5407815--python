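"""CNV segment filtering and fusion-candidate enumeration.

Candidate fusions are derived from copy-number gain (and, as an extension,
loss) segments under a tandem-duplication / inversion / circularization
model.  A tandem duplication of [s, e) creates a novel genomic junction
joining the base just left of ``e`` to the base at ``s``; two gains can be
joined into a circle (optionally with one segment inverted) that is
reintegrated elsewhere, creating one chimeric junction per segment boundary
pair.  A junction yields a fusion candidate when a gene at one flank
transcribes across it into a co-oriented gene at the other flank.

A coding fusion is *stated* only when both criteria hold: the CNV call
exists and at least one supporting read/read pair is found in RNA-seq data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference_io import TranscriptModel

__all__ = [
    "CnvSegment",
    "SegmentFilterParams",
    "FusionCandidate",
    "FusionCallRecord",
    "filter_segments",
    "genes_at_breakpoints",
    "enumerate_fusions",
    "cross_validate",
    "load_cnv_table",
    "write_cnv_table",
    "candidates_to_frame",
    "records_to_frame",
]


@dataclass(frozen=True)
class CnvSegment:
    """A called copy-number segment (internally 0-based half-open)."""

    sample_id: str
    contig: str
    start: int
    end: int
    kind: str  # "gain" | "loss"
    marker_count: int
    segment_id: str = ""

    def __post_init__(self):
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"kind must be 'gain' or 'loss', got {self.kind!r}")
        if not self.start < self.end:
            raise ValueError("segment start must precede end")
        if self.marker_count < 0:
            raise ValueError("marker_count must be >= 0")
        if not self.segment_id:
            object.__setattr__(
                self,
                "segment_id",
                f"{self.sample_id}:{self.contig}:{self.start}-{self.end}:{self.kind}",
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentFilterParams:
    """Segment-calling thresholds (defaults: >= 200 kb and >= 50 markers)."""

    min_length: int = 200_000
    min_markers: int = 50

    def __post_init__(self):
        if self.min_length < 0 or self.min_markers < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass(frozen=True)
class FusionCandidate:
    """A CNV-derived candidate gene fusion (5' partner first)."""

    sample_id: str
    five_gene: str
    three_gene: str
    five_breakpoint: int
    three_breakpoint: int
    mechanism: str  # "tandem_dup" | "dup_inversion" | "circularized_pair"
    requires_inversion: bool
    source_segments: tuple[str, ...]

    def __post_init__(self):
        if self.five_gene == self.three_gene:
            raise ValueError("fusion partners must differ")
        if self.mechanism not in ("tandem_dup", "dup_inversion", "circularized_pair"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")

    @property
    def name(self) -> str:
        return f"{self.five_gene}-{self.three_gene}"


@dataclass(frozen=True)
class FusionCallRecord:
    """Cross-validated fusion status: stated = CNV call AND read support."""

    sample_id: str
    fusion: str
    cnv_called: bool
    read_supported: bool

    @property
    def stated(self) -> bool:
        return self.cnv_called and self.read_supported


def filter_segments(
    segments: Sequence[CnvSegment], params: SegmentFilterParams
) -> list[CnvSegment]:
    """Keep exactly the segments passing both thresholds; order preserved."""
    return [
        s
        for s in segments
        if s.length >= params.min_length and s.marker_count >= params.min_markers
    ]


@dataclass(frozen=True)
class _GeneSpan:
    gene: str
    contig: str
    start: int  # first exon start (introns included)
    end: int  # last exon end
    strand: str


def _gene_spans(annotation: Iterable[TranscriptModel]) -> list[_GeneSpan]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in annotation:
        by_gene.setdefault(tx.gene_name, []).append(tx)
    spans = []
    for gene, txs in by_gene.items():
        contigs = {t.contig for t in txs}
        strands = {t.strand for t in txs}
        if len(contigs) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gene!r} has inconsistent contig/strand")
        start = min(t.genomic_span[0] for t in txs)
        end = max(t.genomic_span[1] for t in txs)
        spans.append(_GeneSpan(gene, contigs.pop(), start, end, strands.pop()))
    return spans


def _genes_at(spans: Sequence[_GeneSpan], contig: str, pos: int) -> list[_GeneSpan]:
    return [g for g in spans if g.contig == contig and g.start <= pos < g.end]


def genes_at_breakpoints(
    segment: CnvSegment, annotation: Sequence[TranscriptModel]
) -> tuple[list[str], list[str]]:
    """Genes whose genomic span (introns included) covers each breakpoint.

    Returns (genes at segment start, genes at segment end).
    """
    spans = _gene_spans(annotation)
    at_start = [g.gene for g in _genes_at(spans, segment.contig, segment.start)]
    at_end = [g.gene for g in _genes_at(spans, segment.contig, segment.end - 1)]
    return at_start, at_end


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def _junction_fusions(
    spans: Sequence[_GeneSpan],
    contig: str,
    left_pos: int,
    left_orient: str,
    right_pos: int,
    right_orient: str,
) -> list[tuple[str, str, int, int]]:
    """Fusions readable across a junction joining two oriented flanks.

    The junction joins the sequence ending at ``left_pos`` (taken from a
    segment traversed in ``left_orient``) to the sequence starting at
    ``right_pos`` (segment traversed in ``right_orient``).  A fusion forms
    when a gene transcribes *toward* the junction on one flank and a gene
    transcribes *away* from it on the other, in the same reading direction.
    Both reading directions of the derived allele are considered.
    Returns (five_gene, three_gene, five_breakpoint, three_breakpoint).
    """
    out = []
    left = _genes_at(spans, contig, left_pos if left_orient == "-" else left_pos - 1)
    right = _genes_at(
        spans, contig, right_pos - 1 if right_orient == "-" else right_pos
    )
    # forward reading: 5' partner ends the left flank, 3' partner opens the right
    for g5 in left:
        if g5.strand != left_orient:
            continue
        for g3 in right:
            if g3.strand != right_orient or g3.gene == g5.gene:
                continue
            out.append((g5.gene, g3.gene, left_pos, right_pos))
    # reverse-complement reading of the same junction
    for g5 in right:
        if g5.strand != _flip(right_orient):
            continue
        for g3 in left:
            if g3.strand != _flip(left_orient) or g3.gene == g5.gene:
                continue
            out.append((g5.gene, g3.gene, right_pos, left_pos))
    return out


def enumerate_fusions(
    segments: Sequence[CnvSegment], annotation: Sequence[TranscriptModel]
) -> list[FusionCandidate]:
    """Enumerate fusion candidates from filtered CNV segments.

    Single gains are modelled as head-to-tail tandem duplications; when the
    breakpoint genes cannot form a colinear fusion, inversion-requiring
    candidates are emitted instead.  Pairs of same-sample, same-contig gains
    are modelled as a reintegrated circle in both relative orientations.
    Losses join their flanking sequence (deletion fusions) and are reported
    under the tandem_dup mechanism.
    """
    spans = _gene_spans(annotation)
    candidates: list[FusionCandidate] = []
    seen: set[tuple] = set()

    def emit(sample, g5, g3, b5, b3, mechanism, inversion, sources):
        key = (sample, g5, g3, b5, b3, mechanism, inversion)
        if key in seen:
            return
        seen.add(key)
        candidates.append(
            FusionCandidate(
                sample_id=sample,
                five_gene=g5,
                three_gene=g3,
                five_breakpoint=b5,
                three_breakpoint=b3,
                mechanism=mechanism,
                requires_inversion=inversion,
                source_segments=tuple(sources),
            )
        )

    by_sample: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)

    for sample, segs in by_sample.items():
        for seg in segs:
            if seg.kind == "gain":
                # tandem duplication: ...e-1 | s...
                colinear = _junction_fusions(
                    spans, seg.contig, seg.end, "+", seg.start, "+"
                )
                for g5, g3, b5, b3 in colinear:
                    emit(sample, g5, g3, b5, b3, "tandem_dup", False,
                         [seg.segment_id])
                if not colinear:
                    # duplication with an inverted copy: the junction joining
                    # the inverted copy's far end to the resumed reference
                    # admits (minus@s -> plus@e) and (minus@e -> plus@s).
                    for g5, g3, b5, b3 in _junction_fusions(
                        spans, seg.contig, seg.start, "-", seg.end, "+"
                    ):
                        emit(sample, g5, g3, b5, b3, "dup_inversion", True,
                             [seg.segment_id])
            else:  # loss: flanks join directly ...s-1 | e...
                for g5, g3, b5, b3 in _junction_fusions(
                    spans, seg.contig, seg.start, "+", seg.end, "+"
                ):
                    emit(sample, g5, g3, b5, b3, "tandem_dup", False,
                         [seg.segment_id])

        gains = [s for s in segs if s.kind == "gain"]
        for i in range(len(gains)):
            for j in range(i + 1, len(gains)):
                a, b = sorted((gains[i], gains[j]), key=lambda s: s.start)
                if a.contig != b.contig:
                    continue
                sources = [a.segment_id, b.segment_id]
                # circle [A+, B+]: junctions a2|b1 and b2|a1
                for left, lo, right, ro, inv in (
                    (a.end, "+", b.start, "+", False),
                    (b.end, "+", a.start, "+", False),
                    # circle [A+, B-]: junctions a2|b2(rev) and b1(rev)|a1
                    (a.end, "+", b.end, "-", True),
                    (b.start, "-", a.start, "+", True),
                ):
                    for g5, g3, b5, b3 in _junction_fusions(
                        spans, a.contig, left, lo, right, ro
                    ):
                        emit(sample, g5, g3, b5, b3, "circularized_pair", inv,
                             sources)
    return candidates


def cross_validate(
    candidates: Sequence[FusionCandidate],
    evidence: Mapping[str, object],
    cnv_calls: Mapping[str, bool],
) -> list[FusionCallRecord]:
    """Combine CNV calls with read evidence into stated/not-stated records.

    ``evidence`` maps fusion name -> SupportEvidence (or an integer count of
    unique supporting fragments); ``cnv_calls`` maps fusion name -> whether a
    CNV gain/loss call backs the fusion.  Fusions present in either mapping
    but absent from ``candidates`` are also reported (read-only evidence).
    """

    def count(fusion: str) -> int:
        ev = evidence.get(fusion)
        if ev is None:
            return 0
        if isinstance(ev, int):
            return ev
        return ev.total_supporting

    names: list[tuple[str, str]] = []
    seen = set()
    for cand in candidates:
        key = (cand.sample_id, cand.name)
        if key not in seen:
            seen.add(key)
            names.append(key)
    for fusion in list(evidence) + list(cnv_calls):
        key = ("", fusion)
        if not any(n[1] == fusion for n in names) and key not in seen:
            seen.add(key)
            names.append(key)

    records = []
    for sample, fusion in names:
        records.append(
            FusionCallRecord(
                sample_id=sample,
                fusion=fusion,
                cnv_called=bool(cnv_calls.get(fusion, False)),
                read_supported=count(fusion) >= 1,
            )
        )
    return records


# ---------------------------------------------------------------------------
# tabular IO

def load_cnv_table(path: str | Path) -> list[CnvSegment]:
    """Read a CNV segment TSV (1-based inclusive coordinates in the file)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "contig": str})
    required = {"sample_id", "contig", "start", "end", "kind", "marker_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CNV table missing columns: {sorted(missing)}")
    segments = []
    for row in df.itertuples(index=False):
        segments.append(
            CnvSegment(
                sample_id=row.sample_id,
                contig=row.contig,
                start=int(row.start) - 1,  # to 0-based half-open
                end=int(row.end),
                kind=row.kind,
                marker_count=int(row.marker_count),
            )
        )
    return segments


def write_cnv_table(segments: Sequence[CnvSegment], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "contig": s.contig,
            "start": s.start + 1,  # back to 1-based inclusive
            "end": s.end,
            "kind": s.kind,
            "marker_count": s.marker_count,
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def candidates_to_frame(candidates: Sequence[FusionCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "fusion": c.name,
                "five_gene": c.five_gene,
                "three_gene": c.three_gene,
                "five_breakpoint": c.five_breakpoint + 1,  # 1-based display
                "three_breakpoint": c.three_breakpoint + 1,
                "mechanism": c.mechanism,
                "requires_inversion": c.requires_inversion,
                "source_segments": ";".join(c.source_segments),
            }
            for c in candidates
        ]
    )


def records_to_frame(records: Sequence[FusionCallRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "fusion": r.fusion,
                "cnv_called": r.cnv_called,
                "read_supported": r.read_supported,
                "stated": r.stated,
            }
            for r in records
        ]
    )
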