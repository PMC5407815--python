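"""Junction read support: matching, classification, deduplication.

Reads are matched to junction templates with an internal seed-and-extend
matcher: exact k-mer seeds define candidate diagonals, each diagonal is
extended ungapped over the full read/template overlap, and the match is the
maximum-identity run whose reference span does not exceed the configured
cap.  The screening filters follow the junction-read counting scheme the
package implements: at least ``min_matched_bases`` identities are required
(default 70, of an assumed 75-base mapped span), and the reference span
from map-start to map-end may not exceed ``max_reference_span`` (default
80).

A mate is *spanning* when its match covers the junction with strictly more
than the template's minimum overlap on each side.  A pair is a *split pair*
when neither mate spans, one maps entirely on the 5' side and the other
entirely on the 3' side (the insert counts with the 3' side).  Fragments
are deduplicated to unique supporting templates by their match start
coordinates and orientations.  Reads that tie between templates of
different gene pairs (pseudogene-like ambiguity) are excluded from support
and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .junction_templates import JunctionTemplate
from .reference_io import reverse_complement

__all__ = [
    "FilterParams",
    "ReadMatch",
    "SupportEvidence",
    "TemplateIndex",
    "match_read",
    "classify_pair",
    "assign_pair",
    "collect_evidence",
    "collect_evidence_from_fastq",
    "iter_fastq_pairs",
]


@dataclass(frozen=True)
class FilterParams:
    """Read-filtering thresholds for junction support extraction."""

    min_matched_bases: int = 70
    assumed_read_span: int = 75
    max_reference_span: int = 80
    default_min_breakpoint_overlap: int = 2
    seed_length: int = 11

    def __post_init__(self):
        if not (
            0
            < self.min_matched_bases
            <= self.assumed_read_span
            <= self.max_reference_span
        ):
            raise ValueError(
                "require 0 < min_matched_bases <= assumed_read_span "
                "<= max_reference_span"
            )
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")


@dataclass(frozen=True)
class ReadMatch:
    """An accepted ungapped match of one read on one template."""

    read_id: str
    mate: int
    template_id: str
    ref_start: int
    ref_end: int
    matched_bases: int
    orientation: str  # "forward" | "revcomp"

    def __post_init__(self):
        if not self.ref_start < self.ref_end:
            raise ValueError("ref_start must precede ref_end")
        if self.matched_bases > self.ref_end - self.ref_start:
            raise ValueError("matched_bases cannot exceed the reference span")


@dataclass
class SupportEvidence:
    """Per-template junction support after classification and dedup."""

    template_id: str
    spanning: list[ReadMatch] = field(default_factory=list)
    split_pairs: list[tuple[ReadMatch, ReadMatch]] = field(default_factory=list)
    unique_count: int = 0
    ambiguous_count: int = 0
    total_supporting: int = 0

    @property
    def raw_supporting(self) -> int:
        """Spanning reads plus split pairs, before dedup (cf. unique_count)."""
        return len(self.spanning) + len(self.split_pairs)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


class TemplateIndex:
    """Exact k-mer index over a set of junction templates."""

    def __init__(self, templates: Sequence[JunctionTemplate], params: FilterParams):
        ids = [t.template_id for t in templates]
        if len(set(ids)) != len(ids):
            raise ValueError("template ids must be unique")
        self.params = params
        self.templates = {t.template_id: t for t in templates}
        self.arrays = {t.template_id: _encode(t.sequence) for t in templates}
        k = params.seed_length
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for t in templates:
            seq = t.sequence.upper()
            for pos in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos : pos + k], []).append(
                    (t.template_id, pos)
                )

    def _diagonals(self, read: str) -> dict[str, set[int]]:
        k = self.params.seed_length
        hits: dict[str, set[int]] = {}
        for i in range(len(read) - k + 1):
            for tid, pos in self.kmers.get(read[i : i + k], ()):
                hits.setdefault(tid, set()).add(pos - i)
        return hits

    def best_matches(
        self, read: str, read_id: str = "", mate: int = 1
    ) -> dict[str, ReadMatch]:
        """Best accepted match per template, both orientations tried.

        The best candidate maximises matched bases; ties prefer the smaller
        template start, then the forward orientation.
        """
        read = read.upper()
        out: dict[str, tuple[tuple, ReadMatch]] = {}
        for orientation, oriented in (
            ("forward", read),
            ("revcomp", reverse_complement(read)),
        ):
            arr = _encode(oriented)
            for tid, diagonals in self._diagonals(oriented).items():
                tarr = self.arrays[tid]
                for d in sorted(diagonals):
                    cand = _extend(arr, tarr, d, self.params)
                    if cand is None:
                        continue
                    matched, ref_start, ref_end = cand
                    rank = (-matched, ref_start, orientation != "forward")
                    if tid not in out or rank < out[tid][0]:
                        out[tid] = (
                            rank,
                            ReadMatch(
                                read_id=read_id,
                                mate=mate,
                                template_id=tid,
                                ref_start=ref_start,
                                ref_end=ref_end,
                                matched_bases=matched,
                                orientation=orientation,
                            ),
                        )
        return {
            tid: m
            for tid, (_, m) in out.items()
            if m.matched_bases >= self.params.min_matched_bases
        }


def _extend(
    read_arr: np.ndarray, tarr: np.ndarray, d: int, params: FilterParams
) -> tuple[int, int, int] | None:
    """Ungapped extension on one diagonal.

    Returns (matched_bases, ref_start, ref_end) of the maximum-identity
    window with span <= max_reference_span, trimmed to its first and last
    identity; leftmost window on ties.
    """
    r0 = max(0, -d)
    r1 = min(len(read_arr), len(tarr) - d)
    if r1 - r0 < 1:
        return None
    eq = read_arr[r0:r1] == tarr[r0 + d : r1 + d]
    n = r1 - r0
    w = min(params.max_reference_span, n)
    cs = np.concatenate(([0], np.cumsum(eq, dtype=np.int64)))
    sums = cs[w:] - cs[:-w]
    best = int(np.argmax(sums))  # leftmost maximum
    matched = int(sums[best])
    if matched == 0:
        return None
    window = eq[best : best + w]
    inside = np.flatnonzero(window)
    lo = best + int(inside[0])
    hi = best + int(inside[-1]) + 1
    return matched, d + r0 + lo, d + r0 + hi


def match_read(
    read: str,
    template: JunctionTemplate,
    params: FilterParams,
    *,
    read_id: str = "",
    mate: int = 1,
) -> ReadMatch | None:
    """Best accepted match of one read on one template, or None."""
    if len(read) < params.seed_length:
        raise ValueError("read shorter than seed length")
    index = TemplateIndex([template], params)
    return index.best_matches(read, read_id, mate).get(template.template_id)


def _is_spanning(m: ReadMatch, bp: int, min_overlap: int) -> bool:
    return (bp - m.ref_start) > min_overlap and (m.ref_end - bp) > min_overlap


def classify_pair(
    m1: ReadMatch | None,
    m2: ReadMatch | None,
    template: JunctionTemplate,
    params: FilterParams,
) -> tuple[str, list[ReadMatch]]:
    """Classify a mate pair as ('spanning' | 'split_pair' | 'none').

    Returns the category and the supporting matches (the spanning mates,
    or both mates of a split pair).  Symmetric in mate order.
    """
    present = [m for m in (m1, m2) if m is not None]
    if not present:
        return "none", []
    if len({m.template_id for m in present}) > 1:
        raise ValueError("mates matched on different templates")
    if present[0].template_id != template.template_id:
        raise ValueError("matches do not belong to the given template")
    bp = template.breakpoint_offset
    minov = template.min_breakpoint_overlap
    spanning = [m for m in present if _is_spanning(m, bp, minov)]
    if spanning:
        return "spanning", spanning
    if len(present) == 2:
        a, b = present
        five_side = lambda m: m.ref_end <= bp
        three_side = lambda m: m.ref_start >= bp
        if (five_side(a) and three_side(b)) or (five_side(b) and three_side(a)):
            return "split_pair", [a, b]
    return "none", []


def _fragment_key(matches: Sequence[ReadMatch]) -> tuple:
    return tuple(sorted((m.ref_start, m.orientation) for m in matches))


def assign_pair(
    index: TemplateIndex,
    m1s: dict[str, ReadMatch],
    m2s: dict[str, ReadMatch],
    params: FilterParams,
) -> tuple[str | None, str, list[ReadMatch], list[str]]:
    """Assign a mate pair to its best template and classify it.

    Returns (template_id | None, category, supporting matches, tied ids).
    The winning template maximises the combined matched bases of the
    accepted mates.  An exact tie across templates of different gene pairs
    is ambiguous (category 'ambiguous', tied ids returned); a tie within
    one gene pair is dropped (category 'tie').
    """
    tids = set(m1s) | set(m2s)
    if not tids:
        return None, "none", [], []
    scores = {
        tid: (m1s[tid].matched_bases if tid in m1s else 0)
        + (m2s[tid].matched_bases if tid in m2s else 0)
        for tid in tids
    }
    top = max(scores.values())
    winners = [tid for tid, s in scores.items() if s == top]
    if len(winners) > 1:
        gene_pairs = {index.templates[tid].gene_pair for tid in winners}
        if len(gene_pairs) > 1:
            return None, "ambiguous", [], sorted(winners)
        return None, "tie", [], sorted(winners)
    tid = winners[0]
    category, matches = classify_pair(
        m1s.get(tid), m2s.get(tid), index.templates[tid], params
    )
    return tid, category, matches, []


def collect_evidence(
    read_pairs: Iterable[tuple[str, str, str]],
    templates: Sequence[JunctionTemplate],
    params: FilterParams,
) -> dict[str, SupportEvidence]:
    """Collect per-template support from paired reads.

    ``read_pairs`` yields (read_id, mate1_sequence, mate2_sequence).  Each
    pair is assigned to the template with the highest combined matched-base
    score of its accepted mates; exact score ties across templates of
    different gene pairs mark the pair ambiguous (excluded from support),
    ties within one gene pair are simply dropped.  Fragments are
    deduplicated by match start coordinates and orientations.
    """
    index = TemplateIndex(templates, params)
    evidence = {t.template_id: SupportEvidence(t.template_id) for t in templates}
    keys: dict[str, set] = {t.template_id: set() for t in templates}

    for read_id, seq1, seq2 in read_pairs:
        m1s = index.best_matches(seq1, read_id, 1)
        m2s = index.best_matches(seq2, read_id, 2)
        tid, category, matches, tied = assign_pair(index, m1s, m2s, params)
        if tid is None:
            if category == "ambiguous":
                for t in tied:
                    evidence[t].ambiguous_count += 1
            continue
        if category == "spanning":
            evidence[tid].spanning.extend(matches)
        elif category == "split_pair":
            evidence[tid].split_pairs.append(tuple(matches))
        else:
            continue
        present = [m for m in (m1s.get(tid), m2s.get(tid)) if m is not None]
        keys[tid].add(_fragment_key(present))

    for tid, ev in evidence.items():
        ev.unique_count = len(keys[tid])
        ev.total_supporting = len(keys[tid])
    return evidence


def iter_fastq_pairs(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[str, str, str]]:
    """Iterate (read_id, seq1, seq2) from two FASTQ files (.gz allowed)."""
    import gzip

    def opener(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    from Bio import SeqIO

    with opener(path1) as fh1, opener(path2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        sentinel = object()
        from itertools import zip_longest

        for r1, r2 in zip_longest(it1, it2, fillvalue=sentinel):
            if r1 is sentinel or r2 is sentinel:
                raise ValueError("paired FASTQ files differ in read count")
            yield r1.id, str(r1.seq), str(r2.seq)


def collect_evidence_from_fastq(
    path1: str | Path,
    path2: str | Path,
    templates: Sequence[JunctionTemplate],
    params: FilterParams,
) -> dict[str, SupportEvidence]:
    """collect_evidence over a paired FASTQ file pair."""
    return collect_evidence(iter_fastq_pairs(path1, path2), templates, params)
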