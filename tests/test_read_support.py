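"""Seed-and-extend matching, spanning/split classification, dedup, filters."""

import numpy as np
import pytest

from fusionjunction.junction_templates import JunctionTemplate
from fusionjunction.read_support import (
    FilterParams,
    classify_pair,
    collect_evidence,
    match_read,
)
from fusionjunction.reference_io import reverse_complement

PARAMS = FilterParams()  # 70 / 75 / 80, overlap 2, seed 11


def make_template(seq, bp=None, tid="T", five="G5", three="G3", minov=2):
    bp = bp if bp is not None else len(seq) // 2
    return JunctionTemplate(
        template_id=tid,
        five_label=five,
        three_label=three,
        sequence=seq,
        breakpoint_offset=bp,
        insert_length=0,
        kind="fusion_junction" if five != three else "wildtype_junction",
        min_breakpoint_overlap=minov,
    )


@pytest.fixture(scope="module")
def template():
    rng = np.random.default_rng(42)
    return make_template("".join(rng.choice(list("ACGT"), size=600)), bp=300)


def mutate(seq, positions):
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = rot[out[p]]
    return "".join(out)


class TestMatchRead:
    def test_exact_substring_fully_matched(self, template):
        read = template.sequence[100:175]
        m = match_read(read, template, PARAMS)
        assert m is not None
        assert m.matched_bases == 75
        assert (m.ref_start, m.ref_end) == (100, 175)
        assert m.orientation == "forward"

    def test_revcomp_substring_found(self, template):
        read = reverse_complement(template.sequence[100:175])
        m = match_read(read, template, PARAMS)
        assert m is not None and m.orientation == "revcomp"
        assert (m.ref_start, m.ref_end) == (100, 175)

    def test_identity_threshold_70_of_75(self, template):
        read = template.sequence[100:175]
        five_off = mutate(read, [5, 20, 35, 50, 65])
        m = match_read(five_off, template, PARAMS)
        assert m is not None and m.matched_bases == 70
        six_off = mutate(read, [5, 20, 35, 50, 65, 33])
        assert match_read(six_off, template, PARAMS) is None

    def test_random_read_rejected(self, template):
        rng = np.random.default_rng(0)
        read = "".join(rng.choice(list("ACGT"), size=75))
        assert match_read(read, template, PARAMS) is None


def _oracle_best(read, tseq, params):
    """Exhaustive all-offset, all-orientation scoring oracle.

    For every diagonal, the best max-identity window of span at most
    ``max_reference_span`` is found by direct enumeration; trimming and
    tie-breaks (leftmost window, forward first) mirror the declared
    matcher contract.
    """
    best = None  # (matched, ref_start, ref_end, orientation)
    for orientation, r in (("forward", read), ("revcomp", reverse_complement(read))):
        for d in range(-(len(r) - 1), len(tseq)):
            r0, r1 = max(0, -d), min(len(r), len(tseq) - d)
            if r1 <= r0:
                continue
            eq = [r[i] == tseq[i + d] for i in range(r0, r1)]
            n = len(eq)
            w = min(params.max_reference_span, n)
            for i in range(n - w + 1):
                window = eq[i : i + w]
                matched = sum(window)
                if matched == 0:
                    continue
                lo = i + window.index(True)
                hi = i + w - 1 - window[::-1].index(True) + 1
                cand = (
                    -matched,
                    d + r0 + lo,
                    orientation != "forward",
                    d + r0 + hi,
                )
                if best is None or cand < best:
                    best = cand
    if best is None or -best[0] < params.min_matched_bases:
        return None
    return (-best[0], best[1], best[3], "revcomp" if best[2] else "forward")


def test_matcher_agrees_with_exhaustive_placement_oracle(template):
    """Accept/reject, matched bases and best placement equal the oracle for
    substring reads with up to 5 scattered mismatches (which always retain
    an exact 11-mer seed) and for unrelated random reads."""
    rng = np.random.default_rng(987)
    for _ in range(120):
        kind = rng.integers(3)
        if kind < 2:
            start = int(rng.integers(0, 525))
            read = template.sequence[start : start + 75]
            n_mut = int(rng.integers(0, 6))
            pos = rng.choice(75, size=n_mut, replace=False)
            read = mutate(read, [int(p) for p in pos])
            if kind == 1:
                read = reverse_complement(read)
        else:
            read = "".join(rng.choice(list("ACGT"), size=75))
        got = match_read(read, template, PARAMS)
        want = _oracle_best(read, template.sequence, PARAMS)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert (
                got.matched_bases, got.ref_start, got.ref_end, got.orientation
            ) == want


class TestClassifyPair:
    def test_overlap_strictly_greater_than_minimum(self, template):
        # read covering the breakpoint with 3 bases on the short side
        read = template.sequence[228:303]  # 72 five-side, 3 three-side
        m = match_read(read, template, PARAMS)
        cat, matches = classify_pair(m, None, template, PARAMS)
        assert cat == "spanning" and matches == [m]

    def test_overlap_equal_to_minimum_is_not_spanning(self):
        rng = np.random.default_rng(3)
        t5 = make_template(
            "".join(rng.choice(list("ACGT"), size=600)), bp=300, minov=5
        )
        six = match_read(t5.sequence[231 : 231 + 75], t5, PARAMS)
        cat, _ = classify_pair(six, None, t5, PARAMS)  # 6 bases on the 3' side
        assert cat == "spanning"
        five = match_read(t5.sequence[230 : 230 + 75], t5, PARAMS)
        cat, _ = classify_pair(five, None, t5, PARAMS)  # only 5 bases
        assert cat == "none"

    def test_exactly_70_spanning_placements_for_default_overlap(self, template):
        """All 526 placements of a perfect 75 bp read on a 600 bp template
        with the junction at 300: exactly starts 229..298 (1-based) span."""
        spanning_starts = []
        for start in range(0, 526):
            read = template.sequence[start : start + 75]
            m = match_read(read, template, PARAMS)
            assert m is not None
            cat, _ = classify_pair(m, None, template, PARAMS)
            if cat == "spanning":
                spanning_starts.append(start)
        assert len(spanning_starts) == 70
        assert spanning_starts == list(range(228, 298))  # 0-based

    def test_split_pair_and_symmetry(self, template):
        m1 = match_read(template.sequence[150:225], template, PARAMS)
        m2 = match_read(template.sequence[320:395], template, PARAMS)
        cat, matches = classify_pair(m1, m2, template, PARAMS)
        assert cat == "split_pair" and len(matches) == 2
        cat_swapped, _ = classify_pair(m2, m1, template, PARAMS)
        assert cat_swapped == "split_pair"

    def test_five_side_pair_is_not_split(self, template):
        m1 = match_read(template.sequence[50:125], template, PARAMS)
        m2 = match_read(template.sequence[150:225], template, PARAMS)
        assert classify_pair(m1, m2, template, PARAMS)[0] == "none"

    def test_mates_on_different_templates_error(self, template):
        other = make_template(template.sequence, bp=300, tid="U")
        m1 = match_read(template.sequence[100:175], template, PARAMS)
        m2 = match_read(template.sequence[320:395], other, PARAMS)
        with pytest.raises(ValueError):
            classify_pair(m1, m2, template, PARAMS)


class TestCollectEvidence:
    def test_identical_fragments_collapse_to_one_unique(self, template):
        span = template.sequence[260:335]
        mate = template.sequence[350:425]
        pairs = [(f"r{i}", span, reverse_complement(mate)) for i in range(10)]
        ev = collect_evidence(pairs, [template], PARAMS)["T"]
        assert len(ev.spanning) == 10
        assert ev.unique_count == 1 and ev.total_supporting == 1

    def test_distinct_starts_counted_separately(self, template):
        pairs = [
            (f"r{i}", template.sequence[260 + i : 335 + i],
             reverse_complement(template.sequence[400:475]))
            for i in range(8)
        ]
        ev = collect_evidence(pairs, [template], PARAMS)["T"]
        assert ev.total_supporting == 8

    def test_cross_gene_pair_tie_is_ambiguous(self, template):
        decoy = make_template(
            template.sequence, bp=300, tid="PSEUDO", five="P5", three="P3"
        )
        read = template.sequence[260:335]
        ev = collect_evidence(
            [("r", read, reverse_complement(template.sequence[320:395]))],
            [template, decoy],
            PARAMS,
        )
        assert ev["T"].total_supporting == 0
        assert ev["T"].ambiguous_count == 1
        assert ev["PSEUDO"].ambiguous_count == 1

    def test_same_gene_pair_tie_dropped_without_ambiguity(self, template):
        twin = make_template(
            template.sequence, bp=300, tid="T2",
            five=template.five_label, three=template.three_label,
        )
        read = template.sequence[260:335]
        ev = collect_evidence(
            [("r", read, reverse_complement(template.sequence[320:395]))],
            [template, twin],
            PARAMS,
        )
        assert ev["T"].total_supporting == 0
        assert ev["T"].ambiguous_count == 0

    def test_higher_identity_wins_over_shared_flank(self, template):
        """A template sharing only the 5' flank loses a junction-crossing
        read to the template matching it in full."""
        rng = np.random.default_rng(5)
        shared = template.sequence[:300] + "".join(
            rng.choice(list("ACGT"), size=300)
        )
        wt = make_template(shared, bp=300, tid="WT", five="G5", three="G5")
        read = template.sequence[260:335]  # crosses the junction of T
        ev = collect_evidence(
            [("r", read, reverse_complement(template.sequence[400:475]))],
            [template, wt],
            PARAMS,
        )
        assert ev["T"].total_supporting == 1
        assert ev["WT"].total_supporting == 0

    def test_mismatched_stream_lengths_error(self, tmp_path, template):
        from fusionjunction.read_support import collect_evidence_from_fastq

        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        r1.write_text("@a/1\n" + template.sequence[100:175] + "\n+\n" + "I" * 75 + "\n")
        r2.write_text("")
        with pytest.raises(ValueError, match="differ in read count"):
            collect_evidence_from_fastq(r1, r2, [template], PARAMS)


class TestFilterMonotonicity:
    def _planted_pairs(self, template, rng, n=40):
        pairs = []
        for i in range(n):
            start = int(rng.integers(228, 298))
            read = mutate(
                template.sequence[start : start + 75],
                [int(p) for p in rng.choice(75, size=int(rng.integers(0, 4)),
                                            replace=False)],
            )
            mate = template.sequence[330:405]
            pairs.append((f"r{i}", read, reverse_complement(mate)))
        return pairs

    def test_raising_min_matched_never_increases_counts(self, template):
        rng = np.random.default_rng(11)
        pairs = self._planted_pairs(template, rng)
        prev = None
        for mm in (70, 72, 74, 76, 80):
            p = FilterParams(min_matched_bases=mm, assumed_read_span=max(75, mm))
            ev = collect_evidence(pairs, [template], p)["T"]
            counts = (len(ev.spanning), len(ev.split_pairs), ev.total_supporting)
            if prev is not None:
                assert all(c <= q for c, q in zip(counts, prev))
            prev = counts

    def test_raising_breakpoint_overlap_never_increases_spanning(self, template):
        rng = np.random.default_rng(12)
        pairs = self._planted_pairs(template, rng)
        prev = None
        for minov in (0, 2, 5, 10, 20):
            t = make_template(template.sequence, bp=300, minov=minov)
            ev = collect_evidence(pairs, [t], PARAMS)["T"]
            if prev is not None:
                assert len(ev.spanning) <= prev
            prev = len(ev.spanning)


def test_accepted_matches_respect_filters_fuzz(template):
    """Filter soundness: any accepted match has span <= 80 and >= 70
    identities under default parameters, for arbitrary read content."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = int(rng.integers(20, 120))
        if rng.integers(2):
            start = int(rng.integers(0, 600 - min(n, 599)))
            read = template.sequence[start : start + n]
            read = mutate(read, [int(p) for p in rng.choice(
                len(read), size=int(rng.integers(0, max(1, len(read) // 8))),
                replace=False)])
        else:
            read = "".join(rng.choice(list("ACGT"), size=n))
        if len(read) < PARAMS.seed_length:
            continue
        m = match_read(read, template, PARAMS)
        if m is not None:
            assert m.ref_end - m.ref_start <= 80
            assert m.matched_bases >= 70
            assert m.matched_bases <= m.ref_end - m.ref_start
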