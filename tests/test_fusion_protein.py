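"""Fusion cDNA assembly, reading-frame calls, translation, domains, PCR."""

import numpy as np
import pytest

from fusionjunction.fusion_protein import (
    DomainAnnotation,
    PrimerPair,
    assemble_fusion_cds,
    classify_frame,
    in_silico_pcr,
    translate_fusion,
)
from fusionjunction.reference_io import reverse_complement, transcript_sequence

from conftest import build_toy


class TestAssembly:
    def test_matches_per_base_concatenation(self, scaffold):
        tx5 = scaffold.transcripts["GTF2I"]
        tx3 = scaffold.transcripts["BRAF"]
        ins = scaffold.insert_17bp
        ft = assemble_fusion_cds(tx5, 19, tx3, 10, ins, scaffold.genome)
        s5 = transcript_sequence(scaffold.genome, tx5)
        s3 = transcript_sequence(scaffold.genome, tx3)
        b5 = tx5.exon_end_offset(19)
        o3 = tx3.exon_offset(10)
        assert ft.fused_cdna == s5[:b5] + ins + s3[o3:]
        assert ft.junction_offset == b5
        assert len(ft.fused_cdna) == b5 + 17 + (len(s3) - o3)

    def test_empty_insert_offset_is_prefix_length(self, scaffold):
        tx5 = scaffold.transcripts["KIAA1549"]
        tx3 = scaffold.transcripts["BRAF"]
        ft = assemble_fusion_cds(tx5, 16, tx3, 9, "", scaffold.genome)
        assert ft.junction_offset == tx5.exon_end_offset(16)
        assert ft.fused_cdna.startswith(
            transcript_sequence(scaffold.genome, tx5)[: ft.junction_offset]
        )

    def test_bad_exon_indices(self, scaffold):
        tx5 = scaffold.transcripts["GTF2I"]
        tx3 = scaffold.transcripts["BRAF"]
        with pytest.raises(ValueError):
            assemble_fusion_cds(tx5, 0, tx3, 10, "", scaffold.genome)
        with pytest.raises(ValueError):
            assemble_fusion_cds(tx5, 19, tx3, 99, "", scaffold.genome)


def _coding_spliced(rng, n_codons, utr5, utr3):
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    cds = "".join(codons) + "TAA"
    seq = (
        "".join(rng.choice(list("ACGT"), size=utr5))
        + cds
        + "".join(rng.choice(list("ACGT"), size=utr3))
    )
    return seq, utr5, utr5 + len(cds)


def _random_coding_gene(rng, name, n_exons=3):
    n_codons = int(rng.integers(40, 90))
    utr5 = int(rng.integers(0, 12))
    spliced, cs, ce = _coding_spliced(rng, n_codons, utr5, int(rng.integers(10, 30)))
    cuts = sorted(rng.choice(range(10, len(spliced) - 10), size=n_exons - 1,
                             replace=False))
    bounds = [0] + [int(c) for c in cuts] + [len(spliced)]
    exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
    return {
        "gene": name, "strand": "+", "spliced": spliced,
        "exon_lens": exon_lens, "cds_start": cs, "cds_end": ce,
    }


class TestFrameClassification:
    def test_codon_boundary_no_insert_is_in_frame(self, rng):
        spec5 = _random_coding_gene(rng, "F5")
        spec3 = _random_coding_gene(rng, "F3")
        # force: junction at 5' codon boundary, entry at 3' codon boundary
        spec5["cds_start"] = 0
        spec5["cds_end"] = 3 * (len(spec5["spliced"]) // 3)
        spec5["exon_lens"] = [30, len(spec5["spliced"]) - 30]
        spec3["cds_start"] = 0
        spec3["cds_end"] = 3 * (len(spec3["spliced"]) // 3)
        spec3["exon_lens"] = [27, len(spec3["spliced"]) - 27]
        genome, (tx5, tx3) = build_toy(rng, [spec5, spec3])
        in_frame = assemble_fusion_cds(tx5, 1, tx3, 2, "", genome)
        assert classify_frame(in_frame) == "in_frame"
        shifted = assemble_fusion_cds(tx5, 1, tx3, 2, "G", genome)
        assert classify_frame(shifted) == "out_of_frame"
        assert classify_frame(
            assemble_fusion_cds(tx5, 1, tx3, 2, "GGG", genome)
        ) == "in_frame"

    def test_agrees_with_translation_oracle_on_random_fusions(self, rng):
        """On 500 random toy fusions with insert lengths 0-30, the phase
        rule agrees with direct translation: in-frame iff the fusion
        protein terminates with the 3' wild-type protein's C-terminus."""
        checked = 0
        while checked < 500:
            spec5 = _random_coding_gene(rng, "F5")
            spec3 = _random_coding_gene(rng, "F3")
            genome, (tx5, tx3) = build_toy(rng, [spec5, spec3])
            last5 = int(rng.integers(1, tx5.n_exons + 1))
            if tx5.exon_end_offset(last5) <= tx5.cds_start:
                continue
            # pick a 3' entry exon inside the CDS, well before the stop
            entries = [
                i
                for i in range(1, tx3.n_exons + 1)
                if tx3.cds_start
                <= tx3.exon_offset(i)
                <= tx3.cds_end - 30
            ]
            if not entries:
                continue
            first3 = int(rng.choice(entries))
            insert = "".join(rng.choice(list("ACGT"),
                                        size=int(rng.integers(0, 31))))
            ft = assemble_fusion_cds(tx5, last5, tx3, first3, insert, genome)
            # oracle: walk codons straight through (no stop cut) and ask
            # whether the 3' wild-type residue sequence reappears downstream
            from Bio.Seq import Seq

            orf = ft.fused_cdna[tx5.cds_start :]
            full = str(Seq(orf[: len(orf) - len(orf) % 3]).translate())
            wt3, _ = _translate(transcript_sequence(genome, tx3), tx3.cds_start)
            tail = wt3[-8:]
            oracle_in_frame = tail in full
            assert (classify_frame(ft) == "in_frame") == oracle_in_frame
            checked += 1


def _translate(cdna, start):
    from Bio.Seq import Seq

    orf = cdna[start:]
    orf = orf[: len(orf) - len(orf) % 3]
    protein = str(Seq(orf).translate())
    if "*" in protein:
        return protein[: protein.index("*")], True
    return protein, False


class TestTranslation:
    def test_out_of_frame_seven_novel_residues(self, rng):
        """Hand-constructed out-of-frame junction: one hybrid codon plus six
        shifted codons before the stop gives 7 novel residues."""
        spliced5 = "ATG" + "GGC" * 9 + "A"  # junction 1 base into codon 11
        spliced3 = "CA" + "GGC" * 6 + "TAA" + "CAT" * 20
        genome, (tx5, tx3) = build_toy(
            np.random.default_rng(0),
            [
                {"gene": "F5", "strand": "+", "spliced": spliced5,
                 "exon_lens": [len(spliced5)], "cds_start": 0, "cds_end": 30},
                {"gene": "F3", "strand": "+", "spliced": spliced3,
                 "exon_lens": [len(spliced3)], "cds_start": 0, "cds_end": 21},
            ],
        )
        ft = assemble_fusion_cds(tx5, 1, tx3, 1, "", genome)
        rep = translate_fusion(ft, genome=genome)
        assert rep.frame == "out_of_frame"
        assert rep.protein_length == 17  # 10 parental + 7 novel
        assert rep.new_aa_count == 7
        assert rep.five_breakpoint_aa == 10

    def test_in_frame_length_equals_direct_translation(self, scaffold):
        tx5 = scaffold.transcripts["GTF2I"]
        tx3 = scaffold.transcripts["BRAF"]
        ft = assemble_fusion_cds(
            tx5, 19, tx3, 10, scaffold.insert_17bp, scaffold.genome
        )
        rep = translate_fusion(ft, genome=scaffold.genome)
        protein, stopped = _translate(ft.fused_cdna, tx5.cds_start)
        assert stopped and rep.protein_length == len(protein)
        assert rep.frame == "in_frame"

    def test_self_fusion_reproduces_wildtype_protein(self, scaffold):
        tx = scaffold.transcripts["GTF2I"]
        ft = assemble_fusion_cds(tx, 10, tx, 11, "", scaffold.genome)
        rep = translate_fusion(ft, genome=scaffold.genome)
        wt, _ = _translate(
            transcript_sequence(scaffold.genome, tx), tx.cds_start
        )
        assert rep.protein_sequence == wt
        assert rep.new_aa_count == 0 and rep.frame == "in_frame"

    def test_junction_upstream_of_start_codon_reports_non_coding(self, rng):
        spec5 = _random_coding_gene(rng, "F5")
        spec5["cds_start"] = len(spec5["spliced"]) - 31
        spec5["cds_end"] = spec5["cds_start"] + 30
        spec5["exon_lens"] = [10, len(spec5["spliced"]) - 10]
        spec3 = _random_coding_gene(rng, "F3")
        genome, (tx5, tx3) = build_toy(rng, [spec5, spec3])
        rep = translate_fusion(
            assemble_fusion_cds(tx5, 1, tx3, 1, "", genome), genome=genome
        )
        assert not rep.coding and rep.protein_length == 0


class TestDomains:
    def _report(self, scaffold, domains):
        tx5 = scaffold.transcripts["GTF2I"]
        tx3 = scaffold.transcripts["BRAF"]
        ft = assemble_fusion_cds(
            tx5, 19, tx3, 10, scaffold.insert_17bp, scaffold.genome
        )
        return translate_fusion(ft, domains, genome=scaffold.genome)

    def test_retention_and_truncation(self, scaffold):
        rep0 = self._report(scaffold, [])
        bp5, bp3 = rep0.five_breakpoint_aa, rep0.three_breakpoint_aa
        domains = [
            DomainAnnotation("SIM_GTF2I", "DNA_binding", 10, 100),
            DomainAnnotation("SIM_GTF2I", "cut_by_breakpoint", bp5 - 5, bp5 + 5),
            DomainAnnotation("SIM_GTF2I", "lost_downstream", bp5 + 10, bp5 + 40),
            DomainAnnotation("SIM_BRAF", "kinase", bp3 + 20, bp3 + 120),
            DomainAnnotation("SIM_BRAF", "lost_N_terminal", 5, bp3 - 10),
            DomainAnnotation("SIM_BRAF", "cut_3prime", bp3 - 5, bp3 + 5),
        ]
        rep = self._report(scaffold, domains)
        assert set(rep.retained_domains) == {"DNA_binding", "kinase"}
        assert set(rep.truncated_domains) == {"cut_by_breakpoint", "cut_3prime"}

    def test_retention_monotone_in_breakpoint_position(self, scaffold):
        """Moving the 5' breakpoint later never loses a retained 5' domain."""
        tx5 = scaffold.transcripts["GTF2I"]
        tx3 = scaffold.transcripts["BRAF"]
        domains = [
            DomainAnnotation("SIM_GTF2I", f"D{i}", 50 * i, 50 * i + 40)
            for i in range(1, 60)
        ]
        previous: set[str] = set()
        for last5 in range(5, 20):
            ft = assemble_fusion_cds(tx5, last5, tx3, 10, "", scaffold.genome)
            rep = translate_fusion(ft, domains, genome=scaffold.genome)
            retained = set(rep.retained_domains)
            assert previous <= retained
            previous = retained


class TestInSilicoPcr:
    def test_product_size_by_hand(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=60))
        fwd = "".join(rng.choice(list("ACGT"), size=20))
        rev_site = "".join(rng.choice(list("ACGT"), size=20))
        template = "AA" + fwd + core + rev_site + "TT"
        primers = PrimerPair("p", fwd, reverse_complement(rev_site))
        assert in_silico_pcr(template, primers) == [100]

    def test_wrong_orientation_gives_no_product(self, rng):
        fwd = "".join(rng.choice(list("ACGT"), size=20))
        rev_site = "".join(rng.choice(list("ACGT"), size=20))
        template = rev_site + "ACGT" * 20 + fwd  # reverse site upstream
        primers = PrimerPair("p", fwd, reverse_complement(rev_site))
        assert in_silico_pcr(template, primers) == []

    def test_repeated_binding_site_gives_two_products(self, rng):
        fwd = "".join(rng.choice(list("ACGT"), size=20))
        rev_site = "".join(rng.choice(list("ACGT"), size=20))
        template = fwd + "A" * 30 + rev_site + "C" * 30 + rev_site
        primers = PrimerPair("p", fwd, reverse_complement(rev_site))
        assert in_silico_pcr(template, primers) == [70, 120]
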