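# fusionjunction

A reusable pipeline for discovering and quantifying gene fusions created
by genomic tandem duplications, from combined copy-number (CNV) and
RNA-seq evidence — the class of rearrangement that drives pilocytic
astrocytoma (PA), where a duplication on 7q34 fuses the 5' end of
*KIAA1549* to the kinase domain of *BRAF*, and where rarer variants such
as *GTF2I-BRAF* arise from two duplications joined by a circularization
event.  It is written for bioinformaticians who need a transparent,
fully-testable implementation of junction-read counting around candidate
breakpoints rather than a black-box fusion caller.

## What it computes

**CNV candidates.** Called segments are filtered by the calling
thresholds (length ≥ 200 kb and marker count ≥ 50 by default;
configurable).  A single gain whose breakpoints fall inside two genes is
modelled as a head-to-tail tandem duplication: the derived junction joins
the sequence left of the segment end to the segment start, and a fusion
candidate is emitted when a gene transcribes across that junction into a
co-oriented partner (either reading direction of the derived allele).
Two same-contig gains are additionally modelled as a reintegrated circle
in both relative orientations; opposite-strand partners are reported as
requiring an inversion.

**Junction templates and read support.** For every junction of interest
a template of up to 600 bp is cut from spliced mRNA — 300 bases from the
5' side and 300 from the 3' side, plus an optional intronic insert
counted with the 3' side.  Reads are matched by a seed-and-extend,
ungapped local aligner; a match is accepted when at least 70 bases map
coherently (of an assumed 75-base span) with a reference span of at most
80 bases (all parameters).  A read is **spanning** when its match covers
the junction with strictly more than the per-template minimum overlap on
each side (>2 by default, >5 for noisier junctions); a **split pair**
maps one mate entirely on each side.  Fragments are deduplicated by
placement to *unique supporting fragments*; reads that tie between
templates of different gene pairs (pseudogene-style ambiguity) are
excluded.

**Expression.** Junction expression is the unique supporting fragment
count normalized to the sample's total raw reads (reported per million);
fold changes between junctions and across sample groups use each
sample's own normalization.

**Fusion proteins.** The fused cDNA is the 5' spliced prefix + insert +
3' spliced suffix.  The junction is in frame when the 3' partner's
native codon phase is restored (prefix CDS bases + insert + 3' phase
lead ≡ 0 mod 3); translation runs to the first stop, novel residues and
retained/truncated protein domains are reported, and exact-match
in-silico PCR sizes the junction amplicons.

**Stating.** A coding fusion is *stated* for a sample only when both
criteria hold: a CNV gain/loss call supports it **and** at least one
supporting fragment is found in the RNA-seq data.

**Synthetic study.** Because the real study's raw data are not publicly
deposited, the package ships a deterministic generator
(`fusionjunction.synthetic_data`) that emulates the six-sample design on
a ~87 kb toy genome: five samples with the common KIAA1549-BRAF 16-9
duplication (one read-negative with a flat CNV profile) and one sample
with two circularized duplications yielding GTF2I-BRAF 19-10 (17 bp
intron-9 insert, in frame) and DENND2A-GTF2IRD1 14-2 (out of frame), at
the study's observed support levels and expression ratios, with a truth
manifest for exact verification.

## Worked example

```bash
python examples/04_expression_folds.py
```

prints (seed 1):

```
GTF2I-BRAF support in PA3: 109 fragments (16029.4 per million raw reads)
wild-type GTF2I over the fusion:     18-fold
GTF2I-BRAF over KIAA1549-BRAF:       13-fold
wild-type GTF2I over KIAA1549:       106-fold
wild-type DENND2A over its fusion:   6-fold
```

The 109 fragments are the unique deduplicated placements supporting the
GTF2I-BRAF junction (115 spanning reads plus 9 split pairs before
dedup); the fold changes compare normalized junction expression — the
fusion is expressed far below its wild-type 5' partner, but well above
the KIAA1549-BRAF fusions of the other samples, reflecting the stronger
promoter.  `examples/05_fusion_protein.py` reconstructs the fusion
proteins (GTF2I-BRAF in frame through its 17 bp insert,
DENND2A-GTF2IRD1 out of frame with novel C-terminal residues) and sizes
the junction RT-PCR products (222 / 291 / 249 bp).

A thin CLI mirrors the stages:

```bash
fusionjunction simulate --scenario study --seed 1 --out sim/
fusionjunction candidates --genome sim/reference.fa --annotation sim/annotation.bed \
    --cnv sim/cnv.tsv --min-length 2000 --min-markers 10 --out candidates.tsv
fusionjunction run-all --config pipeline.cfg --out results/
```

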