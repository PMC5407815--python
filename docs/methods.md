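# Methods

This note documents the models, parameters and numerical choices behind
`fusionjunction`, and what the synthetic study does and does not
demonstrate about real data.

## Rearrangement model

A copy-number **gain** `[s, e)` is interpreted as a head-to-tail tandem
duplication.  On the derived allele the novel junction joins the base at
`e-1` to the base at `s`.  Whether a fusion gene results depends only on
the transcription directions of the genes containing the breakpoints:
reading the derived allele left-to-right, a plus-strand gene at `e` can
run into a plus-strand gene at `s`; reading right-to-left (the reverse
complement), a minus-strand gene at `s` can run into a minus-strand gene
at `e`.  Both readings are enumerated.  When the two breakpoint genes
are on opposite strands no colinear fusion exists and the candidate is
emitted with `requires_inversion = True`, modelling a duplication whose
second copy is inverted.

Two same-sample gains on one contig are additionally modelled as a
**circularized pair**: the two segments join into a circle that is
reintegrated elsewhere.  The circle has two junctions and two relative
orientations (second segment same-sense or inverted); all four junction
readings are enumerated and each orientation-consistent gene pair
becomes a candidate.  No distance cutoff is applied between the gains
(the motivating rearrangement spans ~25 Mb).  The integration site of
the circle is unknowable from segment data, so only junctions are
scored, never genomic position of reinsertion.

**Losses** are accepted as deletion fusions joining the flanking
sequence; they are reported under the `tandem_dup` mechanism label since
the candidate record's mechanism enum has no separate deletion member.
Gene extent for breakpoint mapping runs from first exon start to last
exon end (introns included), because DNA-level fusion breakpoints are
intronic.

Segment filtering defaults to length ≥ 200 000 bp and ≥ 50 markers,
the array-calling thresholds of the motivating study; the synthetic
study scales them to 2 000 bp / 10 markers to match its kb-scale events
(marker density 1 per 150 bp).

## Junction templates

A junction template is at most 300 bases of spliced mRNA on each side
of the junction, truncated when a transcript end is nearer.  Fusion
templates may include an intronic insert between the sides.  The insert
is treated as 3'-side, fusion-specific sequence: the classification
breakpoint sits at the 5'-partner/insert boundary, so a read entering
the insert from the 5' side counts as junction-crossing.  "Spliced
mRNA" deliberately includes UTR — one of the modelled junctions lands
6 bp upstream of the 3' partner's start codon.  Template IDs follow
`GENE5-GENE3_eN-eM` in the exon numbering of the supplied models.
Automatic discovery of insert sequences from read data is out of scope;
inserts are inputs (planted by the generator or supplied by the user).

## Read matching and support filters

The matcher is a deterministic seed-and-extend, **ungapped** local
aligner: exact k-mer seeds (k = 11) nominate diagonals, each diagonal is
scored over its full read/template overlap, and the reported match is
the maximum-identity window whose reference span does not exceed the
cap, trimmed to its first and last identity (ties: leftmost window,
smaller template start, forward orientation).  Acceptance requires
`matched_bases >= 70` within a span of at most 80 (defaults; the
70-of-75 rule with 5 bases of span slack).  Because extension is
ungapped, reads containing indels relative to the template lose
sensitivity that a gapped aligner would retain; this is a known,
documented divergence.  A read with more than 5 mismatches in 75 bases
may also lack an exact 11-mer seed; at the acceptance threshold
(≤ 5 mismatches) a seed always exists by pigeonhole.

The default span parameters describe 75-base mapping; the simulated
libraries are 2 × 100 bp, and the pipeline configuration for them keeps
the identity floor at 70 while scaling the span cap to read length + 5
(`simulated_filter_params`).  Both parameterizations are explicit
`FilterParams` values — the tension between the 75-base filter
arithmetic of the defaults and 100-base sequencing is preserved as
configuration, not silently resolved.

Classification: a mate is **spanning** iff its match covers the
breakpoint with *strictly more* than the template's minimum overlap on
each side (default >2; per-template overrides, e.g. >5 where flank
sequence is repetitive); a pair is a **split pair** iff neither mate
spans, one lies entirely 5' and the other entirely 3' of the junction.
Each fragment is assigned to the template maximising the combined
matched bases of its accepted mates.  An exact tie across templates of
*different* gene pairs marks the fragment ambiguous and removes it from
support (the pseudogene guard); ties within one gene pair are dropped.
Pair-level scoring is what disambiguates templates sharing a flank
(wild-type vs fusion): the mate beyond the shared sequence decides.
Unique support is counted by collapsing fragments with identical
(match start, orientation) keys — the finest information a junction
coverage plot displays — so PCR duplicates count once.  Raw spanning
read and split-pair counts are reported alongside the deduplicated
fragment count, since the two bookkeepings differ (115 + 9 raw supports
collapse to 109 unique fragments in the flagship scenario).

Monotonicity (raising thresholds never increases counts) holds per
template; across templates, reassignment under a changed threshold can
in principle move a fragment between templates, so the property is
stated and tested at the single-template level.

## Expression and fold changes

Junction expression = unique supporting fragments / total raw reads in
the sample ("fpm" = per million).  Normalization uses single reads (a
pair contributes 2 to the denominator); this is configurable in spirit
by passing the appropriate total.  Cross-sample comparisons compute
each sample's fpm against its own total and aggregate with the
arithmetic mean (median available) before forming the ratio.  Integer
folds are round-half-up of max(ratio, 1/ratio) with a direction flag;
`log2_fpm` is reported as missing for zero support rather than −inf.

## Reading frame and fusion proteins

With `b5` the junction offset in the 5' transcript, `cds5` its CDS
start, `ins` the insert length and `lead3` the number of 3'-partner
bases preceding that partner's next native codon boundary, the junction
is in frame iff `(b5 − cds5) + ins + lead3 ≡ 0 (mod 3)`.  When the
junction lands upstream of the 3' start codon, `lead3` is the full
distance to the ATG, so in-frame means the 5' ORF reads through into
the native ORF.  Translation runs from the 5' start codon to the first
stop (standard nuclear code); a missing stop is flagged
`runs_off_transcript`.  Frame classification is pure phase arithmetic —
an in-frame fusion whose insert happens to encode a stop is still
called in frame, and the truncation shows in the protein length.

Novel residues: out-of-frame fusions count every residue from the
junction-affected codon onward (the 5' prefix is unchanged, everything
after it is new).  In-frame fusions count hybrid junction codons whose
residue matches neither parent, computed by subtracting the longest
parental prefix and suffix.  Domains wholly inside a retained parental
residue range are retained; domains cut by a breakpoint are listed
separately as truncated; 3'-partner domains are only considered for
in-frame fusions.  In-silico PCR is exact-match: forward primer on the
given strand, reverse primer as its reverse complement strictly
downstream; all products are reported, sized from forward 5' end
through reverse 5' end inclusive.

## Synthetic study

`build_scaffold` lays out analogs of GTF2IRD1(+), GTF2I(+),
KIAA1549(−), DENND2A(−) and BRAF(−) plus three bystander genes on one
~87 kb contig, reproducing the relative order and strands of the real
loci.  CDS phases are arranged so the KIAA1549-BRAF 16-9 junction and
the GTF2I-BRAF 19-10 junction (through its 17 bp BRAF-intron-9 insert)
are in frame while DENND2A-GTF2IRD1 14-2 (joining 6 bp upstream of the
GTF2IRD1 ATG) is out of frame.  Exons are drawn at 610–700 bp — longer
than real exons — so that no 600 bp template contains a second
junction; this keeps template attribution well defined and is the main
deliberate unrealism of the scaffold.  Breakpoints sit mid-intron;
exonic breakpoints are rejected.

Reads are stranded 2 × 100 bp pairs with constant qualities (the
filters are identity-based, qualities are ignored), fragment length
N(300, 30), substitution errors at a configurable rate (default 0 — the
recovery guarantees are stated at zero error).  Junction support is
planted explicitly per junction as single-spanning, double-spanning and
split fragments at distinct placement keys; each planted fragment is
verified to be uniquely attributable to its intended template (via the
same assignment rule the pipeline uses) and re-placed on the rare
sequence coincidence, so the truth manifest's expected counts are exact
by construction.  Background fragments come from bystander transcripts
only, so planted junction counts are not contaminated; junction-local
coverage is therefore controlled directly rather than emerging from a
transcript-abundance model.  Passing tests consequently demonstrate
correctness of the counting/classification machinery, not robustness to
real-library phenomena (indels, quality-dependent errors, coverage
bias, intron retention).

The six-sample study plants the motivating study's observed support
structure as its default conditions: 109 GTF2I-BRAF fragments (115
spanning + 9 split) and 11 DENND2A-GTF2IRD1 fragments in the
two-duplication sample; 6/7/9/11 KIAA1549-BRAF fragments with a 2-fold
wild-type excess in four samples; one flat-profile, read-negative
sample with 2-fold elevated wild-type BRAF; 1 962 wild-type GTF2I
fragments per sample and per-sample totals fixed at 3 400 fragments so
the planted count ratios are exactly the expression ratios (18-, 13-,
106- and 6-fold).  A screened-fusion list (the in-silico analogue of a
targeted qPCR panel) quantifies the three known junctions in every
sample.  The primer panel is generated from the fused cDNAs with the
assay's product sizes (222 / 291 / 249 bp), each amplicon spanning its
junction.

Problem sizes: the full study is ~20 000 fragments across six samples
and runs in seconds; module tests use reduced plant tables (tens to
hundreds of fragments) and 10 seeds for the exact-recovery property.

## Determinism

All randomness flows from numpy `default_rng` seeded from the study
seed (per-sample streams derived via CRC of the sample id); identical
seeds give byte-identical FASTA/BED/FASTQ/TSV outputs, and the pipeline
itself is RNG-free, so reruns are byte-identical.

## Known limitations

- Ungapped matching (no indel tolerance within a read).
- No genome-wide mapping: reads are only compared against candidate
  templates, so fusions without a CNV-derived or screened candidate are
  invisible (de novo discovery is out of scope).
- The circularization model scores junctions only; reintegration
  position and more complex derivative chromosomes are not modelled.
- Expression normalization is raw-read based; no length/GC corrections
  or library-size modelling.
- The generator's wild-type expression enters through planted junction
  coverage, not a full transcriptome model.
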