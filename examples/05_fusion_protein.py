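"""Reconstruct fusion transcripts and proteins; predict PCR products.

Assembles the fused cDNA for each study fusion, calls the reading frame
by phase arithmetic, translates to the first stop, and sizes the
junction-spanning RT-PCR amplicons.
Run: python examples/05_fusion_protein.py
"""

from fusionjunction.fusion_protein import (
    DomainAnnotation,
    assemble_fusion_cds,
    in_silico_pcr,
    translate_fusion,
)
from fusionjunction.synthetic_data import (
    build_scaffold,
    screen_fusion_defs,
    study_primer_table,
)

scaffold = build_scaffold(1)
primers = {p.name: p for p in study_primer_table(scaffold)}

# toy domain annotations on the analog proteins: a DNA-binding region on
# the 5' partner and the kinase domain on BRAF's C-terminal half
domains = [
    DomainAnnotation("SIM_GTF2I", "DNA_binding", 100, 600),
    DomainAnnotation("SIM_BRAF", "kinase", 2100, 2500),
]

for fd in screen_fusion_defs(scaffold):
    ft = assemble_fusion_cds(
        scaffold.transcripts[fd.five_gene], fd.last_exon5,
        scaffold.transcripts[fd.three_gene], fd.first_exon3,
        fd.insert, scaffold.genome,
    )
    rep = translate_fusion(ft, domains, genome=scaffold.genome)
    products = in_silico_pcr(ft.fused_cdna, primers[fd.name])
    insert_note = f" + {len(fd.insert)} bp insert" if fd.insert else ""
    print(f"{fd.name} e{fd.last_exon5}-e{fd.first_exon3}{insert_note}")
    print(f"  frame: {rep.frame}, protein {rep.protein_length} aa "
          f"({rep.new_aa_count} novel residues)")
    print(f"  breakpoints at residue {rep.five_breakpoint_aa} (5') / "
          f"{rep.three_breakpoint_aa} (3')")
    print(f"  retained domains: {list(rep.retained_domains) or '-'}")
    print(f"  RT-PCR product: {products} bp")

print()
print("In-frame fusions read through into the 3' partner's native frame")
print("(the 17 bp insert contributes whole junction codons); out-of-frame")
print("fusions translate novel residues until a premature stop, truncating")
print("the 5' partner.")
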