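"""Reconstruct excision products at an att locus and run the PCR assay.

Builds a locus emulating the mutS-integrated element: 12-bp direct-repeat
cores with 2 extra host bases riding on the left core. Excision rejoins the
host gene (attB) minus those 2 bp — a frameshift that exposes a premature
stop — and circularises the element (attP). A four-amplicon in-silico PCR
assay distinguishes integrated, excised and mixed populations.
"""

from attmut.excision import assay_state, design_assay_primers, find_direct_repeats
from attmut.sim import build_att_locus

bundle = build_att_locus(
    upstream_len=300, element_len=27_000, core_len=12, scar_offset=2, seed=42
)
locus, products = bundle.locus, bundle.products

left = locus.host_upstream[-60:] + locus.core_left + locus.element[:60]
right = locus.element[-60:] + locus.core_right + locus.host_downstream[:60]
top = find_direct_repeats(left, right, min_core=6)[0]
print(f"direct repeat at the junctions: {top.sequence} ({top.length} bp)")

print(f"attB = {len(products.attB_sequence)} bp, attP = {len(products.attP_sequence)} bp, "
      f"integrated = {len(locus.integrated_sequence)} bp (bases conserved)")
print(f"scar: {products.scar_length} bp lost from the host gene -> "
      f"frameshift={products.frameshift}, premature stop at codon "
      f"{products.premature_stop_codon_position} "
      f"(wild-type stop at {products.wildtype_stop_codon_position})")

primers = design_assay_primers(locus, max_len=1000)
for label, genotype in [
    ("integrated", locus),
    ("excised", products),
    ("50:50 mixture", [locus, products]),
]:
    bands = assay_state(genotype, primers)
    called = " ".join(f"{k}{'+' if v else '-'}" for k, v in bands.items())
    print(f"  {label:>13}: {called}")
print(
    "\nattL/attR bands mean the element is in the chromosome; attB/attP mean\n"
    "it has excised; all four together indicate a mixed population."
)
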