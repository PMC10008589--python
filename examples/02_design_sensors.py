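"""Design sensors against a CCA site: default, short, allstop and SNV modes.

A sensor is the reverse complement of a window centred on the CCA, with one
G->A substitution creating a central in-frame UAG.  Editing that A (A-to-I,
read as G) turns the amber stop into tryptophan and lets translation read
through into the payload.
"""

from dartvadar import (
    design_allstop,
    design_sensor,
    design_snv_sensor,
    scan_cca,
    simulate_editing,
    translate,
)
from dartvadar.fixture_sim import SimSpec, make_snv_pair, make_trigger

trigger = make_trigger(SimSpec(seed=42))
site = scan_cca(trigger)[0]

design = design_sensor(trigger, site)  # default 75 nt
print(f"{site.name}: {design.length}-nt sensor, UAG at offset {design.uag_offset} "
      f"(codon {design.uag_offset // 3 + 1})")
print(f"  sensor : {design.sensor_seq}")
print(f"  peptide: {design.peptide}   <- exactly one '*', the editable stop")
edited = simulate_editing(design)
print(f"  edited : {translate(edited, 0)}   <- stop-less after A-to-I editing")

short = design_sensor(trigger, site, length=51)
print(f"short preset: {short.length} nt, UAG at offset {short.uag_offset}")

allstop = design_allstop(trigger, site)
print(f"allstop mode: {len(allstop.stop_codon_offsets)} editable UAG codon(s), "
      f"{len(allstop.skipped_cca)} out-of-frame CCA(s) left perfectly paired")

# SNV discrimination: a point variant (c.658T>C) creates a CCA in the mutant.
wt, variant = make_snv_pair(SimSpec(seed=3, trigger_length=900, utr5_length=60, cds_length=780))
snv = design_snv_sensor(wt, variant)
print(f"SNV sensor for {variant}: perfectly complementary to wild type "
      f"(A:T pair, uneditable), single A:C mismatch against the mutant -> "
      f"only mutant-expressing cells switch on")
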