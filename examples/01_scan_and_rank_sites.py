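"""Scan a trigger transcript for editable CCA sites and rank them.

Builds a synthetic 500-nt trigger (60-nt 5'UTR, 300-nt CDS, 140-nt 3'UTR)
with CCA motifs planted in the CDS and the 3'UTR, then scans, classifies and
ranks them.  Ribosome-free contexts (3'UTR, secreted-product CDS) rank above
translated CDS because ribosomes strip the sensor-trigger duplex.
"""

from dartvadar import classify_context, rank_sites, scan_cca
from dartvadar.fixture_sim import SimSpec, make_trigger

trigger = make_trigger(SimSpec(seed=42, planted_cca_positions=(60, 330)))
# anchored position 60 is in the CDS (+1 = A of ATG); 330 is in the 3'UTR

sites = scan_cca(trigger)
for site in sites:
    classify_context(site, trigger)

ranked = rank_sites(sites, trigger)
print(f"trigger {trigger.id}: {len(trigger)} nt, {len(sites)} CCA site(s)")
for s in ranked:
    print(f"  rank {s.rank_score}: {s.name:<8} offset {s.motif_start:<4} context {s.context.value}")
# The 3'UTR site ranks first: it is the better ADAR substrate even though it
# sits further from the start codon.
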