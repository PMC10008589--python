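"""Regenerate the bundled component fixture FASTA.

P2A, the wild-type MS2 stem-loop, the PKI-type NES and the GS linker are
canonical short sequences included verbatim.  The long parts (CMV promoter,
TagBFP, mNeonGreen, MCP, ADAR2 deaminase domain E488Q, ADAR1 p150 CDS, bGH
terminator) are deterministic SYNTHETIC stand-ins generated here at the real
sequence lengths: coding stand-ins are stop-free random codons starting with
ATG, non-coding stand-ins are uniform random DNA.  Users with the real parts
can override any fixture via ``load_components(directory=...)``.

Run from the repository root:  python scripts/make_synthetic_components.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src/dartvadar/data/components/synthetic_components.fasta"

CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SENSE_CODONS = [c for c in CODONS if c not in {"TAA", "TAG", "TGA"}]

# canonical short sequences (verbatim)
P2A = (
    "GGAAGCGGAGCTACTAACTTCAGCCTGCTGAAGCAGGCTGGAGACGTGGAGGAGAACCCTGGACCT"
)  # GSGATNFSLLKQAGDVEENPGP, 66 nt
MS2_HAIRPIN = "ACATGAGGATTACCCATGT"  # 19-nt wild-type MS2 stem-loop
NES = "CTGGCCCTGAAGCTGGCCGGCCTGGACATC"  # PKI-type NES, LALKLAGLDI
GS_LINKER = "GGAGGCGGAGGC"  # GGGG

# synthetic stand-in lengths (nt), matching the real parts
SYNTHETIC_CODING = {
    "tagbfp": 702,  # 233 aa fluorophore + Met
    "mneongreen": 711,
    "mcp": 390,  # MS2 major coat protein, 129 aa + Met
    "adar2dd_e488q": 1209,  # ADAR2 deaminase domain (residues ~299-701)
    "adar1_p150": 3681,  # full-length ADAR1 p150 CDS incl. stop
}
SYNTHETIC_NONCODING = {
    "cmv_promoter": 584,
    "bgh_terminator": 225,
}


def synthetic_cds(rng: np.random.Generator, length: int, terminal_stop: bool = False) -> str:
    assert length % 3 == 0
    n = length // 3 - 1 - (1 if terminal_stop else 0)
    body = "".join(rng.choice(SENSE_CODONS, size=n))
    return "ATG" + body + ("TAA" if terminal_stop else "")


def synthetic_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def main() -> None:
    rng = np.random.default_rng(20230311)
    records: list[tuple[str, str, str]] = [
        ("p2a", "P2A self-cleaving peptide (canonical)", P2A),
        ("ms2_hairpin", "wild-type MS2 stem-loop, 19 nt (canonical)", MS2_HAIRPIN),
        ("nes", "PKI-type nuclear export signal (canonical)", NES),
        ("gs_linker", "GS linker (canonical)", GS_LINKER),
    ]
    for name, length in SYNTHETIC_CODING.items():
        terminal = name == "adar1_p150"
        records.append(
            (
                name,
                f"SYNTHETIC stand-in CDS, {length} nt (real-part length)",
                synthetic_cds(rng, length, terminal_stop=terminal),
            )
        )
    for name, length in SYNTHETIC_NONCODING.items():
        records.append(
            (name, f"SYNTHETIC stand-in, {length} nt (real-part length)", synthetic_dna(rng, length))
        )

    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        for name, desc, seq in records:
            fh.write(f">{name} {desc}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    print(f"wrote {OUT} ({sum(len(s) for _, _, s in records)} nt in {len(records)} records)")


if __name__ == "__main__":
    main()
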