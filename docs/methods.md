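# Methods

This note documents the models, conventions, parameters and numerical
choices behind `dartvadar`, and what the synthetic-data generator does and
does not emulate.

## Coordinate and alphabet conventions

Sequences are stored in the DNA alphabet (`A/C/G/T/N`); RNA input (`U`) is
accepted and normalised to `T` everywhere, and `as_rna()` renders output
with `U`. The rationale is that plasmid-level artifacts (GenBank maps) are
DNA while the editing chemistry is described in RNA; one internal alphabet
with a render flag avoids mixed-state bugs. Internally all coordinates are
0-based half-open. User-facing positions are 1-based and, when a CDS is
annotated, anchored at the start codon: the A of `ATG` is position +1, and a
site named `CCA60` has the first C of its motif at anchored position 60.
Annotation files (GFF3 or the TSV region dialect) use 1-based inclusive
coordinates and are converted losslessly on read. `N` is accepted in input
sequences but any design window containing `N` is rejected, since pairing
cannot be guaranteed across an ambiguous base.

Site naming numbers the **first C** of the CCA motif. The anchoring of the
number to a specific motif base is a convention choice (the central C or the
A are equally defensible); `scan_cca(naming=...)` exposes all three so users
can match an existing nomenclature.

## Site enumeration, classification and ranking

`scan_cca` reports every CCA occurrence, including overlapping ones
(`CCACCA` → two sites); downstream filtering belongs to the designer, not
the scanner. Context classification assigns the region containing the motif
start (`cds_translated`, `cds_secreted` when the transcript is flagged as
encoding an ER-targeted product, `three_prime_utr`, `five_prime_utr`,
`noncoding` with a warning for unannotated positions). A site straddling a
region boundary is classified by its first base.

Ranking is a total order by context priority — secreted-product CDS, then
3'UTR, then 5'UTR, then translated CDS — with ties broken by ascending
position. The ordering encodes the observation that ribosome-free RNA is
the better ADAR substrate: translating ribosomes strip the sensor–trigger
duplex, while ER-targeted transcripts (stalled early in translation) and
UTRs stay accessible. The priority table is a `RankPolicy` parameter, not a
constant. Nuclear-localized transcripts return an **empty** ranking with an
advisory rather than a down-weighted one: sensors against nuclear RNAs do
not activate at all, because editing in this system is cytoplasmic, so a
soft penalty would misleadingly suggest partial viability. No
thermodynamic or secondary-structure scoring is applied; a site passing the
frame constraints is assumed targetable, and the ranking hook is the place
a structure-aware plugin would attach.

## Sensor design

For a window of length `L` centred on the motif's central C, the sensor is
`revcomp(window)` with the single substitution G→A opposite that C. The
length constraint `L ≡ 3 (mod 6)` (default 75, short preset 51) puts the
created `TAG` on a codon boundary of sensor frame 0 at offset `(L−3)/2`
(75 → 36, i.e. codon 13). The constraint exists because `(L−3)/2` must be a
multiple of 3 for the central triplet to be in frame in a symmetric window.
Asymmetric windows and ±1-codon UAG shifts to dodge residual stops are not
implemented: central placement keeps designs canonical and comparable, and a
rejected site simply yields to the next-ranked one. A rejection is a
returned record (site, length, reason), not an exception — it is an
expected outcome of scanning, not an error. With random background
sequence, roughly two-thirds of 75-nt windows are rejected for a residual
in-frame stop, which is why ranking produces an ordered list rather than a
single candidate.

`allstop` mode converts every additional target CCA in the window whose
opposing sensor triplet lies in frame 0 (`TGG`→`TAG`, one extra A:C
mismatch each); out-of-frame CCAs are left perfectly paired and reported,
since converting them would break the reading frame contract rather than
add an editable stop.

SNV discrimination requires the ALT allele to create a CCA whose central C
is the variant base (wild-type local context C-T-A). The sensor is a
standard centred design against the mutant, then verified both ways: zero
mismatches against wild type (the sensor A pairs A:T — a paired adenosine
is not an ADAR substrate) and exactly the central A:C mismatch against the
mutant. The mutant-side lesion is modelled as an A:C mismatch rather than
an unpaired bulge; for design purposes the two are equivalent (both expose
the adenosine), and the mismatch model keeps the duplex arithmetic exact.
`codon_index` (ceil(pos/3)) maps coding positions to residues, e.g.
c.658 → codon 220.

Editing is simulated by A→G at every designed TAG middle base;
`validate_design` checks that this yields a stop-free frame-0 translation
with `TGG` (Trp) at the centre, and that reverting all designed
substitutions restores the exact reverse complement of the window.

## Construct assembly

Topologies: `closed_loop` (marker, sensor module, payload, MCP-ADAR — four
coding components insulated by P2A), `open_loop_sensor` /
`open_loop_adar_trans` (MCP-ADAR constitutive from a separate cassette),
`basic_no_adar`, and `stopless_backbone` (sensor UAG pre-reverted to UGG;
the maximum-expression reference). All coding components have lengths that
are multiples of 3 and are concatenated on codon boundaries; the ORF check
verifies frame, exactly one terminal stop, the expected internal in-frame
TAG count (1, or 0 for the stop-less backbone), and scans junction codons.
The terminal stop is `TAA` so the sensor's `TAG` remains the unique amber
codon in the ORF.

MS2 hairpin placement: each hairpin (19-nt wild-type stem-loop) is padded
with neutral A/C linker bases to a 21-nt block (a multiple of 3), so the
downstream payload frame is preserved wherever the block lands. Spacers
count nucleotides between the UAG codon and the nearest block edge;
configuration `C` puts one block on each side, `L`/`R` put both on one
side. If a junction codon would create a new in-frame stop, the pad split
is shifted in silent single-base steps (three arrangements) before failing.
Defaults: config `C`, spacers (9, 9). The spacer values are honest
configuration knobs with an arbitrary documented default — the optimal
edit-site–hairpin distances are an empirical, construct-specific property —
and the hairpins are translated in-frame blocks (adding 14 residues to the
sensor peptide), which the layout records. Whether skipping them
translationally would be preferable is untested here.

`size_budget` sums all components (promoter and terminator included)
against a 5,000-nt capacity, the packaging limit of clinically used AAV
vectors: the default closed loop comes to 4,181 nt (84% of capacity), while
a full-length ADAR1 p150 CDS alone is 3,681 nt (74%) — the case for the
minimal MCP-recruited deaminase domain. GenBank export writes one feature
per component plus the sensor UAG and round-trips through Biopython.

### Component fixtures

P2A (66 nt), the 19-nt wild-type MS2 stem-loop, a PKI-type NES and a short
GS linker are canonical sequences included verbatim. The long parts (CMV
promoter, TagBFP, mNeonGreen, MCP, ADAR2 deaminase domain E488Q, ADAR1 p150
CDS, bGH terminator) are deterministic synthetic stand-ins at the real
parts' lengths — stop-free random codons for CDSs — clearly labelled in the
bundled FASTA. Every structural validation (frame, junctions, stop counts,
size budget) is therefore exact, but the bundled construct sequences are
not cloning-ready; users supply real parts via
`load_components(directory=...)`.

## Editing quantification

The pileup counts A/C/G/T/N per reference position. FASTQ (or raw string)
reads are placed by exhaustive ungapped minimum-mismatch offset search,
ties to the leftmost offset — appropriate because amplicons of a fixed
construct differ from the reference only by substitutions; reads whose best
placement exceeds `max_mismatch_frac` (default 0.2) of their length are
discarded and counted. Indel-containing data should arrive as SAM, which is
taken at face value via aligned pairs (SAM stores SEQ reference-oriented,
so reverse-strand records need no extra handling). Editing fraction is
`G/(A+G)`, not G/depth, so sequencing errors to C or T do not deflate the
estimate; positions with `A+G < min_depth` (default 100) are reported
missing, as are non-A reference positions. Base quality is ignored — the
simulator emits constant quality, and substitution noise is already
handled by the mismatch ceiling and the A+G denominator.

`logo_matrix` returns per-position base frequencies (rows sum to 1;
zero-depth rows are all-NaN) for logo rendering or CSV export.

## Fluorescence statistics

`fold_change` is the ratio of geometric means of ON and OFF reporter
intensities, with a seeded percentile bootstrap (default 1,000 resamples,
both arms independently) for the 95% CI. Percentile bootstrap was chosen
for being assumption-free about the intensity distribution; the geometric
mean is computed as `exp(mean(log x))`, so non-positive intensities are a
hard error with instructions to floor or filter upstream. Marker binning
assigns cells to bins of width 0.5 log₁₀ units ("half-log intervals")
anchored at 10⁰, so bin edges are deterministic and comparable across
samples. `topology_ratios` compares matched closed-loop/open-loop variants
as `log10(FC_CL/FC_OL)` (positive = autocatalysis helps) and
`log10(OFF_CL/OFF_OL)` (negative = reduced background).

## Synthetic-data generator

`make_trigger` rejection-samples a random transcript (default 500 nt:
60-nt 5'UTR, 300-nt CDS with ATG/TAA landmarks, 140-nt 3'UTR) so that CCA
occurs exactly at the planted anchored positions and nowhere else, and —
by default — so that every planted site admits a stop-free sensor at the
configured length, making triggers usable end-to-end. `simulate_reads`
emits full-length amplicon reads with independent per-read A→G conversion
at the planted per-position probabilities and optional uniform substitution
errors (default 0, keeping recovery oracles exactly binomial).
`simulate_cells` draws log-normal reporter intensities with
`mean_log_on − mean_log_off = ln(FC_true)`, so the planted geometric-mean
fold change is exact by construction; defaults are 2,000 cells per arm,
planted FC 9 and σ_log 1.0 — the regime of interest for this sensor class
(up to ~9-fold activation, fold changes computed from at least 2,000
cells; σ_log 1.0 gives the decade-wide intensity spread typical of
transient transfection).

What the generator does **not** emulate: realistic sequencing error
profiles (quality-dependent, strand-biased), PCR duplicates, alignment
ambiguity from indels, cytometry autofluorescence/spillover, or any
correlation between marker and reporter beyond independence. Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to instrument artefacts. Likewise the
trigger generator's uniform-random background has none of the secondary
structure or repeat content of real transcripts, so the observed
~one-third design acceptance rate is a property of random sequence, not a
biological constant.

## Problem sizes in tests and the acceptance script

The recovery suites use depth 5,000 at amplicon scale (117–150 nt), 100
seeded replicates per editing regime (rates 0.03 and 0.30, the
endogenous/exogenous regimes), and 100 seeds of 2,000-cell-per-arm
fold-change simulations with 500–1,000 bootstrap resamples — sizes chosen
to match the study conditions the package emulates while keeping the full
suite in the tens of seconds. The scan oracle cross-check runs 1,000
random 500-mers against a brute-force sliding window.

## Known limitations

- No off-target complementarity search across a transcriptome; site
  ranking is context-based only.
- No immunogenicity assessment of sensor-encoded peptides, and no
  codon-level optimisation (both would change the peptide the sensor
  window dictates).
- No kinetic model of the feedback loop; closed- vs open-loop comparisons
  are measurement utilities over observed populations.
- The built-in read placer is substitution-only; gapped alignment must
  come from an external aligner via SAM.
- Genome-space (spliced) coordinates and ambiguity codes beyond N are out
  of scope.
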