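"""Build sensor sequences against ranked CCA sites.

A sensor is the reverse complement of a target window centred on a CCA motif,
with a single designed substitution: the base opposite the central C of the
CCA is changed G->A, turning the central codon TGG into the amber stop TAG.
Hybridization with the target puts that A in an A:C mismatch (with a 5'-U
neighbour), the preferred ADAR substrate; editing A->I(G) restores TGG, a
tryptophan codon, and translation reads through into the payload.

Window lengths are constrained to ``L % 6 == 3`` so that ``(L-3)/2`` is a
multiple of 3 and the central triplet sits on a codon boundary of the insert
frame (frame 0 of the sensor).  Default L=75, short preset L=51.

Variant modes:

* ``allstop`` — every additional target CCA in the window whose opposing
  sensor triplet is in frame 0 is likewise converted TGG->TAG, giving several
  editable stops per sensor; out-of-frame CCAs stay perfectly paired.
* ``snv_discrimination`` — for a point variant that *creates* a CCA (WT local
  context C-T-A -> mutant C-C-A, e.g. p53 c.658T>C / Y220H), the sensor is
  built against the mutant.  Against wild type it is then perfectly
  complementary (the sensor A pairs A:T, uneditable); against the mutant the
  single central A:C mismatch exposes the adenosine for editing.

A window whose sensor would retain another in-frame stop is rejected (a
rejection record, not an exception): the stop cannot be recoded without
breaking complementarity, so the site is simply unusable at that length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .seq_core import Transcript, ValidationError, revcomp, translate
from .site_finder import MOTIF, EditSite, scan_cca

__all__ = [
    "DesignRejection",
    "Mismatch",
    "SensorDesign",
    "SensorMode",
    "ValidationReport",
    "design_allstop",
    "design_sensor",
    "design_snv_sensor",
    "duplex_mismatches",
    "parse_variant",
    "simulate_editing",
    "validate_design",
]

DEFAULT_LENGTH = 75
SHORT_LENGTH = 51

STOP_CODONS = {"TAA", "TAG", "TGA"}


class SensorMode(str, Enum):
    SINGLE_STOP = "single_stop"
    ALLSTOP = "allstop"
    SNV_DISCRIMINATION = "snv_discrimination"


@dataclass(frozen=True)
class Mismatch:
    """A designed sensor-target mismatch (sensor offset, sensor base, opposing target base)."""

    sensor_offset: int
    sensor_base: str
    opposing_target_base: str


@dataclass
class SensorDesign:
    site: EditSite
    window: tuple[int, int]  # 0-based half-open on the target transcript
    sensor_seq: str
    uag_offset: int  # 0-based offset of the T of the central TAG (U in RNA)
    mismatches: list[Mismatch]
    mode: SensorMode
    peptide: str
    skipped_cca: list[int] = field(default_factory=list)  # allstop: out-of-frame target CCAs

    @property
    def length(self) -> int:
        return len(self.sensor_seq)

    @property
    def stop_codon_offsets(self) -> list[int]:
        """Frame-0 offsets of stop codons in the sensor."""
        return [
            i
            for i in range(0, self.length - 2, 3)
            if self.sensor_seq[i : i + 3] in STOP_CODONS
        ]


@dataclass
class DesignRejection:
    """A site that cannot carry a sensor at the requested length, with the reason."""

    site: EditSite
    length: int
    reason: str


def _check_length(length: int) -> None:
    if length < 9 or length % 6 != 3:
        raise ValueError(
            f"sensor length must be >= 9 with length % 6 == 3 (got {length}); "
            "this centres the editable triplet on a codon boundary"
        )


def _window_for_site(transcript: Transcript, site: EditSite, length: int) -> tuple[int, int]:
    half = (length - 3) // 2
    start = site.motif_start - half
    end = site.motif_start + 3 + half
    if start < 0 or end > len(transcript):
        raise ValidationError(
            f"{site.name}: {length}-nt window [{start}, {end}) does not fit on "
            f"{transcript.id} (length {len(transcript)})"
        )
    return start, end


def duplex_mismatches(sensor_seq: str, target_window: str) -> list[Mismatch]:
    """Mismatch map of a sensor hybridized to a target window.

    Sensor offset ``i`` pairs with target-window offset ``L-1-i``; a position
    matches when the sensor base is the complement of the opposing base.
    """
    if len(sensor_seq) != len(target_window):
        raise ValueError("sensor and window lengths differ")
    perfect = revcomp(target_window)
    out = []
    for i, (got, want) in enumerate(zip(sensor_seq, perfect)):
        if got != want:
            out.append(Mismatch(i, got, target_window[len(target_window) - 1 - i]))
    return out


def design_sensor(
    transcript: Transcript, site: EditSite, length: int = DEFAULT_LENGTH
) -> SensorDesign | DesignRejection:
    """Design a single-stop sensor centred on a CCA site.

    Returns a :class:`SensorDesign`, or a :class:`DesignRejection` when the
    reverse-complemented window retains another in-frame stop (the site is
    unusable at this length; try the next-ranked site or the short preset).
    Out-of-bounds windows and N-containing windows raise.
    """
    _check_length(length)
    start, end = _window_for_site(transcript, site, length)
    window = transcript.seq[start:end]
    if "N" in window:
        raise ValidationError(f"{site.name}: window contains N; pairing cannot be guaranteed")
    if transcript.seq[site.motif_start : site.motif_start + 3] != MOTIF:
        raise ValidationError(f"{site.name}: no CCA motif at offset {site.motif_start}")

    sensor = list(revcomp(window))
    uag_offset = (length - 3) // 2
    assert sensor[uag_offset : uag_offset + 3] == list("TGG")
    sensor[uag_offset + 1] = "A"  # G->A opposite the central C: TGG -> TAG
    sensor_seq = "".join(sensor)

    design = SensorDesign(
        site=site,
        window=(start, end),
        sensor_seq=sensor_seq,
        uag_offset=uag_offset,
        mismatches=[Mismatch(uag_offset + 1, "A", "C")],
        mode=SensorMode.SINGLE_STOP,
        peptide=translate(sensor_seq, 0),
    )
    residual = [o for o in design.stop_codon_offsets if o != uag_offset]
    if residual:
        return DesignRejection(
            site,
            length,
            "residual in-frame stop in sensor frame 0 at offset(s) "
            f"{residual}; cannot recode without breaking target complementarity",
        )
    return design


def design_allstop(
    transcript: Transcript, site: EditSite, length: int = DEFAULT_LENGTH
) -> SensorDesign | DesignRejection:
    """Convert every frame-alignable target CCA in the window into an editable TAG.

    Starting from the single-stop design, each additional CCA in the target
    window whose opposing sensor triplet lies in frame 0 is converted
    TGG->TAG (one extra A:C mismatch each).  CCAs misaligned to the frame
    are left as perfect TGG pairs and reported in ``skipped_cca`` (window-
    relative offsets of their first C).
    """
    base = design_sensor(transcript, site, length)
    if isinstance(base, DesignRejection):
        return base
    start, _ = base.window
    window = transcript.seq[base.window[0] : base.window[1]]
    sensor = list(base.sensor_seq)
    mismatches = list(base.mismatches)
    skipped: list[int] = []

    central_rel = site.motif_start - start
    for m in re.finditer("(?=CCA)", window):
        rel = m.start()
        if rel == central_rel:
            continue
        # target CCA at window-relative [rel, rel+3) opposes sensor [L-rel-3, L-rel)
        opp = length - rel - 3
        if opp < 0 or opp + 3 > length:
            continue
        if opp % 3 != 0:
            skipped.append(rel)
            continue
        assert sensor[opp : opp + 3] == list("TGG")
        sensor[opp + 1] = "A"
        mismatches.append(Mismatch(opp + 1, "A", "C"))

    sensor_seq = "".join(sensor)
    design = SensorDesign(
        site=site,
        window=base.window,
        sensor_seq=sensor_seq,
        uag_offset=base.uag_offset,
        mismatches=sorted(mismatches, key=lambda m: m.sensor_offset),
        mode=SensorMode.ALLSTOP,
        peptide=translate(sensor_seq, 0),
        skipped_cca=skipped,
    )
    expected_stops = {m.sensor_offset - 1 for m in design.mismatches}
    residual = [o for o in design.stop_codon_offsets if o not in expected_stops]
    if residual:
        return DesignRejection(site, length, f"residual in-frame stop at offset(s) {residual}")
    return design


_VARIANT_RE = re.compile(r"^c\.(\d+)([ACGTU])>([ACGTU])$", re.IGNORECASE)


def parse_variant(variant_spec: str) -> tuple[int, str, str]:
    """Parse an HGVS-like coding substitution ``c.POSREF>ALT`` (e.g. ``c.658T>C``)."""
    m = _VARIANT_RE.match(variant_spec.strip())
    if not m:
        raise ValidationError(
            f"cannot parse variant {variant_spec!r}; expected the form c.658T>C"
        )
    pos = int(m.group(1))
    ref = m.group(2).upper().replace("U", "T")
    alt = m.group(3).upper().replace("U", "T")
    if ref == alt:
        raise ValidationError(f"{variant_spec}: REF and ALT are identical")
    return pos, ref, alt


def design_snv_sensor(
    transcript_wt: Transcript, variant_spec: str, length: int = DEFAULT_LENGTH
) -> SensorDesign | DesignRejection:
    """Design a point-variant-discriminating sensor.

    Applicable only when the ALT allele creates a CCA motif at the variant
    locus (the variant base becomes the central C; WT context C-T-A).  The
    sensor is a standard centred design against the mutant transcript, then
    verified: (a) zero mismatches against the wild-type window — the sensor A
    pairs A:T with WT, so the adenosine cannot be edited; (b) exactly one
    mismatch against the mutant — the central editable A:C.
    """
    pos, ref, alt = parse_variant(variant_spec)
    offset = transcript_wt.offset_of_cds_position(pos)
    if transcript_wt.seq[offset] != ref:
        raise ValidationError(
            f"{variant_spec}: wild-type base at c.{pos} is {transcript_wt.seq[offset]}, not {ref}"
        )
    mutant = transcript_wt.with_substitution(offset, alt)
    mutant.id = f"{transcript_wt.id}_{variant_spec}"

    before = {s.motif_start for s in scan_cca(transcript_wt)}
    after = {s.motif_start for s in scan_cca(mutant)}
    created = sorted(after - before)
    # the discriminating motif must have the variant base as its central C
    target_motifs = [m for m in created if m + 1 == offset]
    if not target_motifs:
        raise ValidationError(
            f"{variant_spec}: ALT does not create a CCA motif centred on the variant "
            f"(WT local context must be C-{ref}-A with ALT=C); SNV discrimination mode "
            "is inapplicable to this variant"
        )
    motif_start = target_motifs[0]
    site = next(s for s in scan_cca(mutant) if s.motif_start == motif_start)

    design = design_sensor(mutant, site, length)
    if isinstance(design, DesignRejection):
        return design

    start, end = design.window
    wt_window = transcript_wt.seq[start:end]
    mut_window = mutant.seq[start:end]
    mm_wt = duplex_mismatches(design.sensor_seq, wt_window)
    mm_mut = duplex_mismatches(design.sensor_seq, mut_window)
    if mm_wt:
        raise ValidationError(
            f"{variant_spec}: sensor is not fully complementary to wild type "
            f"({len(mm_wt)} mismatches); internal consistency failure"
        )
    if len(mm_mut) != 1 or mm_mut[0].sensor_offset != design.uag_offset + 1:
        raise ValidationError(
            f"{variant_spec}: expected exactly the central A:C mismatch against the "
            f"mutant, got {mm_mut}; internal consistency failure"
        )
    design.mode = SensorMode.SNV_DISCRIMINATION
    return design


def simulate_editing(design: SensorDesign) -> str:
    """Sensor sequence after A->G editing at every designed TAG middle base.

    This is the activated ('stop-less') state: each designed TAG reverts to
    TGG (Trp) and the sensor becomes the exact reverse complement of its
    target window.
    """
    sensor = list(design.sensor_seq)
    for m in design.mismatches:
        if sensor[m.sensor_offset] == "A":
            sensor[m.sensor_offset] = "G"
    return "".join(sensor)


@dataclass
class ValidationReport:
    design_length: int
    frame_compatible: bool  # L % 3 == 0 so the downstream payload frame is preserved
    mismatches: list[Mismatch]
    stop_count: int
    stop_offsets: list[int]
    edited_stop_count: int
    edited_central_codon: str
    passed: bool
    reasons: list[str]


def validate_design(design: SensorDesign, transcript: Transcript) -> ValidationReport:
    """Validate a constructed design against its transcript; failures are reported, not raised."""
    reasons: list[str] = []
    start, end = design.window
    window = transcript.seq[start:end]
    mismatches = duplex_mismatches(design.sensor_seq, window)
    if mismatches != design.mismatches:
        reasons.append("recorded mismatch map disagrees with recomputed duplex")

    stops = design.stop_codon_offsets
    designed_stop_offsets = {m.sensor_offset - 1 for m in design.mismatches}
    extra = [o for o in stops if o not in designed_stop_offsets]
    if extra:
        reasons.append(f"residual in-frame stop at offset(s) {extra}")
    if design.sensor_seq[design.uag_offset : design.uag_offset + 3] != "TAG":
        reasons.append("central codon is not TAG")

    edited = simulate_editing(design)
    edited_stops = [
        i for i in range(0, len(edited) - 2, 3) if edited[i : i + 3] in STOP_CODONS
    ]
    if edited_stops:
        reasons.append(f"edited sensor retains stop(s) at {edited_stops}")
    edited_central = edited[design.uag_offset : design.uag_offset + 3]
    if edited_central != "TGG":
        reasons.append(f"edited central codon is {edited_central}, not TGG (Trp)")

    frame_ok = design.length % 3 == 0
    if not frame_ok:
        reasons.append("sensor length not a multiple of 3; payload frame broken")

    return ValidationReport(
        design_length=design.length,
        frame_compatible=frame_ok,
        mismatches=mismatches,
        stop_count=len(stops),
        stop_offsets=stops,
        edited_stop_count=len(edited_stops),
        edited_central_codon=edited_central,
        passed=not reasons,
        reasons=reasons,
    )
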