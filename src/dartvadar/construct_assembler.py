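"""Assemble and validate full single-transcript sensor expression constructs.

The closed-loop (autocatalytic) architecture is a single transcript carrying
four in-frame coding components insulated by self-cleaving 2A peptides:

    promoter - marker(TagBFP) - 2A - [MS2 / sensor / MS2] - 2A - payload
    (mNeonGreen) - 2A - MCP-ADAR - stop - terminator

The sensor's central UAG is the only internal in-frame stop: unedited, the
ribosome terminates inside the sensor module and only the marker is made;
edited (UAG->UIG, read as UGG/Trp), one uninterrupted ORF produces marker,
sensor peptide, payload and MCP-ADAR — which is recruited back to the MS2
hairpins flanking the edit site, closing the positive feedback loop.

Other topologies: ``open_loop_sensor`` (hairpin sensor without cis ADAR),
``open_loop_adar_trans`` (separate constitutive MCP-ADAR cassette),
``basic_no_adar`` (marker/sensor/payload only) and ``stopless_backbone``
(sensor UAG pre-reverted to UGG; the maximum-expression reference).

Everything is validated structurally: single ORF, codon-aligned junctions,
internal in-frame TAG count, and a size budget against the ~5 kb packaging
limit of clinically used AAV vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .seq_core import normalize_seq, translate
from .sensor_designer import STOP_CODONS, SensorDesign, simulate_editing

__all__ = [
    "AssemblyError",
    "Component",
    "ConstructLayout",
    "HairpinConfig",
    "OrfChecks",
    "SensorModule",
    "SizeBudget",
    "Topology",
    "assemble",
    "load_components",
    "place_hairpins",
    "size_budget",
    "write_genbank",
]

AAV_CAPACITY_NT = 5000


class AssemblyError(RuntimeError):
    pass


class Topology(str, Enum):
    CLOSED_LOOP = "closed_loop"
    OPEN_LOOP_SENSOR = "open_loop_sensor"
    OPEN_LOOP_ADAR_TRANS = "open_loop_adar_trans"
    BASIC_NO_ADAR = "basic_no_adar"
    STOPLESS_BACKBONE = "stopless_backbone"


class HairpinConfig(str, Enum):
    """Placement of the two MS2 hairpins relative to the edit site.

    C = one hairpin on each side of the UAG; L = both 5' of it; R = both 3'.
    """

    L = "L"
    R = "R"
    C = "C"


@dataclass(frozen=True)
class Component:
    name: str
    seq: str
    coding: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_seq(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


def load_components(directory: str | Path | None = None) -> dict[str, Component]:
    """Load the bundled component sequences (or an override directory of FASTAs).

    The bundled set ships in the package data.  P2A, the 19-nt wild-type MS2
    stem-loop and the PKI-type NES are canonical short sequences; the longer
    parts (promoter, fluorophores, MCP, ADAR2 deaminase domain, ADAR1 p150
    CDS, terminator) are deterministic synthetic stand-ins at the real
    lengths, as documented in their FASTA headers.  Any fixture may be
    overridden by pointing ``directory`` at FASTAs with the same record ids.
    """
    noncoding = {"cmv_promoter", "bgh_terminator", "ms2_hairpin"}
    components: dict[str, Component] = {}

    def _ingest(fasta_path) -> None:
        for record in SeqIO.parse(str(fasta_path), "fasta"):
            components[record.id] = Component(
                name=record.id, seq=str(record.seq), coding=record.id not in noncoding
            )

    if directory is None:
        data_dir = resources.files("dartvadar").joinpath("data/components")
        for entry in sorted(data_dir.iterdir(), key=lambda p: p.name):
            if entry.name.endswith(".fasta"):
                _ingest(entry)
    else:
        for entry in sorted(Path(directory).glob("*.fasta")):
            _ingest(entry)
    return components


def _mcp_adar_fusion(components: dict[str, Component]) -> Component:
    """MCP-ADAR2DD(E488Q)-NES fusion: coat protein, GS linker, deaminase domain, NES."""
    seq = (
        components["mcp"].seq
        + components["gs_linker"].seq
        + components["adar2dd_e488q"].seq
        + components["nes"].seq
    )
    return Component("mcp_adar", seq, coding=True)


@dataclass
class SensorModule:
    """A sensor insert with MS2 hairpin blocks placed around the edit site."""

    seq: str
    uag_offset: int  # offset of the T of the sensor TAG within the module
    hairpin_spans: list[tuple[int, int]]
    config: HairpinConfig
    spacers: tuple[int, int]
    design: SensorDesign


def _frame0_stops(seq: str) -> list[int]:
    return [i for i in range(0, len(seq) - 2, 3) if seq[i : i + 3] in STOP_CODONS]


def _hairpin_block(hairpin: str, pad_left: int) -> str:
    """Pad the hairpin with neutral A/C linker bases to a multiple of 3."""
    total_pad = (-len(hairpin)) % 3
    if total_pad == 0:
        total_pad = 3  # always leave at least one shim position to play with
    pad_left %= total_pad + 1
    left = ("ACA" * 2)[:pad_left]
    right = ("CAC" * 2)[: total_pad - pad_left]
    return left + hairpin + right


def place_hairpins(
    design: SensorDesign,
    config: HairpinConfig | str = HairpinConfig.C,
    spacer_left: int = 9,
    spacer_right: int = 9,
    hairpin_seq: str | None = None,
    components: dict[str, Component] | None = None,
) -> SensorModule:
    """Insert two frame-preserving MS2 hairpin blocks into a sensor.

    Spacers count the nucleotides between the sensor UAG codon and the
    nearest end of each hairpin block.  Each block is the hairpin padded
    with neutral linker bases to a multiple of 3, so the downstream payload
    frame is untouched wherever the block lands; if a junction would create
    a new in-frame stop, the padding is shifted in silent single-base steps
    (up to 3 arrangements) before giving up with :class:`AssemblyError`.
    """
    config = HairpinConfig(config)
    if spacer_left < 0 or spacer_right < 0:
        raise ValueError("spacers must be >= 0")
    if hairpin_seq is None:
        components = components or load_components()
        hairpin_seq = components["ms2_hairpin"].seq
    hairpin_seq = normalize_seq(hairpin_seq)

    sensor = design.sensor_seq
    uag = design.uag_offset
    if config is HairpinConfig.C:
        insert_points = [uag - spacer_left, uag + 3 + spacer_right]
        doubled = [False, False]
    elif config is HairpinConfig.L:
        insert_points = [uag - spacer_left]
        doubled = [True]
    else:
        insert_points = [uag + 3 + spacer_right]
        doubled = [True]
    for p in insert_points:
        if not (0 <= p <= len(sensor)):
            raise AssemblyError(
                f"hairpin insertion point {p} outside the {len(sensor)}-nt sensor; "
                "reduce the spacer"
            )

    sensor_stops = _frame0_stops(sensor)  # the UAG, plus extra TAGs in allstop mode
    for shift in range(3):  # silent single-base pad shifts
        block = _hairpin_block(hairpin_seq, shift)
        pieces: list[str] = []
        spans: list[tuple[int, int]] = []
        cursor = 0
        offset_added = 0
        new_uag = uag
        for p, dbl in sorted(zip(insert_points, doubled)):
            insert = block * (2 if dbl else 1)
            pieces.append(sensor[cursor:p])
            start = p + offset_added
            if dbl:
                spans.extend([(start, start + len(block)), (start + len(block), start + 2 * len(block))])
            else:
                spans.append((start, start + len(insert)))
            pieces.append(insert)
            if p <= uag:
                new_uag += len(insert)
            offset_added += len(insert)
            cursor = p
        pieces.append(sensor[cursor:])
        module_seq = "".join(pieces)

        expected_stops = sorted(
            o + sum(len(block) * (2 if dbl else 1)
                    for p, dbl in zip(insert_points, doubled) if p <= o)
            for o in sensor_stops
        )
        stops = _frame0_stops(module_seq)
        if stops == expected_stops:
            return SensorModule(
                seq=module_seq,
                uag_offset=new_uag,
                hairpin_spans=spans,
                config=config,
                spacers=(spacer_left, spacer_right),
                design=design,
            )
    raise AssemblyError(
        "could not place hairpin blocks without creating an in-frame stop "
        "within 3 silent pad shifts"
    )


@dataclass
class OrfChecks:
    coding_length: int
    frame_ok: bool
    internal_tag_count: int
    internal_stop_count: int
    terminal_stop: bool
    junction_stops: list[str]
    passed: bool


@dataclass
class ConstructLayout:
    topology: Topology
    components: list[Component]
    hairpin_config: HairpinConfig | None
    spacers: tuple[int, int] | None
    total_length: int
    orf_checks: OrfChecks
    sensor_uag_span: tuple[int, int] | None = None  # construct coordinates of the sensor TAG
    trans_cassette: "ConstructLayout | None" = None  # separate ADAR cassette for OL-in-trans

    @property
    def coding_components(self) -> list[Component]:
        return [c for c in self.components if c.coding and not c.name.startswith("p2a")
                and c.name != "stop"]

    @property
    def sequence(self) -> str:
        return "".join(c.seq for c in self.components)


def _orf_checks(components: list[Component]) -> OrfChecks:
    coding = [c for c in components if c.coding]
    concat = "".join(c.seq for c in coding)
    frame_ok = len(concat) % 3 == 0
    stops = _frame0_stops(concat)
    terminal_stop = bool(stops) and stops[-1] == len(concat) - 3
    internal = stops[:-1] if terminal_stop else stops
    internal_tag = sum(1 for i in internal if concat[i : i + 3] == "TAG")

    junction_stops: list[str] = []
    pos = 0
    for left, right in zip(coding, coding[1:]):
        pos += len(left.seq)
        for i in range(max(0, pos - 2), min(pos, len(concat) - 2)):
            if i % 3 == 0 and concat[i : i + 3] in STOP_CODONS:
                junction_stops.append(f"{left.name}|{right.name}")
                break
    passed = frame_ok and terminal_stop and not junction_stops
    return OrfChecks(
        coding_length=len(concat),
        frame_ok=frame_ok,
        internal_tag_count=internal_tag,
        internal_stop_count=len(internal),
        terminal_stop=terminal_stop,
        junction_stops=junction_stops,
        passed=passed,
    )


def assemble(
    design: SensorDesign | None,
    topology: Topology | str,
    components: dict[str, Component] | None = None,
    hairpin_config: HairpinConfig | str | None = None,
    spacers: tuple[int, int] = (9, 9),
) -> ConstructLayout:
    """Assemble a construct layout for the requested topology.

    ``hairpin_config`` adds the two MS2 blocks to the sensor module (required
    for MCP-ADAR recruitment in closed-loop designs; defaults to C for
    closed_loop/stopless/open-loop-sensor, none for basic_no_adar).
    ``open_loop_adar_trans`` returns the sensor construct with the separate
    constitutive MCP-ADAR cassette attached as ``trans_cassette``.
    """
    topology = Topology(topology)
    parts = components or load_components()
    for required in ("cmv_promoter", "tagbfp", "p2a", "mneongreen", "bgh_terminator"):
        if required not in parts:
            raise AssemblyError(f"missing component fixture {required!r}")

    if topology is Topology.OPEN_LOOP_ADAR_TRANS and design is None:
        # bare trans cassette: promoter - MCP-ADAR - stop - terminator
        comps = [
            parts["cmv_promoter"],
            _mcp_adar_fusion(parts),
            Component("stop", "TAA", coding=True),
            parts["bgh_terminator"],
        ]
        checks = _orf_checks(comps)
        return ConstructLayout(
            topology=topology,
            components=comps,
            hairpin_config=None,
            spacers=None,
            total_length=sum(len(c) for c in comps),
            orf_checks=checks,
        )

    if design is None:
        raise AssemblyError(f"topology {topology.value} requires a SensorDesign")

    if hairpin_config is None and topology is not Topology.BASIC_NO_ADAR:
        hairpin_config = HairpinConfig.C

    sensor_seq = design.sensor_seq
    uag_in_module = design.uag_offset
    module: SensorModule | None = None
    if topology is Topology.STOPLESS_BACKBONE:
        edited = simulate_editing(design)
        design_for_module = SensorDesign(
            site=design.site,
            window=design.window,
            sensor_seq=edited,
            uag_offset=design.uag_offset,
            mismatches=[],
            mode=design.mode,
            peptide=translate(edited, 0),
        )
    else:
        design_for_module = design

    if hairpin_config is not None:
        module = place_hairpins(
            design_for_module, hairpin_config, spacers[0], spacers[1], components=parts
        )
        sensor_seq = module.seq
        uag_in_module = module.uag_offset
    else:
        sensor_seq = design_for_module.sensor_seq
        uag_in_module = design_for_module.uag_offset

    sensor_component = Component("sensor_module", sensor_seq, coding=True)
    comps: list[Component] = [
        parts["cmv_promoter"],
        parts["tagbfp"],
        Component("p2a_1", parts["p2a"].seq, coding=True),
        sensor_component,
        Component("p2a_2", parts["p2a"].seq, coding=True),
        parts["mneongreen"],
    ]
    if topology in (Topology.CLOSED_LOOP, Topology.STOPLESS_BACKBONE):
        comps.append(Component("p2a_3", parts["p2a"].seq, coding=True))
        comps.append(_mcp_adar_fusion(parts))
    comps.append(Component("stop", "TAA", coding=True))
    comps.append(parts["bgh_terminator"])

    checks = _orf_checks(comps)
    expected_internal_tag = 0 if topology is Topology.STOPLESS_BACKBONE else 1
    if checks.internal_stop_count != expected_internal_tag or (
        checks.internal_tag_count != expected_internal_tag
    ):
        bad = checks.junction_stops or "sensor/fixture sequences"
        raise AssemblyError(
            f"{topology.value}: expected {expected_internal_tag} internal in-frame TAG, "
            f"found {checks.internal_tag_count} TAG / {checks.internal_stop_count} stops "
            f"(suspect junction(s): {bad})"
        )
    if checks.junction_stops:
        raise AssemblyError(f"unintended in-frame stop at junction(s) {checks.junction_stops}")

    uag_span = None
    if topology is not Topology.STOPLESS_BACKBONE:
        offset = 0
        for c in comps:
            if c.name == "sensor_module":
                uag_span = (offset + uag_in_module, offset + uag_in_module + 3)
                break
            offset += len(c)

    layout = ConstructLayout(
        topology=topology,
        components=comps,
        hairpin_config=HairpinConfig(hairpin_config) if hairpin_config else None,
        spacers=spacers if hairpin_config else None,
        total_length=sum(len(c) for c in comps),
        orf_checks=checks,
        sensor_uag_span=uag_span,
    )
    if topology is Topology.OPEN_LOOP_ADAR_TRANS:
        layout.trans_cassette = assemble(None, Topology.OPEN_LOOP_ADAR_TRANS, parts)
    return layout


@dataclass
class SizeBudget:
    total_nt: int
    capacity_nt: int
    fraction_of_capacity: float
    within_budget: bool


def size_budget(layout: ConstructLayout, capacity_nt: int = AAV_CAPACITY_NT) -> SizeBudget:
    """Check the full cassette (promoter and terminator included) against a
    packaging capacity, by default the ~5 kb AAV limit."""
    total = sum(len(c) for c in layout.components)
    return SizeBudget(
        total_nt=total,
        capacity_nt=capacity_nt,
        fraction_of_capacity=total / capacity_nt if capacity_nt else 0.0,
        within_budget=total < capacity_nt,
    )


def write_genbank(layout: ConstructLayout, path: str | Path, name: str = "construct") -> None:
    """Write the layout as an annotated GenBank record (one feature per
    component, plus the sensor UAG when present)."""
    seq = layout.sequence
    record = SeqRecord(Seq(seq), id=name[:16], name=name[:16], description=layout.topology.value)
    record.annotations["molecule_type"] = "DNA"
    offset = 0
    for comp in layout.components:
        ftype = "CDS" if comp.coding else "misc_feature"
        record.features.append(
            SeqFeature(
                FeatureLocation(offset, offset + len(comp)),
                type=ftype,
                qualifiers={"label": [comp.name]},
            )
        )
        offset += len(comp)
    if layout.sensor_uag_span is not None:
        s, e = layout.sensor_uag_span
        record.features.append(
            SeqFeature(
                FeatureLocation(s, e),
                type="misc_feature",
                qualifiers={"label": ["sensor_UAG"], "note": ["editable amber stop codon"]},
            )
        )
    SeqIO.write([record], str(path), "genbank")
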