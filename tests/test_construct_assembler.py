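import dataclasses

import pytest
from Bio import SeqIO

from dartvadar.construct_assembler import (
    AssemblyError,
    ConstructLayout,
    HairpinConfig,
    OrfChecks,
    Topology,
    _orf_checks,
    assemble,
    place_hairpins,
    size_budget,
    write_genbank,
)
from dartvadar.seq_core import translate
from dartvadar.sensor_designer import STOP_CODONS


def frame0_stops(seq):
    return [i for i in range(0, len(seq) - 2, 3) if seq[i : i + 3] in STOP_CODONS]


class TestPlaceHairpins:
    def test_center_config_flanks_uag_at_spacers(self, design75, components):
        m = place_hairpins(design75, "C", 9, 9, components=components)
        assert len(m.hairpin_spans) == 2
        (l0, l1), (r0, r1) = m.hairpin_spans
        assert l1 + 9 == m.uag_offset  # left block ends 9 nt 5' of the UAG
        assert r0 == m.uag_offset + 3 + 9  # right block starts 9 nt 3' of it
        assert m.seq[m.uag_offset : m.uag_offset + 3] == "TAG"

    def test_zero_spacers_abut_the_uag(self, design75, components):
        m = place_hairpins(design75, "C", 0, 0, components=components)
        (l0, l1), (r0, r1) = m.hairpin_spans
        assert l1 == m.uag_offset and r0 == m.uag_offset + 3

    @pytest.mark.parametrize("config", ["L", "R", "C"])
    def test_frame_preserved_and_no_new_stop(self, design75, components, config):
        m = place_hairpins(design75, config, 9, 9, components=components)
        assert (len(m.seq) - design75.length) % 3 == 0
        assert len(m.seq) % 3 == design75.length % 3
        assert frame0_stops(m.seq) == [m.uag_offset]
        # both hairpin copies present
        assert len(m.hairpin_spans) == 2

    def test_one_sided_configs_put_both_blocks_on_one_side(self, design75, components):
        left = place_hairpins(design75, "L", 9, 9, components=components)
        assert all(end <= left.uag_offset for _, end in left.hairpin_spans)
        right = place_hairpins(design75, "R", 9, 9, components=components)
        assert all(start >= right.uag_offset + 3 for start, _ in right.hairpin_spans)

    def test_hairpin_sequence_is_embedded(self, design75, components):
        m = place_hairpins(design75, "C", 9, 9, components=components)
        hp = components["ms2_hairpin"].seq
        for start, end in m.hairpin_spans:
            assert hp in m.seq[start:end]

    def test_oversized_spacer_is_an_assembly_error(self, design75, components):
        with pytest.raises(AssemblyError, match="insertion point"):
            place_hairpins(design75, "C", 500, 9, components=components)

    def test_negative_spacer_rejected(self, design75, components):
        with pytest.raises(ValueError):
            place_hairpins(design75, "C", -1, 9, components=components)


class TestAssemble:
    def test_closed_loop_has_four_2a_insulated_coding_components(self, design75, components):
        layout = assemble(design75, "closed_loop", components)
        assert [c.name for c in layout.coding_components] == [
            "tagbfp",
            "sensor_module",
            "mneongreen",
            "mcp_adar",
        ]
        linkers = [c.name for c in layout.components if c.name.startswith("p2a")]
        assert linkers == ["p2a_1", "p2a_2", "p2a_3"]
        assert layout.orf_checks.internal_tag_count == 1
        assert layout.orf_checks.passed

    def test_stopless_backbone_has_zero_internal_stops(self, design75, components):
        layout = assemble(design75, "stopless_backbone", components)
        assert layout.orf_checks.internal_tag_count == 0
        assert layout.orf_checks.internal_stop_count == 0

    def test_basic_no_adar_has_three_coding_components(self, design75, components):
        layout = assemble(design75, "basic_no_adar", components)
        assert [c.name for c in layout.coding_components] == [
            "tagbfp",
            "sensor_module",
            "mneongreen",
        ]

    def test_open_loop_in_trans_carries_separate_adar_cassette(self, design75, components):
        layout = assemble(design75, "open_loop_adar_trans", components)
        assert layout.trans_cassette is not None
        names = [c.name for c in layout.trans_cassette.components]
        assert names == ["cmv_promoter", "mcp_adar", "stop", "bgh_terminator"]
        assert "mcp_adar" not in [c.name for c in layout.components]

    def test_missing_fixture_is_configuration_error(self, design75, components):
        broken = {k: v for k, v in components.items() if k != "tagbfp"}
        with pytest.raises(AssemblyError, match="tagbfp"):
            assemble(design75, "closed_loop", broken)

    def test_sensor_uag_span_points_at_tag(self, design75, components):
        layout = assemble(design75, "closed_loop", components)
        s, e = layout.sensor_uag_span
        assert layout.sequence[s:e] == "TAG"

    def test_assembly_is_deterministic(self, design75, components):
        a = assemble(design75, "closed_loop", components)
        b = assemble(design75, "closed_loop", components)
        assert a.sequence == b.sequence
        assert [c.name for c in a.components] == [c.name for c in b.components]


class TestOrfSemantics:
    def test_edited_transcript_is_single_orf_with_all_payloads_in_order(
        self, design75, components
    ):
        layout = assemble(design75, "closed_loop", components)
        s, _ = layout.sensor_uag_span
        seq = layout.sequence
        edited = seq[: s + 1] + "G" + seq[s + 2 :]  # UAG -> UGG at the edit site
        coding_start = len(components["cmv_promoter"].seq)
        coding_len = layout.orf_checks.coding_length
        peptide = translate(edited[coding_start : coding_start + coding_len], 0)
        assert peptide.count("*") == 1 and peptide.endswith("*")
        marker = translate(components["tagbfp"].seq)
        payload = translate(components["mneongreen"].seq)
        mcp = translate(components["mcp"].seq)
        assert marker in peptide and payload in peptide and mcp in peptide
        assert peptide.index(marker) < peptide.index(payload) < peptide.index(mcp)

    def test_unedited_translation_truncates_within_sensor_module(self, design75, components):
        layout = assemble(design75, "closed_loop", components)
        coding_start = len(components["cmv_promoter"].seq)
        coding_len = layout.orf_checks.coding_length
        peptide = translate(layout.sequence[coding_start : coding_start + coding_len], 0)
        first_stop_nt = coding_start + peptide.index("*") * 3
        s, e = layout.sensor_uag_span
        assert (s, e) == (first_stop_nt, first_stop_nt + 3)
        assert translate(components["mneongreen"].seq) not in peptide[: peptide.index("*")]


class TestSizeBudget:
    def test_closed_loop_fits_aav(self, design75, components):
        layout = assemble(design75, "closed_loop", components)
        budget = size_budget(layout)
        assert budget.within_budget
        assert budget.total_nt < 5000

    def test_full_length_adar1_p150_exceeds_70_percent_of_capacity(self, components):
        layout = ConstructLayout(
            topology=Topology.OPEN_LOOP_ADAR_TRANS,
            components=[components["adar1_p150"]],
            hairpin_config=None,
            spacers=None,
            total_length=len(components["adar1_p150"]),
            orf_checks=_orf_checks([components["adar1_p150"]]),
        )
        budget = size_budget(layout, capacity_nt=5000)
        assert budget.fraction_of_capacity > 0.70

    def test_empty_layout(self):
        layout = ConstructLayout(
            topology=Topology.BASIC_NO_ADAR,
            components=[],
            hairpin_config=None,
            spacers=None,
            total_length=0,
            orf_checks=OrfChecks(0, True, 0, 0, False, [], False),
        )
        budget = size_budget(layout)
        assert (budget.total_nt, budget.fraction_of_capacity) == (0, 0.0)


class TestGenbank:
    def test_round_trip_preserves_sequence_and_features(self, design75, components, tmp_path):
        layout = assemble(design75, "closed_loop", components)
        path = tmp_path / "construct.gb"
        write_genbank(layout, path)
        record = SeqIO.read(str(path), "genbank")
        assert str(record.seq) == layout.sequence
        assert len(record.features) == len(layout.components) + 1  # + sensor UAG feature
        assert len(record.seq) == size_budget(layout).total_nt

    def test_payload_feature_coordinates_match_offsets(self, design75, components, tmp_path):
        layout = assemble(design75, "closed_loop", components)
        path = tmp_path / "construct.gb"
        write_genbank(layout, path)
        record = SeqIO.read(str(path), "genbank")
        expected_offset = 0
        for comp in layout.components:
            if comp.name == "mneongreen":
                break
            expected_offset += len(comp)
        feat = next(f for f in record.features if f.qualifiers.get("label") == ["mneongreen"])
        assert (int(feat.location.start), int(feat.location.end)) == (
            expected_offset,
            expected_offset + len(components["mneongreen"]),
        )
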