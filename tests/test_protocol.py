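import math

import pytest
from hypothesis import given, settings, strategies as st

from mdmsim.chip import ChipLayout, ChipUnit, Microchannel, Microwell
from mdmsim.errors import ProtocolParseError
from mdmsim.protocol import (
    HoldCommand,
    IncubateCommand,
    LayerCode,
    MagnetPosition,
    MixCommand,
    MoveCommand,
    Protocol,
    builtin_elisa_protocol,
    estimate_duration,
    format_command,
    parse_motion_command,
    parse_script,
    read_protocol,
    validate_protocol,
    write_protocol,
)


class TestParsing:
    def test_move_command_example(self):
        cmd = parse_motion_command("T1 to N5")
        assert cmd == MoveCommand(MagnetPosition(LayerCode.TOP, 1),
                                  MagnetPosition(LayerCode.NEUTRAL, 5))

    def test_case_insensitive_layers(self):
        cmd = parse_motion_command("b3 to b4")
        assert cmd.start.layer is LayerCode.BOTTOM
        assert (cmd.start.keypoint, cmd.end.keypoint) == (3, 4)

    @pytest.mark.parametrize("text,fragment", [
        ("X2 to N5", "unknown layer"),
        ("T0 to N5", "outside 1-9"),
        ("T1 to N10", "outside 1-9"),
        ("MIX 4", "takes 2 arguments"),
        ("HOLD B1", "takes 2 arguments"),
        ("INCUBATE 1 900", "takes 3 arguments"),
        ("MIX ten 3", "expected integer"),
        ("FROBNICATE 1", "cannot parse"),
        ("", "empty"),
    ])
    def test_malformed_commands_name_the_problem(self, text, fragment):
        with pytest.raises(ProtocolParseError, match=fragment):
            parse_motion_command(text)

    def test_keyword_commands(self):
        assert parse_motion_command("mix 4 50") == MixCommand(4, 50)
        assert parse_motion_command("HOLD B1 20") == HoldCommand(
            MagnetPosition(LayerCode.BOTTOM, 1), 20.0)
        assert parse_motion_command("INCUBATE 1 900 50") == IncubateCommand(1, 900.0, 50)

    def test_script_with_comments(self):
        proto = parse_script("# wash stage\nB1 to B2  # extract\n\nMIX 2 3\n")
        assert len(proto.steps) == 2
        assert isinstance(proto.steps[0], MoveCommand)
        assert isinstance(proto.steps[1], MixCommand)


_positions = st.builds(
    MagnetPosition,
    layer=st.sampled_from(list(LayerCode)),
    keypoint=st.integers(1, 9),
)
_commands = st.one_of(
    st.builds(MoveCommand, start=_positions, end=_positions),
    st.builds(MixCommand, keypoint=st.integers(1, 9), cycles=st.integers(1, 100)),
    st.builds(HoldCommand, position=_positions,
              duration=st.floats(0, 1e4, allow_nan=False)),
    st.builds(IncubateCommand, keypoint=st.integers(1, 9),
              duration=st.floats(0, 1e5, allow_nan=False),
              embedded_mix_cycles=st.integers(0, 100)),
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(cmd=_commands)
def test_parse_format_round_trip(cmd):
    """parse(format(cmd)) is the identity on every command type."""
    assert parse_motion_command(format_command(cmd)) == cmd


class TestBuiltinProtocol:
    def test_first_incubation_embeds_50_cycles(self, protocol):
        first = next(s for s in protocol.steps if isinstance(s, IncubateCommand))
        assert first.keypoint == 1
        assert first.embedded_mix_cycles == 50
        assert first.duration == 900.0

    def test_bottom_holds_are_20s(self, protocol):
        holds = [s for s in protocol.steps if isinstance(s, HoldCommand)]
        assert holds[0].position == MagnetPosition(LayerCode.BOTTOM, 1)
        assert all(h.duration == 20.0 for h in holds)
        assert all(h.position.layer is LayerCode.BOTTOM for h in holds)

    def test_wash_stations(self, protocol):
        washes = {w for w, species in protocol.manifest.items()
                  if "wash_buffer" in species}
        assert washes == {2, 3, 5, 6, 7}
        assert all(protocol.manifest[w]["wash_buffer"] == 30.0 for w in washes)

    def test_reagent_manifest_volumes(self, protocol):
        m = protocol.manifest
        assert m[1] == {"sample": 30.0, "capture_beads": 5.0, "suspension_g": 0.5}
        assert m[4] == {"detection_antibody": 30.0}
        assert m[8] == {"tmb_substrate": 50.0}
        assert m[9] == {"stop_solution": 10.0}

    def test_substrate_volume_overridable(self):
        proto = builtin_elisa_protocol(tmb_volume_ul=40.0)
        assert proto.manifest[8]["tmb_substrate"] == 40.0

    def test_validates_against_builtin_layout(self, protocol, layout):
        assert validate_protocol(protocol, layout) == []

    def test_bead_path_has_eight_extraction_moves(self, protocol):
        bottom_moves = [s for s in protocol.steps
                        if isinstance(s, MoveCommand)
                        and s.start.layer is LayerCode.BOTTOM
                        and s.start.keypoint != s.end.keypoint]
        # eight forward transfers plus the stop-droplet return
        assert len(bottom_moves) == 9
        assert [(s.start.keypoint, s.end.keypoint) for s in bottom_moves[:8]] == \
            [(i, i + 1) for i in range(1, 9)]
        assert (bottom_moves[8].start.keypoint, bottom_moves[8].end.keypoint) == (9, 8)

    def test_round_trip_through_json(self, protocol, tmp_path):
        path = tmp_path / "protocol.json"
        write_protocol(protocol, path)
        back = read_protocol(path)
        assert back.steps == protocol.steps
        assert back.manifest == protocol.manifest


class TestValidator:
    @pytest.fixture()
    def tiny_layout(self):
        wells = [Microwell(id=i, center=(6.0 * i, 6.0), diameter=4.0,
                           nominal_volume=30.0) for i in (1, 2, 3)]
        unit = ChipUnit(index=1, wells=wells,
                        channels=[Microchannel(wells=(1, 2), width=0.6)],
                        keypoint_map={1: 1, 2: 2, 3: 3})
        return ChipLayout(units=[unit], footprint=(30.0, 30.0))

    def test_unknown_keypoint_flagged(self, tiny_layout):
        proto = Protocol("p", [MixCommand(keypoint=5, cycles=1)])
        assert any("keypoint 5" in v for v in validate_protocol(proto, tiny_layout))

    def test_bottom_move_without_channel_flagged(self, tiny_layout):
        proto = parse_script("B1 to B3")
        assert any("no channel" in v for v in validate_protocol(proto, tiny_layout))

    def test_diagonal_move_flagged(self, tiny_layout):
        proto = parse_script("T1 to N2")
        assert any("diagonal" in v for v in validate_protocol(proto, tiny_layout))

    def test_lateral_top_move_flagged(self, tiny_layout):
        proto = parse_script("T1 to T2")
        assert any("NEUTRAL" in v for v in validate_protocol(proto, tiny_layout))

    def test_empty_protocol_flagged(self, tiny_layout):
        assert validate_protocol(Protocol("p", []), tiny_layout) == ["protocol has no steps"]


class TestDuration:
    def test_two_incubations_sum(self, layout):
        proto = Protocol("p", [IncubateCommand(1, 900.0, 50), IncubateCommand(4, 900.0, 50)])
        assert estimate_duration(proto, layout) == 1800.0

    def test_empty_step_list_is_zero(self, layout):
        assert estimate_duration(Protocol("p", []), layout) == 0.0

    def test_doubling_speed_halves_travel(self, layout):
        proto = parse_script("N1 to N5\nB1 to B2")
        t1 = estimate_duration(proto, layout, speed=1.0)
        t2 = estimate_duration(proto, layout, speed=2.0)
        assert t1 == pytest.approx(2.0 * t2)

    def test_embedded_mix_cycles_add_nothing(self, layout):
        a = Protocol("a", [IncubateCommand(1, 600.0, 0)])
        b = Protocol("b", [IncubateCommand(1, 600.0, 50)])
        assert estimate_duration(a, layout) == estimate_duration(b, layout)

    def test_builtin_turnaround_is_about_45_minutes(self, protocol, layout):
        total = estimate_duration(protocol, layout, speed=1.0)
        assert 2400.0 <= total <= 3000.0  # ~45 min
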