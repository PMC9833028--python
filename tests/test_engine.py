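import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdmsim.chip import builtin_elisa_layout
from mdmsim.engine import (
    ChipState,
    DEFAULT_P_RETAIN,
    EngineParams,
    EventLog,
    TransitionOutcome,
    apply_step,
    audit_conservation,
    classify_channel_transition,
    droplet_footprint_diameter,
    retention_summary,
    run_protocol,
)
from mdmsim.errors import TransitionError
from mdmsim.protocol import (
    HoldCommand,
    IncubateCommand,
    LayerCode,
    MagnetPosition,
    Protocol,
    builtin_elisa_protocol,
    parse_script,
)


def _cap_volume_numeric(radius, theta, n=200_000):
    """Numerically integrate the spherical-cap volume (independent oracle)."""
    h = radius * (1.0 - math.cos(theta))
    z = np.linspace(radius - h, radius, n)
    r_sq = radius ** 2 - z ** 2
    return float(np.trapezoid(math.pi * r_sq, z))


class TestFootprintDiameter:
    @pytest.mark.parametrize("volume,expected", [(10.0, 2.68), (30.0, 3.87)])
    def test_printed_droplet_sizes(self, volume, expected):
        assert droplet_footprint_diameter(volume, 150.0) == pytest.approx(expected, abs=0.01)

    def test_zero_volume(self):
        assert droplet_footprint_diameter(0.0) == 0.0

    @pytest.mark.parametrize("volume,angle", [(10.0, 150.0), (30.0, 150.0),
                                              (5.0, 120.0), (50.0, 95.0)])
    def test_against_numerical_cap_integration(self, volume, angle):
        """The closed-form radius reproduces the requested volume when the
        cap is integrated numerically."""
        theta = math.radians(angle)
        width = droplet_footprint_diameter(volume, angle)
        radius = width / 2.0  # angle > 90 so width is the equator
        assert _cap_volume_numeric(radius, theta) == pytest.approx(volume, rel=1e-6)

    def test_monotone_in_volume(self):
        widths = [droplet_footprint_diameter(v) for v in np.linspace(0.1, 60, 40)]
        assert all(b > a for a, b in zip(widths, widths[1:]))

    @pytest.mark.parametrize("angle", [0.0, -10.0, 181.0])
    def test_bad_contact_angle_rejected(self, angle):
        with pytest.raises(ValueError):
            droplet_footprint_diameter(10.0, angle)


class TestChannelClassification:
    def test_wide_channel_passes_small_droplet(self):
        assert classify_channel_transition(1.3, 2.5) == TransitionOutcome.PASS_DROPLET

    def test_narrow_channel_extracts_from_large_droplet(self):
        assert classify_channel_transition(0.6, 3.7) == TransitionOutcome.EXTRACT_BEADS

    def test_channel_wider_than_droplet_always_passes(self):
        for r_pass in (0.1, 0.35, 0.9, 1.0):
            assert classify_channel_transition(4.0, 3.0, r_pass) == TransitionOutcome.PASS_DROPLET

    def test_both_documented_cases_hold_across_threshold_band(self):
        for r_pass in np.linspace(0.25, 0.51, 27):
            assert classify_channel_transition(1.3, 2.5, r_pass) == TransitionOutcome.PASS_DROPLET
            assert classify_channel_transition(0.6, 3.7, r_pass) == TransitionOutcome.EXTRACT_BEADS

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_channel_transition(0.0, 3.0)
        with pytest.raises(ValueError):
            classify_channel_transition(1.3, -1.0)


def _bare_state(layout):
    return ChipState(unit_index=1)


class TestApplySteps:
    def test_droplet_merge_conserves_volume(self, layout):
        state = _bare_state(layout)
        state.new_droplet(9, 10.0, species={"stop_solution": 10.0})
        state.new_droplet(8, 30.0, species={"tmb_substrate": 30.0})
        log = EventLog()
        rng = np.random.default_rng(0)
        params = EngineParams()
        # droplet in 9 is small; the 8-9 channel is wide -> whole droplet moves
        apply_step(state, parse_script("B9 to B8").steps[0], layout, params, rng, log)
        assert set(state.droplets) == {8}
        merged = state.droplets[8]
        assert merged.volume == pytest.approx(40.0)
        assert merged.species == {"stop_solution": 10.0, "tmb_substrate": 30.0}
        assert merged.homogeneity == 0.0

    def test_extraction_with_full_retention_keeps_all_beads(self, layout):
        from mdmsim.engine import BeadPopulation

        state = _bare_state(layout)
        state.new_droplet(1, 35.0)
        state.beads = BeadPopulation(count=5000, location=1, clustered=True)
        log = EventLog()
        params = EngineParams(p_retain=1.0)
        apply_step(state, parse_script("B1 to B2").steps[0], layout, params,
                   np.random.default_rng(0), log)
        assert state.beads.count == 5000
        assert state.beads.location == 2

    def test_extraction_survivors_are_binomial(self, layout):
        from mdmsim.engine import BeadPopulation

        p = DEFAULT_P_RETAIN
        n = 10_000
        survivors = []
        for seed in range(50):
            state = _bare_state(layout)
            state.new_droplet(1, 35.0)
            state.beads = BeadPopulation(count=n, location=1, clustered=True)
            apply_step(state, parse_script("B1 to B2").steps[0], layout,
                       EngineParams(), np.random.default_rng(seed), EventLog())
            survivors.append(state.beads.count)
        mean = np.mean(survivors)
        se = math.sqrt(n * p * (1 - p) / len(survivors))
        assert abs(mean - n * p) < 3 * se

    def test_extraction_requires_clustered_beads(self, layout):
        from mdmsim.engine import BeadPopulation

        state = _bare_state(layout)
        state.new_droplet(1, 35.0)
        state.beads = BeadPopulation(count=100, location=1, clustered=False)
        with pytest.raises(TransitionError, match="not clustered"):
            apply_step(state, parse_script("B1 to B2").steps[0], layout,
                       EngineParams(), np.random.default_rng(0), EventLog())

    def test_bottom_move_without_channel_rejected(self, layout):
        state = _bare_state(layout)
        with pytest.raises(TransitionError, match="no channel"):
            apply_step(state, parse_script("B1 to B5").steps[0], layout,
                       EngineParams(), np.random.default_rng(0), EventLog())

    def test_neutral_moves_change_nothing_but_position(self, layout):
        state = _bare_state(layout)
        state.new_droplet(1, 30.0)
        log = EventLog()
        apply_step(state, parse_script("N1 to N5").steps[0], layout,
                   EngineParams(), np.random.default_rng(0), log)
        assert state.magnet == MagnetPosition(LayerCode.NEUTRAL, 5)
        assert state.droplets[1].volume == 30.0

    def test_hold_clusters_beads(self, layout):
        from mdmsim.engine import BeadPopulation

        state = _bare_state(layout)
        state.beads = BeadPopulation(count=100, location=1, clustered=False)
        apply_step(state, HoldCommand(MagnetPosition(LayerCode.BOTTOM, 1), 20.0),
                   layout, EngineParams(), np.random.default_rng(0), EventLog())
        assert state.beads.clustered

    def test_mix_advances_homogeneity(self, layout):
        from mdmsim.protocol import MixCommand

        state = _bare_state(layout)
        d = state.new_droplet(1, 30.0, homogeneity=0.0)
        apply_step(state, MixCommand(1, 3), layout, EngineParams(),
                   np.random.default_rng(0), EventLog())
        assert d.homogeneity == pytest.approx(0.95)

    def test_overflow_is_logged_not_raised(self, layout):
        state = _bare_state(layout)
        state.new_droplet(9, 10.0)
        state.new_droplet(8, 55.0)
        log = EventLog()
        apply_step(state, parse_script("B9 to B8").steps[0], layout,
                   EngineParams(), np.random.default_rng(0), log)
        assert log.of_kind("overflow_warning")


class TestFullRuns:
    def test_builtin_run_retains_about_78_percent(self, layout, protocol):
        _, log = run_protocol(layout, protocol, seed=11, initial_beads=10_000)
        r = retention_summary(log)
        # single run: binomial spread around 0.78
        assert abs(r - 0.78) < 5 * math.sqrt(0.78 * 0.22 / 10_000)

    def test_protocol_without_extractions_retains_everything(self, layout):
        proto = Protocol("idle", parse_script("N1 to N5\nMIX 1 3").steps,
                         manifest={1: {"sample": 30.0}}, metadata={"bead_well": 1})
        _, log = run_protocol(layout, proto, seed=0, initial_beads=1000)
        assert retention_summary(log) == 1.0

    def test_determinism_same_seed_same_outcome(self, layout, protocol):
        s1, l1 = run_protocol(layout, protocol, seed=123)
        s2, l2 = run_protocol(layout, protocol, seed=123)
        assert s1.beads.count == s2.beads.count
        assert s1.total_volume() == s2.total_volume()
        assert [(e.kind, e.payload) for e in l1] == [(e.kind, e.payload) for e in l2]

    def test_different_seeds_vary(self, layout, protocol):
        counts = {run_protocol(layout, protocol, seed=s)[0].beads.count
                  for s in range(6)}
        assert len(counts) > 1

    def test_volume_and_bead_conservation(self, layout, protocol):
        for seed in range(20):
            state, log = run_protocol(layout, protocol, seed=seed)
            audit = audit_conservation(log, state)
            assert audit["volume_error_ul"] == pytest.approx(0.0, abs=1e-9)
            assert audit["bead_error"] == 0

    def test_transition_error_reports_step_index(self, layout):
        proto = Protocol("bad", parse_script("B1 to B5").steps,
                         manifest={1: {"sample": 30.0}}, metadata={"bead_well": 1})
        with pytest.raises(TransitionError, match=r"step 1"):
            run_protocol(layout, proto, seed=0)

    def test_stop_droplet_returns_through_wide_channel(self, layout, protocol):
        state, log = run_protocol(layout, protocol, seed=5)
        # final droplet sits in the observation well with stop solution merged in
        final_well = state.beads.location
        assert final_well == 8
        final = state.droplets[8]
        assert "stop_solution" in final.species
        assert final.volume == pytest.approx(60.5)

    def test_retention_mean_matches_compounded_probability(self, layout, protocol):
        rs = [retention_summary(run_protocol(layout, protocol, seed=s)[1])
              for s in range(60)]
        expected = DEFAULT_P_RETAIN ** 8
        se = np.std(rs, ddof=1) / math.sqrt(len(rs))
        assert abs(np.mean(rs) - expected) < 3 * se + 1e-6


class TestRetentionSummary:
    def test_no_extractions_is_unity(self, layout):
        proto = Protocol("idle", parse_script("N1 to N2").steps,
                         manifest={1: {"sample": 30.0}}, metadata={"bead_well": 1})
        _, log = run_protocol(layout, proto, seed=0, initial_beads=500)
        assert retention_summary(log) == 1.0

    def test_single_half_retention_extraction(self, layout):
        proto = Protocol(
            "one-wash",
            parse_script("HOLD B1 20\nB1 to B2").steps,
            manifest={1: {"sample": 30.0}}, metadata={"bead_well": 1})
        rs = [retention_summary(run_protocol(layout, proto, seed=s,
                                             initial_beads=10_000,
                                             params=EngineParams(p_retain=0.5))[1])
              for s in range(30)]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.01)

    def test_zero_initial_beads_rejected(self, layout):
        proto = Protocol("idle", parse_script("N1 to N2").steps,
                         manifest={1: {"sample": 30.0}}, metadata={"bead_well": 1})
        _, log = run_protocol(layout, proto, seed=0, initial_beads=0)
        with pytest.raises(ValueError, match="zero initial beads"):
            retention_summary(log)
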