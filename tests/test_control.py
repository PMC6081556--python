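"""Translator graph, command/proportional control, NP progress index."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgkit import (
    Calibration,
    Edge,
    Module,
    ModuleGraph,
    clamp_error,
    command_map,
    np_index,
    progress_report,
    proportional_speed,
    validate_graph,
)
from emgkit.control import NO_OP, load_command_library


def _chain():
    return ModuleGraph(
        modules=[
            Module("emg", "input"),
            Module("ann", "processing"),
            Module("robot", "executor"),
        ],
        edges=[Edge("emg", "ann"), Edge("ann", "robot")],
    )


class TestGraphValidation:
    def test_minimal_chain_is_ok(self):
        assert validate_graph(_chain()) == []

    def test_input_to_executor_is_named_violation(self):
        g = _chain()
        g.edges.append(Edge("emg", "robot", "aux"))
        violations = validate_graph(g)
        assert any("emg" in v and "robot" in v for v in violations)

    def test_fan_out_to_two_executors_is_ok(self):
        g = ModuleGraph(
            modules=[
                Module("emg", "input"),
                Module("ann", "processing"),
                Module("lego", "executor"),
                Module("nao", "executor"),
            ],
            edges=[Edge("emg", "ann"), Edge("ann", "lego"), Edge("ann", "nao")],
        )
        assert validate_graph(g) == []

    def test_doubly_connected_slot_and_orphans(self):
        g = _chain()
        g.edges.append(Edge("emg", "ann"))  # same default slot twice
        assert any("twice" in v for v in validate_graph(g))
        orphan = ModuleGraph(
            modules=[Module("ann", "processing")], edges=[]
        )
        assert any("no incoming" in v for v in validate_graph(orphan))

    def test_edge_kinds_exhaustive_enumeration(self):
        """Over all 9 ordered kind pairs, exactly input->processing and
        processing->executor validate; brute-force rule as the oracle."""
        kinds = ("input", "processing", "executor")
        for src_kind, dst_kind in itertools.product(kinds, repeat=2):
            g = ModuleGraph(
                modules=[Module("a", src_kind), Module("b", dst_kind)],
                edges=[Edge("a", "b")],
            )
            edge_violations = [
                v for v in validate_graph(g) if "illegal edge" in v
            ]
            legal = (src_kind, dst_kind) in {
                ("input", "processing"),
                ("processing", "executor"),
            }
            assert (edge_violations == []) == legal

    def test_unknown_module_reported_not_raised(self):
        g = ModuleGraph(modules=[Module("emg", "input")], edges=[Edge("emg", "ghost")])
        assert any("ghost" in v for v in validate_graph(g))


class TestCommandMap:
    def test_bound_unbound_and_macro(self):
        library = load_command_library({0: "go-forward", 1: ["rotate-A", "rotate-B"]})
        assert command_map(0, library) == ["go-forward"]
        assert command_map(1, library) == ["rotate-A", "rotate-B"]
        assert command_map(7, library) == [NO_OP]

    def test_duplicate_binding_rejected_at_load(self):
        with pytest.raises(ValueError, match="more than once"):
            load_command_library([(0, "stop"), (0, "go-forward")])


class TestProportionalSpeed:
    @pytest.mark.parametrize(
        "mav_value, expected",
        [(0.1, 0.0), (0.9, 100.0), (0.5, 50.0), (0.0, 0.0), (5.0, 100.0)],
    )
    def test_anchors_midpoint_clamping(self, mav_value, expected):
        calib = Calibration(mav_rest=0.1, mav_max=0.9)
        assert proportional_speed(mav_value, calib) == pytest.approx(expected)

    def test_bad_calibration_raises(self):
        with pytest.raises(ValueError):
            Calibration(mav_rest=0.5, mav_max=0.5)
        with pytest.raises(ValueError):
            Calibration(mav_rest=-0.1, mav_max=1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=40))
    def test_monotone_and_bounded(self, mavs):
        calib = Calibration(mav_rest=0.2, mav_max=2.0)
        speeds = [proportional_speed(m, calib) for m in sorted(mavs)]
        assert all(0.0 <= s <= 100.0 for s in speeds)
        assert all(a <= b + 1e-12 for a, b in zip(speeds, speeds[1:]))


class TestNpIndex:
    def test_equal_errors_give_exact_zero(self):
        for e in (0.001, 0.2, 1.0):
            assert np_index(e, e) == 0.0

    def test_known_ratios(self):
        assert np_index(0.2 / math.e, 0.2) == pytest.approx(-1.0, abs=1e-12)
        assert np_index(0.4, 0.2) == pytest.approx(math.log(2.0), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(0.01, 100.0, allow_nan=False),
        e=st.floats(1e-4, 1.0, allow_nan=False),
    )
    def test_log_ratio_identity(self, a, e):
        """np_index(a*E, E) == ln(a) regardless of the base error."""
        assert np_index(a * e, e) == pytest.approx(math.log(a), abs=1e-9)

    def test_nonpositive_errors_rejected(self):
        with pytest.raises(ValueError):
            np_index(0.0, 0.2)
        with pytest.raises(ValueError):
            np_index(0.2, -0.1)

    def test_clamp_error_floor(self):
        assert clamp_error(0.0, 90) == pytest.approx(1.0 / 180.0)
        assert clamp_error(0.25, 90) == 0.25


class TestProgressReport:
    def test_day_one_anchor_and_improvement(self):
        assert progress_report([0.2]).np_values == [0.0]
        report = progress_report([0.2, 0.1])
        assert report.np_values[0] == 0.0
        assert report.np_values[1] == pytest.approx(math.log(0.5), abs=1e-12)

    def test_constant_performance_is_flat(self):
        assert progress_report([0.2, 0.2, 0.2]).np_values == [0.0, 0.0, 0.0]

    def test_validation(self):
        with pytest.raises(ValueError):
            progress_report([])
        with pytest.raises(ValueError):
            progress_report([0.2, 0.0])
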