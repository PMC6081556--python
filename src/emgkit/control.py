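"""Signal-translator graph, hybrid command/proportional control, NP index.

The translator is a directed graph of three module kinds: *input* modules
source the normalized feature stream, *processing* modules wrap a classifier,
and *executor* modules drive a (here virtual) robotic device.  Legal edges
run input->processing and processing->executor only; one output may fan out
to several free input slots, but each input slot accepts a single edge.

Streaming control emits exactly one :class:`CommandEvent` per feature window:
the recognized gesture pattern selects the command (via a pattern->command
library) and the window's MAV sets the actuation speed as a percentage,
affinely between a calibrated rest MAV (0%) and maximum-effort MAV (100%).

Across training sessions, progress is tracked by the neurointerface
performance index

    NP = ln(E_i / E_1),

the log-ratio of the current session's classification error to the first
session's; NP is 0 on day one by construction, negative when performance
improves and positive when it degrades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import WindowConfig, featurize
from .mlp import MlpModel, classify
from .synth import EmgRecording

__all__ = [
    "Module",
    "ModuleGraph",
    "Calibration",
    "CommandEvent",
    "TrainingProgress",
    "NO_OP",
    "validate_graph",
    "load_command_library",
    "command_map",
    "proportional_speed",
    "run_stream",
    "np_index",
    "clamp_error",
    "progress_report",
]

#: Command emitted for patterns with no binding in the library.
NO_OP = "no-op"

_KINDS = ("input", "processing", "executor")
_LEGAL_EDGES = {("input", "processing"), ("processing", "executor")}


@dataclass(frozen=True)
class Module:
    """One node of the translator graph."""

    name: str
    kind: str  # input | processing | executor
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown module kind {self.kind!r}; use {_KINDS}")


@dataclass(frozen=True)
class Edge:
    """Connection from a module output to a named input slot of another."""

    src: str
    dst: str
    dst_slot: str = "in"


@dataclass
class ModuleGraph:
    modules: list[Module]
    edges: list[Edge]

    def module(self, name: str) -> Module:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    def of_kind(self, kind: str) -> list[Module]:
        return [m for m in self.modules if m.kind == kind]


def validate_graph(graph: ModuleGraph) -> list[str]:
    """All rule violations in the graph; an empty list means the graph is ok.

    Checked: edges reference known modules; edge kinds are input->processing
    or processing->executor only; no input slot receives two edges; every
    processing and executor module has at least one incoming edge.
    """
    violations: list[str] = []
    kinds = {m.name: m.kind for m in graph.modules}
    seen_slots: set[tuple[str, str]] = set()
    fed: set[str] = set()
    for e in graph.edges:
        if e.src not in kinds:
            violations.append(f"edge references unknown module {e.src!r}")
            continue
        if e.dst not in kinds:
            violations.append(f"edge references unknown module {e.dst!r}")
            continue
        pair = (kinds[e.src], kinds[e.dst])
        if pair not in _LEGAL_EDGES:
            violations.append(
                f"illegal edge {e.src!r} ({pair[0]}) -> {e.dst!r} ({pair[1]}): "
                "only input->processing and processing->executor are allowed"
            )
            continue
        slot = (e.dst, e.dst_slot)
        if slot in seen_slots:
            violations.append(
                f"input slot {e.dst_slot!r} of {e.dst!r} is connected twice"
            )
        seen_slots.add(slot)
        fed.add(e.dst)
    for m in graph.modules:
        if m.kind in ("processing", "executor") and m.name not in fed:
            violations.append(f"{m.kind} module {m.name!r} has no incoming edge")
    return violations


def load_command_library(bindings) -> dict[int, list[str]]:
    """Normalize a pattern->command library.

    Accepts a mapping ``{pattern: command-or-sequence}`` or an iterable of
    ``(pattern, command-or-sequence)`` pairs (the JSON on-disk form, where
    duplicate pattern bindings are detectable and rejected).
    """
    items = bindings.items() if hasattr(bindings, "items") else bindings
    library: dict[int, list[str]] = {}
    for pattern, cmd in items:
        pattern = int(pattern)
        if pattern in library:
            raise ValueError(f"pattern {pattern} bound more than once")
        library[pattern] = [cmd] if isinstance(cmd, str) else [str(c) for c in cmd]
    return library


def command_map(pattern_id: int, library) -> list[str]:
    """Command sequence bound to a recognized pattern; ``[NO_OP]`` if unbound."""
    library = load_command_library(library) if not isinstance(library, dict) else library
    seq = library.get(int(pattern_id))
    if seq is None:
        return [NO_OP]
    return [seq] if isinstance(seq, str) else [str(c) for c in seq]


@dataclass(frozen=True)
class Calibration:
    """MAV anchors mapping effort to speed: rest -> 0%, maximum -> 100%."""

    mav_rest: float
    mav_max: float

    def __post_init__(self) -> None:
        if not (self.mav_max > self.mav_rest >= 0):
            raise ValueError(
                f"calibration requires mav_max > mav_rest >= 0, got "
                f"rest={self.mav_rest}, max={self.mav_max}"
            )


def proportional_speed(mav: float, calibration: Calibration) -> float:
    """Speed in percent of maximum actuation, affine in MAV and clamped."""
    frac = (mav - calibration.mav_rest) / (calibration.mav_max - calibration.mav_rest)
    return 100.0 * float(np.clip(frac, 0.0, 1.0))


@dataclass(frozen=True)
class CommandEvent:
    """One time-stamped device command with proportional speed."""

    t_ms: float
    command: str  # ';'-joined sequence when a pattern maps to a macro
    speed_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.speed_pct <= 100.0):
            raise ValueError("speed_pct must lie in [0, 100]")


def run_stream(
    graph: ModuleGraph,
    recording: EmgRecording,
    model: MlpModel,
    config: WindowConfig,
    calibration: Calibration,
    library=None,
) -> list[CommandEvent]:
    """Run the full translator loop over a recording.

    For each feature window in order: normalize (stored model bounds),
    classify, map the pattern to its command sequence, and attach the
    MAV-proportional speed.  Emits exactly one event per window and is
    deterministic given its inputs.  The command library may be passed
    directly or carried in an executor module's ``params['library']``.
    """
    violations = validate_graph(graph)
    if violations:
        raise ValueError("invalid module graph: " + "; ".join(violations))
    if library is None:
        library = {}
        for m in graph.of_kind("executor"):
            library.update(load_command_library(m.params.get("library", {})))
    else:
        library = load_command_library(library)

    events: list[CommandEvent] = []
    for w in featurize(recording, config):
        pattern = classify(model, w.rms)
        commands = command_map(pattern, library)
        events.append(
            CommandEvent(
                t_ms=w.t_end / recording.sampling_rate * 1000.0,
                command=";".join(commands),
                speed_pct=proportional_speed(w.mav, calibration),
            )
        )
    return events


def np_index(e_i: float, e_1: float) -> float:
    """Neurointerface performance index NP = ln(E_i / E_1).

    Both error rates must be strictly positive (clamp perfect sessions with
    :func:`clamp_error` first).  Negative NP means improvement over the
    first session, positive means degradation.
    """
    if not (np.isfinite(e_i) and np.isfinite(e_1)):
        raise ValueError("error rates must be finite")
    if e_i <= 0 or e_1 <= 0:
        raise ValueError(
            f"NP is undefined for non-positive error rates (E_i={e_i}, "
            f"E_1={e_1}); clamp perfect sessions with clamp_error()"
        )
    return float(np.log(e_i / e_1))


def clamp_error(error: float, n_test_windows: int) -> float:
    """Raise a perfect (zero) session error to half of one misclassified
    window, 1 / (2 n), so the NP log-ratio stays defined while preserving
    session ordering."""
    if n_test_windows < 1:
        raise ValueError("n_test_windows must be >= 1")
    return max(float(error), 1.0 / (2.0 * n_test_windows))


@dataclass
class TrainingProgress:
    """Per-session classification errors and the NP trajectory."""

    errors: list[float]
    np_values: list[float]

    def __post_init__(self) -> None:
        if any(not (0.0 < e <= 1.0) for e in self.errors):
            raise ValueError("session errors must lie in (0, 1]")


def progress_report(session_errors) -> TrainingProgress:
    """NP per session relative to session 1; the first entry is exactly 0."""
    errors = [float(e) for e in session_errors]
    if not errors:
        raise ValueError("at least one session error is required")
    if any(e <= 0 for e in errors):
        raise ValueError(
            "all session errors must be > 0; clamp perfect sessions with "
            "clamp_error()"
        )
    np_values = [0.0] + [np_index(e, errors[0]) for e in errors[1:]]
    return TrainingProgress(errors=errors, np_values=np_values)
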