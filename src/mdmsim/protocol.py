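"""Magnet-motion protocol DSL: grammar, parser, validator and the built-in assay.

The magnet controller is programmed with a tiny command language over a
layer × keypoint grid. The vertical axis is discretized into four layers —
TOP (T), NEUTRAL (N), MEZZANINE (M) and BOTTOM (B) — and each layer has nine
keypoints coinciding with the microwell centers. A move is written
``"T1 to N5"``: from top-layer keypoint 1 to neutral-layer keypoint 5.
Keyword commands cover the composite operations:

    MIX <keypoint> <cycles>                 agitate the droplet in place
    HOLD <layer><keypoint> <seconds>        park the magnet (e.g. B1 20)
    INCUBATE <keypoint> <seconds> <cycles>  timed incubation with embedded mixing

Layer semantics constrain lateral motion: the magnet may roam freely in the
NEUTRAL layer (too weak to disturb droplets), may traverse the BOTTOM layer
only along a microchannel (this is what drags droplets or extracts beads),
and must change layers vertically at a single keypoint.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass, field

from .chip import ChipLayout
from .errors import ProtocolParseError

#: Wall-clock seconds per mixing cycle (one vertical reciprocal + one
#: circular motion); calibrated so 3 cycles take the observed ~54 s.
MIX_CYCLE_SECONDS = 18.0


class LayerCode(enum.Enum):
    TOP = "T"
    NEUTRAL = "N"
    MEZZANINE = "M"
    BOTTOM = "B"

    @classmethod
    def from_letter(cls, letter: str) -> "LayerCode":
        try:
            return cls(letter.upper())
        except ValueError:
            raise ProtocolParseError(f"unknown layer {letter!r}") from None


@dataclass(frozen=True)
class MagnetPosition:
    layer: LayerCode
    keypoint: int

    def __post_init__(self):
        if not 1 <= self.keypoint <= 9:
            raise ProtocolParseError(f"keypoint {self.keypoint} outside 1-9")

    def __str__(self) -> str:
        return f"{self.layer.value}{self.keypoint}"


@dataclass(frozen=True)
class MoveCommand:
    start: MagnetPosition
    end: MagnetPosition
    speed: float = 1.0  # mm/s

    def format(self) -> str:
        return f"{self.start} to {self.end}"


@dataclass(frozen=True)
class MixCommand:
    keypoint: int
    cycles: int

    def format(self) -> str:
        return f"MIX {self.keypoint} {self.cycles}"


@dataclass(frozen=True)
class HoldCommand:
    position: MagnetPosition
    duration: float  # s

    def format(self) -> str:
        return f"HOLD {self.position} {_fmt_num(self.duration)}"


@dataclass(frozen=True)
class IncubateCommand:
    keypoint: int
    duration: float  # s
    embedded_mix_cycles: int = 0

    def format(self) -> str:
        return f"INCUBATE {self.keypoint} {_fmt_num(self.duration)} {self.embedded_mix_cycles}"


Command = MoveCommand | MixCommand | HoldCommand | IncubateCommand


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


@dataclass
class Protocol:
    """An ordered magnet program plus the reagent manifest it assumes.

    ``manifest`` maps well id -> {species: volume µL}; it describes what a
    technician preloads before pressing GO and is what the simulator uses to
    seed the initial droplets.
    """

    name: str
    steps: list[Command]
    manifest: dict[int, dict[str, float]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# parsing

_POS_RE = re.compile(r"^([A-Za-z])(\d+)$")
_MOVE_RE = re.compile(r"^(\S+)\s+to\s+(\S+)$", re.IGNORECASE)


def _parse_position(token: str) -> MagnetPosition:
    m = _POS_RE.match(token)
    if not m:
        raise ProtocolParseError(f"cannot parse magnet position {token!r}")
    layer = LayerCode.from_letter(m.group(1))
    kp = int(m.group(2))
    if not 1 <= kp <= 9:
        raise ProtocolParseError(f"keypoint {kp} outside 1-9 in {token!r}")
    return MagnetPosition(layer, kp)


def _parse_int(token: str, what: str, minimum: int = 0) -> int:
    try:
        val = int(token)
    except ValueError:
        raise ProtocolParseError(f"{what}: expected integer, got {token!r}") from None
    if val < minimum:
        raise ProtocolParseError(f"{what}: {val} < {minimum}")
    return val


def _parse_float(token: str, what: str) -> float:
    try:
        val = float(token)
    except ValueError:
        raise ProtocolParseError(f"{what}: expected number, got {token!r}") from None
    if val < 0:
        raise ProtocolParseError(f"{what}: must be >= 0, got {val}")
    return val


def parse_motion_command(text: str) -> Command:
    """Parse one command line ("T1 to N5", "MIX 4 50", "HOLD B1 20", ...).

    Layer letters and keywords are case-insensitive. Raises
    :class:`ProtocolParseError` naming the offending token otherwise.
    """
    line = text.strip()
    if not line:
        raise ProtocolParseError("empty command")
    tokens = line.split()
    head = tokens[0].upper()
    if head == "MIX":
        if len(tokens) != 3:
            raise ProtocolParseError(f"MIX takes 2 arguments, got {len(tokens) - 1}: {line!r}")
        kp = _parse_int(tokens[1], "MIX keypoint", minimum=1)
        if kp > 9:
            raise ProtocolParseError(f"keypoint {kp} outside 1-9")
        return MixCommand(keypoint=kp, cycles=_parse_int(tokens[2], "MIX cycles", minimum=1))
    if head == "HOLD":
        if len(tokens) != 3:
            raise ProtocolParseError(f"HOLD takes 2 arguments, got {len(tokens) - 1}: {line!r}")
        return HoldCommand(position=_parse_position(tokens[1]),
                           duration=_parse_float(tokens[2], "HOLD duration"))
    if head == "INCUBATE":
        if len(tokens) != 4:
            raise ProtocolParseError(f"INCUBATE takes 3 arguments, got {len(tokens) - 1}: {line!r}")
        kp = _parse_int(tokens[1], "INCUBATE keypoint", minimum=1)
        if kp > 9:
            raise ProtocolParseError(f"keypoint {kp} outside 1-9")
        return IncubateCommand(
            keypoint=kp,
            duration=_parse_float(tokens[2], "INCUBATE duration"),
            embedded_mix_cycles=_parse_int(tokens[3], "INCUBATE mix cycles"),
        )
    m = _MOVE_RE.match(line)
    if m:
        return MoveCommand(start=_parse_position(m.group(1)), end=_parse_position(m.group(2)))
    raise ProtocolParseError(f"cannot parse command {line!r}")


def format_command(cmd: Command) -> str:
    return cmd.format()


def parse_script(text: str, name: str = "script") -> Protocol:
    """Parse a line-oriented protocol script ('#' starts a comment)."""
    steps = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            steps.append(parse_motion_command(line))
        except ProtocolParseError as exc:
            raise ProtocolParseError(f"line {lineno}: {exc}") from None
    return Protocol(name=name, steps=steps)


def format_script(protocol: Protocol) -> str:
    return "\n".join(step.format() for step in protocol.steps) + "\n"


# JSON form: {"name":..., "steps": ["T1 to N5", ...], "manifest": {"1": {...}}}

def protocol_to_dict(protocol: Protocol) -> dict:
    return {
        "name": protocol.name,
        "steps": [s.format() for s in protocol.steps],
        "manifest": {str(k): v for k, v in protocol.manifest.items()},
        "metadata": protocol.metadata,
    }


def protocol_from_dict(doc: dict) -> Protocol:
    try:
        return Protocol(
            name=doc.get("name", "protocol"),
            steps=[parse_motion_command(s) for s in doc["steps"]],
            manifest={int(k): {s: float(v) for s, v in d.items()}
                      for k, d in doc.get("manifest", {}).items()},
            metadata=doc.get("metadata", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ProtocolParseError(f"malformed protocol document: {exc!r}") from exc


def write_protocol(protocol: Protocol, path) -> None:
    with open(path, "w") as fh:
        json.dump(protocol_to_dict(protocol), fh, indent=1)
        fh.write("\n")


def read_protocol(path) -> Protocol:
    """Read a protocol from JSON (dict form) or a line-oriented script."""
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ProtocolParseError(f"cannot parse {path}: line {exc.lineno}: {exc.msg}") from exc
        return protocol_from_dict(doc)
    import os
    return parse_script(text, name=os.path.basename(str(path)))


# ---------------------------------------------------------------------------
# validation against a layout

def validate_protocol(protocol: Protocol, layout: ChipLayout) -> list[str]:
    """Static checks of a protocol against a chip layout.

    Flags keypoints absent from the layout's keypoint map, BOTTOM-layer
    traversals between wells not joined by a channel, lateral motion in the
    TOP/MEZZANINE layers, and diagonal (layer+keypoint) moves. A protocol
    with no violations executes in the engine without transition errors.
    """
    v: list[str] = []
    if not protocol.steps:
        v.append("protocol has no steps")
        return v
    unit = layout.units[0]
    kps = set(unit.keypoint_map)

    def check_kp(kp: int, where: str):
        if kp not in kps:
            v.append(f"step {where}: keypoint {kp} not in layout keypoint_map")

    for i, step in enumerate(protocol.steps, start=1):
        if isinstance(step, MoveCommand):
            check_kp(step.start.keypoint, f"{i} ({step.format()})")
            check_kp(step.end.keypoint, f"{i} ({step.format()})")
            same_kp = step.start.keypoint == step.end.keypoint
            same_layer = step.start.layer == step.end.layer
            if not same_kp and not same_layer:
                v.append(f"step {i} ({step.format()}): diagonal move (change layer and keypoint separately)")
            elif not same_kp and step.start.layer == LayerCode.BOTTOM:
                if step.start.keypoint in kps and step.end.keypoint in kps:
                    wa = unit.keypoint_map[step.start.keypoint]
                    wb = unit.keypoint_map[step.end.keypoint]
                    if unit.channel_between(wa, wb) is None:
                        v.append(f"step {i} ({step.format()}): no channel joins wells {wa} and {wb}")
            elif not same_kp and step.start.layer in (LayerCode.TOP, LayerCode.MEZZANINE):
                v.append(f"step {i} ({step.format()}): lateral motion only allowed in NEUTRAL or along a BOTTOM channel")
        elif isinstance(step, MixCommand):
            check_kp(step.keypoint, f"{i} ({step.format()})")
        elif isinstance(step, HoldCommand):
            check_kp(step.position.keypoint, f"{i} ({step.format()})")
        elif isinstance(step, IncubateCommand):
            check_kp(step.keypoint, f"{i} ({step.format()})")
    for wid in protocol.manifest:
        try:
            unit.well(wid)
        except KeyError:
            v.append(f"manifest references unknown well {wid}")
    return v


# ---------------------------------------------------------------------------
# built-in ELISA protocol

def builtin_elisa_protocol(tmb_volume_ul: float = 50.0,
                           develop_seconds: float = 300.0) -> Protocol:
    """The built-in bead-based sandwich-ELISA magnet program.

    Workflow per unit: sample + capture beads incubate in well 1 (~15 min,
    50 mixing cycles), beads are clustered with a 20 s bottom hold and
    extracted through narrow channels into two 1-min washes (wells 2-3,
    3 mixing cycles each), incubated with the enzyme-labelled detection
    antibody in well 4 (~15 min, 50 cycles), washed three more times
    (wells 5-7), developed with the chromogen substrate in well 8, then the
    beads are extracted into well 9 and used to drag the small stop-solution
    droplet back through the wide 9-8 channel to quench the reaction in the
    observation well.

    The substrate development time is not a printed quantity; the default
    ``develop_seconds`` of 300 s is a package choice and can be overridden,
    as can the substrate volume (see the 40 vs 50 µL manifest ambiguity in
    the docs).
    """
    B = LayerCode.BOTTOM
    N = LayerCode.NEUTRAL

    def hold(kp): return HoldCommand(MagnetPosition(B, kp), 20.0)

    def move(a, b): return MoveCommand(MagnetPosition(B, a), MagnetPosition(B, b))

    steps: list[Command] = [
        MoveCommand(MagnetPosition(N, 1), MagnetPosition(N, 1)),  # home
        IncubateCommand(1, 900.0, 50),      # sample + capture beads
        hold(1), move(1, 2),
        IncubateCommand(2, 60.0, 3),        # wash 1
        hold(2), move(2, 3),
        IncubateCommand(3, 60.0, 3),        # wash 2
        hold(3), move(3, 4),
        IncubateCommand(4, 900.0, 50),      # detection antibody
        hold(4), move(4, 5),
        IncubateCommand(5, 60.0, 3),        # wash 3
        hold(5), move(5, 6),
        IncubateCommand(6, 60.0, 3),        # wash 4
        hold(6), move(6, 7),
        IncubateCommand(7, 60.0, 3),        # wash 5
        hold(7), move(7, 8),
        IncubateCommand(8, develop_seconds, 3),  # substrate development
        hold(8), move(8, 9),                # extract beads away from substrate
        hold(9), move(9, 8),                # drag stop droplet back (wide channel)
        MixCommand(8, 3),                   # blend stop into the developed droplet
    ]
    manifest = {
        1: {"sample": 30.0, "capture_beads": 5.0, "suspension_g": 0.5},
        2: {"wash_buffer": 30.0},
        3: {"wash_buffer": 30.0},
        4: {"detection_antibody": 30.0},
        5: {"wash_buffer": 30.0},
        6: {"wash_buffer": 30.0},
        7: {"wash_buffer": 30.0},
        8: {"tmb_substrate": float(tmb_volume_ul)},
        9: {"stop_solution": 10.0},
    }
    return Protocol(
        name="builtin-elisa",
        steps=steps,
        manifest=manifest,
        metadata={"target_assay": "bead-sandwich-elisa", "bead_well": 1},
    )


# ---------------------------------------------------------------------------
# duration model

def estimate_duration(protocol: Protocol, layout: ChipLayout, speed: float = 1.0,
                      mix_cycle_s: float = MIX_CYCLE_SECONDS) -> float:
    """Estimate wall-clock seconds to run a protocol.

    Sums hold and incubation durations, travel time (planar keypoint-to-
    keypoint distance at ``speed``), and standalone mixing at
    ``mix_cycle_s`` per cycle. Mixing cycles embedded in an incubation are
    assumed to happen within the incubation window and add nothing.
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    unit = layout.units[0]
    total = 0.0
    for step in protocol.steps:
        if isinstance(step, MoveCommand):
            if step.start.keypoint != step.end.keypoint:
                ax, ay = unit.global_center(unit.keypoint_map[step.start.keypoint])
                bx, by = unit.global_center(unit.keypoint_map[step.end.keypoint])
                total += math.hypot(bx - ax, by - ay) / speed
        elif isinstance(step, HoldCommand):
            total += step.duration
        elif isinstance(step, IncubateCommand):
            total += step.duration
        elif isinstance(step, MixCommand):
            total += step.cycles * mix_cycle_s
    return total
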