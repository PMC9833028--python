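"""Chip geometry: microwells, microchannels, units, and layout I/O.

A chip is a thermoformed sheet carrying one or more identical *units*. Each
unit is a small network of recessed microwells joined by microchannels.
Droplets sit in the wells; channels gate what can move between neighbouring
wells: a wide channel lets the whole droplet squeeze through, a narrow one
lets only the magnetic-bead cluster pass, which is what makes bead
extraction (and hence washing) possible.

Coordinates are millimetres. Well centers are unit-local with the origin at
the unit's lower-left corner, y pointing up; a unit's ``origin`` places it on
the chip. Each unit also carries a *keypoint map*: the magnet controller only
ever stops at nine predefined x/y stations (keypoints 1-9) which coincide
with microwell centers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

from .errors import LayoutError

SCHEMA_VERSION = "1.0"

#: Exemplar channel widths (mm): wide passes droplets, narrow extracts beads.
WIDE_CHANNEL_MM = 1.3
NARROW_CHANNEL_MM = 0.6


@dataclass(frozen=True)
class Microwell:
    """A recessed well that pins a droplet to a chip location.

    ``observation_window`` marks wells whose cover region is left uncoated so
    the camera can see the droplet for optical readout.
    """

    id: int
    center: tuple[float, float]  # mm, unit-local
    diameter: float  # mm
    nominal_volume: float  # µL
    observation_window: bool = False


@dataclass(frozen=True)
class Microchannel:
    """A channel joining two wells of the same unit; ``wells`` is unordered."""

    wells: tuple[int, int]
    width: float  # mm
    depth: float = 0.3  # mm, metadata only

    def joins(self, a: int, b: int) -> bool:
        return set(self.wells) == {a, b}


@dataclass
class ChipUnit:
    """One self-contained reaction unit: wells, channels and the keypoint map."""

    index: int
    wells: list[Microwell]
    channels: list[Microchannel]
    keypoint_map: dict[int, int]  # keypoint (1-9) -> well id
    origin: tuple[float, float] = (0.0, 0.0)  # mm, on-chip placement
    size: tuple[float, float] = (30.0, 30.0)  # mm footprint

    def well(self, well_id: int) -> Microwell:
        for w in self.wells:
            if w.id == well_id:
                return w
        raise KeyError(f"unit {self.index} has no well {well_id}")

    def well_at_keypoint(self, keypoint: int) -> Microwell:
        return self.well(self.keypoint_map[keypoint])

    def keypoint_of_well(self, well_id: int) -> int:
        for kp, wid in self.keypoint_map.items():
            if wid == well_id:
                return kp
        raise KeyError(f"well {well_id} is not mapped to a keypoint")

    def channel_between(self, well_a: int, well_b: int) -> Microchannel | None:
        for ch in self.channels:
            if ch.joins(well_a, well_b):
                return ch
        return None

    def global_center(self, well_id: int) -> tuple[float, float]:
        w = self.well(well_id)
        return (self.origin[0] + w.center[0], self.origin[1] + w.center[1])


@dataclass
class ChipLayout:
    """A full chip: a set of units on a rectangular footprint."""

    units: list[ChipUnit]
    footprint: tuple[float, float] = (60.0, 60.0)  # mm
    schema_version: str = SCHEMA_VERSION

    def unit(self, index: int) -> ChipUnit:
        for u in self.units:
            if u.index == index:
                return u
        raise KeyError(f"layout has no unit {index}")


def builtin_elisa_layout(tmb_volume_ul: float = 50.0) -> ChipLayout:
    """The built-in 4-unit ELISA chip.

    Each unit has nine wells on a 3x3 serpentine path joined by eight
    channels. Wells 1-7 (diameter 6 mm) hold 30 µL, well 8 (7 mm) holds
    ``tmb_volume_ul`` of chromogen substrate (nominally 50 µL), well 9
    (4 mm) holds 10 µL of stop solution. All channels are narrow (0.6 mm,
    bead extraction) except the 8-9 channel which is wide (1.3 mm) so the
    small stop-solution droplet can be carried back through it; keypoint i
    maps to well i. Well 8 is the observation window used for readout.
    """
    # serpentine 3x3 grid, 9 mm pitch, so consecutive wells are channel-adjacent
    centers = {
        1: (6.0, 6.0), 2: (15.0, 6.0), 3: (24.0, 6.0),
        4: (24.0, 15.0), 5: (15.0, 15.0), 6: (6.0, 15.0),
        7: (6.0, 24.0), 8: (15.0, 24.0), 9: (24.0, 24.0),
    }
    diameters = {**{i: 6.0 for i in range(1, 8)}, 8: 7.0, 9: 4.0}
    volumes = {**{i: 30.0 for i in range(1, 8)}, 8: tmb_volume_ul, 9: 10.0}
    origins = {1: (0.0, 0.0), 2: (30.0, 0.0), 3: (0.0, 30.0), 4: (30.0, 30.0)}

    units = []
    for idx in range(1, 5):
        wells = [
            Microwell(
                id=i,
                center=centers[i],
                diameter=diameters[i],
                nominal_volume=volumes[i],
                observation_window=(i == 8),
            )
            for i in range(1, 10)
        ]
        channels = [
            Microchannel(
                wells=(i, i + 1),
                width=WIDE_CHANNEL_MM if {i, i + 1} == {8, 9} else NARROW_CHANNEL_MM,
            )
            for i in range(1, 9)
        ]
        units.append(
            ChipUnit(
                index=idx,
                wells=wells,
                channels=channels,
                keypoint_map={i: i for i in range(1, 10)},
                origin=origins[idx],
                size=(30.0, 30.0),
            )
        )
    return ChipLayout(units=units, footprint=(60.0, 60.0))


# ---------------------------------------------------------------------------
# validation

def _validate_unit(unit: ChipUnit) -> list[str]:
    v: list[str] = []
    ids = [w.id for w in unit.wells]
    if len(ids) != len(set(ids)):
        v.append(f"unit {unit.index}: duplicate well ids")
    for w in unit.wells:
        if w.diameter <= 0:
            v.append(f"unit {unit.index} well {w.id}: diameter must be > 0")
        if w.nominal_volume <= 0:
            v.append(f"unit {unit.index} well {w.id}: nominal_volume must be > 0")
    known = set(ids)
    for ch in unit.channels:
        a, b = ch.wells
        if a == b:
            v.append(f"unit {unit.index}: channel {ch.wells} is a self-loop")
        for wid in ch.wells:
            if wid not in known:
                v.append(f"unit {unit.index}: channel references unknown well {wid}")
        if ch.width <= 0:
            v.append(f"unit {unit.index}: channel {ch.wells} width must be > 0")
    # keypoint map must be a bijection onto the unit's wells
    kps = set(unit.keypoint_map)
    mapped = list(unit.keypoint_map.values())
    if not kps <= set(range(1, 10)):
        v.append(f"unit {unit.index}: keypoints outside 1-9: {sorted(kps - set(range(1, 10)))}")
    if len(mapped) != len(set(mapped)) or set(mapped) != known or len(kps) != len(known):
        v.append(f"unit {unit.index}: keypoint_map not a bijection onto wells")
    # channel graph connectivity (over wells that exist)
    if unit.wells and not _connected(known, unit.channels):
        v.append(f"unit {unit.index}: channel graph is not connected")
    return v


def _connected(wells: set[int], channels: list[Microchannel]) -> bool:
    if len(wells) <= 1:
        return True
    adj: dict[int, set[int]] = {w: set() for w in wells}
    for ch in channels:
        a, b = ch.wells
        if a in adj and b in adj and a != b:
            adj[a].add(b)
            adj[b].add(a)
    seen = set()
    stack = [next(iter(wells))]
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(adj[n] - seen)
    return seen == wells


def validate_layout(layout: ChipLayout) -> list[str]:
    """Check every structural invariant; violations are returned as strings.

    An empty list means the layout is valid. Violations name the offending
    element so a layout author can fix the file.
    """
    v: list[str] = []
    if not layout.units:
        v.append("layout has no units")
    idxs = [u.index for u in layout.units]
    if len(idxs) != len(set(idxs)):
        v.append("duplicate unit indices")
    for u in layout.units:
        v.extend(_validate_unit(u))
    # unit footprints pairwise disjoint (axis-aligned boxes)
    for i, a in enumerate(layout.units):
        for b in layout.units[i + 1:]:
            if _boxes_overlap(a, b):
                v.append(f"units {a.index} and {b.index} overlap")
    return v


def _boxes_overlap(a: ChipUnit, b: ChipUnit) -> bool:
    ax, ay = a.origin
    bx, by = b.origin
    aw, ah = a.size
    bw, bh = b.size
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah


# ---------------------------------------------------------------------------
# JSON serialization

def layout_to_dict(layout: ChipLayout) -> dict:
    return {
        "schema_version": layout.schema_version,
        "footprint_mm": list(layout.footprint),
        "units": [
            {
                "index": u.index,
                "origin_mm": list(u.origin),
                "size_mm": list(u.size),
                "wells": [
                    {
                        "id": w.id,
                        "center_mm": list(w.center),
                        "diameter_mm": w.diameter,
                        "volume_ul": w.nominal_volume,
                        "observation_window": w.observation_window,
                    }
                    for w in u.wells
                ],
                "channels": [
                    {"wells": list(c.wells), "width_mm": c.width, "depth_mm": c.depth}
                    for c in u.channels
                ],
                "keypoint_map": {str(k): v for k, v in u.keypoint_map.items()},
            }
            for u in layout.units
        ],
    }


def layout_from_dict(doc: dict) -> ChipLayout:
    try:
        version = doc["schema_version"]
        if version != SCHEMA_VERSION:
            raise LayoutError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})")
        units = []
        for ud in doc["units"]:
            wells = [
                Microwell(
                    id=int(wd["id"]),
                    center=(float(wd["center_mm"][0]), float(wd["center_mm"][1])),
                    diameter=float(wd["diameter_mm"]),
                    nominal_volume=float(wd["volume_ul"]),
                    observation_window=bool(wd.get("observation_window", False)),
                )
                for wd in ud["wells"]
            ]
            channels = [
                Microchannel(
                    wells=(int(cd["wells"][0]), int(cd["wells"][1])),
                    width=float(cd["width_mm"]),
                    depth=float(cd.get("depth_mm", 0.3)),
                )
                for cd in ud["channels"]
            ]
            units.append(
                ChipUnit(
                    index=int(ud["index"]),
                    wells=wells,
                    channels=channels,
                    keypoint_map={int(k): int(v) for k, v in ud["keypoint_map"].items()},
                    origin=tuple(float(x) for x in ud.get("origin_mm", (0.0, 0.0))),
                    size=tuple(float(x) for x in ud.get("size_mm", (30.0, 30.0))),
                )
            )
        fp = doc.get("footprint_mm", (60.0, 60.0))
        return ChipLayout(units=units, footprint=(float(fp[0]), float(fp[1])), schema_version=version)
    except LayoutError:
        raise
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        raise LayoutError(f"malformed layout document: {exc!r}") from exc


def write_layout(layout: ChipLayout, path) -> None:
    with open(path, "w") as fh:
        json.dump(layout_to_dict(layout), fh, indent=1)
        fh.write("\n")


def read_layout(path) -> ChipLayout:
    """Read a layout JSON file, raising :class:`LayoutError` on bad documents.

    The parsed layout is additionally run through :func:`validate_layout`;
    structural violations raise.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise LayoutError(f"cannot parse {path}: line {exc.lineno}: {exc.msg}") from exc
    layout = layout_from_dict(doc)
    violations = validate_layout(layout)
    if violations:
        raise LayoutError("invalid layout: " + "; ".join(violations))
    return layout
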