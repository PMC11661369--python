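"""Multi-material G-code post-processing for filament-mixing prints.

Implements the printing-side computations needed to turn single-material
sliced G-code plus a region/mixture manifest into a mixing-extruder print:
purge-tower planning and insertion, z-hop on tower transitions,
axis-restricted (rectilinear) travel rewriting, per-channel mixing commands
and filament accounting.

Supported dialect: absolute positioning (G90), millimeter units (G21),
absolute or relative extrusion (M82/M83).  Region identity comes from
``;region:<label>`` comment markers emitted by the design/synthesis tools.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

from phantomforge.errors import PlanningError, UnsupportedDialectError
from phantomforge.mixing import MixingRatio

__all__ = [
    "GcodeCommand",
    "GcodeProgram",
    "MixturePlan",
    "PurgeTowerSpec",
    "PostprocessConfig",
    "UsageReport",
    "parse_gcode",
    "emit_gcode",
    "plan_purge_towers",
    "active_towers",
    "insert_purge_sequences",
    "rectilinearize_travels",
    "inject_mixing_commands",
    "estimate_usage",
    "postprocess",
]

_WORD_RE = re.compile(r"([A-Za-z])\s*(-?\d+\.?\d*)")
_REGION_RE = re.compile(r";\s*region\s*:\s*(\S+)")


@dataclass
class GcodeCommand:
    """One G-code line: parsed words plus the raw text for faithful emission."""

    letter: str | None  # 'G', 'M', 'T' or None for comment/blank lines
    code: int | None
    params: dict[str, float] = field(default_factory=dict)
    comment: str | None = None
    raw: str | None = None  # original text; None for synthesized commands

    @property
    def region_marker(self) -> str | None:
        if self.comment is None:
            return None
        m = _REGION_RE.match(";" + self.comment)
        return m.group(1) if m else None

    def is_move(self) -> bool:
        return self.letter == "G" and self.code in (0, 1)

    def text(self) -> str:
        if self.raw is not None:
            return self.raw
        parts = []
        if self.letter is not None:
            parts.append(f"{self.letter}{self.code}")
        for k, v in self.params.items():
            if float(v).is_integer() and abs(v) < 1e15:
                parts.append(f"{k}{int(v)}")
            else:
                parts.append(f"{k}{v:.5f}".rstrip("0").rstrip("."))
        line = " ".join(parts)
        if self.comment is not None:
            line = f"{line} ;{self.comment}" if line else f";{self.comment}"
        return line


class WalkState(NamedTuple):
    """Machine state immediately before a command executes."""

    x: float
    y: float
    z: float
    e: float
    region: str | None
    layer: int
    relative_e: bool


@dataclass
class GcodeProgram:
    """Ordered command sequence with absolute coordinates in mm."""

    commands: list[GcodeCommand]
    layer_thickness: float = 0.2

    def copy(self) -> "GcodeProgram":
        return GcodeProgram(
            [replace(c, params=dict(c.params)) for c in self.commands],
            self.layer_thickness,
        )

    def walk(self):
        """Yield (command, WalkState-before) for every command."""
        x = y = z = e = 0.0
        region = None
        relative_e = False
        for cmd in self.commands:
            layer = int(round(z / self.layer_thickness)) if z > 0 else 0
            yield cmd, WalkState(x, y, z, e, region, layer, relative_e)
            marker = cmd.region_marker
            if marker is not None:
                region = marker
            if cmd.is_move():
                x = cmd.params.get("X", x)
                y = cmd.params.get("Y", y)
                z = cmd.params.get("Z", z)
                if "E" in cmd.params:
                    e = e + cmd.params["E"] if relative_e else cmd.params["E"]
            elif cmd.letter == "G" and cmd.code == 92:
                e = cmd.params.get("E", e)
            elif cmd.letter == "M" and cmd.code == 83:
                relative_e = True
            elif cmd.letter == "M" and cmd.code == 82:
                relative_e = False
        return

    @staticmethod
    def extrusion_delta(cmd: GcodeCommand, state: WalkState) -> float:
        if not (cmd.is_move() and "E" in cmd.params):
            return 0.0
        d = cmd.params["E"] if state.relative_e else cmd.params["E"] - state.e
        return max(d, 0.0)

    def total_extrusion(self) -> float:
        total = 0.0
        for cmd, state in self.walk():
            total += self.extrusion_delta(cmd, state)
        return total

    def layer_count(self) -> int:
        z_max = 0.0
        for cmd in self.commands:
            if cmd.is_move() and "Z" in cmd.params:
                z_max = max(z_max, cmd.params["Z"])
        return int(round(z_max / self.layer_thickness))

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over all extruding moves."""
        xs, ys = [], []
        for cmd, state in self.walk():
            if self.extrusion_delta(cmd, state) > 0:
                xs.extend([state.x, cmd.params.get("X", state.x)])
                ys.extend([state.y, cmd.params.get("Y", state.y)])
        if not xs:
            raise ValueError("program has no extruding moves")
        return (min(xs), min(ys), max(xs), max(ys))


@dataclass
class MixturePlan:
    """Region label -> mixing ratio, plus per-layer region presence."""

    mixtures: dict[str, MixingRatio]
    layers: dict[int, set[str]] = field(default_factory=dict)

    def unique_ratios(self) -> list[tuple[float, float, float]]:
        seen: list[tuple[float, float, float]] = []
        for r in self.mixtures.values():
            t = r.as_tuple()
            if t not in seen:
                seen.append(t)
        return seen

    def last_heterogeneous_layer(self) -> int | None:
        """Highest layer on which more than one distinct mixture prints."""
        last = None
        for layer, labels in self.layers.items():
            ratios = {self.mixtures[lb].as_tuple() for lb in labels if lb in self.mixtures}
            if len(ratios) > 1 and (last is None or layer > last):
                last = layer
        return last

    def to_json_dict(self) -> dict:
        return {
            "mixtures": {
                k: {"Rg": r.rg, "Rw": r.rw, "Rt": r.rt}
                for k, r in self.mixtures.items()
            },
            "layers": {str(k): sorted(v) for k, v in self.layers.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MixturePlan":
        return cls(
            mixtures={
                k: MixingRatio(v["Rg"], v["Rw"], v["Rt"])
                for k, v in d["mixtures"].items()
            },
            layers={int(k): set(v) for k, v in d.get("layers", {}).items()},
        )


@dataclass(frozen=True)
class PurgeTowerSpec:
    """One purge tower: footprint rectangle, anchor and active layer range."""

    anchor: tuple[float, float]  # min-corner, mm
    size: tuple[float, float]  # (x, y) extent, mm
    mixture: tuple[float, float, float]  # the (Rg, Rw, Rt) it purges into
    first_layer: int
    last_layer: int

    def active_on(self, layer: int) -> bool:
        return self.first_layer <= layer <= self.last_layer


@dataclass
class PostprocessConfig:
    """Print/post-processing parameters (defaults follow the printed setup)."""

    z_hop: float = 0.3
    rectilinear_travel: bool = True
    purge_volume_per_transition: float | None = None  # mm^3; None -> tower layer
    layer_thickness: float = 0.2
    line_width: float = 0.3
    max_speed: float = 22.0  # mm/s
    infill_ratio: float = 110.0  # percent
    extruder_temp: float = 205.0
    filament_diameter: float = 1.75
    filament_density: float = 1.24  # g/cm^3, PLA
    tower_size: tuple[float, float] = (15.0, 15.0)
    tower_gap: float = 10.0  # model bbox -> first tower
    inter_tower_gap: float = 5.0
    build_area: tuple[float, float] = (300.0, 300.0)

    def __post_init__(self) -> None:
        for name in (
            "z_hop",
            "layer_thickness",
            "line_width",
            "max_speed",
            "infill_ratio",
            "extruder_temp",
            "filament_diameter",
            "filament_density",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        w, h = self.tower_size
        if not (15.0 <= w <= 15.0 + 1e-9 and 15.0 <= h <= 35.0):
            # the characterized tower range is 15x15 to 15x35 mm
            if w <= 0 or h <= 0:
                raise ValueError("tower size must be positive")

    @property
    def filament_area(self) -> float:
        return math.pi * (self.filament_diameter / 2.0) ** 2

    @property
    def default_purge_volume(self) -> float:
        """One full tower layer of extrusion, mm^3."""
        w, h = self.tower_size
        return w * h * self.layer_thickness * self.infill_ratio / 100.0

    @property
    def purge_volume(self) -> float:
        if self.purge_volume_per_transition is not None:
            return self.purge_volume_per_transition
        return self.default_purge_volume


@dataclass
class UsageReport:
    """Per-channel filament consumption."""

    length_mm: dict[str, float]
    mass_g: dict[str, float]

    @property
    def total_length_mm(self) -> float:
        return sum(self.length_mm.values())

    @property
    def total_mass_g(self) -> float:
        return sum(self.mass_g.values())


# ---------------------------------------------------------------------------
# parsing / emission


def parse_gcode(text: str, layer_thickness: float = 0.2) -> GcodeProgram:
    """Parse absolute-positioning, millimeter-unit G-code.

    Unknown commands are preserved verbatim.  A switch to relative
    positioning (G91) or inch units (G20) raises
    :class:`UnsupportedDialectError` naming the offending line.
    """
    commands: list[GcodeCommand] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        comment = None
        body = stripped
        if ";" in stripped:
            body, comment = stripped.split(";", 1)
            body = body.strip()
        if not body:
            commands.append(
                GcodeCommand(None, None, comment=comment, raw=line)
            )
            continue
        words = _WORD_RE.findall(body)
        if not words:
            commands.append(GcodeCommand(None, None, comment=comment, raw=line))
            continue
        letter = words[0][0].upper()
        code = int(float(words[0][1]))
        params = {w[0].upper(): float(w[1]) for w in words[1:]}
        if letter == "G" and code == 91:
            raise UnsupportedDialectError(
                f"line {ln}: relative positioning (G91) is not supported: {stripped!r}"
            )
        if letter == "G" and code == 20:
            raise UnsupportedDialectError(
                f"line {ln}: inch units (G20) are not supported: {stripped!r}"
            )
        commands.append(GcodeCommand(letter, code, params, comment, raw=line))
    return GcodeProgram(commands, layer_thickness)


def emit_gcode(program: GcodeProgram) -> str:
    return "\n".join(c.text() for c in program.commands) + "\n"


# ---------------------------------------------------------------------------
# purge towers


def plan_purge_towers(
    plan: MixturePlan,
    model_bbox: tuple[float, float, float, float],
    config: PostprocessConfig | None = None,
) -> list[PurgeTowerSpec]:
    """One tower per unique mixture of a contiguous model.

    Towers sit in a row on the +x side of the model bounding box.  They are
    active from the first layer through the last heterogeneous layer; a
    single-mixture model needs no towers at all.
    """
    config = config or PostprocessConfig()
    if not plan.mixtures:
        raise ValueError("mixture plan has no regions")
    ratios = plan.unique_ratios()
    if len(ratios) < 2:
        return []
    last_hetero = plan.last_heterogeneous_layer()
    if last_hetero is None:
        last_hetero = max(plan.layers) if plan.layers else 1
    xmin, ymin, xmax, ymax = model_bbox
    w, h = config.tower_size
    towers = []
    x0 = xmax + config.tower_gap
    y = ymin
    for ratio in ratios:
        towers.append(
            PurgeTowerSpec(
                anchor=(x0, y),
                size=(w, h),
                mixture=ratio,
                first_layer=1,
                last_layer=last_hetero,
            )
        )
        y += h + config.inter_tower_gap
    bx, by = config.build_area
    if x0 + w > bx or y - config.inter_tower_gap > by:
        need = (x0 + w, y - config.inter_tower_gap)
        raise PlanningError(
            f"purge towers do not fit the build area {config.build_area}; "
            f"required extent {need}"
        )
    return towers


def active_towers(towers: Iterable[PurgeTowerSpec], layer: int) -> list[PurgeTowerSpec]:
    return [t for t in towers if t.active_on(layer)]


def _mixture_commands(ratio: tuple[float, float, float]) -> list[GcodeCommand]:
    """Per-channel weight commands for a mixing hotend (M163/M164 dialect)."""
    cmds = [
        GcodeCommand("M", 163, {"S": float(ch), "P": round(frac, 4)})
        for ch, frac in enumerate(f / 100.0 for f in ratio)
    ]
    cmds.append(GcodeCommand("M", 164, {"S": 0.0}))
    return cmds


def _travel(x: float, y: float, rectilinear: bool) -> list[GcodeCommand]:
    if rectilinear:
        return [
            GcodeCommand("G", 0, {"X": x}),
            GcodeCommand("G", 0, {"Y": y}),
        ]
    return [GcodeCommand("G", 0, {"X": x, "Y": y})]


def _purge_block(
    tower: PurgeTowerSpec, layer_z: float, config: PostprocessConfig
) -> list[GcodeCommand]:
    """Serpentine tower infill extruding the configured purge volume."""
    w, h = tower.size
    x0, y0 = tower.anchor
    n_lines = max(int(math.ceil(h / config.line_width)), 1)
    total_filament = config.purge_volume / config.filament_area
    e_per_line = total_filament / n_lines
    cmds: list[GcodeCommand] = [
        GcodeCommand(None, None, comment=f"purge-infill:{tower.mixture}")
    ]
    for i in range(n_lines):
        yy = min(y0 + i * config.line_width, y0 + h)
        if i > 0:
            cmds.append(GcodeCommand("G", 1, {"Y": round(yy, 5)}))
        x_target = x0 + w if i % 2 == 0 else x0
        cmds.append(GcodeCommand("G", 1, {"X": round(x_target, 5), "E": e_per_line}))
    return cmds


def insert_purge_sequences(
    program: GcodeProgram,
    towers: list[PurgeTowerSpec],
    plan: MixturePlan,
    config: PostprocessConfig | None = None,
) -> GcodeProgram:
    """Insert a tower purge at every mixture transition.

    Each sequence: z-hop up, travel to the incoming mixture's tower, set the
    new mixture, purge one configured volume as tower infill, z-hop back to
    the interrupted position, restore the layer Z.  Emitted purge extrusions
    use relative E bookkeeping via G92 resets so the model's own absolute E
    values remain untouched.
    """
    config = config or PostprocessConfig()
    by_mixture = {t.mixture: t for t in towers}
    out: list[GcodeCommand] = []
    current_mix: tuple[float, float, float] | None = None
    pending_region: str | None = None

    for cmd, state in program.walk():
        x, y, z = state.x, state.y, state.z
        marker = cmd.region_marker
        if marker is not None:
            if marker not in plan.mixtures:
                raise PlanningError(f"program references unknown region {marker!r}")
            pending_region = marker
        is_extruding = program.extrusion_delta(cmd, state) > 0
        if is_extruding and pending_region is not None:
            mix = plan.mixtures[pending_region].as_tuple()
            if current_mix is not None and mix != current_mix:
                layer = max(int(round(z / program.layer_thickness)), 1)
                tower = by_mixture.get(mix)
                if tower is None or not tower.active_on(layer):
                    raise PlanningError(
                        f"mixture transition to {mix} on layer {layer} has no "
                        "active purge tower"
                    )
                layer_z = z
                hop_z = round(layer_z + config.z_hop, 6)
                seq: list[GcodeCommand] = [
                    GcodeCommand(None, None, comment=f"purge-begin layer={layer}"),
                    GcodeCommand("G", 1, {"Z": hop_z}),
                ]
                seq += _travel(*tower.anchor, config.rectilinear_travel)
                seq.append(GcodeCommand("G", 1, {"Z": round(layer_z, 6)}))
                seq += _mixture_commands(mix)
                seq.append(GcodeCommand("M", 83, {}))  # relative E for the purge
                seq += _purge_block(tower, layer_z, config)
                if not state.relative_e:
                    seq.append(GcodeCommand("M", 82, {}))
                    seq.append(GcodeCommand("G", 92, {"E": round(state.e, 6)}))
                seq.append(GcodeCommand("G", 1, {"Z": hop_z}))
                seq += _travel(x, y, config.rectilinear_travel)
                seq.append(GcodeCommand("G", 1, {"Z": round(layer_z, 6)}))
                seq.append(GcodeCommand(None, None, comment="purge-end"))
                out.extend(seq)
            if mix != current_mix:
                current_mix = mix
        out.append(cmd)
    return GcodeProgram(out, program.layer_thickness)


def rectilinearize_travels(program: GcodeProgram) -> GcodeProgram:
    """Split diagonal travel (non-extruding) moves into x-then-y segments."""
    out: list[GcodeCommand] = []
    for cmd, state in program.walk():
        if (
            cmd.is_move()
            and program.extrusion_delta(cmd, state) <= 0
            and "X" in cmd.params
            and "Y" in cmd.params
            and not math.isclose(cmd.params["X"], state.x, abs_tol=1e-9)
            and not math.isclose(cmd.params["Y"], state.y, abs_tol=1e-9)
        ):
            first = dict(cmd.params)
            ty = first.pop("Y")
            out.append(GcodeCommand(cmd.letter, cmd.code, first, cmd.comment))
            out.append(GcodeCommand(cmd.letter, cmd.code, {"Y": ty}))
        else:
            out.append(cmd)
    return GcodeProgram(out, program.layer_thickness)


def inject_mixing_commands(
    program: GcodeProgram, plan: MixturePlan
) -> GcodeProgram:
    """Emit per-channel weight commands before each region's first extrusion."""
    out: list[GcodeCommand] = []
    current: tuple[float, float, float] | None = None
    pending: str | None = None
    for cmd, state in program.walk():
        marker = cmd.region_marker
        if marker is not None:
            if marker not in plan.mixtures:
                raise PlanningError(
                    f"region {marker!r} has no mixture in the plan"
                )
            pending = marker
        if pending is not None and program.extrusion_delta(cmd, state) > 0:
            mix = plan.mixtures[pending].as_tuple()
            if mix != current:
                out.extend(_mixture_commands(mix))
                current = mix
        out.append(cmd)
    return GcodeProgram(out, program.layer_thickness)


def estimate_usage(
    program: GcodeProgram,
    plan: MixturePlan,
    config: PostprocessConfig | None = None,
) -> UsageReport:
    """Per-channel filament length and mass implied by the program."""
    config = config or PostprocessConfig()
    channels = ("gray", "white", "translucent")
    length = dict.fromkeys(channels, 0.0)
    weights = (1.0, 0.0, 0.0)  # default before any region marker
    for cmd, state in program.walk():
        d = program.extrusion_delta(cmd, state)
        if d <= 0:
            continue
        if state.region is not None and state.region in plan.mixtures:
            weights = plan.mixtures[state.region].channel_weights()
        for ch, wt in zip(channels, weights):
            length[ch] += d * wt
    # mm of 1.75 mm filament -> g
    mm3_per_mm = config.filament_area
    mass = {
        ch: length[ch] * mm3_per_mm / 1000.0 * config.filament_density
        for ch in channels
    }
    return UsageReport(length_mm=length, mass_g=mass)


def postprocess(
    program: GcodeProgram,
    plan: MixturePlan,
    config: PostprocessConfig | None = None,
) -> tuple[GcodeProgram, list[PurgeTowerSpec]]:
    """Full pipeline: mixing commands, travel rewriting, purge insertion."""
    config = config or PostprocessConfig()
    bbox = program.bounding_box()
    towers = plan_purge_towers(plan, bbox, config)
    result = inject_mixing_commands(program, plan)
    if config.rectilinear_travel:
        result = rectilinearize_travels(result)
    if towers:
        result = insert_purge_sequences(result, towers, plan, config)
    return result, towers
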