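"""Parametric phantom geometry generators.

Each generator returns a :class:`PhantomDesign`: a labeled set of prism
regions (optionally over a background slab), each carrying either a target
optical-property pair to be resolved through the mixing model or an
explicit mixing ratio.  Designs can be resolved into a
:class:`~phantomforge.gcode.MixturePlan` and exported as watertight STL
meshes plus a JSON manifest.

Printed dimensions (slab sizes, inclusion diameters, thicknesses, depths)
are hard-coded to their published values; layout coordinates that are only
shown in figures live in the ``*_LAYOUT`` dictionaries and can be edited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from phantomforge.errors import InfeasibleDesignError, MeshingError
from phantomforge.gcode import MixturePlan
from phantomforge.meshing import (
    circle_ring,
    is_watertight,
    mesh_volume,
    prism_mesh,
    rect_ring,
    write_stl,
)
from phantomforge.mixing import (
    LinearMixingModel,
    MixingRatio,
    OpticalProperties,
    feasible_range,
    invert,
)

__all__ = [
    "RegionShape",
    "BoxShape",
    "CylinderShape",
    "Region",
    "PhantomDesign",
    "design_titration_ruler",
    "design_benchmarks",
    "design_qa_phantom",
    "design_dot_phantom",
    "design_three_mixture_standin",
    "resolve_mixtures",
    "export_meshes",
    "QA_BACKGROUND",
    "QA_LAYOUT",
    "DOT_LAYOUT",
]

_CIRCLE_SEGMENTS = 64


@dataclass(frozen=True)
class RegionShape:
    """Vertical prism between two heights; subclasses define the footprint."""

    z0: float
    z1: float

    def ring(self) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def hole_rings(self) -> list[np.ndarray]:
        return []

    def footprint(self) -> Polygon:
        return Polygon(self.ring(), [h[::-1] for h in self.hole_rings()])

    def volume(self) -> float:
        return self.footprint().area * (self.z1 - self.z0)

    def mesh(self) -> np.ndarray:
        return prism_mesh(self.ring(), [self.z0, self.z1], [self.hole_rings()])


@dataclass(frozen=True)
class BoxShape(RegionShape):
    origin: tuple[float, float] = (0.0, 0.0)
    size: tuple[float, float] = (1.0, 1.0)
    #: optional rectangular cutout (used by frame-shaped benchmark regions)
    hole_origin: tuple[float, float] | None = None
    hole_size: tuple[float, float] | None = None

    def ring(self) -> np.ndarray:
        return rect_ring(self.origin, self.size)

    def hole_rings(self) -> list[np.ndarray]:
        if self.hole_origin is None:
            return []
        return [rect_ring(self.hole_origin, self.hole_size)]


@dataclass(frozen=True)
class CylinderShape(RegionShape):
    center: tuple[float, float] = (0.0, 0.0)
    diameter: float = 1.0

    def ring(self) -> np.ndarray:
        return circle_ring(self.center, self.diameter, _CIRCLE_SEGMENTS)


@dataclass(frozen=True)
class Region:
    label: str
    shape: RegionShape
    target: OpticalProperties | None = None
    ratio: MixingRatio | None = None

    def __post_init__(self) -> None:
        if self.target is None and self.ratio is None:
            raise ValueError(f"region {self.label!r} needs a target or a ratio")


@dataclass
class PhantomDesign:
    """Background slab plus labeled inclusion regions, dimensions in mm."""

    name: str
    outer_size: tuple[float, float, float]
    regions: list[Region]
    background: Region | None = None
    layer_thickness: float = 0.2
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if self.background is not None:
            labels.append(self.background.label)
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        sx, sy, sz = self.outer_size
        outer = Polygon(rect_ring((0, 0), (sx, sy)))
        for r in self.regions:
            if r.shape.z0 < -1e-9 or r.shape.z1 > sz + 1e-9:
                raise ValueError(f"region {r.label!r} exceeds slab thickness")
            if not outer.buffer(1e-9).contains(r.shape.footprint()):
                raise ValueError(f"region {r.label!r} extends outside the slab")
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1 :]:
                if a.shape.z1 <= b.shape.z0 + 1e-9 or b.shape.z1 <= a.shape.z0 + 1e-9:
                    continue  # disjoint in z
                if a.shape.footprint().intersection(b.shape.footprint()).area > 1e-9:
                    raise ValueError(
                        f"regions {a.label!r} and {b.label!r} overlap"
                    )

    def all_regions(self) -> list[Region]:
        out = list(self.regions)
        if self.background is not None:
            out.append(self.background)
        return out

    def slab_volume(self) -> float:
        sx, sy, sz = self.outer_size
        return sx * sy * sz

    def unique_targets(self) -> list[tuple[float, float]]:
        seen: list[tuple[float, float]] = []
        for r in self.all_regions():
            if r.target is not None:
                t = (r.target.mua, r.target.musp)
            else:
                t = ("ratio", r.ratio.as_tuple())  # type: ignore[assignment]
            if t not in seen:
                seen.append(t)
        return seen

    def layer_presence(self) -> dict[int, set[str]]:
        """Region labels present on each printed layer (1-based)."""
        _, _, sz = self.outer_size
        n_layers = int(round(sz / self.layer_thickness))
        presence: dict[int, set[str]] = {}
        for layer in range(1, n_layers + 1):
            z_lo = (layer - 1) * self.layer_thickness
            z_hi = layer * self.layer_thickness
            labels = set()
            if self.background is not None:
                labels.add(self.background.label)
            for r in self.regions:
                if r.shape.z0 < z_hi - 1e-9 and r.shape.z1 > z_lo + 1e-9:
                    labels.add(r.label)
            presence[layer] = labels
        return presence


# ---------------------------------------------------------------------------
# generators


def design_titration_ruler(
    segment_ratios: list[MixingRatio], name: str = "ruler"
) -> PhantomDesign:
    """Four 1.5 x 2 x 1.5 cm segments stacked into a 1.5 x 2 x 6 cm ruler."""
    if len(segment_ratios) != 4:
        raise ValueError(f"a ruler has exactly 4 segments, got {len(segment_ratios)}")
    regions = [
        Region(
            label=f"{name}-{chr(ord('A') + i)}",
            shape=BoxShape(z0=15.0 * i, z1=15.0 * (i + 1), origin=(0, 0), size=(15, 20)),
            ratio=ratio,
        )
        for i, ratio in enumerate(segment_ratios)
    ]
    return PhantomDesign(name=name, outer_size=(15, 20, 60), regions=regions)


def design_benchmarks() -> list[PhantomDesign]:
    """The three filament-mixing benchmark prints.

    #1: three 1.5 x 1.5 x 0.5 cm solid segments in a row, pure-gray to
    pure-white.  #2: two adjacent 3 x 3 x 0.5 cm square frames with
    concentric 1.5 cm square inclusions, materials swapped between frames.
    #3: a 3 x 3 palette of 1.5 cm tiles, each a unique mixture.
    """
    gray = MixingRatio(100, 0, 0)
    half = MixingRatio(50, 50, 0)
    white = MixingRatio(0, 100, 0)

    b1 = PhantomDesign(
        name="benchmark1",
        outer_size=(45, 15, 5),
        regions=[
            Region(
                f"segment{i + 1}",
                BoxShape(z0=0, z1=5, origin=(15.0 * i, 0), size=(15, 15)),
                ratio=r,
            )
            for i, r in enumerate((gray, half, white))
        ],
    )

    def frame(i: int, outer_ratio: MixingRatio, inner_ratio: MixingRatio):
        x0 = 30.0 * i
        return [
            Region(
                f"frame{i + 1}",
                BoxShape(
                    z0=0,
                    z1=5,
                    origin=(x0, 0),
                    size=(30, 30),
                    hole_origin=(x0 + 7.5, 7.5),
                    hole_size=(15, 15),
                ),
                ratio=outer_ratio,
            ),
            Region(
                f"inclusion{i + 1}",
                BoxShape(z0=0, z1=5, origin=(x0 + 7.5, 7.5), size=(15, 15)),
                ratio=inner_ratio,
            ),
        ]

    b2 = PhantomDesign(
        name="benchmark2",
        outer_size=(60, 30, 5),
        regions=frame(0, gray, white) + frame(1, white, gray),
    )

    # 9 unique mixtures spanning the simplex corners and interior
    palette = [
        MixingRatio.from_gray_white(rg, rw)
        for rg, rw in [
            (100, 0), (50, 50), (0, 100),
            (50, 0), (25, 50), (0, 50),
            (25, 0), (0, 25), (0, 0),
        ]
    ]
    b3 = PhantomDesign(
        name="benchmark3",
        outer_size=(45, 45, 5),
        regions=[
            Region(
                f"tile{r * 3 + c + 1}",
                BoxShape(z0=0, z1=5, origin=(15.0 * c, 15.0 * r), size=(15, 15)),
                ratio=palette[r * 3 + c],
            )
            for r in range(3)
            for c in range(3)
        ],
    )
    return [b1, b2, b3]


#: skull/scalp-mimicking background at 630 nm
QA_BACKGROUND = OpticalProperties(mua=0.019, musp=0.83)

#: figure-matching inclusion placement for the 9 x 9 x 0.5 cm QA slab (mm)
QA_LAYOUT = {
    "C1": {"center": (25.0, 70.0), "diameter": 15.0},
    "C2": {"center": (45.0, 70.0), "diameter": 10.0},
    "C3": {"center": (65.0, 70.0), "diameter": 5.0},
    "C4": {"center": (75.0, 15.0), "diameter": 5.0},
    "B1": {"origin": (10.0, 15.0), "size": (5.0, 20.0)},
    "B2": {"origin": (25.0, 15.0), "size": (5.0, 20.0)},
    "B3": {"origin": (45.0, 15.0), "size": (5.0, 20.0)},
    "B4": {"origin": (60.0, 15.0), "size": (5.0, 20.0)},
}


def design_qa_phantom(
    background: OpticalProperties = QA_BACKGROUND,
    layout: dict | None = None,
) -> PhantomDesign:
    """Quality-assurance slab: 9 x 9 x 0.5 cm with 8 thin inclusions.

    Disks C1-C3 (diameters 1.5 / 1.0 / 0.5 cm) share 15x background
    absorption and 3x background scattering; C4 (0.5 cm) is 25x / 3x.  Two
    bar pairs (0.5 x 2 cm) carry 2x scattering with 6x and 12x absorption.
    All inclusions are 1 mm thick at the bottom face.
    """
    layout = layout or QA_LAYOUT
    mua0, musp0 = background.mua, background.musp

    def props(fa: float, fs: float) -> OpticalProperties:
        return OpticalProperties(mua=fa * mua0, musp=fs * musp0)

    contrasts = {
        "C1": (15, 3), "C2": (15, 3), "C3": (15, 3), "C4": (25, 3),
        "B1": (6, 2), "B2": (6, 2), "B3": (12, 2), "B4": (12, 2),
    }
    regions = []
    for label, (fa, fs) in contrasts.items():
        geo = layout[label]
        if "diameter" in geo:
            shape = CylinderShape(
                z0=0.0, z1=1.0, center=geo["center"], diameter=geo["diameter"]
            )
        else:
            shape = BoxShape(z0=0.0, z1=1.0, origin=geo["origin"], size=geo["size"])
        regions.append(Region(label, shape, target=props(fa, fs)))
    return PhantomDesign(
        name="qa-phantom",
        outer_size=(90, 90, 5),
        regions=regions,
        background=Region(
            "background", BoxShape(z0=0, z1=5, origin=(0, 0), size=(90, 90)),
            target=background,
        ),
        notes={"contrast_multipliers": contrasts},
    )


#: layout for the 10 x 5 x 1.5 cm tomography slab: 4 cylinders + 12 bars (mm)
DOT_LAYOUT = {
    "C1": {"center": (16.0, 32.0), "diameter": 20.0, "z1": 13.0},
    "C2": {"center": (42.0, 32.0), "diameter": 15.0, "z1": 14.0},
    "C3": {"center": (62.0, 32.0), "diameter": 7.5, "z1": 15.0},
    "C4": {"center": (76.0, 32.0), "diameter": 5.0, "z1": 15.0},
    **{
        f"B{i + 1}": {"origin": (6.0 + 12.0 * i, 6.0), "size": (4.0, 8.0)}
        for i in range(8)
    },
    "B9": {"origin": (84.0, 20.0), "size": (4.0, 8.0)},
    "B10": {"origin": (92.0, 20.0), "size": (4.0, 8.0)},
    "B11": {"origin": (84.0, 32.0), "size": (4.0, 8.0)},
    "B12": {"origin": (92.0, 32.0), "size": (4.0, 8.0)},
}

#: eight target property sets (mua, musp in mm^-1), two inclusions each;
#: chosen on the achievable surface of the published mixing coefficients
DOT_PROPERTY_SETS = [
    (0.0541, 0.87), (0.1026, 1.39), (0.1511, 1.91), (0.1996, 2.43),
    (0.2586, 2.11), (0.3271, 2.13), (0.41935, 3.0), (0.4736, 2.51),
]


def design_dot_phantom(layout: dict | None = None) -> PhantomDesign:
    """Tomography stress-test slab: 10 x 5 x 1.5 cm, 16 inclusions.

    Eight unique target property sets, two inclusions per set.  All
    inclusions span the full 15 mm thickness except the largest cylinder
    (extends 13 mm, ending 2 mm below the surface) and the second largest
    (14 mm, ending 1 mm below).
    """
    layout = layout or DOT_LAYOUT
    background = OpticalProperties(mua=0.019, musp=0.83)
    order = ["C1", "C2", "C3", "C4"] + [f"B{i + 1}" for i in range(12)]
    regions = []
    for k, label in enumerate(order):
        geo = layout[label]
        target = OpticalProperties(*DOT_PROPERTY_SETS[k % 8])
        if "diameter" in geo:
            shape = CylinderShape(
                z0=0.0,
                z1=geo.get("z1", 15.0),
                center=geo["center"],
                diameter=geo["diameter"],
            )
        else:
            shape = BoxShape(z0=0.0, z1=15.0, origin=geo["origin"], size=geo["size"])
        regions.append(Region(label, shape, target=target))
    return PhantomDesign(
        name="dot-phantom",
        outer_size=(100, 50, 15),
        regions=regions,
        background=Region(
            "background", BoxShape(z0=0, z1=15, origin=(0, 0), size=(100, 50)),
            target=background,
        ),
    )


def design_three_mixture_standin() -> PhantomDesign:
    """Stand-in for a three-tissue anatomical print (purge-planning tests).

    A soft-tissue slab with a lung-like inclusion over the lower z range and
    a brain-like inclusion higher up, so lower slices intersect only two of
    the three mixtures while all three appear in one contiguous model.
    Mixtures are set explicitly (soft 0/5/95, lung 4/11/85, brain 26/40/34).
    """
    return PhantomDesign(
        name="three-mixture-standin",
        outer_size=(30, 20, 40),
        regions=[
            Region(
                "lung",
                BoxShape(z0=5.0, z1=20.0, origin=(8, 6), size=(14, 8)),
                ratio=MixingRatio(4, 11, 85),
            ),
            Region(
                "brain",
                CylinderShape(z0=25.0, z1=35.0, center=(15, 10), diameter=10.0),
                ratio=MixingRatio(26, 40, 34),
            ),
        ],
        background=Region(
            "soft-tissue",
            BoxShape(z0=0, z1=40, origin=(0, 0), size=(30, 20)),
            ratio=MixingRatio(0, 5, 95),
        ),
    )


# ---------------------------------------------------------------------------
# resolution and export


def resolve_mixtures(
    design: PhantomDesign,
    model: LinearMixingModel,
    feasibility_threshold: float = 0.05,
) -> MixturePlan:
    """Map every region's target to an integer mixing ratio via the model.

    Identical targets resolve to identical ratios.  Regions whose targets
    fall outside the model's achievable range are collected into an
    :class:`InfeasibleDesignError`.
    """
    cache: dict[tuple[float, float], MixingRatio] = {}
    infeasible: list[str] = []
    mixtures: dict[str, MixingRatio] = {}
    ranges = feasible_range(model)
    for region in design.all_regions():
        if region.ratio is not None:
            mixtures[region.label] = region.ratio
            continue
        key = (region.target.mua, region.target.musp)
        if key not in cache:
            result = invert(
                model,
                region.target,
                rounding="integer",
                feasibility_threshold=feasibility_threshold,
            )
            out_of_range = not (
                ranges["mua"][0] - 1e-12 <= key[0] <= ranges["mua"][1] + 1e-12
                and ranges["musp"][0] - 1e-12 <= key[1] <= ranges["musp"][1] + 1e-12
            )
            cache[key] = result.ratio if (result.feasible and not out_of_range) else None
        if cache[key] is None:
            infeasible.append(region.label)
        else:
            mixtures[region.label] = cache[key]
    if infeasible:
        raise InfeasibleDesignError(
            f"regions not achievable by the mixing model: {infeasible}",
            regions=infeasible,
        )
    return MixturePlan(mixtures=mixtures, layers=design.layer_presence())


def background_mesh(design: PhantomDesign) -> np.ndarray:
    """Mesh of the background slab with all inclusion volumes subtracted."""
    if design.background is None:
        raise ValueError(f"design {design.name!r} has no background region")
    sx, sy, sz = design.outer_size
    breaks = sorted({0.0, sz} | {r.shape.z0 for r in design.regions} | {r.shape.z1 for r in design.regions})
    holes_per_interval = []
    for z0, z1 in zip(breaks[:-1], breaks[1:]):
        holes = []
        for r in design.regions:
            if r.shape.z0 < z1 - 1e-9 and r.shape.z1 > z0 + 1e-9:
                holes.append(r.shape.ring())
                holes.extend(r.shape.hole_rings())
        holes_per_interval.append(holes)
    return prism_mesh(rect_ring((0, 0), (sx, sy)), breaks, holes_per_interval)


def export_meshes(
    design: PhantomDesign,
    outdir,
    plan: MixturePlan | None = None,
    binary: bool = True,
) -> dict:
    """Write per-region STL meshes plus a JSON manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []

    def _export(label: str, mesh: np.ndarray, region: Region | None):
        if not is_watertight(mesh):
            raise MeshingError(f"mesh for region {label!r} is not watertight")
        fname = f"{design.name}_{label}.stl"
        write_stl(outdir / fname, mesh, name=f"{design.name}:{label}", binary=binary)
        entry = {
            "label": label,
            "mesh": fname,
            "volume_mm3": round(mesh_volume(mesh), 6),
        }
        if region is not None:
            if region.target is not None:
                entry["target"] = {
                    "mua": region.target.mua,
                    "musp": region.target.musp,
                }
            if region.ratio is not None:
                entry["ratio"] = region.ratio.as_tuple()
        if plan is not None and label in plan.mixtures:
            entry["mixture"] = plan.mixtures[label].as_tuple()
        entries.append(entry)

    for region in design.regions:
        _export(region.label, region.shape.mesh(), region)
    if design.background is not None:
        _export(design.background.label, background_mesh(design), design.background)

    manifest = {
        "design": design.name,
        "outer_size_mm": list(design.outer_size),
        "units": "mm",
        "regions": entries,
    }
    with open(outdir / f"{design.name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
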