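"""Seeded generators for every test input the package needs.

Synthetic titration tables (forward-model values plus configurable noise),
synthetic SFDI frame sets with known per-region ground truth, and toy
multi-region G-code programs with exact transition counts and extrusion
totals.  Everything is deterministic given a seed and carries its ground
truth alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from phantomforge.mixing import (
    LinearMixingModel,
    MixingRatio,
    OpticalProperties,
    TitrationRecord,
    predict,
)
from phantomforge.sfdi import (
    DEFAULT_PIXEL_PITCH,
    PHASE_OFFSETS,
    CalibrationReference,
    FrameSet,
)
from phantomforge.wmc import ReflectanceLUT, diffusion_rd

__all__ = [
    "SynthConfig",
    "PUBLISHED_MUA_COEFFS",
    "PUBLISHED_MUSP_COEFFS",
    "published_model",
    "default_titration_ratios",
    "validation_ratios",
    "synth_titration",
    "synth_sfdi_frames",
    "qa_region_map",
    "toy_gcode",
]

#: the reported linear-mixing coefficients (A, B, C) at 635 nm, mm^-1
PUBLISHED_MUA_COEFFS = (0.0078, 0.00095, 0.0056)
PUBLISHED_MUSP_COEFFS = (0.036, 0.034, 0.35)


def published_model() -> LinearMixingModel:
    """Mixing model built from the reported titration-fit coefficients."""
    return LinearMixingModel.from_coefficients(
        PUBLISHED_MUA_COEFFS, PUBLISHED_MUSP_COEFFS
    )


def default_titration_ratios() -> list[MixingRatio]:
    """A 16-point titration design: 4 rulers x 4 segments.

    The published table is organized as four 4-segment rulers; the exact
    ratio values are not reproduced here, so this uses a crossed
    (Rg, Rw) grid spanning a comparable span of the mixing simplex.
    """
    grid = [
        (rg, rw)
        for rg in (0.0, 6.0, 12.0, 18.0)
        for rw in (0.0, 10.0, 20.0, 30.0)
    ]
    return [MixingRatio.from_gray_white(rg, rw) for rg, rw in grid]


def validation_ratios() -> list[MixingRatio]:
    """Five held-out ratios not present in the titration design."""
    return [
        MixingRatio.from_gray_white(rg, rw)
        for rg, rw in [(3, 5), (9, 15), (15, 25), (4, 28), (16, 8)]
    ]


@dataclass
class SynthConfig:
    """Common knobs for the synthetic generators."""

    seed: int = 0
    noise_model: Literal["none", "multiplicative", "additive", "shot"] = "none"
    noise_sigma: float = 0.0
    image_shape: tuple[int, int] = (64, 64)
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    fx_list: tuple[float, ...] = (0.0, 0.1)
    phase_offsets: tuple[float, ...] = PHASE_OFFSETS
    gain: float = 20000.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if min(self.image_shape) < 1:
            raise ValueError("image dimensions must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(values: np.ndarray, config: SynthConfig, rng) -> np.ndarray:
    if config.noise_model == "none" or config.noise_sigma == 0:
        return values
    if config.noise_model == "multiplicative":
        return values * (1.0 + config.noise_sigma * rng.standard_normal(values.shape))
    if config.noise_model == "additive":
        return values + config.noise_sigma * rng.standard_normal(values.shape)
    if config.noise_model == "shot":
        scaled = np.clip(values, 0, None) / config.noise_sigma
        return rng.poisson(scaled) * config.noise_sigma
    raise ValueError(f"unknown noise model {config.noise_model!r}")


def synth_titration(
    true_model: LinearMixingModel,
    ratios: list[MixingRatio] | None = None,
    config: SynthConfig | None = None,
) -> list[TitrationRecord]:
    """Titration records on (or noisily around) a known mixing plane."""
    config = config or SynthConfig()
    ratios = ratios if ratios is not None else default_titration_ratios()
    rng = config.rng()
    records = []
    for i, ratio in enumerate(ratios):
        clean = predict(true_model, ratio)
        vals = _apply_noise(np.array([clean.mua, clean.musp]), config, rng)
        mua = float(np.clip(vals[0], 1e-6, None))
        musp = float(np.clip(vals[1], 1e-6, None))
        ruler, seg = divmod(i, 4)
        records.append(
            TitrationRecord(
                ratio=ratio,
                measured=OpticalProperties(mua, musp),
                mua_sd=config.noise_sigma * clean.mua,
                musp_sd=config.noise_sigma * clean.musp,
                label=f"{ruler + 1}{chr(ord('A') + seg)}",
            )
        )
    return records


def qa_region_map(
    shape: tuple[int, int] = (90, 90),
    background: OpticalProperties | None = None,
) -> tuple[np.ndarray, dict[int, OpticalProperties], dict[str, int]]:
    """Pixelated QA-phantom layout: labeled map plus per-label properties.

    Returns (label_map, properties-by-label, region-name -> label).  The map
    is a scaled-down raster of the QA design's footprint (1 px per mm at the
    default shape).
    """
    from phantomforge.designs import QA_LAYOUT

    background = background or OpticalProperties(0.019, 0.83)
    h, w = shape
    sy, sx = 90.0 / h, 90.0 / w
    yy, xx = np.mgrid[0:h, 0:w]
    x_mm = (xx + 0.5) * sx
    y_mm = (yy + 0.5) * sy
    label_map = np.zeros(shape, dtype=int)
    props = {0: background}
    names = {"background": 0}
    contrasts = {
        "C1": (15, 3), "C2": (15, 3), "C3": (15, 3), "C4": (25, 3),
        "B1": (6, 2), "B2": (6, 2), "B3": (12, 2), "B4": (12, 2),
    }
    for k, (name, (fa, fs)) in enumerate(contrasts.items(), start=1):
        geo = QA_LAYOUT[name]
        if "diameter" in geo:
            cx, cy = geo["center"]
            mask = (x_mm - cx) ** 2 + (y_mm - cy) ** 2 <= (geo["diameter"] / 2) ** 2
        else:
            ox, oy = geo["origin"]
            w_, h_ = geo["size"]
            mask = (x_mm >= ox) & (x_mm <= ox + w_) & (y_mm >= oy) & (y_mm <= oy + h_)
        label_map[mask] = k
        props[k] = OpticalProperties(fa * background.mua, fs * background.musp)
        names[name] = k
    return label_map, props, names


def synth_sfdi_frames(
    region_map: np.ndarray,
    region_properties: dict[int, OpticalProperties],
    forward: Literal["lut", "diffusion"] = "diffusion",
    lut: ReflectanceLUT | None = None,
    reference_properties: OpticalProperties | None = None,
    config: SynthConfig | None = None,
    n_index: float = 1.4,
) -> tuple[FrameSet, CalibrationReference, dict[str, np.ndarray]]:
    """Synthesize a 3-phase SFDI acquisition with known ground truth.

    Per pixel, ``Ii = gain * Rd(fx) * (1 + cos(2 pi fx x + phi_i)) / 2`` so
    frames are non-negative; a homogeneous reference at
    ``reference_properties`` is generated with the same gain.  Returns the
    sample frames, the calibration reference, and ground-truth maps.
    """
    config = config or SynthConfig()
    region_map = np.asarray(region_map)
    labels = np.unique(region_map)
    missing = [int(l) for l in labels if int(l) not in region_properties]
    if missing:
        raise ValueError(f"region labels without properties: {missing}")
    reference_properties = reference_properties or OpticalProperties(0.0064, 1.42)

    def rd_of(props: OpticalProperties, fx: float) -> float:
        if forward == "lut":
            if lut is None:
                raise ValueError("forward='lut' requires a lut")
            return lut.value(props.mua, props.musp, fx)
        return diffusion_rd(props.mua, props.musp, fx, n=n_index)

    rng = config.rng()
    h, w = region_map.shape
    x_mm = (np.arange(w) + 0.5) * config.pixel_pitch

    truth_mua = np.zeros((h, w))
    truth_musp = np.zeros((h, w))
    for lab in labels:
        p = region_properties[int(lab)]
        truth_mua[region_map == lab] = p.mua
        truth_musp[region_map == lab] = p.musp

    def frames_for(rd_maps: dict[float, np.ndarray]) -> FrameSet:
        stacks = {}
        for fx in config.fx_list:
            rd = rd_maps[fx]
            stack = np.empty((len(config.phase_offsets), h, w))
            for i, phi in enumerate(config.phase_offsets):
                pattern = 0.5 * (1.0 + np.cos(2.0 * np.pi * fx * x_mm + phi))
                stack[i] = config.gain * rd * pattern[None, :]
            stack = _apply_noise(stack, config, rng)
            stacks[fx] = np.clip(stack, 0.0, None)
        return FrameSet(frames=stacks, pixel_pitch=config.pixel_pitch)

    sample_rd = {}
    for fx in config.fx_list:
        rd = np.zeros((h, w))
        for lab in labels:
            rd[region_map == lab] = rd_of(region_properties[int(lab)], fx)
        sample_rd[fx] = rd
    ref_rd = {
        fx: np.full((h, w), rd_of(reference_properties, fx))
        for fx in config.fx_list
    }

    sample = frames_for(sample_rd)
    reference = CalibrationReference(
        frames=frames_for(ref_rd), properties=reference_properties
    )
    truth = {
        "mua": truth_mua,
        "musp": truth_musp,
        **{f"rd_fx{fx:g}": sample_rd[fx] for fx in config.fx_list},
    }
    return sample, reference, truth


# ---------------------------------------------------------------------------
# toy G-code


def toy_gcode(
    pattern: Literal["single", "stripes", "checkerboard"] = "stripes",
    layers: int = 2,
    mixtures: list[MixingRatio] | None = None,
    block_size: float = 10.0,
    layer_thickness: float = 0.2,
    flow: float = 0.05,
) -> tuple[str, dict]:
    """Minimal absolute-mode program with labeled region blocks.

    Patterns: ``single`` (one region), ``stripes`` (two side-by-side blocks
    per layer), ``checkerboard`` (2 x 2 blocks per layer, alternating).
    Each block is a serpentine of 3 extrusion lines; extrusion per move is
    ``block_size * flow`` mm of filament.  The manifest records region
    mixtures, per-layer presence, expected within-layer transition counts
    and the exact extrusion total.
    """
    if mixtures is None:
        mixtures = [MixingRatio(100, 0, 0), MixingRatio(0, 100, 0)]
    if not mixtures:
        raise ValueError("need at least one mixture")
    if pattern == "single":
        cells = [(0.0, 0.0, 0)]
    elif pattern == "stripes":
        cells = [(0.0, 0.0, 0), (block_size, 0.0, 1 % len(mixtures))]
    elif pattern == "checkerboard":
        # serpentine visit order of the 2x2 board: m0 m1 / m1 m0 becomes
        # the alternating print sequence m0, m1, m0, m1
        cells = [
            (0.0, 0.0, 0),
            (block_size, 0.0, 1 % len(mixtures)),
            (block_size, block_size, 0),
            (0.0, block_size, 1 % len(mixtures)),
        ]
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    lines = ["G21 ; mm units", "G90 ; absolute positioning", "M82 ; absolute E"]
    e = 0.0
    e_per_move = block_size * flow
    n_moves_per_block = 3
    labels_used = sorted({f"region{idx}" for _, _, idx in cells})
    # within-layer transitions: consecutive blocks with differing mixtures
    transitions_per_layer = sum(
        1
        for prev, cur in zip(cells, cells[1:])
        if mixtures[prev[2]].as_tuple() != mixtures[cur[2]].as_tuple()
    )
    for layer in range(1, layers + 1):
        z = layer * layer_thickness
        lines.append(f"G1 Z{z:.2f} F600")
        for cx, cy, midx in cells:
            label = f"region{midx}"
            lines.append(f";region:{label}")
            lines.append(f"G0 X{cx:.3f} Y{cy:.3f}")
            for j in range(n_moves_per_block):
                yy = cy + (j + 1) * (block_size / (n_moves_per_block + 1))
                x_target = cx + block_size if j % 2 == 0 else cx
                e += e_per_move
                lines.append(f"G1 X{x_target:.3f} Y{yy:.3f} E{e:.5f}")
    text = "\n".join(lines) + "\n"

    mix_map = {f"region{i}": m for i, m in enumerate(mixtures) if f"region{i}" in labels_used}
    per_layer = {
        layer: sorted({f"region{idx}" for _, _, idx in cells})
        for layer in range(1, layers + 1)
    }
    manifest = {
        "pattern": pattern,
        "layers": layers,
        "mixtures": {k: v.as_tuple() for k, v in mix_map.items()},
        "per_layer_regions": per_layer,
        "within_layer_transitions": transitions_per_layer,
        "blocks_per_layer": len(cells),
        "extrusion_total": e,
        "extrusion_per_move": e_per_move,
        "moves_per_block": n_moves_per_block,
        "layer_thickness": layer_thickness,
    }
    return text, manifest
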