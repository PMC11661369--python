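"""Three-phase SFDI demodulation, calibration and LUT inversion.

Pipeline: sinusoidal illumination frames at each spatial frequency are
demodulated to AC amplitude maps, converted to diffuse reflectance via a
reference phantom of known optical properties, and inverted per pixel
against a Monte-Carlo reflectance lookup table to yield mua / musp maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from phantomforge.mixing import OpticalProperties, RoiSummary, summarize_roi
from phantomforge.wmc import ReflectanceLUT

__all__ = [
    "FrameSet",
    "CalibrationReference",
    "OpticalPropertyMap",
    "PHASE_OFFSETS",
    "demodulate",
    "calibrate",
    "invert_lut",
    "recover",
    "read_frame",
    "write_frame",
]

#: the three equally spaced phase offsets of the illumination pattern
PHASE_OFFSETS = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)

#: default camera pixel pitch in mm (per-pixel area ~0.035 mm^2)
DEFAULT_PIXEL_PITCH = float(np.sqrt(0.035))


@dataclass
class FrameSet:
    """Three phase frames per spatial frequency, plus camera geometry."""

    frames: dict[float, np.ndarray]  # fx -> array of shape (3, H, W)
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    bit_depth: int = 16

    def __post_init__(self) -> None:
        shapes = set()
        for fx, stack in self.frames.items():
            stack = np.asarray(stack, dtype=float)
            if stack.ndim != 3 or stack.shape[0] != 3:
                raise ValueError(
                    f"fx={fx}: expected 3 phase frames, got shape {stack.shape}"
                )
            if np.any(stack < 0):
                raise ValueError(f"fx={fx}: negative pixel values")
            self.frames[fx] = stack
            shapes.add(stack.shape[1:])
        if len(shapes) > 1:
            raise ValueError(f"frame shapes differ across fx: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        stack = next(iter(self.frames.values()))
        return stack.shape[1:]

    @property
    def fx_list(self) -> tuple[float, ...]:
        return tuple(sorted(self.frames))


@dataclass
class CalibrationReference:
    """Frames measured (or synthesized) on a homogeneous reference phantom."""

    frames: FrameSet
    properties: OpticalProperties


@dataclass
class OpticalPropertyMap:
    """Recovered per-pixel optical properties with a validity mask."""

    mua_map: np.ndarray
    musp_map: np.ndarray
    validity_mask: np.ndarray
    intermediates: dict = field(default_factory=dict)

    def roi_summary(
        self, roi: tuple[int, int, int, int], pixel_area_mm2: float
    ) -> dict[str, RoiSummary]:
        return {
            "mua": summarize_roi(np.where(self.validity_mask, self.mua_map, np.nan), roi, pixel_area_mm2),
            "musp": summarize_roi(np.where(self.validity_mask, self.musp_map, np.nan), roi, pixel_area_mm2),
        }


def demodulate(phase_frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demodulate three equally phase-shifted frames into (AC, DC) maps.

    AC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2);
    DC = (I1 + I2 + I3) / 3.
    """
    stack = np.asarray(phase_frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"expected shape (3, H, W), got {stack.shape}")
    i1, i2, i3 = stack
    ac = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    dc = (i1 + i2 + i3) / 3.0
    return ac, dc


def _lut_interpolators(lut: ReflectanceLUT) -> dict[float, RegularGridInterpolator]:
    return {
        float(fx): RegularGridInterpolator(
            (lut.mua_grid, lut.musp_grid), lut.rd[:, :, k], bounds_error=False
        )
        for k, fx in enumerate(lut.fx_list)
    }


def calibrate(
    sample_ac: dict[float, np.ndarray],
    reference_ac: dict[float, np.ndarray],
    reference_properties: OpticalProperties,
    lut: ReflectanceLUT,
) -> tuple[dict[float, np.ndarray], np.ndarray]:
    """Convert sample AC maps to diffuse reflectance using the reference.

    ``Rd_sample(fx) = AC_sample / AC_reference * Rd_model(reference, fx)``
    with ``Rd_model`` interpolated from the LUT.  Returns the Rd maps and a
    boolean mask flagging pixels where the reference AC was zero.
    """
    interp = _lut_interpolators(lut)
    p = reference_properties
    rd_maps: dict[float, np.ndarray] = {}
    ok: np.ndarray | None = None
    for fx, ac_s in sample_ac.items():
        if float(fx) not in interp:
            raise ValueError(f"fx={fx} not present in LUT (has {list(interp)})")
        ac_r = reference_ac[fx]
        if ac_r.shape != ac_s.shape:
            raise ValueError("sample and reference AC shapes differ")
        rd_ref = float(interp[float(fx)]((p.mua, p.musp)))
        if not np.isfinite(rd_ref):
            raise ValueError("reference properties outside LUT bounds")
        good = ac_r > 0
        rd = np.zeros_like(ac_s, dtype=float)
        np.divide(ac_s, ac_r, out=rd, where=good)
        rd *= rd_ref
        rd_maps[fx] = rd
        ok = good if ok is None else (ok & good)
    return rd_maps, ok


def invert_lut(
    rd0_map: np.ndarray,
    rd1_map: np.ndarray,
    lut: ReflectanceLUT,
    fx_pair: tuple[float, float] = (0.0, 0.1),
    residual_tol: float = 1e-3,
    refine_iters: int = 25,
) -> OpticalPropertyMap:
    """Per-pixel inversion of (Rd(fx0), Rd(fx1)) to (mua, musp).

    Strategy: nearest LUT node in Rd space (k-d tree over all grid nodes),
    then local Gauss-Newton refinement on the bilinear interpolant.  Pixels
    whose reflectance pair cannot be matched within ``residual_tol``
    (Euclidean distance in Rd space) are masked invalid.
    """
    rd0 = np.asarray(rd0_map, dtype=float)
    rd1 = np.asarray(rd1_map, dtype=float)
    if rd0.shape != rd1.shape:
        raise ValueError("rd0 and rd1 maps must share a shape")
    k0 = int(np.argmin(np.abs(lut.fx_list - fx_pair[0])))
    k1 = int(np.argmin(np.abs(lut.fx_list - fx_pair[1])))
    table0 = lut.rd[:, :, k0]
    table1 = lut.rd[:, :, k1]

    nodes = np.column_stack([table0.ravel(), table1.ravel()])
    tree = cKDTree(nodes)

    # deduplicate identical reflectance pairs (synthetic region maps have few)
    pairs = np.column_stack([rd0.ravel(), rd1.ravel()])
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)

    _, idx = tree.query(uniq)
    i_mua, i_musp = np.unravel_index(idx, table0.shape)

    f0 = RegularGridInterpolator(
        (lut.mua_grid, lut.musp_grid), table0, bounds_error=False, fill_value=None
    )
    f1 = RegularGridInterpolator(
        (lut.mua_grid, lut.musp_grid), table1, bounds_error=False, fill_value=None
    )
    lo = np.array([lut.mua_grid[0], lut.musp_grid[0]])
    hi = np.array([lut.mua_grid[-1], lut.musp_grid[-1]])

    mua_u = np.empty(len(uniq))
    musp_u = np.empty(len(uniq))
    valid_u = np.zeros(len(uniq), dtype=bool)
    h = np.array(
        [1e-4 * (hi[0] - lo[0]), 1e-4 * (hi[1] - lo[1])]
    )  # finite-difference steps

    def _ev(f, p):
        return float(np.asarray(f(p)).reshape(-1)[0])

    for i, (t0, t1) in enumerate(uniq):
        p = np.array([lut.mua_grid[i_mua[i]], lut.musp_grid[i_musp[i]]])
        target = np.array([t0, t1])
        resid = np.array([_ev(f0, p) - t0, _ev(f1, p) - t1])
        if np.linalg.norm(resid) == 0.0:
            mua_u[i], musp_u[i] = p
            valid_u[i] = True
            continue
        for _ in range(refine_iters):
            # numerical Jacobian of (Rd0, Rd1) wrt (mua, musp)
            J = np.empty((2, 2))
            for j in range(2):
                pp = p.copy()
                pm = p.copy()
                pp[j] = min(pp[j] + h[j], hi[j])
                pm[j] = max(pm[j] - h[j], lo[j])
                dj = pp[j] - pm[j]
                J[0, j] = (_ev(f0, pp) - _ev(f0, pm)) / dj
                J[1, j] = (_ev(f1, pp) - _ev(f1, pm)) / dj
            resid = np.array([_ev(f0, p) - target[0], _ev(f1, p) - target[1]])
            if np.linalg.norm(resid) < 1e-12:
                break
            try:
                step = np.linalg.lstsq(J, resid, rcond=None)[0]
            except np.linalg.LinAlgError:  # pragma: no cover
                break
            p_new = np.clip(p - step, lo, hi)
            if np.allclose(p_new, p, rtol=0, atol=1e-14):
                break
            p = p_new
        resid = np.array([_ev(f0, p) - target[0], _ev(f1, p) - target[1]])
        mua_u[i], musp_u[i] = p
        valid_u[i] = np.linalg.norm(resid) <= residual_tol

    shape = rd0.shape
    return OpticalPropertyMap(
        mua_map=mua_u[inverse].reshape(shape),
        musp_map=musp_u[inverse].reshape(shape),
        validity_mask=valid_u[inverse].reshape(shape),
    )


def recover(
    sample: FrameSet,
    reference: CalibrationReference,
    lut: ReflectanceLUT,
    fx_pair: tuple[float, float] = (0.0, 0.1),
    residual_tol: float = 1e-3,
) -> OpticalPropertyMap:
    """Full pipeline: demodulate -> calibrate -> invert, with audit trail."""
    sample_ac = {}
    sample_dc = {}
    ref_ac = {}
    for fx in fx_pair:
        if fx not in sample.frames or fx not in reference.frames.frames:
            raise ValueError(f"fx={fx} missing from sample or reference frames")
        sample_ac[fx], sample_dc[fx] = demodulate(sample.frames[fx])
        ref_ac[fx], _ = demodulate(reference.frames.frames[fx])

    rd_maps, ok = calibrate(sample_ac, ref_ac, reference.properties, lut)
    result = invert_lut(
        rd_maps[fx_pair[0]], rd_maps[fx_pair[1]], lut, fx_pair, residual_tol
    )
    result.validity_mask &= ok
    result.intermediates = {
        "ac": sample_ac,
        "dc": sample_dc,
        "reference_ac": ref_ac,
        "rd": rd_maps,
    }
    return result


# ---------------------------------------------------------------------------
# image IO (16-bit grayscale TIFF / PNG)


def read_frame(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), dtype=float)


def write_frame(path, image: np.ndarray, bit_depth: int = 16) -> None:
    path = Path(path)
    arr = np.asarray(image)
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    arr = np.clip(np.rint(arr), 0, np.iinfo(dtype).max).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
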