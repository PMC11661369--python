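"""White Monte Carlo photon transport and diffuse-reflectance lookup tables.

A single absorption-free ("white") simulation at a reference scattering
coefficient yields per-photon exit records (radius, pathlength, residual
weight).  Absorption is applied post hoc by weighting each record with
``exp(-mua * L)``, and other reduced scattering values are reached by
similarity rescaling of all lengths, so one run populates the whole
(mua, musp) lookup table used for SFDI inversion.

Geometry: pencil beam, normal incidence at the origin of a semi-infinite
half-space (z > 0), Henyey-Greenstein scattering, Fresnel reflection at the
planar boundary for a refractive-index mismatch against air (n = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import j0

from phantomforge.errors import DomainError

__all__ = [
    "MediumModel",
    "WMCRun",
    "ReflectanceLUT",
    "simulate_white_mc",
    "first_interaction_depths",
    "radial_reflectance",
    "hankel_transform",
    "build_lut",
    "diffusion_rd",
    "default_mua_grid",
    "default_musp_grid",
    "DEFAULT_FX",
]

DEFAULT_FX = (0.0, 0.1)

#: roulette parameters (standard MCML-style survival lottery; unbiased —
#: the threshold trades tail variance for speed)
ROULETTE_THRESHOLD = 1e-3
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class MediumModel:
    """Semi-infinite turbid medium for the white-MC reference run."""

    n: float = 1.4
    g: float = 0.9
    mus_ref: float = 10.0

    def __post_init__(self) -> None:
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if not (-1.0 < self.g < 1.0):
            raise ValueError("anisotropy must lie in (-1, 1)")
        if self.mus_ref <= 0:
            raise ValueError("reference scattering coefficient must be > 0")

    @property
    def musp_ref(self) -> float:
        return self.mus_ref * (1.0 - self.g)


@dataclass
class WMCRun:
    """Detected-photon records of one white-MC simulation."""

    exit_radius: np.ndarray  # mm, at the reference scattering scale
    pathlength: np.ndarray  # mm
    weight: np.ndarray  # residual weight deposited at exit
    n_photons: int
    seed: int
    medium: MediumModel
    specular_fraction: float
    lost_weight: float  # weight discarded at the pathlength cutoff
    max_path: float

    @property
    def detected_fraction(self) -> float:
        """Detected diffuse weight per launched photon (specular excluded)."""
        return float(self.weight.sum()) / self.n_photons


_U64_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(inline="always")
def _u01(s):  # pragma: no cover
    # xorshift64*: fast, full-period, plenty for photon transport
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    v = (s * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)
    return s, np.float64(v) * _INV_2_53


@njit(inline="always")
def _seed_state(seed):  # pragma: no cover
    # splitmix64 scrambles small consecutive seeds into distant states
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & _U64_MASK
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True)
def _wmc_kernel(n_photons, mus, g, n_rel, w0, max_path, seed):  # pragma: no cover
    state = _seed_state(seed)
    cap = n_photons * 4
    out_r = np.empty(cap, dtype=np.float32)
    out_l = np.empty(cap, dtype=np.float32)
    out_w = np.empty(cap, dtype=np.float32)
    count = 0
    lost = 0.0
    matched = n_rel == 1.0
    inv_mus = 1.0 / mus

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = w0
        L = 0.0
        alive = True

        while alive:
            state, u = _u01(state)
            s = -math.log(u) * inv_mus
            while s > 0.0:
                if uz < 0.0 and z + uz * s < 0.0:
                    db = -z / uz
                    x += ux * db
                    y += uy * db
                    z = 0.0
                    L += db
                    s -= db
                    # Fresnel at the boundary (photon inside, going out)
                    ci = -uz
                    if matched:
                        R = 0.0
                    else:
                        st2 = n_rel * n_rel * (1.0 - ci * ci)
                        if st2 >= 1.0:
                            R = 1.0  # total internal reflection
                        else:
                            ct = math.sqrt(1.0 - st2)
                            rs = (n_rel * ci - ct) / (n_rel * ci + ct)
                            rp = (ci - n_rel * ct) / (ci + n_rel * ct)
                            R = 0.5 * (rs * rs + rp * rp)
                    if R < 1.0:
                        if count >= cap:
                            cap *= 2
                            nr = np.empty(cap, dtype=np.float32)
                            nl = np.empty(cap, dtype=np.float32)
                            nw = np.empty(cap, dtype=np.float32)
                            nr[:count] = out_r[:count]
                            nl[:count] = out_l[:count]
                            nw[:count] = out_w[:count]
                            out_r, out_l, out_w = nr, nl, nw
                        out_r[count] = math.sqrt(x * x + y * y)
                        out_l[count] = L
                        out_w[count] = w * (1.0 - R)
                        count += 1
                        w *= R
                    uz = -uz
                    if w <= 0.0:
                        alive = False
                        break
                else:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    L += s
                    s = 0.0
            if not alive:
                break
            if L > max_path:
                lost += w
                break
            if w < ROULETTE_THRESHOLD:
                state, u = _u01(state)
                if u < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    break
            # Henyey-Greenstein scatter
            state, u = _u01(state)
            if g == 0.0:
                ct = 2.0 * u - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
            st = math.sqrt(1.0 - ct * ct)
            state, u = _u01(state)
            phi = 2.0 * math.pi * u
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                nx = st * cp
                ny = st * sp
                nz = ct * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = math.sqrt(1.0 - uz * uz)
                nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
                ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nz = -st * cp * den + uz * ct
            norm = math.sqrt(nx * nx + ny * ny + nz * nz)
            ux = nx / norm
            uy = ny / norm
            uz = nz / norm

    return out_r[:count], out_l[:count], out_w[:count], lost


def simulate_white_mc(
    medium: MediumModel,
    n_photons: int,
    seed: int,
    max_path: float | None = None,
) -> WMCRun:
    """Run an absorption-free Monte Carlo simulation in a half-space.

    Parameters
    ----------
    medium
        Refractive index, anisotropy and reference scattering coefficient.
    n_photons
        Photons to launch (>= 1).
    seed
        RNG seed; runs are deterministic given (seed, n_photons, medium).
    max_path
        Pathlength cutoff in mm at the reference scale; photons exceeding it
        are terminated and their weight reported as ``lost_weight``.
        Defaults to 2000 transport mean free paths.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if max_path is None:
        max_path = 2000.0 / medium.musp_ref
    # specular reflection at normal incidence, handled by exact weight deduction
    rs = ((medium.n - 1.0) / (medium.n + 1.0)) ** 2 if medium.n != 1.0 else 0.0
    r, l, w, lost = _wmc_kernel(
        int(n_photons),
        float(medium.mus_ref),
        float(medium.g),
        float(medium.n),  # relative index inside vs air
        1.0 - rs,
        float(max_path),
        int(seed),
    )
    return WMCRun(
        exit_radius=r,
        pathlength=l,
        weight=w,
        n_photons=int(n_photons),
        seed=int(seed),
        medium=medium,
        specular_fraction=rs,
        lost_weight=float(lost),
        max_path=float(max_path),
    )


@njit(cache=True)
def _first_depth_kernel(n, mus, seed):  # pragma: no cover
    state = _seed_state(seed)
    out = np.empty(n)
    for i in range(n):
        state, u = _u01(state)
        out[i] = -math.log(u) / mus
    return out


def first_interaction_depths(medium: MediumModel, n: int, seed: int) -> np.ndarray:
    """Depths of the first photon-medium interaction (for sampling-law checks)."""
    return _first_depth_kernel(int(n), float(medium.mus_ref), int(seed))


def default_radial_edges(r_max: float = 50.0, dr: float = 0.1) -> np.ndarray:
    return np.arange(0.0, r_max + dr / 2, dr)


def radial_reflectance(
    run: WMCRun,
    mua: float,
    musp: float,
    radial_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially resolved diffuse reflectance Rd(rho) in mm^-2.

    Applies similarity rescaling from the reference run to the target
    ``musp`` (lengths scale by ``mus_ref / mus_target`` with
    ``mus_target = musp / (1 - g)``), then absorption weighting
    ``exp(-mua * L)``.  Returns ``(edges, rd)`` where ``rd[i]`` is the
    detected weight per launched photon per unit area in annulus ``i``;
    weight beyond the last edge is discarded (overflow excluded).
    """
    if run.exit_radius.size == 0:
        raise ValueError("empty WMC run")
    if musp <= 0:
        raise DomainError("musp must be positive")
    if mua < 0:
        raise DomainError("mua must be >= 0")
    if radial_edges is None:
        radial_edges = default_radial_edges()
    edges = np.asarray(radial_edges, dtype=float)

    scale = run.medium.mus_ref / (musp / (1.0 - run.medium.g))
    r = run.exit_radius.astype(np.float64) * scale
    L = run.pathlength.astype(np.float64) * scale
    w = run.weight.astype(np.float64) * np.exp(-mua * L)

    hist, _ = np.histogram(r, bins=edges, weights=w)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    rd = hist / (run.n_photons * areas)
    return edges, rd


def hankel_transform(
    rd_radial: np.ndarray, radial_edges: np.ndarray, fx: float
) -> float:
    """Project a radial reflectance kernel to spatial frequency ``fx``.

    ``Rd(fx) = 2 pi * sum_i rd_i * J0(2 pi fx rho_i) * rho_i * drho_i``
    using annulus midpoints as quadrature nodes.
    """
    edges = np.asarray(radial_edges, dtype=float)
    rd = np.asarray(rd_radial, dtype=float)
    mid = 0.5 * (edges[1:] + edges[:-1])
    dr = np.diff(edges)
    return float(2.0 * np.pi * np.sum(rd * j0(2.0 * np.pi * fx * mid) * mid * dr))


def default_mua_grid() -> np.ndarray:
    return np.geomspace(0.001, 0.8, 60)


def default_musp_grid() -> np.ndarray:
    return np.linspace(0.2, 4.5, 50)


@dataclass
class ReflectanceLUT:
    """Diffuse reflectance Rd over a (mua, musp) grid at each spatial frequency."""

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    fx_list: np.ndarray
    rd: np.ndarray  # shape (n_mua, n_musp, n_fx)
    metadata: dict = field(default_factory=dict)

    def value(self, mua: float, musp: float, fx: float) -> float:
        """Bilinearly interpolated Rd at (mua, musp) for one tabulated fx."""
        k = int(np.argmin(np.abs(self.fx_list - fx)))
        if abs(self.fx_list[k] - fx) > 1e-12:
            raise ValueError(f"fx={fx} not tabulated; available: {self.fx_list}")
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.mua_grid, self.musp_grid), self.rd[:, :, k]
        )
        return float(interp((mua, musp)))

    def save(self, path) -> None:
        np.savez(
            path,
            mua_grid=self.mua_grid,
            musp_grid=self.musp_grid,
            fx_list=self.fx_list,
            rd=self.rd,
            metadata=np.array([repr(self.metadata)], dtype=object),
        )

    @classmethod
    def load(cls, path) -> "ReflectanceLUT":
        with np.load(path, allow_pickle=True) as z:
            metadata = eval(z["metadata"][0]) if "metadata" in z else {}  # noqa: S307
            return cls(
                mua_grid=z["mua_grid"],
                musp_grid=z["musp_grid"],
                fx_list=z["fx_list"],
                rd=z["rd"],
                metadata=metadata,
            )


def build_lut(
    run: WMCRun,
    mua_grid: np.ndarray | None = None,
    musp_grid: np.ndarray | None = None,
    fx_list: Sequence[float] = DEFAULT_FX,
    radial_edges: np.ndarray | None = None,
    n_path_bins: int = 1024,
    enforce_monotone: bool = True,
) -> ReflectanceLUT:
    """Fill a reflectance LUT from one white-MC run.

    For each target musp the run is similarity-rescaled once and compressed
    into a (pathlength, radius) histogram; absorption weighting and the
    Hankel projection are then applied on the compact histogram, which keeps
    the full grid evaluation to a few matrix products.
    """
    mua_grid = default_mua_grid() if mua_grid is None else np.asarray(mua_grid, float)
    musp_grid = (
        default_musp_grid() if musp_grid is None else np.asarray(musp_grid, float)
    )
    for name, grid in (("mua", mua_grid), ("musp", musp_grid)):
        if np.any(grid <= 0):
            raise ValueError(f"{name} grid values must be > 0")
        if np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} grid must be strictly increasing")
    fx = np.asarray(list(fx_list), dtype=float)
    if radial_edges is None:
        radial_edges = default_radial_edges()
    edges = np.asarray(radial_edges, dtype=float)
    mid = 0.5 * (edges[1:] + edges[:-1])
    dr = np.diff(edges)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    n_r = mid.size

    # Hankel quadrature row per fx: Rd(fx) = kernel @ rd_radial
    kernel = np.stack(
        [2.0 * np.pi * j0(2.0 * np.pi * f * mid) * mid * dr for f in fx]
    )  # (n_fx, n_r)

    r0 = run.exit_radius.astype(np.float64)
    l0 = run.pathlength.astype(np.float64)
    w0 = run.weight.astype(np.float64)
    lmin, lmax = float(l0.min()), float(l0.max())

    rd = np.empty((mua_grid.size, musp_grid.size, fx.size))
    for jm, musp in enumerate(musp_grid):
        scale = run.medium.mus_ref / (musp / (1.0 - run.medium.g))
        r = r0 * scale
        L = l0 * scale
        # log-spaced pathlength bins at this scale
        lo, hi = lmin * scale, lmax * scale
        ledges = np.geomspace(lo * (1 - 1e-12), hi * (1 + 1e-12), n_path_bins + 1)
        lmid = np.sqrt(ledges[1:] * ledges[:-1])
        li = np.clip(np.searchsorted(ledges, L, side="right") - 1, 0, n_path_bins - 1)
        ri = np.floor_divide(r, edges[1] - edges[0]).astype(np.int64)
        keep = ri < n_r  # overflow beyond the last edge excluded
        flat = li[keep] * n_r + ri[keep]
        hist = np.bincount(flat, weights=w0[keep], minlength=n_path_bins * n_r)
        H = hist.reshape(n_path_bins, n_r) / (run.n_photons * areas)[None, :]
        decay = np.exp(-np.outer(mua_grid, lmid))  # (n_mua, n_path_bins)
        rd_radial = decay @ H  # (n_mua, n_r)
        rd[:, jm, :] = rd_radial @ kernel.T  # (n_mua, n_fx)

    if enforce_monotone:
        # Rd must not increase with absorption.  At fx > 0 the Hankel kernel
        # has negative lobes, so Monte-Carlo noise can produce tiny
        # violations; clamp with a running minimum along the mua axis.
        rd = np.minimum.accumulate(rd, axis=0)

    return ReflectanceLUT(
        mua_grid=mua_grid,
        musp_grid=musp_grid,
        fx_list=fx,
        rd=rd,
        metadata={
            "seed": run.seed,
            "n_photons": run.n_photons,
            "n": run.medium.n,
            "g": run.medium.g,
            "mus_ref": run.medium.mus_ref,
            "max_path": run.max_path,
        },
    )


def diffusion_lut(
    mua_grid: np.ndarray | None = None,
    musp_grid: np.ndarray | None = None,
    fx_list: Sequence[float] = DEFAULT_FX,
    n: float = 1.4,
) -> ReflectanceLUT:
    """Reflectance LUT tabulated from the diffusion closed form.

    Useful as a fast, Monte-Carlo-free forward model for pipeline tests;
    only valid in the diffusive regime.
    """
    mua_grid = default_mua_grid() if mua_grid is None else np.asarray(mua_grid, float)
    musp_grid = (
        default_musp_grid() if musp_grid is None else np.asarray(musp_grid, float)
    )
    fx = np.asarray(list(fx_list), dtype=float)
    rd = np.empty((mua_grid.size, musp_grid.size, fx.size))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, mua in enumerate(mua_grid):
            for j, musp in enumerate(musp_grid):
                for k, f in enumerate(fx):
                    rd[i, j, k] = diffusion_rd(mua, musp, f, n)
    return ReflectanceLUT(
        mua_grid=mua_grid,
        musp_grid=musp_grid,
        fx_list=fx,
        rd=rd,
        metadata={"model": "diffusion", "n": n},
    )


def _effective_reflection_coefficient(n: float) -> float:
    # Groenhuis / Egan-Hilgeman empirical fit for the internal reflection
    # coefficient of an index-mismatched boundary against air.
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def diffusion_rd(mua: float, musp: float, fx: float = 0.0, n: float = 1.4) -> float:
    """Closed-form diffusion-approximation Rd(fx) for a semi-infinite medium.

    Valid in the diffusive regime (``musp >> mua``); warns outside
    ``musp / mua >= 10``.  Serves as the independent oracle for the
    Monte-Carlo lookup table.
    """
    if mua <= 0 or musp <= 0:
        raise DomainError("mua and musp must be positive")
    if musp / mua < 10:
        import warnings

        warnings.warn(
            f"diffusion approximation unreliable at musp/mua = {musp / mua:.1f}",
            stacklevel=2,
        )
    mutr = mua + musp
    a_prime = musp / mutr
    mueff_prime = math.sqrt(3.0 * mua * mutr + (2.0 * math.pi * fx) ** 2)
    reff = _effective_reflection_coefficient(n) if n != 1.0 else 0.0
    A = (1.0 - reff) / (2.0 * (1.0 + reff))
    x = mueff_prime / mutr
    return 3.0 * A * a_prime / ((x + 1.0) * (x + 3.0 * A))
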