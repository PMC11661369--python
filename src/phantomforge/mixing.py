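"""Linear filament-mixing model: calibration, prediction and inverse design.

The optical properties (absorption coefficient ``mua`` and reduced
scattering coefficient ``musp``, both in mm^-1) of a three-filament mix are
modeled as an affine function of the gray and white filament percentages::

    mu = A * Rg + B * Rw + C

where the translucent fraction is ``Rt = 100 - Rg - Rw``.  This module fits
the (A, B, C) coefficients from titration measurements, predicts properties
for arbitrary mixing ratios, solves the constrained inverse problem (find
the ratio realizing a target property pair), and provides the relative-error
and ROI-summary helpers used when validating printed phantoms.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from phantomforge.errors import (
    DomainError,
    InsufficientDataError,
    RankDeficiencyError,
)

__all__ = [
    "MixingRatio",
    "OpticalProperties",
    "TitrationRecord",
    "PropertyFit",
    "LinearMixingModel",
    "InverseDesignResult",
    "RoiSummary",
    "fit_linear_mixing",
    "fit_mixing_model",
    "predict",
    "invert",
    "relative_error",
    "feasible_range",
    "summarize_roi",
    "read_titration_csv",
    "write_titration_csv",
]

_RATIO_TOL = 1e-9


@dataclass(frozen=True)
class MixingRatio:
    """Percent mixing ratio of (gray, white, translucent) filament.

    Components are percentages in [0, 100] and must sum to 100.
    """

    rg: float
    rw: float
    rt: float

    def __post_init__(self) -> None:
        total = self.rg + self.rw + self.rt
        if abs(total - 100.0) > 1e-9 * max(1.0, abs(total)) + _RATIO_TOL:
            raise ValueError(f"mixing ratio must sum to 100, got {total!r}")
        for name, v in (("rg", self.rg), ("rw", self.rw), ("rt", self.rt)):
            if not (-_RATIO_TOL <= v <= 100.0 + _RATIO_TOL):
                raise ValueError(f"{name}={v!r} outside [0, 100]")

    @classmethod
    def from_gray_white(cls, rg: float, rw: float) -> "MixingRatio":
        return cls(float(rg), float(rw), 100.0 - float(rg) - float(rw))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rg, self.rw, self.rt)

    def channel_weights(self) -> tuple[float, float, float]:
        """Per-channel extruder weights, normalized to sum to 1."""
        return (self.rg / 100.0, self.rw / 100.0, self.rt / 100.0)

    def rounded(self) -> "MixingRatio":
        """Nearest integer-valued ratio still summing to 100."""
        rg, rw = round(self.rg), round(self.rw)
        return MixingRatio.from_gray_white(float(rg), float(rw))


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering coefficients in mm^-1."""

    mua: float
    musp: float
    wavelength: float = 635.0

    def __post_init__(self) -> None:
        if self.mua <= 0 or self.musp <= 0:
            raise ValueError(
                f"optical properties must be positive, got mua={self.mua}, musp={self.musp}"
            )


@dataclass(frozen=True)
class TitrationRecord:
    """One titration sample: a printed mixing ratio and its measured properties."""

    ratio: MixingRatio
    measured: OpticalProperties
    mua_sd: float = 0.0
    musp_sd: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.mua_sd < 0 or self.musp_sd < 0:
            raise ValueError("dispersion components must be >= 0")


@dataclass(frozen=True)
class PropertyFit:
    """Fitted plane ``mu = A*Rg + B*Rw + C`` for one optical property."""

    A: float
    B: float
    C: float
    r_squared: float = 1.0
    residuals: tuple[float, ...] = field(default_factory=tuple)

    def __call__(self, rg: float, rw: float) -> float:
        return self.A * rg + self.B * rw + self.C


@dataclass(frozen=True)
class LinearMixingModel:
    """Per-property linear-mixing fits plus provenance metadata."""

    mua: PropertyFit
    musp: PropertyFit
    filaments: tuple[str, str, str] = ("gray", "white", "translucent")
    wavelength: float = 635.0

    def to_json(self) -> str:
        def _fit(f: PropertyFit) -> dict:
            return {
                "A": f.A,
                "B": f.B,
                "C": f.C,
                "r_squared": f.r_squared,
                "residuals": list(f.residuals),
            }

        return json.dumps(
            {
                "model": "linear-mixing",
                "units": "mm^-1",
                "wavelength_nm": self.wavelength,
                "filaments": list(self.filaments),
                "mua": _fit(self.mua),
                "musp": _fit(self.musp),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearMixingModel":
        d = json.loads(text)

        def _fit(k: str) -> PropertyFit:
            f = d[k]
            return PropertyFit(
                f["A"], f["B"], f["C"], f.get("r_squared", 1.0),
                tuple(f.get("residuals", ())),
            )

        return cls(
            mua=_fit("mua"),
            musp=_fit("musp"),
            filaments=tuple(d.get("filaments", ("gray", "white", "translucent"))),
            wavelength=d.get("wavelength_nm", 635.0),
        )

    @classmethod
    def from_coefficients(
        cls,
        mua_coeffs: Sequence[float],
        musp_coeffs: Sequence[float],
        **kwargs,
    ) -> "LinearMixingModel":
        """Build a model directly from (A, B, C) triples, bypassing fitting."""
        return cls(PropertyFit(*mua_coeffs), PropertyFit(*musp_coeffs), **kwargs)


@dataclass(frozen=True)
class InverseDesignResult:
    """Outcome of inverse design: the ratio realizing a target property pair."""

    ratio: MixingRatio
    continuous_ratio: MixingRatio
    achieved: OpticalProperties
    target: OpticalProperties
    relative_errors: dict[str, float]
    feasible: bool
    objective: float


@dataclass(frozen=True)
class RoiSummary:
    median: float
    std: float
    pixel_count: int
    area_mm2: float


def fit_linear_mixing(
    records: Iterable[TitrationRecord],
    property_selector: Literal["mua", "musp"],
    weighted: bool = False,
) -> PropertyFit:
    """Ordinary least-squares plane fit of one property against (Rg, Rw).

    Parameters
    ----------
    records
        Titration measurements; at least three, with non-collinear
        (Rg, Rw) design points.
    property_selector
        Which measured property to fit, ``"mua"`` or ``"musp"``.
    weighted
        If True, weight each record by the inverse variance of its reported
        dispersion (records with zero dispersion get the median weight).
    """
    records = list(records)
    if property_selector not in ("mua", "musp"):
        raise ValueError(f"unknown property selector {property_selector!r}")
    if len(records) < 3:
        raise InsufficientDataError(
            f"need at least 3 titration records to fit a plane, got {len(records)}"
        )

    rg = np.array([r.ratio.rg for r in records], dtype=float)
    rw = np.array([r.ratio.rw for r in records], dtype=float)
    y = np.array(
        [getattr(r.measured, property_selector) for r in records], dtype=float
    )
    X = np.column_stack([rg, rw, np.ones_like(rg)])

    if weighted:
        sd = np.array(
            [getattr(r, f"{property_selector}_sd") for r in records], dtype=float
        )
        positive = sd[sd > 0]
        fill = np.median(positive) if positive.size else 1.0
        sd = np.where(sd > 0, sd, fill)
        w = 1.0 / sd
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y

    # Rank check on the unweighted design so the error names the geometry.
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[-1] <= 1e-10 * s[0]:
        direction = vt[-1]
        raise RankDeficiencyError(
            "titration (Rg, Rw) points are collinear; design is degenerate "
            f"along direction (dRg, dRw, d1) = ({direction[0]:+.3f}, "
            f"{direction[1]:+.3f}, {direction[2]:+.3f})",
            direction=direction,
        )

    coeffs, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    fitted = X @ coeffs
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    fit = PropertyFit(
        A=float(coeffs[0]),
        B=float(coeffs[1]),
        C=float(coeffs[2]),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        residuals=tuple(resid.tolist()),
    )
    if fit.C <= 0:
        warnings.warn(
            f"fitted intercept C={fit.C:.4g} mm^-1 is non-positive; "
            "physically the pure-translucent print should have a positive "
            f"{property_selector}",
            stacklevel=2,
        )
    return fit


def fit_mixing_model(
    records: Iterable[TitrationRecord], weighted: bool = False
) -> LinearMixingModel:
    """Fit both property planes from one titration data set."""
    records = list(records)
    wl = records[0].measured.wavelength if records else 635.0
    return LinearMixingModel(
        mua=fit_linear_mixing(records, "mua", weighted=weighted),
        musp=fit_linear_mixing(records, "musp", weighted=weighted),
        wavelength=wl,
    )


def predict(model: LinearMixingModel, ratio: MixingRatio) -> OpticalProperties:
    """Forward-evaluate the mixing model at a ratio."""
    return OpticalProperties(
        mua=model.mua(ratio.rg, ratio.rw),
        musp=model.musp(ratio.rg, ratio.rw),
        wavelength=model.wavelength,
    )


def relative_error(measured: float, predicted: float) -> float:
    """Relative error |measured - predicted| / predicted."""
    if predicted == 0:
        raise DomainError("relative error undefined for predicted value 0")
    return abs(measured - predicted) / abs(predicted)


def feasible_range(model: LinearMixingModel) -> dict[str, tuple[float, float]]:
    """Per-property (min, max) achievable over the mixing simplex.

    The model is affine in (Rg, Rw), so extremes occur at simplex vertices
    (0, 0), (100, 0) and (0, 100).
    """
    vertices = [(0.0, 0.0), (100.0, 0.0), (0.0, 100.0)]
    out = {}
    for name in ("mua", "musp"):
        f: PropertyFit = getattr(model, name)
        vals = [f(rg, rw) for rg, rw in vertices]
        out[name] = (min(vals), max(vals))
    return out


def _objective(model: LinearMixingModel, target: OpticalProperties, rg, rw) -> float:
    e_mua = (model.mua(rg, rw) - target.mua) / target.mua
    e_musp = (model.musp(rg, rw) - target.musp) / target.musp
    return e_mua**2 + e_musp**2


def _continuous_invert(
    model: LinearMixingModel, target: OpticalProperties
) -> tuple[float, float]:
    # Unconstrained weighted least squares is a 2x2 linear solve; fall back
    # to SLSQP only when the solution violates the simplex constraints.
    M = np.array(
        [
            [model.mua.A / target.mua, model.mua.B / target.mua],
            [model.musp.A / target.musp, model.musp.B / target.musp],
        ]
    )
    b = np.array(
        [
            (target.mua - model.mua.C) / target.mua,
            (target.musp - model.musp.C) / target.musp,
        ]
    )
    sol, *_ = np.linalg.lstsq(M, b, rcond=None)
    rg, rw = float(sol[0]), float(sol[1])
    if rg >= -1e-12 and rw >= -1e-12 and rg + rw <= 100.0 + 1e-12:
        return (min(max(rg, 0.0), 100.0), min(max(rw, 0.0), 100.0))

    res = minimize(
        lambda x: _objective(model, target, x[0], x[1]),
        x0=np.clip([rg, rw], 0.0, 50.0),
        method="SLSQP",
        bounds=[(0.0, 100.0), (0.0, 100.0)],
        constraints=[{"type": "ineq", "fun": lambda x: 100.0 - x[0] - x[1]}],
        options={"ftol": 1e-14, "maxiter": 200},
    )
    return float(res.x[0]), float(res.x[1])


def invert(
    model: LinearMixingModel,
    target: OpticalProperties,
    rounding: Literal["none", "integer"] = "integer",
    feasibility_threshold: float = 0.05,
) -> InverseDesignResult:
    """Find the mixing ratio whose predicted properties best match ``target``.

    Minimizes the sum of squared relative errors in (mua, musp) subject to
    ``Rg, Rw >= 0`` and ``Rg + Rw <= 100``.  With ``rounding="integer"`` the
    continuous optimum is snapped to the best of its integer neighbors that
    sum to 100 (ties broken toward larger translucent fraction, i.e. less
    pigment).  ``feasible`` reports whether both relative errors at the
    *continuous* optimum are below ``feasibility_threshold``.
    """
    if target.mua <= 0 or target.musp <= 0:
        raise DomainError("target optical properties must be positive")

    rg_c, rw_c = _continuous_invert(model, target)
    continuous = MixingRatio.from_gray_white(rg_c, rw_c)

    pred_c = predict(model, continuous)
    errs_c = {
        "mua": relative_error(target.mua, pred_c.mua),
        "musp": relative_error(target.musp, pred_c.musp),
    }
    feasible = all(e <= feasibility_threshold for e in errs_c.values())

    if rounding == "integer":
        candidates = []
        for rg in {np.floor(rg_c), np.ceil(rg_c), np.round(rg_c)}:
            for rw in {np.floor(rw_c), np.ceil(rw_c), np.round(rw_c)}:
                rg_i, rw_i = float(rg), float(rw)
                if rg_i < 0 or rw_i < 0 or rg_i + rw_i > 100:
                    continue
                candidates.append((rg_i, rw_i))
        # minimal objective; tie-break toward larger Rt (smaller Rg + Rw)
        best = min(
            candidates,
            key=lambda c: (_objective(model, target, *c), c[0] + c[1]),
        )
        chosen = MixingRatio.from_gray_white(*best)
    elif rounding == "none":
        chosen = continuous
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")

    achieved = predict(model, chosen)
    errors = {
        "mua": relative_error(target.mua, achieved.mua),
        "musp": relative_error(target.musp, achieved.musp),
    }
    return InverseDesignResult(
        ratio=chosen,
        continuous_ratio=continuous,
        achieved=achieved,
        target=target,
        relative_errors=errors,
        feasible=feasible,
        objective=_objective(model, target, chosen.rg, chosen.rw),
    )


def summarize_roi(
    property_map: np.ndarray,
    roi: tuple[int, int, int, int],
    pixel_area_mm2: float,
) -> RoiSummary:
    """Median/std summary of a rectangular ROI of a 2-D property map.

    ``roi`` is (row0, col0, height, width) in pixels.
    """
    r0, c0, h, w = roi
    arr = np.asarray(property_map, dtype=float)
    if arr.ndim != 2:
        raise ValueError("property map must be 2-D")
    if h <= 0 or w <= 0:
        raise ValueError("ROI must be non-empty")
    if r0 < 0 or c0 < 0 or r0 + h > arr.shape[0] or c0 + w > arr.shape[1]:
        raise ValueError(f"ROI {roi} outside map of shape {arr.shape}")
    patch = arr[r0 : r0 + h, c0 : c0 + w]
    vals = patch[np.isfinite(patch)]
    if vals.size == 0:
        raise ValueError("ROI contains no finite pixels")
    std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RoiSummary(
        median=float(np.median(vals)),
        std=std,
        pixel_count=int(vals.size),
        area_mm2=float(vals.size) * pixel_area_mm2,
    )


# ---------------------------------------------------------------------------
# CSV / JSON interchange

_CSV_COLUMNS = ["label", "Rg", "Rw", "Rt", "mua", "musp", "mua_sd", "musp_sd"]


def write_titration_csv(records: Iterable[TitrationRecord], path) -> None:
    rows = [
        {
            "label": r.label,
            "Rg": r.ratio.rg,
            "Rw": r.ratio.rw,
            "Rt": r.ratio.rt,
            "mua": r.measured.mua,
            "musp": r.measured.musp,
            "mua_sd": r.mua_sd,
            "musp_sd": r.musp_sd,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    buf = io.StringIO()
    buf.write("# titration data; mua/musp and dispersions in mm^-1; ratios in percent\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_titration_csv(path) -> list[TitrationRecord]:
    df = pd.read_csv(path, comment="#")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            TitrationRecord(
                ratio=MixingRatio(float(row.Rg), float(row.Rw), float(row.Rt)),
                measured=OpticalProperties(float(row.mua), float(row.musp)),
                mua_sd=float(row.mua_sd),
                musp_sd=float(row.musp_sd),
                label=str(row.label),
            )
        )
    return records
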