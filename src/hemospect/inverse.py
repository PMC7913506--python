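"""Per-pixel inversion: absorbance regression and concentration estimation.

Stage one (``mra1``) regresses the absorbance spectrum on the four bundled
extinction spectra plus an intercept over the 16-point analysis grid. Stage
two (``estimate``) maps the five regression coefficients to concentrations
through an :class:`EmpiricalInverseModel` fitted on simulated spectra (see
:mod:`hemospect.calibration`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from . import chromophores
from .grids import analysis_grid

__all__ = [
    "AbsorbanceSpectrum",
    "Mra1Coefficients",
    "ChromophoreEstimate",
    "EmpiricalInverseModel",
    "REFLECTANCE_FLOOR",
    "absorbance",
    "extinction_design",
    "mra1",
    "mra1_projection",
    "estimate",
    "mixed_saturation",
]

#: reflectance floor applied before the decadic log
REFLECTANCE_FLOOR = 1.0e-4

_COEF_NAMES = ("a_methb", "a_hbo", "a_hbr", "a_m", "a_0")
_TARGET_NAMES = ("c_methb", "c_hbo", "c_hbr", "c_m")


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        a = np.asarray(self.values, float)
        if wl.shape != a.shape:
            raise ValueError("shape mismatch")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", a)


@dataclass(frozen=True)
class Mra1Coefficients:
    a_methb: float
    a_hbo: float
    a_hbr: float
    a_m: float
    a_0: float
    residual_norm: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a_methb, self.a_hbo, self.a_hbr, self.a_m, self.a_0])


@dataclass(frozen=True)
class ChromophoreEstimate:
    """Concentrations in vol.% and StO2 in %, after clipping to physical ranges.

    ``raw`` keeps the unclipped model output; ``clipped`` flags whether any
    clipping occurred. Total hemoglobin includes the metHb component. StO2 is
    NaN when total hemoglobin is zero.
    """

    c_methb: float
    c_hbo: float
    c_hbr: float
    c_m: float
    c_hbt: float
    sto2: float
    clipped: bool = False
    raw: tuple = field(default=(), repr=False)


def absorbance(r, wavelengths=None, floor: float = REFLECTANCE_FLOOR) -> AbsorbanceSpectrum:
    """A(lambda) = log10(1 / r(lambda)) on the analysis grid.

    Reflectance is floored at ``floor`` before the log; a non-positive floor
    is rejected.
    """
    if floor <= 0:
        raise ValueError("reflectance floor must be positive")
    r = np.asarray(r, float)
    wl = analysis_grid().values if wavelengths is None else np.asarray(wavelengths, float)
    if r.shape != wl.shape:
        raise ValueError("reflectance and wavelength grids differ in length")
    a = -np.log10(np.maximum(r, floor))
    return AbsorbanceSpectrum(wl, a)


@lru_cache(maxsize=8)
def _design_cached(wl_key: tuple) -> np.ndarray:
    wl = np.array(wl_key)
    cols = [chromophores.load_extinction(name).at(wl) for name in ("metHb", "HbO", "HbR", "melanin")]
    cols.append(np.ones_like(wl))
    return np.column_stack(cols)


def extinction_design(wavelengths=None) -> np.ndarray:
    """Design matrix [eps_metHb, eps_HbO, eps_HbR, eps_m, 1] on the grid."""
    wl = analysis_grid().values if wavelengths is None else np.asarray(wavelengths, float)
    return _design_cached(tuple(wl.tolist()))


def mra1_projection(wavelengths=None, cond_limit: float = 1.0e12) -> np.ndarray:
    """Pseudo-inverse of the extinction design: one 5 x k matrix mapping an
    absorbance spectrum (or a stack of them) to the five regression
    coefficients. Raises on a near-collinear design."""
    x = extinction_design(wavelengths)
    cond = np.linalg.cond(x)
    if cond > cond_limit:
        raise ValueError(f"extinction predictors are collinear on this grid (cond={cond:.3g})")
    return np.linalg.pinv(x)


def mra1(a: AbsorbanceSpectrum | np.ndarray, wavelengths=None) -> Mra1Coefficients:
    """Ordinary least squares of absorbance on the four extinction spectra."""
    if isinstance(a, AbsorbanceSpectrum):
        y = a.values
        wl = a.wavelengths
    else:
        y = np.asarray(a, float)
        wl = analysis_grid().values if wavelengths is None else np.asarray(wavelengths, float)
    x = extinction_design(wl)
    proj = mra1_projection(wl)
    beta = proj @ y
    resid = y - x @ beta
    return Mra1Coefficients(*beta, residual_norm=float(np.linalg.norm(resid)))


def quadratic_features(coefs: np.ndarray) -> np.ndarray:
    """Feature vector(s) [1, linear(5), squares+cross terms(15)] -> length 21.

    ``coefs`` is shape (..., 5); output shape (..., 21).
    """
    c = np.asarray(coefs, float)
    parts = [np.ones(c.shape[:-1] + (1,)), c]
    idx = np.triu_indices(5)
    quad = c[..., idx[0]] * c[..., idx[1]]
    parts.append(quad)
    return np.concatenate(parts, axis=-1)


def linear_features(coefs: np.ndarray) -> np.ndarray:
    c = np.asarray(coefs, float)
    return np.concatenate([np.ones(c.shape[:-1] + (1,)), c], axis=-1)


_FEATURE_BUILDERS = {"linear": linear_features, "quadratic": quadratic_features}


@dataclass(frozen=True)
class EmpiricalInverseModel:
    """Maps MRA1 coefficient vectors to the four chromophore concentrations.

    One coefficient vector ``b`` of length ``z`` per chromophore, applied to
    a polynomial feature expansion of (a_metHb, a_HbO, a_HbR, a_m, a_0).
    Features are standardized internally (stored mean/scale) because the raw
    coefficients and their products span many orders of magnitude.
    """

    order: str
    b: np.ndarray  # (4, z) in standardized-feature space
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    r_squared: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order not in _FEATURE_BUILDERS:
            raise ValueError(f"unknown feature order {self.order!r}")
        b = np.asarray(self.b, float)
        if b.shape != (4, self.z):
            raise ValueError(f"b must have shape (4, {self.z})")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "feature_mean", np.asarray(self.feature_mean, float))
        object.__setattr__(self, "feature_scale", np.asarray(self.feature_scale, float))

    @property
    def z(self) -> int:
        return {"linear": 6, "quadratic": 21}[self.order]

    def features(self, coefs: np.ndarray) -> np.ndarray:
        raw = _FEATURE_BUILDERS[self.order](coefs)
        return (raw - self.feature_mean) / self.feature_scale

    def predict(self, coefs: np.ndarray) -> np.ndarray:
        """Concentrations, shape (..., 4), order (metHb, HbO, HbR, m)."""
        c = np.asarray(coefs, float)
        if c.shape[-1] != 5:
            raise ValueError("expected 5 MRA1 coefficients in the trailing axis")
        return self.features(c) @ self.b.T

    # --- persistence -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "order": self.order,
            "targets": list(_TARGET_NAMES),
            "b": self.b.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "r_squared": {k: float(v) for k, v in self.r_squared.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "EmpiricalInverseModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            order=payload["order"],
            b=np.asarray(payload["b"], float),
            feature_mean=np.asarray(payload["feature_mean"], float),
            feature_scale=np.asarray(payload["feature_scale"], float),
            r_squared=payload.get("r_squared", {}),
        )


def estimate(coefs: Mra1Coefficients, model: EmpiricalInverseModel) -> ChromophoreEstimate:
    """Concentrations and StO2 from one set of MRA1 coefficients."""
    raw = model.predict(coefs.as_array())
    clipped_vals = np.clip(raw, 0.0, 100.0)
    was_clipped = bool(np.any(clipped_vals != raw))
    c_methb, c_hbo, c_hbr, c_m = clipped_vals
    c_hbt = c_methb + c_hbo + c_hbr
    sto2 = float("nan") if c_hbt <= 0 else float(np.clip(100.0 * c_hbo / c_hbt, 0.0, 100.0))
    return ChromophoreEstimate(
        c_methb=float(c_methb),
        c_hbo=float(c_hbo),
        c_hbr=float(c_hbr),
        c_m=float(c_m),
        c_hbt=float(c_hbt),
        sto2=sto2,
        clipped=was_clipped,
        raw=tuple(float(v) for v in raw),
    )


def mixed_saturation(sao2: float, svo2: float, venous_fraction: float) -> float:
    """Blood-volume-weighted arterio-venous mixture saturation, in %."""
    if not 0.0 <= sao2 <= 100.0 or not 0.0 <= svo2 <= 100.0:
        raise ValueError("saturations must lie in [0, 100] %")
    if not 0.0 <= venous_fraction <= 1.0:
        raise ValueError("venous_fraction must lie in [0, 1]")
    return venous_fraction * svo2 + (1.0 - venous_fraction) * sao2
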