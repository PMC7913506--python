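"""End-to-end per-pixel processing of RGB images into chromophore maps.

The whole-image path is a chain of tensor contractions: Wiener
reconstruction (k x 3 matrix), restriction to the analysis grid, decadic
absorbance, a precomputed 5 x 16 least-squares projection for the
first-stage regression, and the empirical inverse model for concentrations.
No per-pixel Python loops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .camera import WienerModel, reconstruct
from .grids import WavelengthGrid, analysis_grid
from .inverse import EmpiricalInverseModel, REFLECTANCE_FLOOR, mra1_projection

__all__ = [
    "RoiSpec",
    "ChromophoreMaps",
    "TimeSeries",
    "GfcReport",
    "GFC_THRESHOLDS",
    "process_image",
    "roi_stats",
    "delta_series",
    "gfc",
    "gfc_label",
]

QUANTITIES = ("c_methb", "c_hbo", "c_hbr", "c_m", "c_hbt", "sto2")

#: label thresholds: > 0.995, >= 0.999, >= 0.9999
GFC_THRESHOLDS = {"colorimetrically accurate": 0.995, "good": 0.999, "excellent": 0.9999}


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest in pixel coordinates."""

    x0: int = 0
    y0: int = 0
    width: int = 300
    height: int = 300

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI must have positive size")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")

    def slices(self, shape) -> tuple[slice, slice]:
        h, w = shape[:2]
        if self.y0 + self.height > h or self.x0 + self.width > w:
            raise ValueError("ROI extends outside image bounds")
        return slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width)


@dataclass
class ChromophoreMaps:
    """Six per-pixel maps plus processing metadata."""

    maps: dict
    clip_fraction_reflectance: float = 0.0
    floored_fraction: float = 0.0
    clipped_fraction_concentration: float = 0.0

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]

    @property
    def shape(self):
        return next(iter(self.maps.values())).shape

    def to_tiff(self, directory) -> None:
        import tifffile

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.maps.items():
            tifffile.imwrite(directory / f"{name}.tiff", arr.astype(np.float32))
        meta = {
            "units": {q: ("%" if q == "sto2" else "vol.%") for q in self.maps},
            "clip_fraction_reflectance": self.clip_fraction_reflectance,
            "floored_fraction": self.floored_fraction,
            "clipped_fraction_concentration": self.clipped_fraction_concentration,
        }
        (directory / "maps.json").write_text(json.dumps(meta, indent=1))


def process_image(
    rgb: np.ndarray,
    wiener: WienerModel,
    model: EmpiricalInverseModel,
    white_balanced: bool = True,
    floor: float = REFLECTANCE_FLOOR,
) -> ChromophoreMaps:
    """Per-pixel reconstruct -> absorbance -> MRA1 -> concentrations.

    ``rgb`` is (H, W, 3); white-balanced values are rescaled by the stored
    white reference so they match the Wiener model's response units.
    Integer input is normalized by its dtype maximum first.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if np.issubdtype(rgb.dtype, np.integer):
        rgb = rgb.astype(float) / np.iinfo(rgb.dtype).max
    else:
        rgb = rgb.astype(float)
    v = rgb * wiener.white if white_balanced else rgb

    spectra, clip_frac = reconstruct(v, wiener, clip=True, return_clip_fraction=True)

    full = WavelengthGrid(wiener.wavelengths)
    ana = analysis_grid()
    idx = full.indices_of(ana)
    r_ana = spectra[..., idx]

    floored = float((r_ana < floor).mean())
    absorb = -np.log10(np.maximum(r_ana, floor))

    proj = mra1_projection(ana.values)  # (5, 16)
    coefs = absorb @ proj.T  # (H, W, 5)

    raw = model.predict(coefs)  # (H, W, 4)
    conc = np.clip(raw, 0.0, 100.0)
    clipped = float((conc != raw).mean())

    c_methb, c_hbo, c_hbr, c_m = np.moveaxis(conc, -1, 0)
    c_hbt = c_methb + c_hbo + c_hbr
    with np.errstate(invalid="ignore", divide="ignore"):
        sto2 = np.where(c_hbt > 0, 100.0 * c_hbo / np.where(c_hbt > 0, c_hbt, 1.0), np.nan)
    sto2 = np.clip(sto2, 0.0, 100.0)

    return ChromophoreMaps(
        maps={
            "c_methb": c_methb,
            "c_hbo": c_hbo,
            "c_hbr": c_hbr,
            "c_m": c_m,
            "c_hbt": c_hbt,
            "sto2": sto2,
        },
        clip_fraction_reflectance=clip_frac,
        floored_fraction=floored,
        clipped_fraction_concentration=clipped,
    )


def roi_stats(image: np.ndarray, roi: RoiSpec) -> tuple[float, float]:
    """Mean and (population) SD over the ROI, NaN pixels excluded."""
    ys, xs = roi.slices(np.asarray(image).shape)
    patch = np.asarray(image, float)[ys, xs]
    valid = patch[np.isfinite(patch)]
    if valid.size == 0:
        return float("nan"), float("nan")
    return float(valid.mean()), float(valid.std())


@dataclass
class TimeSeries:
    """Per-frame ROI means and SDs of each estimated quantity."""

    times: np.ndarray
    means: dict  # quantity -> (n_frames,)
    sds: dict
    control_index: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        n = self.times.size
        for d in (self.means, self.sds):
            for q, v in d.items():
                v = np.asarray(v, float)
                if v.shape != (n,):
                    raise ValueError(f"series for {q} has wrong length")
                d[q] = v
        if not 0 <= self.control_index < n:
            raise ValueError("control index outside series")

    def to_frame(self, deltas: dict | None = None) -> pd.DataFrame:
        rows = []
        deltas = deltas if deltas is not None else delta_series(self)
        for q in self.means:
            for i, t in enumerate(self.times):
                rows.append(
                    {
                        "time": t,
                        "quantity": q,
                        "mean": self.means[q][i],
                        "sd": self.sds[q][i],
                        "delta": deltas[q][i],
                    }
                )
        return pd.DataFrame(rows)


def delta_series(series: TimeSeries) -> dict:
    """Relative change against the control frame: (M - M_c) / M_c.

    Quantities whose control mean is zero map to NaN.
    """
    out = {}
    for q, values in series.means.items():
        m_c = values[series.control_index]
        if m_c == 0 or not np.isfinite(m_c):
            out[q] = np.full_like(values, np.nan)
        else:
            out[q] = (values - m_c) / m_c
    return out


def gfc_label(value: float) -> str:
    if value >= GFC_THRESHOLDS["excellent"]:
        return "excellent"
    if value >= GFC_THRESHOLDS["good"]:
        return "good"
    if value > GFC_THRESHOLDS["colorimetrically accurate"]:
        return "colorimetrically accurate"
    return "below"


@dataclass(frozen=True)
class GfcReport:
    gfc: float
    label: str


def gfc(r_mes, r_est) -> GfcReport:
    """Goodness-of-fit coefficient: |sum r_mes r_est| over the product of norms."""
    a = np.asarray(r_mes, float).ravel()
    b = np.asarray(r_est, float).ravel()
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm spectrum")
    value = float(min(abs(np.dot(a, b)) / (na * nb), 1.0))
    return GfcReport(value, gfc_label(value))
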