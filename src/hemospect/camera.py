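"""Camera forward model and Wiener-estimation spectral reconstruction.

The camera response is ``v = F r`` with a 3 x 29 system matrix built from
filter transmittances, illuminant and sensor sensitivity. The Wiener matrix

    W = <r r^T> F^T (F <r r^T> F^T + N)^-1

reconstructs a 29-point reflectance spectrum from each RGB triple; the
response autocorrelation may include a noise covariance ``N``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import WavelengthGrid, reconstruction_grid

__all__ = [
    "CameraSpectralModel",
    "TrainingEnsemble",
    "WienerModel",
    "default_camera",
    "system_matrix",
    "autocorrelation",
    "wiener_matrix",
    "train_wiener",
    "reconstruct",
    "white_reference",
    "WHITE_REFLECTANCE",
]

logger = logging.getLogger(__name__)

#: reflectance of the white-balance standard diffuser
WHITE_REFLECTANCE = 0.99


@dataclass(frozen=True)
class CameraSpectralModel:
    """Filter transmittances (3 x k), illuminant and sensitivity on one grid."""

    wavelengths: np.ndarray
    u: np.ndarray  # (3, k) filter transmittances
    illuminant: np.ndarray  # (k,)
    sensitivity: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        u = np.asarray(self.u, float)
        e = np.asarray(self.illuminant, float)
        s = np.asarray(self.sensitivity, float)
        k = wl.size
        if u.shape != (3, k) or e.shape != (k,) or s.shape != (k,):
            raise ValueError("camera spectral tables must share one wavelength grid")
        if np.any(u < 0) or np.any(e < 0) or np.any(s < 0):
            raise ValueError("spectral tables must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "illuminant", e)
        object.__setattr__(self, "sensitivity", s)

    @classmethod
    def from_csv(cls, path) -> "CameraSpectralModel":
        """Profile CSV with columns wavelength_nm, u1, u2, u3, E, S."""
        df = pd.read_csv(path, comment="#")
        return cls(
            df["wavelength_nm"].to_numpy(float),
            df[["u1", "u2", "u3"]].to_numpy(float).T,
            df["E"].to_numpy(float),
            df["S"].to_numpy(float),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "u1": self.u[0],
                "u2": self.u[1],
                "u3": self.u[2],
                "E": self.illuminant,
                "S": self.sensitivity,
            }
        ).to_csv(path, index=False)


def default_camera(grid: WavelengthGrid | None = None) -> CameraSpectralModel:
    """Documented default profile: Gaussian RGB passbands centred at
    610/540/460 nm (R, G, B) with 60 nm FWHM, flat illuminant, flat
    sensitivity. Real deployments supply a manufacturer profile CSV."""
    grid = reconstruction_grid() if grid is None else grid
    wl = grid.values
    sigma = 60.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    centers = (610.0, 540.0, 460.0)
    u = np.stack([np.exp(-0.5 * ((wl - c) / sigma) ** 2) for c in centers])
    return CameraSpectralModel(wl, u, np.ones_like(wl), np.ones_like(wl))


def system_matrix(model: CameraSpectralModel, grid: WavelengthGrid | None = None) -> np.ndarray:
    """3 x k system matrix F: row i is u_i * E * S, scaled by the grid step."""
    if grid is not None and not np.array_equal(grid.values, model.wavelengths):
        raise ValueError("camera profile grid does not match the requested grid")
    step = float(model.wavelengths[1] - model.wavelengths[0])
    return model.u * model.illuminant * model.sensitivity * step


@dataclass(frozen=True)
class TrainingEnsemble:
    """A set of reflectance spectra on the reconstruction grid."""

    spectra: np.ndarray  # (n, k)

    def __post_init__(self) -> None:
        spectra = np.atleast_2d(np.asarray(self.spectra, float))
        if spectra.shape[0] < 1:
            raise ValueError("ensemble must contain at least one spectrum")
        if np.any(spectra < 0) or np.any(spectra > 1):
            raise ValueError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "spectra", spectra)

    def __len__(self) -> int:
        return int(self.spectra.shape[0])

    @classmethod
    def from_csv(cls, path) -> "TrainingEnsemble":
        df = pd.read_csv(path, comment="#")
        cols = [c for c in df.columns if c.startswith("r_")]
        return cls(df[cols].to_numpy(float))


def autocorrelation(ensemble: TrainingEnsemble) -> np.ndarray:
    """<r r^T>: average outer product over the ensemble; symmetric PSD."""
    r = ensemble.spectra
    return r.T @ r / r.shape[0]


def wiener_matrix(
    acorr: np.ndarray, f: np.ndarray, noise_cov: np.ndarray | None = None
) -> np.ndarray:
    """W = <r r^T> F^T (F <r r^T> F^T + N)^-1, pseudo-inverted when singular."""
    acorr = np.asarray(acorr, float)
    f = np.asarray(f, float)
    if acorr.ndim != 2 or acorr.shape[0] != acorr.shape[1]:
        raise ValueError("autocorrelation must be square")
    if f.ndim != 2 or f.shape[1] != acorr.shape[0]:
        raise ValueError("F and the autocorrelation matrix have mismatched shapes")
    if not np.allclose(acorr, acorr.T, atol=1e-10 * max(1.0, np.abs(acorr).max())):
        raise ValueError("autocorrelation must be symmetric")
    core = f @ acorr @ f.T
    if noise_cov is not None:
        noise_cov = np.asarray(noise_cov, float)
        if noise_cov.shape != core.shape:
            raise ValueError("noise covariance must be 3 x 3")
        core = core + noise_cov
    return acorr @ f.T @ np.linalg.pinv(core)


@dataclass(frozen=True)
class WienerModel:
    """System matrix, estimation matrix and white reference for one camera."""

    wavelengths: np.ndarray
    f: np.ndarray  # (3, k)
    w: np.ndarray  # (k, 3)
    white: np.ndarray = field(default=None)  # (3,) response to the white standard

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        f = np.asarray(self.f, float)
        w = np.asarray(self.w, float)
        k = wl.size
        if f.shape != (3, k) or w.shape != (k, 3):
            raise ValueError("F must be 3 x k and W must be k x 3")
        white = self.white
        white = f @ np.full(k, WHITE_REFLECTANCE) if white is None else np.asarray(white, float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "white", white)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "wavelengths": self.wavelengths.tolist(),
                    "F": self.f.tolist(),
                    "W": self.w.tolist(),
                    "white": self.white.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "WienerModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["wavelengths"], float),
            np.asarray(d["F"], float),
            np.asarray(d["W"], float),
            np.asarray(d["white"], float),
        )


def white_reference(camera: CameraSpectralModel) -> np.ndarray:
    """Camera response to the 99 %-reflectance white standard."""
    return system_matrix(camera) @ np.full(camera.wavelengths.size, WHITE_REFLECTANCE)


def train_wiener(
    ensemble: TrainingEnsemble,
    camera: CameraSpectralModel,
    noise_cov: np.ndarray | None = None,
) -> WienerModel:
    f = system_matrix(camera)
    w = wiener_matrix(autocorrelation(ensemble), f, noise_cov)
    return WienerModel(camera.wavelengths, f, w, white_reference(camera))


def reconstruct(
    v: np.ndarray,
    model: WienerModel,
    clip: bool = True,
    return_clip_fraction: bool = False,
):
    """Wiener reconstruction r = W v for one response or an RGB image.

    ``v`` has 3 channels in its trailing axis; output appends a k-length
    spectral axis. Values are clipped to [0, 1] and the clipped fraction is
    logged (warning above 1 %).
    """
    v = np.asarray(v, float)
    if v.shape[-1] != 3:
        raise ValueError("expected 3 channels in the trailing axis")
    if np.any(v < 0):
        raise ValueError("camera responses must be non-negative")
    spectra = v @ model.w.T
    clip_fraction = 0.0
    if clip:
        outside = (spectra < 0.0) | (spectra > 1.0)
        clip_fraction = float(outside.mean())
        if clip_fraction > 0.01:
            logger.warning("clipped %.2f%% of reconstructed reflectance values", 100 * clip_fraction)
        spectra = np.clip(spectra, 0.0, 1.0)
    if return_clip_fraction:
        return spectra, clip_fraction
    return spectra
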