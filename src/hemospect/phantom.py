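"""Synthetic ground-truthed scenes, RGB renders and image time series.

A :class:`PhantomForward` interpolates simulated diffuse reflectance over a
tensor-product concentration grid parameterized as (melanin, total
hemoglobin, functional saturation, metHb fraction), which keeps every axis
combination physically feasible. Scenes are rendered to camera responses
through the system matrix, white-balanced, and optionally degraded with
Gaussian noise and quantization. Every artifact carries its ground truth
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import skin_layers
from .camera import CameraSpectralModel, system_matrix, white_reference
from .grids import WavelengthGrid, reconstruction_grid
from .mcsim import McConfig, ScatteringModel, simulate_spectrum

__all__ = [
    "PhantomForward",
    "PhantomScene",
    "PhantomFrame",
    "build_phantom_forward",
    "render_scene",
    "training_spectra",
    "methemoglobinemia_series",
    "pulse_peak_time",
]


@dataclass(frozen=True)
class PhantomForward:
    """Multilinear interpolator of reflectance spectra over the forward grid.

    Axes: melanin vol.%, total hemoglobin vol.%, functional saturation
    C_HbO/(C_HbO+C_HbR) in [0, 1], metHb fraction of HbT in [0, 1].
    """

    c_m_axis: np.ndarray
    c_hbt_axis: np.ndarray
    s_func_axis: np.ndarray
    f_met_axis: np.ndarray
    wavelengths: np.ndarray
    values: np.ndarray  # (n_m, n_hbt, n_s, n_f, k)

    def __post_init__(self) -> None:
        expected = (
            len(self.c_m_axis),
            len(self.c_hbt_axis),
            len(self.s_func_axis),
            len(self.f_met_axis),
            len(self.wavelengths),
        )
        if tuple(np.asarray(self.values).shape) != expected:
            raise ValueError(f"values must have shape {expected}")

    def _interp(self):
        from scipy.interpolate import RegularGridInterpolator

        return RegularGridInterpolator(
            (self.c_m_axis, self.c_hbt_axis, self.s_func_axis, self.f_met_axis),
            self.values,
            method="linear",
            bounds_error=True,
        )

    def spectra(self, c_methb, c_hbo, c_hbr, c_m) -> np.ndarray:
        """Reflectance spectra for arrays of concentrations (broadcastable)."""
        c_methb, c_hbo, c_hbr, c_m = np.broadcast_arrays(
            *(np.atleast_1d(np.asarray(v, float)) for v in (c_methb, c_hbo, c_hbr, c_m))
        )
        c_hbt = c_methb + c_hbo + c_hbr
        if np.any(c_hbt <= 0):
            raise ValueError("total hemoglobin must be positive everywhere")
        f_met = c_methb / c_hbt
        func = c_hbo + c_hbr
        with np.errstate(invalid="ignore", divide="ignore"):
            s_func = np.where(func > 0, c_hbo / np.where(func > 0, func, 1.0), 0.0)
        pts = np.stack(
            [c_m.ravel(), c_hbt.ravel(), s_func.ravel(), f_met.ravel()], axis=-1
        )
        out = self._interp()(pts)
        return out.reshape(c_m.shape + (len(self.wavelengths),))


def build_phantom_forward(
    c_m_axis=(1.0, 5.0, 10.0),
    c_hbt_axis=(0.2, 0.6, 1.0),
    s_func_axis=(0.0, 0.5, 1.0),
    f_met_axis=(0.0, 0.3, 0.6),
    wavelengths: WavelengthGrid | None = None,
    mc: McConfig = McConfig(n_photons=10_000),
    scattering: ScatteringModel = ScatteringModel(),
    paths=None,
) -> PhantomForward:
    """Simulate the forward grid once; one Monte Carlo spectrum per node.

    A prebuilt :class:`hemospect.calibration.SkinPathLibrary` on the same
    wavelength grid evaluates all nodes from shared photon traces.
    """
    grid = reconstruction_grid() if wavelengths is None else wavelengths
    axes = tuple(np.asarray(ax, float) for ax in (c_m_axis, c_hbt_axis, s_func_axis, f_met_axis))
    shape = tuple(len(ax) for ax in axes) + (len(grid),)

    mesh_m, mesh_hbt, mesh_s, mesh_f = np.meshgrid(*axes, indexing="ij")
    mesh_methb = mesh_f * mesh_hbt
    mesh_hbo = mesh_s * (1.0 - mesh_f) * mesh_hbt
    mesh_hbr = (1.0 - mesh_s) * (1.0 - mesh_f) * mesh_hbt

    if paths is not None:
        if not np.array_equal(paths.wavelengths, grid.values):
            raise ValueError("path library wavelengths do not match the requested grid")
        values = paths.spectra(mesh_methb, mesh_hbo, mesh_hbr, mesh_m)
        return PhantomForward(*axes, grid.values, values)

    values = np.empty(shape)
    counter = 0
    for idx in np.ndindex(shape[:-1]):
        c_methb = float(mesh_methb[idx])
        c_hbo = float(mesh_hbo[idx])
        c_hbr = float(mesh_hbr[idx])
        c_m = float(mesh_m[idx])
        counter += 1
        cfg = replace(mc, seed=mc.seed + counter)
        values[idx] = simulate_spectrum(
            lambda wl: skin_layers(c_methb, c_hbo, c_hbr, c_m, wl, scattering),
            grid,
            cfg,
        )
    return PhantomForward(*axes, grid.values, values)


def training_spectra(forward: PhantomForward, n: int = 440, seed: int = 0) -> np.ndarray:
    """``n`` spectra sampled uniformly over the forward grid's hull.

    Used as the default Wiener training ensemble in place of measured skin
    spectra.
    """
    rng = np.random.default_rng(seed)
    c_m = rng.uniform(forward.c_m_axis[0], forward.c_m_axis[-1], n)
    c_hbt = rng.uniform(forward.c_hbt_axis[0], forward.c_hbt_axis[-1], n)
    s = rng.uniform(forward.s_func_axis[0], forward.s_func_axis[-1], n)
    f = rng.uniform(forward.f_met_axis[0], forward.f_met_axis[-1], n)
    c_methb = f * c_hbt
    c_hbo = s * (1 - f) * c_hbt
    c_hbr = (1 - s) * (1 - f) * c_hbt
    return np.clip(forward.spectra(c_methb, c_hbo, c_hbr, c_m), 0.0, 1.0)


@dataclass(frozen=True)
class PhantomScene:
    """Per-pixel ground-truth concentration maps plus a noise model."""

    c_methb: np.ndarray
    c_hbo: np.ndarray
    c_hbr: np.ndarray
    c_m: np.ndarray
    seed: int
    noise_sigma: float = 0.005  # additive Gaussian, fraction of full scale
    bit_depth: int = 8

    def __post_init__(self) -> None:
        shape = np.asarray(self.c_methb).shape
        for name in ("c_hbo", "c_hbr", "c_m"):
            if np.asarray(getattr(self, name)).shape != shape:
                raise ValueError("all truth maps must share one shape")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.bit_depth < 1:
            raise ValueError("bit depth must be >= 1")
        for name in ("c_methb", "c_hbo", "c_hbr", "c_m"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))

    @classmethod
    def uniform(cls, shape, c_methb, c_hbo, c_hbr, c_m, seed, **kw) -> "PhantomScene":
        full = np.full(shape, 1.0)
        return cls(full * c_methb, full * c_hbo, full * c_hbr, full * c_m, seed=seed, **kw)


@dataclass(frozen=True)
class PhantomFrame:
    """White-balanced RGB image plus its spectral and concentration truth."""

    rgb: np.ndarray  # (H, W, 3), white-balanced, in [0, 1]
    spectra: np.ndarray  # (H, W, k) noiseless reflectance truth
    scene: PhantomScene


def render_scene(
    scene: PhantomScene,
    forward: PhantomForward,
    camera: CameraSpectralModel,
    rng: np.random.Generator | None = None,
) -> PhantomFrame:
    """Forward-render a scene: interpolated spectra -> v = F r -> white
    balance -> noise -> quantization. Deterministic for a given seed."""
    if not np.array_equal(camera.wavelengths, forward.wavelengths):
        raise ValueError("camera and forward model use different wavelength grids")
    rng = np.random.default_rng(scene.seed) if rng is None else rng
    spectra = forward.spectra(scene.c_methb, scene.c_hbo, scene.c_hbr, scene.c_m)
    f = system_matrix(camera)
    v = spectra @ f.T
    dn = v / white_reference(camera)
    if scene.noise_sigma > 0:
        dn = dn + rng.normal(0.0, scene.noise_sigma, dn.shape)
    levels = 2**scene.bit_depth - 1
    dn = np.clip(np.round(np.clip(dn, 0.0, 1.0) * levels) / levels, 0.0, 1.0)
    return PhantomFrame(dn, spectra, scene)


def pulse_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Argmax of exp(-t/tau_decay) - exp(-t/tau_rise), closed form."""
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if tau_rise == tau_decay:
        return tau_rise
    return np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def methemoglobinemia_series(
    baseline: PhantomScene,
    forward: PhantomForward,
    camera: CameraSpectralModel,
    peak_methb: float,
    tau_rise: float,
    tau_decay: float,
    n_frames: int,
    t_max: float | None = None,
):
    """Render a rise-then-recovery metHb pulse as an image time series.

    metHb follows a double-exponential pulse peaking at ``peak_methb`` above
    baseline; HbO is reduced by the same amount so total hemoglobin stays
    constant. Returns (frames, truth) where truth is a tidy frame of the
    scene-mean concentrations per time point.
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if peak_methb < 0:
        raise ValueError("peak metHb must be non-negative")
    if np.any(baseline.c_hbo - peak_methb < 0):
        raise ValueError("peak metHb exceeds baseline HbO; total hemoglobin cannot be held")

    t_star = pulse_peak_time(tau_rise, tau_decay)
    norm = np.exp(-t_star / tau_decay) - np.exp(-t_star / tau_rise)
    times = (
        np.array([0.0])
        if n_frames == 1
        else np.linspace(0.0, 3.0 * tau_decay if t_max is None else t_max, n_frames)
    )

    rng = np.random.default_rng(baseline.seed)
    frames = []
    truth_rows = []
    for t in times:
        pulse = (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / norm
        delta = peak_methb * pulse
        scene = replace(
            baseline,
            c_methb=baseline.c_methb + delta,
            c_hbo=baseline.c_hbo - delta,
        )
        frames.append(render_scene(scene, forward, camera, rng=rng))
        truth_rows.append(
            {
                "time": t,
                "c_methb": float(np.mean(scene.c_methb)),
                "c_hbo": float(np.mean(scene.c_hbo)),
                "c_hbr": float(np.mean(scene.c_hbr)),
                "c_m": float(np.mean(scene.c_m)),
            }
        )
    return frames, pd.DataFrame(truth_rows)
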