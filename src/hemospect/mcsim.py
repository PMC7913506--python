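"""Steady-state diffuse reflectance of layered tissue by photon-packet Monte Carlo.

The public surface is :func:`simulate` (one wavelength, one layer stack) and
:func:`simulate_spectrum` (one run per wavelength of a grid, with
deterministically derived per-wavelength seeds). A pencil beam enters the
top surface at normal incidence; total diffuse reflectance is tallied over
the whole top surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._mckernel import _splitmix64, run_photons
from .grids import WavelengthGrid

__all__ = [
    "TissueLayer",
    "McConfig",
    "McResult",
    "ScatteringModel",
    "simulate",
    "simulate_spectrum",
    "PathSet",
    "trace_paths",
    "SEMI_INFINITE",
]

#: thickness (mm) treated as effectively semi-infinite
SEMI_INFINITE = 1.0e7


@dataclass(frozen=True)
class TissueLayer:
    """One homogeneous slab: optical properties and thickness in mm."""

    thickness: float
    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("layer thickness must be positive")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class McConfig:
    """Photon-count, seed and termination settings for one simulation."""

    n_photons: int = 100_000
    seed: int = 0
    weight_threshold: float = 1.0e-4
    roulette_survival: float = 0.1
    ambient_n: float = 1.0
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette_survival must be in (0, 1)")
        if not self.weight_threshold > 0:
            raise ValueError("weight_threshold must be positive")
        if self.ambient_n < 1.0:
            raise ValueError("ambient refractive index must be >= 1")


@dataclass(frozen=True)
class McResult:
    """Fate of the launched unit weight, as fractions summing to one."""

    r_specular: float
    r_diffuse: float
    t_diffuse: float
    absorbed: float
    lost_roulette: float
    n_photons: int

    @property
    def total(self) -> float:
        return (
            self.r_specular
            + self.r_diffuse
            + self.t_diffuse
            + self.absorbed
            + self.lost_roulette
        )


@dataclass(frozen=True)
class ScatteringModel:
    """Power-law reduced scattering: mu_s'(lambda) = a * (lambda/500 nm)^-b.

    Stand-in for literature scattering curves of epidermis/dermis; ``a`` in
    mm^-1 at 500 nm. ``mu_s = mu_s' / (1 - g)``.
    """

    a: float = 4.6
    b: float = 1.4
    g: float = 0.9

    def mu_s_prime(self, wavelength_nm: float) -> float:
        return self.a * (wavelength_nm / 500.0) ** (-self.b)

    def mu_s(self, wavelength_nm: float) -> float:
        return self.mu_s_prime(wavelength_nm) / (1.0 - self.g)


def _pack(layers: Sequence[TissueLayer]):
    z_bounds = np.concatenate([[0.0], np.cumsum([la.thickness for la in layers])])
    mu_a = np.array([la.mu_a for la in layers], float)
    mu_s = np.array([la.mu_s for la in layers], float)
    g = np.array([la.g for la in layers], float)
    n = np.array([la.n for la in layers], float)
    return z_bounds, mu_a, mu_s, g, n


def simulate(layers: Sequence[TissueLayer], config: McConfig = McConfig()) -> McResult:
    """Run one Monte Carlo simulation; deterministic for a given seed."""
    layers = list(layers)
    if not layers:
        raise ValueError("at least one tissue layer is required")
    z_bounds, mu_a, mu_s, g, n = _pack(layers)
    r_sp, r_d, t_d, absorbed, lost = run_photons(
        z_bounds,
        mu_a,
        mu_s,
        g,
        n,
        float(config.ambient_n),
        int(config.n_photons),
        np.uint64(config.seed & 0xFFFFFFFFFFFFFFFF),
        float(config.weight_threshold),
        float(config.roulette_survival),
        int(config.max_steps),
    )
    return McResult(r_sp, r_d, t_d, absorbed, lost, config.n_photons)


def derive_seed(seed: int, index: int) -> int:
    """Deterministic per-wavelength sub-seed."""
    return int(_splitmix64(np.uint64((seed ^ 0xA5A5A5A5A5A5A5A5) + 977 * index & 0xFFFFFFFFFFFFFFFF)))


def simulate_spectrum(
    tissue_builder: Callable[[float], Sequence[TissueLayer]] | Mapping[float, Sequence[TissueLayer]],
    grid: WavelengthGrid,
    config: McConfig = McConfig(),
) -> np.ndarray:
    """Diffuse reflectance at every wavelength of ``grid``.

    ``tissue_builder`` maps a wavelength (nm) to a layer stack; it may be a
    callable or a mapping keyed by wavelength. Per-wavelength seeds are
    derived deterministically from ``config.seed``.
    """
    if isinstance(tissue_builder, Mapping):
        mapping = tissue_builder

        def builder(wl: float) -> Sequence[TissueLayer]:
            if wl not in mapping:
                raise KeyError(f"tissue builder has no entry for {wl:g} nm")
            return mapping[wl]

    else:
        builder = tissue_builder

    out = np.empty(len(grid))
    for j, wl in enumerate(grid.values):
        sub = McConfig(
            n_photons=config.n_photons,
            seed=derive_seed(config.seed, j),
            weight_threshold=config.weight_threshold,
            roulette_survival=config.roulette_survival,
            ambient_n=config.ambient_n,
            max_steps=config.max_steps,
        )
        out[j] = simulate(builder(float(wl)), sub).r_diffuse
    return out


@dataclass(frozen=True)
class PathSet:
    """Per-photon path lengths of top-escaping photons in a scattering-only run.

    Supports exact reweighting: for absorption coefficients ``mu_a`` (one per
    layer) the diffuse reflectance is the mean over launched photons of
    ``(1 - r_specular) * exp(-sum_l mu_a[l] * L[l])`` for escapers (zero for
    the rest). One trace therefore serves every absorption combination at
    fixed scattering, geometry and refractive indices (correlated sampling).
    """

    r_specular: float
    n_photons: int
    lengths: np.ndarray  # (n_escaped, n_layers)

    def reflectance(self, mu_a):
        """Diffuse reflectance for absorption row(s) ``mu_a`` of shape
        (..., n_layers); returns a float for a single row, else an array of
        the leading shape."""
        mu_in = np.asarray(mu_a, float)
        mu = mu_in.reshape(-1, mu_in.shape[-1]) if mu_in.ndim > 1 else mu_in[None, :]
        if np.any(mu < 0):
            raise ValueError("mu_a must be non-negative")
        if mu.shape[-1] != self.lengths.shape[1]:
            raise ValueError("mu_a row length must equal the number of layers")
        atten = np.exp(-(self.lengths @ mu.T))  # (n_escaped, M)
        rd = (1.0 - self.r_specular) * atten.sum(axis=0) / self.n_photons
        if mu_in.ndim == 1:
            return float(rd[0])
        return rd.reshape(mu_in.shape[:-1])


def trace_paths(layers: Sequence[TissueLayer], config: McConfig = McConfig()) -> PathSet:
    """Scattering-only trace recording per-layer path lengths of top escapers.

    ``mu_a`` of the supplied layers is ignored (treated as zero).
    """
    from ._mckernel import run_photon_paths

    layers = list(layers)
    if not layers:
        raise ValueError("at least one tissue layer is required")
    z_bounds, _, mu_s, g, n = _pack(layers)
    r_sp, n_top, lengths = run_photon_paths(
        z_bounds,
        mu_s,
        g,
        n,
        float(config.ambient_n),
        int(config.n_photons),
        np.uint64(config.seed & 0xFFFFFFFFFFFFFFFF),
        int(config.max_steps),
    )
    return PathSet(r_sp, config.n_photons, lengths[:n_top].copy())
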