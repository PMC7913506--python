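"""Simulated-spectra library and second-stage regression (MRA2).

The calibration grid crosses epidermal melanin (1-10 vol.%), dermal total
hemoglobin (0.2-1.0 vol.%) and 31 oxygenation/methemoglobin states per
cell, for 1550 combinations in all. Each grid point is simulated with the
layered Monte Carlo model; the first-stage regression (MRA1) is run on each
simulated spectrum, and MRA2 regresses the true concentrations on a
polynomial expansion of the MRA1 coefficients.

The 31 states are a documented reconstruction: tissue oxygen saturation
StO2 = C_HbO / C_HbT in multiples of 10% crossed with metHb fractions
{0, 0.1, 0.2} subject to StO2 <= 100 * (1 - fraction), plus one fully
methemoglobinized state (fraction 1, StO2 0). That is 11 + 10 + 9 + 1 = 31.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import chromophores
from .grids import WavelengthGrid, analysis_grid
from .inverse import EmpiricalInverseModel, Mra1Coefficients, absorbance, mra1, _FEATURE_BUILDERS
from .mcsim import (
    McConfig,
    ScatteringModel,
    TissueLayer,
    derive_seed,
    simulate_spectrum,
    trace_paths,
)

__all__ = [
    "GridSpec",
    "CalibrationRecord",
    "CalibrationDataset",
    "EmpiricalInverseModel",
    "SkinPathLibrary",
    "default_hb_states",
    "skin_layers",
    "build_dataset",
    "fit_mra2",
    "leave_one_out",
    "EPIDERMIS_THICKNESS_MM",
    "DERMIS_THICKNESS_MM",
    "TISSUE_REFRACTIVE_INDEX",
]

EPIDERMIS_THICKNESS_MM = 0.06
DERMIS_THICKNESS_MM = 4.94
TISSUE_REFRACTIVE_INDEX = 1.4


def default_hb_states() -> list[tuple[float, float]]:
    """The 31 (StO2 %, metHb fraction of HbT) states per grid cell."""
    states: list[tuple[float, float]] = []
    for frac in (0.0, 0.1, 0.2):
        top = int(round(100.0 * (1.0 - frac)))
        for sto2 in range(0, top + 1, 10):
            states.append((float(sto2), frac))
    states.append((0.0, 1.0))
    return states


@dataclass(frozen=True)
class GridSpec:
    """Axes of the calibration grid, all in vol.% except the state list."""

    c_m_values: tuple = tuple(float(v) for v in range(1, 11))
    c_hbt_values: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    hb_states: tuple = field(default_factory=lambda: tuple(default_hb_states()))

    def __post_init__(self) -> None:
        if any(not 0 <= v <= 100 for v in self.c_m_values):
            raise ValueError("melanin values must lie in [0, 100] vol.%")
        if any(not 0 < v <= 100 for v in self.c_hbt_values):
            raise ValueError("total-hemoglobin values must lie in (0, 100] vol.%")
        for sto2, frac in self.hb_states:
            if not 0 <= sto2 <= 100 or not 0 <= frac <= 1:
                raise ValueError("hb state out of range")
            if sto2 > 100.0 * (1.0 - frac) + 1e-9:
                raise ValueError(f"infeasible state: StO2={sto2}, metHb fraction={frac}")

    def __len__(self) -> int:
        return len(self.c_m_values) * len(self.c_hbt_values) * len(self.hb_states)

    def points(self):
        """Yield (c_methb, c_hbo, c_hbr, c_m) for every grid combination."""
        for c_m in self.c_m_values:
            for c_hbt in self.c_hbt_values:
                for sto2, frac in self.hb_states:
                    c_methb = frac * c_hbt
                    c_hbo = sto2 / 100.0 * c_hbt
                    c_hbr = max(c_hbt - c_methb - c_hbo, 0.0)
                    yield (c_methb, c_hbo, c_hbr, float(c_m))


@dataclass(frozen=True)
class CalibrationRecord:
    """Ground truth, simulated spectrum and MRA1 coefficients for one point."""

    c_methb: float
    c_hbo: float
    c_hbr: float
    c_m: float
    wavelengths: np.ndarray
    reflectance: np.ndarray
    coefficients: Mra1Coefficients

    @property
    def c_hbt(self) -> float:
        return self.c_methb + self.c_hbo + self.c_hbr

    @property
    def sto2(self) -> float:
        return 100.0 * self.c_hbo / self.c_hbt if self.c_hbt > 0 else float("nan")

    def analysis_reflectance(self) -> np.ndarray:
        """Reflectance restricted to the 16-point analysis grid."""
        grid = WavelengthGrid(self.wavelengths)
        idx = grid.indices_of(analysis_grid())
        return self.reflectance[idx]


def skin_layers(
    c_methb: float,
    c_hbo: float,
    c_hbr: float,
    c_m: float,
    wavelength_nm: float,
    scattering: ScatteringModel = ScatteringModel(),
) -> list[TissueLayer]:
    """Two-layer epidermis/dermis stack for one wavelength.

    Epidermal absorption comes from melanin, dermal absorption from the
    three hemoglobin derivatives; both layers share the scattering model and
    a refractive index of 1.4.
    """
    mu_a_epi = float(chromophores.melanin_mu_a(c_m, [wavelength_nm]).mu_a[0])
    mu_a_derm = float(
        chromophores.total_hemoglobin_mu_a(c_methb, c_hbo, c_hbr, [wavelength_nm]).mu_a[0]
    )
    mu_s = scattering.mu_s(wavelength_nm)
    g = scattering.g
    return [
        TissueLayer(EPIDERMIS_THICKNESS_MM, mu_a_epi, mu_s, g, TISSUE_REFRACTIVE_INDEX),
        TissueLayer(DERMIS_THICKNESS_MM, mu_a_derm, mu_s, g, TISSUE_REFRACTIVE_INDEX),
    ]


@dataclass(frozen=True)
class SkinPathLibrary:
    """One scattering-only photon trace per wavelength for the skin geometry.

    Scattering, anisotropy, refractive index and layer thicknesses are fixed
    across the calibration grid, so a single trace per wavelength serves
    every absorption combination through exponential path reweighting
    (correlated sampling; unbiased for each point and far cheaper than one
    full simulation per grid point). Grid points evaluated from one library
    share photon noise, unlike independently seeded direct simulations.
    """

    wavelengths: np.ndarray
    path_sets: tuple
    scattering: ScatteringModel
    n_photons: int
    seed: int

    @classmethod
    def build(
        cls,
        grid: WavelengthGrid,
        mc: McConfig = McConfig(n_photons=30_000),
        scattering: ScatteringModel = ScatteringModel(),
    ) -> "SkinPathLibrary":
        sets = []
        for j, wl in enumerate(grid.values):
            layers = skin_layers(0.0, 0.0, 0.0, 0.0, float(wl), scattering)
            cfg = McConfig(
                n_photons=mc.n_photons,
                seed=derive_seed(mc.seed, j),
                weight_threshold=mc.weight_threshold,
                roulette_survival=mc.roulette_survival,
                ambient_n=mc.ambient_n,
                max_steps=mc.max_steps,
            )
            sets.append(trace_paths(layers, cfg))
        return cls(grid.values, tuple(sets), scattering, mc.n_photons, mc.seed)

    def spectra(self, c_methb, c_hbo, c_hbr, c_m) -> np.ndarray:
        """Reflectance spectra for concentration arrays, shape (..., K)."""
        c_methb, c_hbo, c_hbr, c_m = np.broadcast_arrays(
            *(np.atleast_1d(np.asarray(v, float)) for v in (c_methb, c_hbo, c_hbr, c_m))
        )
        shape = c_methb.shape
        flat = [v.ravel() for v in (c_methb, c_hbo, c_hbr, c_m)]
        wl = self.wavelengths
        unit_mel = chromophores.melanin_mu_a(1.0, wl).mu_a
        units = [
            chromophores.hemoglobin_mu_a(chromophores.load_extinction(n, wl), 1.0).mu_a
            for n in ("metHb", "HbO", "HbR")
        ]
        mu_epi = np.outer(flat[3], unit_mel)  # (M, K)
        mu_derm = sum(np.outer(c, u) for c, u in zip(flat[:3], units))
        out = np.empty((flat[0].size, wl.size))
        for j, ps in enumerate(self.path_sets):
            out[:, j] = ps.reflectance(np.stack([mu_epi[:, j], mu_derm[:, j]], axis=-1))
        return out.reshape(shape + (wl.size,))


@dataclass
class CalibrationDataset:
    records: list
    wavelengths: np.ndarray
    mc_photons: int
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "c_methb": rec.c_methb,
                "c_hbo": rec.c_hbo,
                "c_hbr": rec.c_hbr,
                "c_m": rec.c_m,
            }
            for wl, r in zip(rec.wavelengths, rec.reflectance):
                row[f"r_{int(round(wl))}"] = r
            for name, val in zip(
                ("a_methb", "a_hbo", "a_hbr", "a_m", "a_0"), rec.coefficients.as_array()
            ):
                row[name] = val
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationDataset":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("r_")]
        wavelengths = np.array([float(c[2:]) for c in wl_cols])
        records = []
        for _, row in df.iterrows():
            coefs = Mra1Coefficients(
                row["a_methb"], row["a_hbo"], row["a_hbr"], row["a_m"], row["a_0"]
            )
            records.append(
                CalibrationRecord(
                    row["c_methb"],
                    row["c_hbo"],
                    row["c_hbr"],
                    row["c_m"],
                    wavelengths,
                    row[wl_cols].to_numpy(float),
                    coefs,
                )
            )
        return cls(records, wavelengths, mc_photons=0, seed=0)


def build_dataset(
    grid: GridSpec = GridSpec(),
    mc: McConfig = McConfig(n_photons=10_000),
    wavelengths: WavelengthGrid | None = None,
    scattering: ScatteringModel = ScatteringModel(),
    paths: SkinPathLibrary | None = None,
    progress: bool = False,
) -> CalibrationDataset:
    """Simulate one diffuse reflectance spectrum per grid combination.

    ``wavelengths`` defaults to the 16-point analysis grid; pass the
    29-point reconstruction grid to also cover the Wiener range (MRA1 always
    uses the analysis subset). Per-point seeds derive from ``mc.seed``.

    When a :class:`SkinPathLibrary` is supplied, spectra are evaluated from
    its shared photon traces instead of one direct simulation per point.
    """
    wl_grid = analysis_grid() if wavelengths is None else wavelengths
    ana = analysis_grid()
    idx = wl_grid.indices_of(ana)
    points = list(grid.points())

    if paths is not None:
        if not np.array_equal(paths.wavelengths, wl_grid.values):
            raise ValueError("path library wavelengths do not match the requested grid")
        conc = np.array(points)
        spectra = paths.spectra(conc[:, 0], conc[:, 1], conc[:, 2], conc[:, 3])
        records = []
        for (c_methb, c_hbo, c_hbr, c_m), refl in zip(points, spectra):
            coefs = mra1(absorbance(refl[idx]))
            records.append(
                CalibrationRecord(c_methb, c_hbo, c_hbr, c_m, wl_grid.values, refl, coefs)
            )
        return CalibrationDataset(records, wl_grid.values, paths.n_photons, paths.seed)

    records = []
    for k, (c_methb, c_hbo, c_hbr, c_m) in enumerate(points):
        point_mc = McConfig(
            n_photons=mc.n_photons,
            seed=mc.seed + 1 + k,
            weight_threshold=mc.weight_threshold,
            roulette_survival=mc.roulette_survival,
            ambient_n=mc.ambient_n,
            max_steps=mc.max_steps,
        )

        def builder(wl: float):
            return skin_layers(c_methb, c_hbo, c_hbr, c_m, wl, scattering)

        try:
            refl = simulate_spectrum(builder, wl_grid, point_mc)
        except Exception as exc:  # attach grid coordinates to MC failures
            raise RuntimeError(
                f"Monte Carlo failed at grid point C_metHb={c_methb:g}, "
                f"C_HbO={c_hbo:g}, C_HbR={c_hbr:g}, C_m={c_m:g}: {exc}"
            ) from exc
        coefs = mra1(absorbance(refl[idx]))
        records.append(
            CalibrationRecord(c_methb, c_hbo, c_hbr, c_m, wl_grid.values, refl, coefs)
        )
        if progress and (k + 1) % 50 == 0:
            print(f"  simulated {k + 1}/{len(points)} grid points", flush=True)
    return CalibrationDataset(records, wl_grid.values, mc.n_photons, mc.seed)


def cycle_through_camera(dataset: CalibrationDataset, wiener) -> CalibrationDataset:
    """Re-derive every record's MRA1 coefficients from camera-cycled spectra.

    Each simulated spectrum is projected to RGB through the system matrix and
    reconstructed with the Wiener matrix before the first-stage regression.
    Fitting MRA2 on these records makes the inverse model consistent with the
    information that actually survives the three-channel camera, which
    matters when the camera profile is generic rather than measured: the
    spectral-domain model can otherwise misread reconstruction residuals.
    """
    from .inverse import absorbance as _absorbance, mra1 as _mra1

    wl_grid = WavelengthGrid(dataset.wavelengths)
    if not np.array_equal(wiener.wavelengths, dataset.wavelengths):
        raise ValueError("Wiener model and dataset use different wavelength grids")
    idx = wl_grid.indices_of(analysis_grid())
    records = []
    for rec in dataset:
        recon = np.clip(wiener.w @ (wiener.f @ rec.reflectance), 0.0, 1.0)
        coefs = _mra1(_absorbance(recon[idx]))
        records.append(
            CalibrationRecord(
                rec.c_methb, rec.c_hbo, rec.c_hbr, rec.c_m, rec.wavelengths, recon, coefs
            )
        )
    return CalibrationDataset(records, dataset.wavelengths, dataset.mc_photons, dataset.seed)


def _standardize(features: np.ndarray):
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    constant = scale < 1e-12
    mean[constant] = 0.0
    scale[constant] = 1.0
    return mean, scale


def fit_mra2(
    records: Sequence[CalibrationRecord] | CalibrationDataset,
    order: str = "quadratic",
) -> EmpiricalInverseModel:
    """Ordinary least squares of true concentrations on MRA1-coefficient features."""
    recs = list(records)
    build = _FEATURE_BUILDERS.get(order)
    if build is None:
        raise ValueError(f"unknown feature order {order!r}")
    coefs = np.array([r.coefficients.as_array() for r in recs])
    targets = np.array([[r.c_methb, r.c_hbo, r.c_hbr, r.c_m] for r in recs])
    raw = build(coefs)
    z = raw.shape[1]
    if len(recs) <= z:
        raise ValueError(f"need more than {z} records to fit order {order!r}")
    mean, scale = _standardize(raw)
    design = (raw - mean) / scale
    if np.linalg.matrix_rank(design) < z:
        raise ValueError(
            "rank-deficient feature design; the records do not span the grid — "
            "try order='linear' or a richer dataset"
        )
    beta, _, _, _ = np.linalg.lstsq(design, targets, rcond=None)
    fitted = design @ beta
    ss_res = ((targets - fitted) ** 2).sum(axis=0)
    ss_tot = ((targets - targets.mean(axis=0)) ** 2).sum(axis=0)
    r2 = 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0)
    names = ("c_methb", "c_hbo", "c_hbr", "c_m")
    return EmpiricalInverseModel(
        order=order,
        b=beta.T,
        feature_mean=mean,
        feature_scale=scale,
        r_squared=dict(zip(names, (float(v) for v in r2))),
    )


def leave_one_out(
    records: Sequence[CalibrationRecord] | CalibrationDataset,
    order: str = "quadratic",
) -> pd.DataFrame:
    """Refit MRA2 without each record in turn and predict its concentrations.

    Returns a frame with true and predicted concentrations per record.
    """
    recs = list(records)
    rows = []
    for i, rec in enumerate(recs):
        model = fit_mra2(recs[:i] + recs[i + 1 :], order=order)
        pred = model.predict(rec.coefficients.as_array())
        rows.append(
            {
                "c_methb": rec.c_methb,
                "c_hbo": rec.c_hbo,
                "c_hbr": rec.c_hbr,
                "c_m": rec.c_m,
                "pred_c_methb": pred[0],
                "pred_c_hbo": pred[1],
                "pred_c_hbr": pred[2],
                "pred_c_m": pred[3],
            }
        )
    return pd.DataFrame(rows)
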