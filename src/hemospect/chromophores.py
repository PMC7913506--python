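"""Extinction-coefficient spectra of skin chromophores and absorption builders.

Four absorbers are bundled as CSV assets: oxygenated hemoglobin (``HbO``),
deoxygenated hemoglobin (``HbR``), methemoglobin (``metHb``) and ``melanin``.
Hemoglobin tables are molar extinction coefficients in L mol^-1 cm^-1;
the melanin table is an absorption coefficient in cm^-1 per unit melanosome
volume fraction.

Concentrations are expressed as vol.% of whole blood in the tissue volume,
with whole blood anchored at 150 g/L hemoglobin, so that

    mu_a(lambda) [mm^-1] = ln(10) * eps(lambda) * (150/64500) * (C/100) / 10

for the hemoglobin derivatives, linear in C. Melanin scales its bundled
volume-fraction spectrum in the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "CHROMOPHORES",
    "ChromophoreSpectrum",
    "AbsorptionSpectrum",
    "load_extinction",
    "hemoglobin_mu_a",
    "total_hemoglobin_mu_a",
    "melanin_mu_a",
    "HEMOGLOBIN_G_PER_L",
    "HEMOGLOBIN_MOLAR_MASS",
    "BLOOD_MOLARITY",
]

#: grams of hemoglobin per litre of whole blood defining 100 vol.% total hemoglobin
HEMOGLOBIN_G_PER_L = 150.0
#: molar mass of hemoglobin, g/mol
HEMOGLOBIN_MOLAR_MASS = 64500.0
#: molar concentration of hemoglobin in whole blood, mol/L
BLOOD_MOLARITY = HEMOGLOBIN_G_PER_L / HEMOGLOBIN_MOLAR_MASS

CHROMOPHORES = ("metHb", "HbO", "HbR", "melanin")

_DATA_FILES = {
    "metHb": "methb.csv",
    "HbO": "hbo.csv",
    "HbR": "hbr.csv",
    "melanin": "melanin.csv",
}


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Extinction coefficient versus wavelength for one absorber."""

    name: str
    wavelengths: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        if wl.shape != eps.shape or wl.ndim != 1:
            raise ValueError("wavelengths and epsilon must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(eps < 0):
            raise ValueError("extinction coefficients must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "epsilon", eps)

    def at(self, wavelengths) -> np.ndarray:
        """Linear interpolation onto ``wavelengths``; out-of-range is an error."""
        wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        if wl.min() < self.wavelengths[0] or wl.max() > self.wavelengths[-1]:
            raise ValueError(
                f"requested wavelengths outside tabulated range "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm for {self.name}"
            )
        return np.interp(wl, self.wavelengths, self.epsilon)

    def resample(self, wavelengths) -> "ChromophoreSpectrum":
        wl = np.asarray(wavelengths, dtype=float)
        return ChromophoreSpectrum(self.name, wl, self.at(wl))


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Absorption coefficient mu_a (mm^-1) versus wavelength (nm)."""

    wavelengths: np.ndarray
    mu_a: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        mu = np.asarray(self.mu_a, dtype=float)
        if wl.shape != mu.shape or wl.ndim != 1:
            raise ValueError("wavelengths and mu_a must be 1-D and equal length")
        if np.any(mu < 0):
            raise ValueError("mu_a must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "mu_a", mu)

    def at(self, wavelengths) -> np.ndarray:
        wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        if wl.min() < self.wavelengths[0] or wl.max() > self.wavelengths[-1]:
            raise ValueError("requested wavelengths outside range")
        return np.interp(wl, self.wavelengths, self.mu_a)

    def __add__(self, other: "AbsorptionSpectrum") -> "AbsorptionSpectrum":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("wavelength grids differ")
        return AbsorptionSpectrum(self.wavelengths, self.mu_a + other.mu_a)


def _read_table(fname: str) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd

    with resources.files("hemospect.data").joinpath(fname).open("r") as fh:
        df = pd.read_csv(fh, comment="#")
    return df["wavelength_nm"].to_numpy(float), df["epsilon"].to_numpy(float)


_CACHE: dict[str, ChromophoreSpectrum] = {}


def load_extinction(name: str, wavelengths=None) -> ChromophoreSpectrum:
    """Load a bundled extinction spectrum, optionally resampled.

    Parameters
    ----------
    name
        One of ``metHb``, ``HbO``, ``HbR``, ``melanin``.
    wavelengths
        Optional target grid (nm); linear interpolation, no extrapolation.
    """
    if name not in _DATA_FILES:
        raise ValueError(f"unknown chromophore {name!r}; valid names: {', '.join(CHROMOPHORES)}")
    if name not in _CACHE:
        wl, eps = _read_table(_DATA_FILES[name])
        _CACHE[name] = ChromophoreSpectrum(name, wl, eps)
    spec = _CACHE[name]
    if wavelengths is not None:
        spec = spec.resample(wavelengths)
    return spec


def _check_concentration(c: float, upper: float = 100.0) -> float:
    c = float(c)
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if c > upper:
        raise ValueError(f"concentration exceeds {upper} vol.%")
    return c


def hemoglobin_mu_a(spectrum: ChromophoreSpectrum, c_vol: float) -> AbsorptionSpectrum:
    """Absorption coefficient of a hemoglobin derivative at ``c_vol`` vol.% blood.

    100 vol.% corresponds to whole blood with 150 g/L hemoglobin. Output in
    mm^-1, linear in ``c_vol``.
    """
    c = _check_concentration(c_vol)
    # epsilon [1/(M cm)] -> mu_a [mm^-1]: ln10 * eps * molarity / 10
    mu = np.log(10.0) * spectrum.epsilon * BLOOD_MOLARITY * (c / 100.0) / 10.0
    return AbsorptionSpectrum(spectrum.wavelengths, mu)


def total_hemoglobin_mu_a(
    c_methb: float, c_hbo: float, c_hbr: float, wavelengths=None
) -> AbsorptionSpectrum:
    """mu_a of total hemoglobin: sum of the metHb, HbO and HbR contributions."""
    parts = []
    for name, c in (("metHb", c_methb), ("HbO", c_hbo), ("HbR", c_hbr)):
        parts.append(hemoglobin_mu_a(load_extinction(name, wavelengths), c))
    return parts[0] + parts[1] + parts[2]


def melanin_mu_a(c_m: float, wavelengths=None) -> AbsorptionSpectrum:
    """Epidermal absorption coefficient at melanosome volume fraction ``c_m`` vol.%."""
    c = _check_concentration(c_m)
    spec = load_extinction("melanin", wavelengths)
    # table is cm^-1 at 100 vol.%; convert to mm^-1 and scale linearly
    mu = spec.epsilon / 10.0 * (c / 100.0)
    return AbsorptionSpectrum(spec.wavelengths, mu)
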