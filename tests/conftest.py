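"""Shared fixtures. The heavy Monte Carlo artifacts are session-scoped:
one scattering-only path library (29 wavelengths) feeds both the reduced
calibration dataset and the phantom forward grid through exponential
reweighting, keeping the suite inside a desk-scale budget."""

from __future__ import annotations

import numpy as np
import pytest

from hemospect.calibration import (
    GridSpec,
    SkinPathLibrary,
    build_dataset,
    cycle_through_camera,
    fit_mra2,
)
from hemospect.camera import TrainingEnsemble, default_camera, train_wiener
from hemospect.grids import reconstruction_grid
from hemospect.mcsim import McConfig
from hemospect.phantom import PhantomForward, build_phantom_forward, training_spectra


def thinned_states(sto2_step: int = 20, fractions=(0.0, 0.2)) -> tuple:
    states = []
    for frac in fractions:
        top = int(round(100 * (1 - frac)))
        states.extend((float(s), frac) for s in range(0, top + 1, sto2_step))
    states.append((0.0, 1.0))
    return tuple(states)


@pytest.fixture(scope="session")
def path_library() -> SkinPathLibrary:
    """29-wavelength scattering-only traces at 2e4 photons each."""
    return SkinPathLibrary.build(reconstruction_grid(), McConfig(n_photons=20_000, seed=99))


@pytest.fixture(scope="session")
def thinned_grid() -> GridSpec:
    """~200-point thinning of the 1550-point calibration grid."""
    return GridSpec(
        c_m_values=(1.0, 4.0, 7.0, 10.0),
        c_hbt_values=(0.2, 0.4, 0.6, 0.8, 1.0),
        hb_states=thinned_states(sto2_step=25, fractions=(0.0, 0.25)),
    )


@pytest.fixture(scope="session")
def calibration_dataset(thinned_grid, path_library):
    return build_dataset(thinned_grid, wavelengths=reconstruction_grid(), paths=path_library)


@pytest.fixture(scope="session")
def mra2_model(calibration_dataset):
    return fit_mra2(calibration_dataset)


@pytest.fixture(scope="session")
def phantom_forward(path_library):
    """Coarse forward grid on the 29-point reconstruction range."""
    return build_phantom_forward(
        c_m_axis=(1.0, 5.0, 10.0),
        c_hbt_axis=(0.2, 0.6, 1.0),
        s_func_axis=(0.0, 0.5, 1.0),
        f_met_axis=(0.0, 0.3, 0.6),
        paths=path_library,
    )


@pytest.fixture(scope="session")
def camera_model():
    return default_camera()


@pytest.fixture(scope="session")
def wiener_model(phantom_forward, camera_model):
    spectra = training_spectra(phantom_forward, n=440, seed=7)
    return train_wiener(TrainingEnsemble(spectra), camera_model)


@pytest.fixture(scope="session")
def mra2_camera_model(calibration_dataset, wiener_model):
    """Inverse model trained on camera-cycled spectra, for the RGB pipeline."""
    return fit_mra2(cycle_through_camera(calibration_dataset, wiener_model))


@pytest.fixture()
def synthetic_forward():
    """MC-free stand-in forward model: smooth analytic spectra on the grid.

    Fast path for phantom-rendering unit tests that exercise only the
    interpolation/render plumbing, not the physics.
    """
    grid = reconstruction_grid()
    axes = (
        np.array([1.0, 5.0, 10.0]),
        np.array([0.2, 0.6, 1.0]),
        np.array([0.0, 0.5, 1.0]),
        np.array([0.0, 0.5, 1.0]),
    )
    wl = grid.values
    shape = tuple(len(a) for a in axes) + (wl.size,)
    values = np.empty(shape)
    for i, m in enumerate(axes[0]):
        for j, h in enumerate(axes[1]):
            for k, s in enumerate(axes[2]):
                for l, f in enumerate(axes[3]):
                    base = 0.7 - 0.03 * m - 0.2 * h
                    tilt = (wl - 560.0) / 300.0
                    values[i, j, k, l] = np.clip(
                        base + 0.1 * s * tilt - 0.05 * f * tilt**2, 0.05, 0.95
                    )
    return PhantomForward(*axes, wl, values)
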