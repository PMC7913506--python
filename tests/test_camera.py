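import numpy as np
import pytest

from hemospect.camera import (
    CameraSpectralModel,
    TrainingEnsemble,
    WienerModel,
    autocorrelation,
    default_camera,
    reconstruct,
    system_matrix,
    train_wiener,
    white_reference,
    wiener_matrix,
)
from hemospect.grids import reconstruction_grid


def smooth_ensemble(n, k=29, seed=0):
    """Random smooth reflectance spectra in [0, 1]."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, k)
    spectra = []
    for _ in range(n):
        coefs = rng.normal(0, 0.2, 4)
        base = 0.5 + coefs[0] * x + coefs[1] * np.sin(2 * np.pi * x) + coefs[2] * x**2
        spectra.append(np.clip(base + coefs[3], 0.02, 0.98))
    return np.array(spectra)


def test_default_profile_f_shape():
    f = system_matrix(default_camera())
    assert f.shape == (3, 29)
    assert np.all(f >= 0)


def test_delta_passbands_select_bands():
    grid = reconstruction_grid()
    u = np.zeros((3, 29))
    u[0, 5] = 1.0
    u[1, 12] = 1.0
    u[2, 20] = 1.0
    cam = CameraSpectralModel(grid.values, u, np.ones(29), np.ones(29))
    f = system_matrix(cam)
    r = np.arange(29, dtype=float) / 29
    v = f @ r
    np.testing.assert_allclose(v, grid.step * r[[5, 12, 20]])


def test_doubling_illuminant_doubles_f():
    cam = default_camera()
    bright = CameraSpectralModel(cam.wavelengths, cam.u, 2 * cam.illuminant, cam.sensitivity)
    np.testing.assert_allclose(system_matrix(bright), 2 * system_matrix(cam), rtol=1e-12)


def test_autocorrelation_single_spectrum_is_outer_product():
    r0 = smooth_ensemble(1, seed=3)[0]
    acorr = autocorrelation(TrainingEnsemble(r0[None, :]))
    np.testing.assert_allclose(acorr, np.outer(r0, r0), rtol=1e-12)


def test_autocorrelation_unit_vectors_identity():
    acorr = autocorrelation(TrainingEnsemble(np.eye(29)))
    np.testing.assert_allclose(acorr, np.eye(29) / 29, atol=1e-15)


def test_autocorrelation_is_psd():
    acorr = autocorrelation(TrainingEnsemble(smooth_ensemble(440, seed=8)))
    np.testing.assert_allclose(acorr, acorr.T)
    eigvals = np.linalg.eigvalsh(acorr)
    assert eigvals.min() >= -1e-12


def test_empty_ensemble_rejected():
    with pytest.raises(ValueError):
        TrainingEnsemble(np.empty((0, 29)))


def test_toy_identity_system_recovers_input():
    # k = 3, F = I, invertible autocorrelation -> W = I
    rng = np.random.default_rng(0)
    spectra = rng.uniform(0.1, 0.9, (20, 3))
    acorr = spectra.T @ spectra / 20
    w = wiener_matrix(acorr, np.eye(3))
    np.testing.assert_allclose(w, np.eye(3), atol=1e-10)


def test_wiener_matches_normal_equations_oracle():
    spectra = smooth_ensemble(200, seed=1)
    f = system_matrix(default_camera())
    v = spectra @ f.T
    w = wiener_matrix(spectra.T @ spectra / len(spectra), f)
    # independent route: least squares of r on v over the ensemble
    w_oracle = np.linalg.lstsq(v, spectra, rcond=None)[0].T
    np.testing.assert_allclose(w, w_oracle, atol=1e-9)


def test_wiener_minimizes_training_mse_against_perturbations():
    spectra = smooth_ensemble(150, seed=2)
    f = system_matrix(default_camera())
    v = spectra @ f.T
    w = wiener_matrix(spectra.T @ spectra / len(spectra), f)
    base_err = np.mean((spectra - v @ w.T) ** 2)
    rng = np.random.default_rng(5)
    for _ in range(20):
        delta = rng.normal(0, 1e-3, w.shape)
        err = np.mean((spectra - v @ (w + delta).T) ** 2)
        assert err >= base_err - 1e-15


def test_rank_one_ensemble_reconstructed_exactly():
    r0 = smooth_ensemble(1, seed=9)[0]
    scales = np.linspace(0.2, 1.0, 10)
    ensemble = TrainingEnsemble(np.outer(scales, r0))
    f = system_matrix(default_camera())
    w = wiener_matrix(autocorrelation(ensemble), f)
    np.testing.assert_allclose(w @ f @ r0, r0, atol=1e-8)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        wiener_matrix(np.eye(28), system_matrix(default_camera()))
    with pytest.raises(ValueError):
        wiener_matrix(np.eye(29), system_matrix(default_camera()), noise_cov=np.eye(2))


def test_reconstruct_zero_gives_zero():
    model = train_wiener(TrainingEnsemble(smooth_ensemble(50)), default_camera())
    np.testing.assert_array_equal(reconstruct(np.zeros(3), model), np.zeros(29))


def test_reconstruct_is_linear_before_clipping():
    model = train_wiener(TrainingEnsemble(smooth_ensemble(50)), default_camera())
    rng = np.random.default_rng(11)
    v1, v2 = rng.uniform(0, 1, (2, 3))
    lhs = reconstruct(2.0 * v1 + 0.5 * v2, model, clip=False)
    rhs = 2.0 * reconstruct(v1, model, clip=False) + 0.5 * reconstruct(v2, model, clip=False)
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_reconstruct_image_stack_shape():
    model = train_wiener(TrainingEnsemble(smooth_ensemble(50)), default_camera())
    rgb = np.random.default_rng(0).uniform(0, 0.5, (480, 640, 3))
    stack = reconstruct(rgb, model)
    assert stack.shape == (480, 640, 29)
    assert stack.min() >= 0.0 and stack.max() <= 1.0


def test_reconstruct_wrong_channel_count():
    model = train_wiener(TrainingEnsemble(smooth_ensemble(50)), default_camera())
    with pytest.raises(ValueError):
        reconstruct(np.zeros(4), model)


def test_training_spectrum_from_low_rank_ensemble_recovered():
    basis = smooth_ensemble(3, seed=4)
    rng = np.random.default_rng(6)
    weights = rng.uniform(0.1, 0.5, (40, 3))
    spectra = np.clip(weights @ basis, 0, 1)
    cam = default_camera()
    model = train_wiener(TrainingEnsemble(spectra), cam)
    r = spectra[7]
    v = system_matrix(cam) @ r
    np.testing.assert_allclose(reconstruct(v, model, clip=False), r, atol=1e-7)


def test_white_reference_positive():
    assert np.all(white_reference(default_camera()) > 0)


def test_wiener_model_json_roundtrip(tmp_path):
    model = train_wiener(TrainingEnsemble(smooth_ensemble(30)), default_camera())
    path = tmp_path / "wiener.json"
    model.to_json(path)
    loaded = WienerModel.from_json(path)
    np.testing.assert_allclose(loaded.w, model.w)
    np.testing.assert_allclose(loaded.f, model.f)
    np.testing.assert_allclose(loaded.white, model.white)


def test_camera_profile_csv_roundtrip(tmp_path):
    cam = default_camera()
    path = tmp_path / "profile.csv"
    cam.to_csv(path)
    loaded = CameraSpectralModel.from_csv(path)
    np.testing.assert_allclose(loaded.u, cam.u)
    np.testing.assert_allclose(loaded.illuminant, cam.illuminant)


def test_end_to_end_spectral_fidelity_gfc(phantom_forward, wiener_model):
    # phantom-family spectra reconstructed from their own RGB responses keep
    # a median GFC of at least 0.995 against the truth
    from hemospect.phantom import training_spectra
    from hemospect.pipeline import gfc

    spectra = training_spectra(phantom_forward, n=200, seed=99)  # held-out draw
    v = spectra @ wiener_model.f.T
    recon = reconstruct(v, wiener_model)
    values = [gfc(s, r).gfc for s, r in zip(spectra, recon)]
    assert np.median(values) >= 0.995
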