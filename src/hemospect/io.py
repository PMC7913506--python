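"""Small text-format helpers: spectra CSV, spectral stacks, phantom bundles."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def write_spectrum_csv(path, wavelengths, reflectance) -> None:
    pd.DataFrame({"wavelength_nm": wavelengths, "reflectance": reflectance}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    return df["wavelength_nm"].to_numpy(float), df["reflectance"].to_numpy(float)


def write_spectral_stack(path, stack: np.ndarray, wavelengths) -> None:
    """(H, W, k) stack as a multi-page TIFF with a JSON wavelength sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(stack.astype(np.float32), -1, 0))
    path.with_suffix(".json").write_text(
        json.dumps({"wavelength_nm": list(map(float, wavelengths))})
    )


def read_spectral_stack(path) -> tuple[np.ndarray, np.ndarray]:
    import tifffile

    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return np.moveaxis(pages, 0, -1), np.asarray(meta["wavelength_nm"], float)


def write_phantom_bundle(directory, frames, truth: pd.DataFrame, scene_meta: dict) -> None:
    """frame_####.tiff images, truth.csv and scene.yaml in one directory."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        tifffile.imwrite(directory / f"frame_{i:04d}.tiff", frame.rgb.astype(np.float32))
    truth.to_csv(directory / "truth.csv", index=False)
    (directory / "scene.yaml").write_text(yaml.safe_dump(scene_meta, sort_keys=False))


def read_rgb_image(path) -> np.ndarray:
    """Read a PNG/TIFF RGB image as float in [0, 1]."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise ValueError(f"{path}: expected a 3-channel image")
    arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)
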