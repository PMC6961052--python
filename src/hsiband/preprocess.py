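"""Spectral preprocessing chain.

Raw push-broom counts are turned into classifier-ready reflectance in four
steps: radiometric calibration against white/dark references, removal of the
noisy extreme bands, a moving-average smoothing along the spectral axis, and
per-pixel min-max normalization.  Band decimation emulates cameras with a
coarser spectral sampling interval.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import uniform_filter1d

from .types import HSCube, LabeledDataset, ReferencePair, SpectralGrid

logger = logging.getLogger(__name__)


def calibrate(raw: HSCube, refs: ReferencePair) -> HSCube:
    """Radiometric calibration: C = 100 * (R - D) / (W - D).

    The white reference is a near-perfect diffuse reflector captured under the
    acquisition illumination; the dark reference is captured with the shutter
    closed.  The result is percent reflectance on a 0-100 scale.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    white = np.broadcast_to(refs.white, raw.values.shape)
    dark = np.broadcast_to(refs.dark, raw.values.shape)
    denom = white - dark
    if np.any(denom == 0):
        raise ValueError("degenerate reference: white equals dark at some element")
    values = 100.0 * (raw.values - dark) / denom
    return raw.with_values(values, calibrated=True)


def remove_extreme_bands(cube: HSCube, keep_min: float = 440.0, keep_max: float = 902.0) -> HSCube:
    """Drop low-SNR sensor bands outside [keep_min, keep_max] nm."""
    if keep_min >= keep_max:
        raise ValueError("keep_min must be below keep_max")
    wl = cube.grid.wavelengths
    keep = (wl >= keep_min) & (wl <= keep_max)
    if not keep.any():
        raise ValueError(f"no bands remain in [{keep_min}, {keep_max}] nm")
    idx = np.flatnonzero(keep)
    return cube.with_values(cube.values[:, :, idx], grid=cube.grid.subset(idx))


def smooth_spectra(cube: HSCube, window: int = 5) -> HSCube:
    """Centered moving average along the spectral axis.

    Edge bands are averaged over the part of the window that fits
    (shrinking-window convention), so band count is preserved.
    """
    _check_window(window, cube.n_bands)
    if window == 1:
        return cube.with_values(cube.values.copy())
    values = _moving_average_shrink(cube.values, window)
    return cube.with_values(values)


def smooth_matrix(spectra: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing for a pixels x bands matrix."""
    _check_window(window, spectra.shape[-1])
    if window == 1:
        return np.array(spectra, dtype=float)
    return _moving_average_shrink(np.asarray(spectra, dtype=float), window)


def _check_window(window: int, n_bands: int) -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if window > n_bands:
        raise ValueError("smoothing window exceeds band count")


def _moving_average_shrink(values: np.ndarray, window: int) -> np.ndarray:
    # uniform_filter1d with constant zero padding gives window-sums at the
    # edges; dividing by the per-position effective window length yields the
    # shrinking-window mean.
    half = window // 2
    n = values.shape[-1]
    sums = uniform_filter1d(values, size=window, axis=-1, mode="constant", cval=0.0) * window
    pos = np.arange(n)
    counts = np.minimum(pos, half) + np.minimum(n - 1 - pos, half) + 1
    return sums / counts


def normalize_pixel(cube: HSCube) -> HSCube:
    """Per-pixel min-max normalization: P' = (P - Pmin) / (Pmax - Pmin).

    Flattens brightness differences caused by the non-uniform tissue surface
    so classification relies on spectral shape.  Pixels with a constant
    spectrum (zero range, e.g. saturated glare) are set to all zeros and a
    warning is logged.
    """
    if not cube.calibrated:
        raise ValueError("normalize_pixel requires a calibrated cube")
    values = normalize_matrix(cube.pixels()).reshape(cube.values.shape)
    return cube.with_values(values, normalized=True)


def normalize_matrix(spectra: np.ndarray) -> np.ndarray:
    """Min-max normalize each row of a pixels x bands matrix."""
    spectra = np.asarray(spectra, dtype=float)
    pmin = spectra.min(axis=-1, keepdims=True)
    pmax = spectra.max(axis=-1, keepdims=True)
    rng = pmax - pmin
    flat = rng == 0
    if flat.any():
        logger.warning("%d constant pixel(s) normalized to zeros", int(flat.sum()))
    safe = np.where(flat, 1.0, rng)
    out = (spectra - pmin) / safe
    return np.where(flat, 0.0, out)


def sampling_interval(lambda_min: float, lambda_max: float, n_bands: int) -> float:
    """Spectral sampling interval (nm) = (lambda_max - lambda_min) / n_bands."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if lambda_max <= lambda_min:
        raise ValueError("lambda_max must exceed lambda_min")
    return (lambda_max - lambda_min) / n_bands


def decimation_indices(grid: SpectralGrid, n_bands: int) -> np.ndarray:
    """Band indices emulating a camera with ``n_bands`` over the same range.

    Targets are the midpoints of ``n_bands`` equal wavelength intervals,
    lambda_min + (k + 0.5) * interval; each target maps to the nearest
    existing band (ties to the lower index).  Duplicate picks collapse, so
    fewer than ``n_bands`` indices can be returned on very coarse grids.
    """
    if not 1 <= n_bands <= grid.n_bands:
        raise ValueError(f"n_bands must be in [1, {grid.n_bands}]")
    if n_bands == grid.n_bands:
        return np.arange(grid.n_bands)
    interval = sampling_interval(grid.lambda_min, grid.lambda_max, n_bands)
    targets = grid.lambda_min + (np.arange(n_bands) + 0.5) * interval
    wl = grid.wavelengths
    # searchsorted + neighbor comparison; strict '<' keeps ties on the lower index
    right = np.searchsorted(wl, targets)
    right = np.clip(right, 1, wl.size - 1)
    left = right - 1
    pick_right = (wl[right] - targets) < (targets - wl[left])
    idx = np.where(pick_right, right, left)
    return np.unique(idx)


def decimate_bands(cube: HSCube, n_bands: int) -> HSCube:
    """Subsample the spectral axis to emulate a coarser sampling interval."""
    idx = decimation_indices(cube.grid, n_bands)
    return cube.with_values(cube.values[:, :, idx], grid=cube.grid.subset(idx))


def preprocess_cube(
    raw: HSCube,
    refs: ReferencePair | None = None,
    keep_min: float = 440.0,
    keep_max: float = 902.0,
    smooth_window: int = 5,
    n_bands: int | None = None,
) -> HSCube:
    """Full chain: calibrate -> remove extremes -> smooth -> decimate -> normalize.

    Normalization runs last so the per-pixel min-0 / max-1 invariant holds on
    the band set the classifier actually sees.
    """
    cube = calibrate(raw, refs) if refs is not None else raw
    cube = remove_extreme_bands(cube, keep_min, keep_max)
    cube = smooth_spectra(cube, smooth_window)
    if n_bands is not None:
        cube = decimate_bands(cube, n_bands)
    return normalize_pixel(cube)


def preprocess_dataset(
    data: LabeledDataset, smooth_window: int = 5, n_bands: int | None = None
) -> LabeledDataset:
    """Smooth -> decimate -> min-max normalize a flat pixel dataset.

    Mirrors :func:`preprocess_cube` for datasets that are already calibrated
    reflectance (e.g. synthetic cohorts or pixels pooled from cubes).
    """
    spectra = smooth_matrix(data.spectra, smooth_window)
    grid = data.grid
    if n_bands is not None:
        if grid is None:
            raise ValueError("decimation requires a grid")
        idx = decimation_indices(grid, n_bands)
        spectra = spectra[:, idx]
        grid = grid.subset(idx)
    spectra = normalize_matrix(spectra)
    return LabeledDataset(spectra, data.labels, data.patient_ids, data.image_ids, grid=grid)
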