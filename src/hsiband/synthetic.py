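"""Synthetic labeled brain-surface scenes.

Real intraoperative hyperspectral databases are not publicly deposited, so
every downstream stage is exercised on generated data whose first- and
second-order statistics mimic the tissue classes: normal and tumor cortex and
hypervascularized tissue share a smooth reflectance curve carved by hemoglobin
absorption valleys near 540/560/580 nm (deeper where blood content is higher),
while the background class mixes several unrelated materials (bone, dura,
surgical textiles) and therefore has a much larger spectral variance.

A global ``contrast`` knob scales the separation between class means: at 1 the
classes are cleanly separable, at 0 all four class means coincide and any
classifier degrades to chance.  Each synthetic patient carries a smooth
low-frequency offset emulating inter-patient variability, which is what makes
leave-one-patient-out validation meaningful on this data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    CLASS_NAMES,
    UNLABELED,
    GroundTruthMap,
    HSCube,
    LabeledDataset,
    SpectralGrid,
)

DEFAULT_GRID = SpectralGrid.linear(440.0, 902.0, 128)


@dataclass(frozen=True)
class ClassSignatureModel:
    """Mean/stdev reflectance curves for one class on a 0-100 scale."""

    class_id: int
    mean_spectrum: np.ndarray
    stdev_spectrum: np.ndarray
    patient_offset_sd: float = 1.0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean_spectrum, dtype=float)
        sd = np.asarray(self.stdev_spectrum, dtype=float)
        if mean.shape != sd.shape or mean.ndim != 1:
            raise ValueError("mean and stdev spectra must be 1-D and aligned")
        if np.any(sd < 0):
            raise ValueError("stdev spectrum must be nonnegative")
        object.__setattr__(self, "mean_spectrum", mean)
        object.__setattr__(self, "stdev_spectrum", sd)

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.class_id]


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Study conditions for one synthetic cohort."""

    grid: SpectralGrid = DEFAULT_GRID
    n_patients: int = 4
    pixels_per_class_per_patient: int = 500
    glare_fraction: float = 0.02
    seed: int = 0
    contrast: float = 1.0
    #: emulate one patient whose tumor is spectrally indistinguishable from
    #: normal cortex (a known intraoperative failure mode); off by default
    flat_tumor_patient: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("leave-one-patient-out needs at least 2 patients")
        if self.pixels_per_class_per_patient < 1:
            raise ValueError("pixels_per_class_per_patient must be positive")
        if not 0 <= self.glare_fraction < 1:
            raise ValueError("glare_fraction must be in [0, 1)")
        if not 0 <= self.contrast <= 1:
            raise ValueError("contrast must be in [0, 1]")

    def patient_ids(self) -> list[str]:
        return [f"P{i + 1:03d}" for i in range(self.n_patients)]


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _logistic(wl: np.ndarray, center: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - center) / scale))


def build_default_signatures(
    grid: SpectralGrid, contrast: float = 1.0, patient_offset_sd: float = 1.0
) -> list[ClassSignatureModel]:
    """Deterministic signature models for the four scene classes.

    Class means are ``base + contrast * delta_c``: a shared logistic-ramp base
    curve (reflectance rising into the red/NIR, as cortex does) plus a
    class-specific deviation built from Gaussian hemoglobin absorption dips at
    540/560/580 nm and broad albedo shifts.  ``contrast=0`` collapses all
    means onto the base curve.
    """
    if grid.lambda_min > 450 or grid.lambda_max < 850:
        raise ValueError(
            "signatures undefined for grid: need coverage of ~440-902 nm "
            f"(got {grid.lambda_min:.1f}-{grid.lambda_max:.1f})"
        )
    wl = grid.wavelengths
    # Shared cortex-like base: low blue reflectance climbing through the red
    # edge toward a scattering-dominated NIR plateau.
    base = 8.0 + 55.0 * _logistic(wl, 600.0, 45.0) + 6.0 * _logistic(wl, 750.0, 60.0)

    oxy_dips = _gauss(wl, 540.0, 12.0) + _gauss(wl, 580.0, 12.0)  # oxygenated Hb
    deoxy_dip = _gauss(wl, 560.0, 14.0)  # deoxygenated Hb
    nir_tilt = _logistic(wl, 700.0, 80.0)

    # Per-class deviations from the base (applied at full contrast).
    deltas = {
        0: -6.0 * oxy_dips - 2.0 * deoxy_dip + 2.0 * nir_tilt,  # normal
        # tumor: weaker oxygenated / stronger deoxygenated Hb valleys, flatter
        # red edge and depressed NIR scattering plateau than normal cortex
        1: -3.0 * oxy_dips - 7.0 * deoxy_dip - 9.0 * nir_tilt + 4.0 * _gauss(wl, 620.0, 40.0) + 3.0,
        2: -14.0 * oxy_dips - 10.0 * deoxy_dip - 6.0 + 4.0 * nir_tilt,  # hypervascular
    }

    # Background: mixture of >=3 distinct materials present in the surgical
    # scene.  The mixture mean is the class mean; the spread across materials
    # inflates the class stdev far beyond the tissue classes.
    materials = np.stack(
        [
            60.0 + 15.0 * _logistic(wl, 520.0, 60.0),  # skull bone: bright, flat
            12.0 + 30.0 * _logistic(wl, 640.0, 30.0) - 8.0 * oxy_dips,  # dura/blood film
            35.0 + 25.0 * _gauss(wl, 480.0, 60.0),  # blue-green surgical textile
            20.0 * np.ones_like(wl),  # matte instrument
        ]
    )
    deltas[3] = materials.mean(axis=0) - base

    tissue_sd = 1.5 + 1.0 * _logistic(wl, 700.0, 80.0)
    signatures = []
    for class_id in range(3):
        mean = np.clip(base + contrast * deltas[class_id], 0.0, None)
        signatures.append(
            ClassSignatureModel(class_id, mean, tissue_sd, patient_offset_sd=patient_offset_sd)
        )
    bg_mean = np.clip(base + contrast * deltas[3], 0.0, None)
    bg_sd = tissue_sd + contrast * (materials.std(axis=0))
    signatures.append(
        ClassSignatureModel(3, bg_mean, bg_sd, patient_offset_sd=patient_offset_sd)
    )
    return signatures


def _patient_offsets(spec: SyntheticSceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency per-patient additive curves (n_patients x bands)."""
    wl = spec.grid.wavelengths
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    n_terms = 3
    coef = rng.normal(size=(spec.n_patients, n_terms))
    basis = np.stack([np.cos(np.pi * (k + 1) * t) for k in range(n_terms)])
    return coef @ basis / np.sqrt(n_terms)


def generate_dataset(
    spec: SyntheticSceneSpec, signatures: list[ClassSignatureModel] | None = None
) -> LabeledDataset:
    """Draw labeled pixel spectra for every (patient, class) cell.

    Each pixel is ``class mean + patient offset + N(0, stdev_spectrum)``,
    clipped at zero reflectance.  Bitwise reproducible from ``spec.seed``.
    """
    if signatures is None:
        signatures = build_default_signatures(spec.grid, contrast=spec.contrast)
    for sig in signatures:
        if sig.mean_spectrum.size != spec.grid.n_bands:
            raise ValueError("signature length does not match scene grid")
    rng = np.random.default_rng(spec.seed)
    offsets = _patient_offsets(spec, rng)
    n_px = spec.pixels_per_class_per_patient
    blocks, labels, pids, iids = [], [], [], []
    for p, pid in enumerate(spec.patient_ids()):
        flat = spec.flat_tumor_patient and p == spec.n_patients - 1
        for sig in signatures:
            mean = sig.mean_spectrum
            if flat and sig.class_id == 1:
                mean = signatures[0].mean_spectrum  # tumor looks like normal
            off = offsets[p] * sig.patient_offset_sd
            noise = rng.normal(size=(n_px, spec.grid.n_bands)) * sig.stdev_spectrum
            blocks.append(np.clip(mean + off + noise, 0.0, None))
            labels.append(np.full(n_px, sig.class_id))
            pids.append(np.full(n_px, pid, dtype=object))
            iids.append(np.full(n_px, f"{pid}-01", dtype=object))
    return LabeledDataset(
        np.concatenate(blocks),
        np.concatenate(labels),
        np.concatenate(pids),
        np.concatenate(iids),
        grid=spec.grid,
    )


def generate_cube(
    spec: SyntheticSceneSpec,
    signatures: list[ClassSignatureModel] | None = None,
    height: int = 64,
    width: int = 64,
    patient_index: int = 0,
    tumor_share: float = 0.1,
    labeled_fraction: float = 0.6,
) -> tuple[HSCube, GroundTruthMap]:
    """Render one spatial scene for a patient: background border, a tumor
    blob, vessel strips, normal parenchyma, plus glare and unlabeled pixels.

    ``tumor_share`` is the target fraction of labeled pixels carrying the
    tumor class (met to within one pixel row of the blob).  A
    ``spec.glare_fraction`` of pixels is replaced by near-saturated flat
    spectra and marked unlabeled, as glare is in the real labeling protocol.
    """
    if signatures is None:
        signatures = build_default_signatures(spec.grid, contrast=spec.contrast)
    if height < 16 or width < 16:
        raise ValueError("region packing impossible: scene must be at least 16x16")
    if not 0 <= patient_index < spec.n_patients:
        raise ValueError("patient_index out of range")

    labels = np.full((height, width), 3, dtype=np.int16)  # background border default
    border = max(2, height // 10, width // 10)
    labels[border : height - border, border : width - border] = 0  # normal interior

    # vessel strips: two vertical hypervascularized bands inside the interior
    iw = width - 2 * border
    for frac in (0.25, 0.7):
        c0 = border + int(frac * iw)
        labels[border : height - border, c0 : c0 + max(1, iw // 16)] = 2

    # tumor blob: grow a disk row-block around an interior anchor until the
    # requested share of labeled pixels is reached (within one pixel row)
    interior = labels[border : height - border, border : width - border]
    target = int(round(tumor_share * labels.size))
    cy, cx = interior.shape[0] // 3, interior.shape[1] // 3
    yy, xx = np.ogrid[: interior.shape[0], : interior.shape[1]]
    dist = (yy - cy) ** 2 + (xx - cx) ** 2
    order = np.argsort(dist.ravel(), kind="stable")
    blob = order[: min(target, order.size)]
    by, bx = np.unravel_index(blob, interior.shape)
    labels[border + by, border + bx] = 1

    rng = np.random.default_rng(spec.seed + 7919 * (patient_index + 1))
    # un-label a fraction of pixels at random (real gold standards are sparse)
    unlab = rng.random(labels.shape) > labeled_fraction
    gt = labels.copy()
    gt[unlab] = UNLABELED

    offsets = _patient_offsets(spec, np.random.default_rng(spec.seed))
    pid = spec.patient_ids()[patient_index]
    values = np.empty((height, width, spec.grid.n_bands))
    for sig in signatures:
        mask = labels == sig.class_id
        n = int(mask.sum())
        if n == 0:
            continue
        off = offsets[patient_index] * sig.patient_offset_sd
        noise = rng.normal(size=(n, spec.grid.n_bands)) * sig.stdev_spectrum
        values[mask] = np.clip(sig.mean_spectrum + off + noise, 0.0, None)

    if spec.glare_fraction > 0:
        glare = rng.random(labels.shape) < spec.glare_fraction
        n_glare = int(glare.sum())
        values[glare] = 95.0 + rng.random((n_glare, 1)) * 5.0  # near-saturated, flat
        gt[glare] = UNLABELED

    cube = HSCube(values, spec.grid, patient_id=pid, image_id=f"{pid}-01", calibrated=True)
    return cube, GroundTruthMap(gt)
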