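"""Core in-memory containers shared across the pipeline.

A hyperspectral cube is a rows x cols x bands reflectance array tied to a
:class:`SpectralGrid` (the wavelength axis).  Labeled pixel collections are
kept as flat matrices (pixels x bands) with parallel label / patient-id
arrays, which is the natural shape for classifier training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: class codes used throughout: 0 normal, 1 tumor, 2 hypervascularized, 3 background
CLASS_NAMES = ("normal", "tumor", "hypervascularized", "background")
N_CLASSES = 4
UNLABELED = 255

#: classification-map palette: green, red, blue, black for classes 0-3
CLASS_PALETTE = {
    0: (0, 255, 0),
    1: (255, 0, 0),
    2: (0, 0, 255),
    3: (0, 0, 0),
}


@dataclass(frozen=True)
class SpectralGrid:
    """Ordered wavelength axis (band centers, nm)."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelengths must be a nonempty 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    @property
    def lambda_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def lambda_max(self) -> float:
        return float(self.wavelengths[-1])

    def subset(self, indices: np.ndarray) -> "SpectralGrid":
        idx = np.asarray(indices, dtype=int)
        return SpectralGrid(self.wavelengths[idx])

    @classmethod
    def linear(cls, lambda_min: float, lambda_max: float, n_bands: int) -> "SpectralGrid":
        """Evenly spaced grid including both endpoints."""
        return cls(np.linspace(lambda_min, lambda_max, n_bands))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_bands

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and np.allclose(
            self.wavelengths, other.wavelengths
        )


@dataclass
class HSCube:
    """Hyperspectral reflectance cube (rows x cols x bands)."""

    values: np.ndarray
    grid: SpectralGrid
    patient_id: str = "P000"
    image_id: str = "P000-01"
    calibrated: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError("cube values must be 3-D (rows x cols x bands)")
        if v.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"band axis ({v.shape[2]}) does not match grid ({self.grid.n_bands})"
            )
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def pixels(self) -> np.ndarray:
        """Flattened (rows*cols) x bands view of the spectra."""
        return self.values.reshape(-1, self.n_bands)

    def with_values(self, values: np.ndarray, grid: SpectralGrid | None = None, **flags) -> "HSCube":
        out = replace(self, values=values, grid=grid if grid is not None else self.grid)
        for k, v in flags.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class ReferencePair:
    """White / dark reference images for radiometric calibration."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.white, dtype=np.float64)
        d = np.asarray(self.dark, dtype=np.float64)
        if w.shape != d.shape:
            raise ValueError("white and dark references must have identical shapes")
        object.__setattr__(self, "white", w)
        object.__setattr__(self, "dark", d)


@dataclass
class GroundTruthMap:
    """Per-pixel class codes {0,1,2,3} plus 255 for unlabeled."""

    labels: np.ndarray

    VALID_CODES = frozenset({0, 1, 2, 3, UNLABELED})

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("ground truth must be 2-D")
        codes = set(np.unique(lab).tolist())
        if not codes <= self.VALID_CODES:
            raise ValueError(f"invalid class codes: {sorted(codes - self.VALID_CODES)}")
        self.labels = lab.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNLABELED


@dataclass
class LabeledDataset:
    """Flat collection of labeled pixel spectra with provenance ids."""

    spectra: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray
    image_ids: np.ndarray
    grid: SpectralGrid | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.patient_ids = np.asarray(self.patient_ids)
        self.image_ids = np.asarray(self.image_ids)
        n = self.spectra.shape[0]
        if not (self.labels.shape[0] == self.patient_ids.shape[0] == self.image_ids.shape[0] == n):
            raise ValueError("spectra, labels, patient_ids and image_ids must align")
        if self.grid is not None and self.spectra.shape[1] != self.grid.n_bands:
            raise ValueError("spectra band count does not match grid")

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        """Row subset by boolean mask or index array."""
        return LabeledDataset(
            self.spectra[mask],
            self.labels[mask],
            self.patient_ids[mask],
            self.image_ids[mask],
            grid=self.grid,
        )

    def select_bands(self, indices: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.spectra[:, idx],
            self.labels,
            self.patient_ids,
            self.image_ids,
            grid=self.grid.subset(idx) if self.grid is not None else None,
        )

    def patients(self) -> list[str]:
        return sorted(np.unique(self.patient_ids).tolist())

    @staticmethod
    def concatenate(parts: list["LabeledDataset"]) -> "LabeledDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        return LabeledDataset(
            np.concatenate([p.spectra for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.patient_ids for p in parts]),
            np.concatenate([p.image_ids for p in parts]),
            grid=parts[0].grid,
        )


@dataclass(frozen=True)
class BandSubset:
    """Sorted, unique band indices over a spectral grid."""

    indices: np.ndarray
    grid: SpectralGrid

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size == 0:
            raise ValueError("band subset must be nonempty")
        if idx[0] < 0 or idx[-1] >= self.grid.n_bands:
            raise ValueError("band index out of range for grid")
        object.__setattr__(self, "indices", idx)

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths[self.indices]

    @classmethod
    def from_mask(cls, mask: np.ndarray, grid: SpectralGrid) -> "BandSubset":
        return cls(np.flatnonzero(np.asarray(mask, dtype=bool)), grid)

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.n_bands, dtype=bool)
        mask[self.indices] = True
        return mask
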