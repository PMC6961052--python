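"""SVM training/prediction with leave-one-patient-out cross-validation.

Each fold holds out every pixel of one patient, so reported scores measure
inter-patient generalization — the clinically relevant question for a system
that must classify a patient it has never seen.  A linear-kernel SVM (C=1,
one-vs-one multiclass) is the default: fast enough to sit inside wrapper
band-selection loops and free of kernel hyperparameters that could mask the
effect of the selected bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from sklearn.svm import SVC

from .metrics import MetricsReport, report_from_labels
from .types import CLASS_PALETTE, BandSubset, HSCube, LabeledDataset


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"
    C: float = 1.0
    gamma: str | float = "scale"
    seed: int = 0

    def make(self) -> SVC:
        return SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
            decision_function_shape="ovo",
            random_state=self.seed,
        )


@dataclass(frozen=True)
class FoldPlan:
    """Leave-one-patient-out folds: (held-out patient, training patients)."""

    folds: tuple[tuple[str, tuple[str, ...]], ...]

    def __iter__(self):
        return iter(self.folds)

    def __len__(self) -> int:
        return len(self.folds)


def make_folds(data: LabeledDataset) -> FoldPlan:
    patients = data.patients()
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out requires at least 2 patients")
    folds = tuple(
        (held, tuple(p for p in patients if p != held)) for held in patients
    )
    return FoldPlan(folds)


def train_svm(train: LabeledDataset, bands: BandSubset, svm_cfg: SVMConfig = SVMConfig()) -> SVC:
    model = svm_cfg.make()
    model.fit(train.spectra[:, bands.indices], train.labels)
    return model


def run_fold(
    train: LabeledDataset,
    test: LabeledDataset,
    bands: BandSubset,
    svm_cfg: SVMConfig = SVMConfig(),
) -> MetricsReport:
    """Train on ``train`` restricted to ``bands``, report metrics on ``test``."""
    overlap = set(np.unique(train.patient_ids)) & set(np.unique(test.patient_ids))
    if overlap:
        raise ValueError(f"patient leakage between train and test: {sorted(overlap)}")
    model = train_svm(train, bands, svm_cfg)
    predicted = model.predict(test.spectra[:, bands.indices])
    return report_from_labels(test.labels, predicted)


@dataclass
class ClassificationMap:
    """Predicted class codes over a cube's spatial grid, with a fixed palette."""

    labels: np.ndarray
    palette: dict[int, tuple[int, int, int]] = field(default_factory=lambda: dict(CLASS_PALETTE))

    def to_rgb(self) -> np.ndarray:
        rgb = np.zeros((*self.labels.shape, 3), dtype=np.uint8)
        for code, color in self.palette.items():
            rgb[self.labels == code] = color
        return rgb

    def save_png(self, path: str | Path) -> Path:
        path = Path(path).with_suffix(".png")
        Image.fromarray(self.to_rgb()).save(path)
        return path


def render_map(cube: HSCube, model: SVC, bands: BandSubset) -> ClassificationMap:
    """Classify every pixel of the cube (labeled or not) with a trained model."""
    if bands.grid.n_bands != cube.n_bands:
        raise ValueError("band subset grid does not match cube grid")
    predicted = model.predict(cube.pixels()[:, bands.indices])
    return ClassificationMap(predicted.reshape(cube.shape[:2]))


def run_cross_validation(
    data: LabeledDataset,
    bands: BandSubset,
    svm_cfg: SVMConfig = SVMConfig(),
    reduce_fn=None,
) -> dict[str, MetricsReport]:
    """Leave-one-patient-out evaluation of a fixed band subset.

    ``reduce_fn`` (optional) maps the per-fold training dataset to a reduced
    one — the training-set reduction is refit inside every fold so no pixel
    of the held-out patient can influence prototype selection.
    """
    reports: dict[str, MetricsReport] = {}
    for held_out, train_patients in make_folds(data):
        train = data.subset(np.isin(data.patient_ids, train_patients))
        test = data.subset(data.patient_ids == held_out)
        if reduce_fn is not None:
            train = reduce_fn(train)
            assert held_out not in set(np.unique(train.patient_ids))
        reports[held_out] = run_fold(train, test, bands, svm_cfg)
    return reports
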