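"""End-to-end processing frameworks.

Three reproducible experiment drivers over a (synthetic or loaded) labeled
cohort:

* :func:`run_pf1` — sampling-interval sweep: classification quality versus
  the number of retained bands, with and without training-set reduction;
* :func:`run_pf2` — per-fold wrapper band selection (GA or PSO, penalized
  OA or FoM fitness) inside leave-one-patient-out cross-validation, followed
  by coincidence-level aggregation and re-evaluation;
* :func:`run_pf3` — per-fold ACO band ranking with top-k evaluation.

Every stochastic stage derives its seed from the global seed and the stage
name, so stages are independently reproducible and a rerun with the same
config gives bit-identical band sets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import coincidence as coin
from .evaluate import SVMConfig, make_folds, run_fold
from .metrics import MetricsReport, aggregate_reports
from .preprocess import preprocess_dataset
from .reduction import ReductionConfig, reduce_training_set
from .selection import (
    ACOConfig,
    GAConfig,
    PSOConfig,
    aco_rank,
    aco_topk_evaluate,
    ga_select,
    make_wrapper_fitness,
    pso_select,
)
from .synthetic import SyntheticSceneSpec, generate_dataset
from .types import BandSubset, LabeledDataset

logger = logging.getLogger(__name__)

#: default sampling-interval sweep (band counts on the trimmed 440-902 nm grid)
DEFAULT_BAND_SWEEP = (128, 64, 32, 16, 8)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    scene: SyntheticSceneSpec = field(default_factory=SyntheticSceneSpec)
    smooth_window: int = 5
    n_bands: int | None = None  # decimation target; None keeps the scene grid
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    aco: ACOConfig = field(default_factory=ACOConfig)
    method: str = "ga"  # "ga" | "pso"
    fitness: str = "fom_p"  # "oa_p" | "fom_p"
    paper_literal: bool = False  # fitness on the test patient (leaky protocol)
    output_dir: Path | None = None
    global_seed: int = 0

    def seeded(self) -> "RunConfig":
        """Propagate per-stage seeds derived from the global seed."""
        return replace(
            self,
            scene=replace(self.scene, seed=derive_seed(self.global_seed, "scene")),
            reduction=replace(self.reduction, seed=derive_seed(self.global_seed, "reduction")),
            ga=replace(self.ga, seed=derive_seed(self.global_seed, "ga")),
            pso=replace(self.pso, seed=derive_seed(self.global_seed, "pso")),
            aco=replace(self.aco, seed=derive_seed(self.global_seed, "aco")),
        )


def prepare_dataset(cfg: RunConfig) -> LabeledDataset:
    """Generate the synthetic cohort and run the preprocessing chain."""
    raw = generate_dataset(cfg.scene)
    return preprocess_dataset(raw, smooth_window=cfg.smooth_window, n_bands=cfg.n_bands)


def _reduce(train: LabeledDataset, cfg: RunConfig) -> LabeledDataset:
    return reduce_training_set(train, cfg.reduction)


def _all_bands(data: LabeledDataset) -> BandSubset:
    return BandSubset(np.arange(data.n_bands), data.grid)


def loocv_reports(
    data: LabeledDataset, bands: BandSubset, cfg: RunConfig, reduce: bool = True
) -> dict[str, MetricsReport]:
    reports = {}
    for held_out, train_patients in make_folds(data):
        train = data.subset(np.isin(data.patient_ids, train_patients))
        test = data.subset(data.patient_ids == held_out)
        if reduce:
            train = _reduce(train, cfg)
        reports[held_out] = run_fold(train, test, bands, cfg.svm)
    return reports


# ---------------------------------------------------------------------------
# PF1: sampling interval sweep

def run_pf1(cfg: RunConfig, band_sweep=DEFAULT_BAND_SWEEP) -> pd.DataFrame:
    """Accuracy/time versus band count, with original and reduced training.

    Returns one row per (band count, training scheme) with cross-validated
    mean/std OA and per-fold train+classify wall time.
    """
    cfg = cfg.seeded()
    raw = generate_dataset(cfg.scene)
    rows = []
    for n_bands in band_sweep:
        data = preprocess_dataset(raw, smooth_window=cfg.smooth_window, n_bands=n_bands)
        bands = _all_bands(data)
        for reduced in (False, True):
            t0 = time.perf_counter()
            reports = loocv_reports(data, bands, cfg, reduce=reduced)
            elapsed = time.perf_counter() - t0
            agg = aggregate_reports(list(reports.values()))
            rows.append(
                {
                    "n_bands": data.n_bands,
                    "reduced_training": reduced,
                    "oa_mean": agg["oa"]["mean"],
                    "oa_std": agg["oa"]["std"],
                    "tumor_sens_mean": agg["sensitivity"][1]["mean"],
                    "time_s": elapsed / len(reports),
                }
            )
    df = pd.DataFrame(rows)
    _write_artifacts(cfg, "pf1", {"table": df.to_dict(orient="records")})
    return df


# ---------------------------------------------------------------------------
# PF2: GA / PSO wrapper selection

def _fold_fitness(train: LabeledDataset, test: LabeledDataset, cfg: RunConfig):
    """Wrapper fitness for one fold.

    Default: an inner leave-one-patient rotation over the *training* patients
    — each training patient serves as validation once and the candidate
    subset's penalized fitness is averaged across rotations — so selection
    never sees the held-out test patient and does not overfit any single
    validation patient.  ``paper_literal=True`` scores candidate subsets on
    the test patient itself, reproducing the described protocol at the cost
    of selection bias.
    """
    if cfg.paper_literal:
        inner_train = _reduce(train, cfg)
        return make_wrapper_fitness(inner_train, test, cfg.fitness, cfg.svm)
    inner_fns = []
    for val_patient in sorted(np.unique(train.patient_ids)):
        inner = train.subset(train.patient_ids != val_patient)
        validation = train.subset(train.patient_ids == val_patient)
        inner_train = _reduce(inner, cfg)
        inner_fns.append(make_wrapper_fitness(inner_train, validation, cfg.fitness, cfg.svm))

    def fitness(mask):
        values = [fn(mask) for fn in inner_fns]
        mean_value = float(np.mean([v.value for v in values]))
        return replace(values[0], value=mean_value)

    return fitness


def run_pf2(cfg: RunConfig, data: LabeledDataset | None = None) -> dict:
    """Per-fold GA/PSO band selection + evaluation + coincidence aggregation.

    ``data`` (already preprocessed) overrides the synthetic cohort from
    ``cfg.scene``.
    """
    cfg = cfg.seeded()
    if data is None:
        data = prepare_dataset(cfg)
    folds = make_folds(data)
    per_fold: dict[str, dict] = {}
    band_sets: list[BandSubset] = []
    reports: dict[str, MetricsReport] = {}

    for fold_i, (held_out, train_patients) in enumerate(folds):
        train = data.subset(np.isin(data.patient_ids, train_patients))
        test = data.subset(data.patient_ids == held_out)
        fitness = _fold_fitness(train, test, cfg)
        opt_seed = derive_seed(cfg.global_seed, f"{cfg.method}-fold{fold_i}")
        if cfg.method == "ga":
            opt_cfg = replace(cfg.ga, seed=opt_seed)
            subset, trace = ga_select(fitness, data.n_bands, opt_cfg, grid=data.grid)
        elif cfg.method == "pso":
            opt_cfg = replace(cfg.pso, seed=opt_seed)
            subset, trace = pso_select(fitness, data.n_bands, opt_cfg, grid=data.grid)
        else:
            raise ValueError(f"unknown method {cfg.method!r} for PF2")
        reduced_train = _reduce(train, cfg)
        reports[held_out] = run_fold(reduced_train, test, subset, cfg.svm)
        band_sets.append(subset)
        per_fold[held_out] = {
            "bands": subset.indices.tolist(),
            "wavelengths": [round(float(w), 2) for w in subset.wavelengths],
            "fitness_trace": trace,
            "metrics": reports[held_out].to_dict(),
        }
        logger.info(
            "fold %s: %d bands selected, final fitness %.4f, OA %.3f",
            held_out, subset.n_selected, trace[-1], reports[held_out].oa,
        )

    levels = coin.compute_levels(band_sets)

    def harness(subset: BandSubset) -> dict:
        reps = loocv_reports(data, subset, cfg)
        return aggregate_reports(list(reps.values()))

    level_reports = coin.evaluate_levels(levels, harness)
    result = {
        "per_fold": per_fold,
        "aggregate": aggregate_reports(list(reports.values())),
        "levels": {
            f"L{i}": {
                "bands": s.indices.tolist(),
                "ranges_nm": [
                    [round(a, 2), round(b, 2)] for a, b in coin.contiguous_ranges(s)
                ],
                "metrics": level_reports.get(i),
            }
            for i, s in levels.nonempty_levels().items()
        },
    }
    _write_artifacts(cfg, f"pf2-{cfg.method}-{cfg.fitness}", result)
    return result


# ---------------------------------------------------------------------------
# PF3: ACO ranking

def run_pf3(cfg: RunConfig, data: LabeledDataset | None = None) -> dict:
    """Per-fold ACO band ranking with top-k evaluation."""
    cfg = cfg.seeded()
    if data is None:
        data = prepare_dataset(cfg)
    folds = make_folds(data)
    top_k = tuple(k for k in cfg.aco.top_k_list if k <= data.n_bands)
    per_fold: dict[str, dict] = {}

    for fold_i, (held_out, train_patients) in enumerate(folds):
        train = data.subset(np.isin(data.patient_ids, train_patients))
        test = data.subset(data.patient_ids == held_out)
        aco_cfg = replace(cfg.aco, seed=derive_seed(cfg.global_seed, f"aco-fold{fold_i}"))
        reduced_train = _reduce(train, cfg)
        ranking = aco_rank(reduced_train, aco_cfg, svm_cfg=cfg.svm)

        def harness(indices: np.ndarray):
            subset = BandSubset(indices, data.grid)
            return run_fold(reduced_train, test, subset, cfg.svm)

        per_k = aco_topk_evaluate(ranking, top_k, harness)
        per_fold[held_out] = {
            "ranking": ranking.tolist(),
            "per_k": {k: r.to_dict() for k, r in per_k.items()},
        }

    result = {
        "per_fold": per_fold,
        "per_k_aggregate": {
            k: aggregate_reports(
                [MetricsReport(**{**f["per_k"][k]}) for f in per_fold.values()]
            )
            for k in top_k
        },
    }
    _write_artifacts(cfg, "pf3-aco", result)
    return result


# ---------------------------------------------------------------------------
# configuration files

def config_from_yaml(path: str | Path, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file, with keyword overrides.

    Top-level keys mirror the RunConfig fields; nested sections (``scene``,
    ``reduction``, ``svm``, ``ga``, ``pso``, ``aco``) accept the matching
    dataclass fields.  Overrides win over file values.
    """
    import yaml

    from .synthetic import SyntheticSceneSpec
    from .types import SpectralGrid

    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    sections = {
        "scene": SyntheticSceneSpec,
        "reduction": ReductionConfig,
        "svm": SVMConfig,
        "ga": GAConfig,
        "pso": PSOConfig,
        "aco": ACOConfig,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in sections and isinstance(value, dict):
            if key == "scene" and "grid" in value:
                g = value["grid"]
                value = {**value, "grid": SpectralGrid.linear(
                    g["lambda_min"], g["lambda_max"], g["n_bands"])}
            kwargs[key] = sections[key](**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# artifacts

def _write_artifacts(cfg: RunConfig, name: str, payload: dict) -> None:
    if cfg.output_dir is None:
        return
    run_dir = Path(cfg.output_dir) / f"{name}-seed{cfg.global_seed}"
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "result.json").write_text(json.dumps(payload, indent=2, default=_json_default))
    (run_dir / "config.json").write_text(
        json.dumps(asdict(cfg), indent=2, default=_json_default)
    )
    logger.info("artifacts written to %s", run_dir)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)
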