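"""Wrapper band selection with metaheuristics.

A candidate band subset is encoded as a binary mask over the spectral grid
and scored by a user-supplied fitness function (lower is better; in the full
pipeline this trains an SVM on the subset and returns a size-penalized error,
see :func:`make_wrapper_fitness`).  Three search strategies are provided:

* :func:`ga_select` — generational genetic algorithm: tournament selection,
  k-point crossover, per-bit mutation, elitism;
* :func:`pso_select` — binary particle swarm: real-valued velocities updated
  from personal/global bests, positions re-sampled through a sigmoid
  transfer function;
* :func:`aco_rank` — MAX-MIN-style ant colony that deposits pheromone on
  bands appearing in high-quality subsets; the terminal pheromone yields a
  relevance *ranking* rather than a single subset, evaluated at several
  top-k cutoffs.

All three are deterministic under their config seed, and every optimizer
repairs empty masks (a subset must contain at least one band).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .evaluate import SVMConfig
from .metrics import FitnessValue, fom, penalized, report_from_labels
from .types import BandSubset, LabeledDataset, SpectralGrid

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    crossover_points: int = 2
    mutation_rate: float | None = None  # default 1/n_bands per bit
    elitism_count: int = 2
    init_density: float = 0.5
    patience: int = 20
    epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.crossover_rate,):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class PSOConfig:
    n_particles: int = 30
    iterations: int = 100
    alpha: float = 0.72  # inertia weight
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 4.0
    init_density: float = 0.5
    patience: int = 20
    epsilon: float = 1e-6
    seed: int = 0


@dataclass(frozen=True)
class ACOConfig:
    n_ants: int = 20
    iterations: int = 30
    evaporation_rate: float = 0.2
    pheromone_weight: float = 1.0  # alpha exponent on pheromone
    heuristic_weight: float = 2.0  # beta exponent on desirability
    subset_size: int = 20
    top_k_list: tuple[int, ...] = (20, 40, 60, 80, 100)
    tau_min: float = 0.01
    tau_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.evaporation_rate < 1:
            raise ValueError("evaporation_rate must lie in (0, 1)")


# ---------------------------------------------------------------------------
# shared helpers

def _fitness_of(fitness_fn, mask: np.ndarray) -> float:
    out = fitness_fn(mask)
    return float(out.value) if isinstance(out, FitnessValue) else float(out)


class _CachedFitness:
    """Memoize fitness by band mask so identical subsets train once."""

    def __init__(self, fitness_fn):
        self._fn = fitness_fn
        self._cache: dict[bytes, float] = {}
        self.evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            self._cache[key] = _fitness_of(self._fn, mask)
            self.evaluations += 1
        return self._cache[key]


#: tie-break weight: at exactly equal fitness, prefer the smaller subset.
#: Small enough never to override a genuine fitness difference from a
#: finite validation set (whose error granularity is ~1/n_validation).
_SIZE_TIEBREAK = 1e-9


def _ranked(value: float, mask: np.ndarray) -> float:
    """Comparison score: fitness refined by subset size at exact ties.

    The penalized metrics lose their size pressure when the base metric
    saturates at 1 (zero error implies zero penalty for any subset size);
    since the whole point of band selection is the smallest sufficient
    subset, ties are resolved toward fewer bands.
    """
    return value + _SIZE_TIEBREAK * (mask.sum() / mask.size)


def _repair_empty(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask[rng.integers(mask.size)] = True
    return mask


def stopping_rule(trace, patience: int, epsilon: float) -> bool:
    """True when the best fitness improved by < epsilon over the last
    ``patience`` iterations (strict: improvement exactly epsilon continues)."""
    trace = list(trace)
    if len(trace) <= patience:
        return False
    improvement = trace[-patience - 1] - trace[-1]
    return improvement < epsilon


# ---------------------------------------------------------------------------
# genetic algorithm

def ga_select(
    fitness_fn, n_bands_total: int, cfg: GAConfig = GAConfig(), grid: SpectralGrid | None = None
) -> tuple[BandSubset, list[float]]:
    """Binary-chromosome GA minimizing ``fitness_fn``.

    Returns the best-ever subset and the per-generation best-so-far trace
    (non-increasing by construction).
    """
    rng = np.random.default_rng(cfg.seed)
    fit = _CachedFitness(fitness_fn)
    mut_rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n_bands_total

    pop = rng.random((cfg.population_size, n_bands_total)) < cfg.init_density
    for row in pop:
        _repair_empty(row, rng)
    values = np.array([fit(row) for row in pop])
    scores = np.array([_ranked(v, m) for v, m in zip(values, pop)])

    best_idx = int(scores.argmin())
    best_mask, best_value = pop[best_idx].copy(), float(values[best_idx])
    best_score = float(scores[best_idx])
    trace = [best_value]
    ranked_trace = [best_score]

    for _ in range(cfg.generations):
        children = []
        elite_order = np.argsort(scores, kind="stable")[: cfg.elitism_count]
        while len(children) < cfg.population_size - cfg.elitism_count:
            p1 = _tournament(scores, rng)
            p2 = _tournament(scores, rng)
            c1, c2 = pop[p1].copy(), pop[p2].copy()
            if rng.random() < cfg.crossover_rate:
                c1, c2 = _k_point_crossover(c1, c2, cfg.crossover_points, rng)
            for child in (c1, c2):
                flip = rng.random(n_bands_total) < mut_rate
                child ^= flip
                _repair_empty(child, rng)
                children.append(child)
        pop = np.array([pop[i] for i in elite_order] + children[: cfg.population_size - cfg.elitism_count])
        values = np.array([fit(row) for row in pop])
        scores = np.array([_ranked(v, m) for v, m in zip(values, pop)])
        gen_best = int(scores.argmin())
        if scores[gen_best] < best_score:
            best_score = float(scores[gen_best])
            best_value = float(values[gen_best])
            best_mask = pop[gen_best].copy()
        trace.append(best_value)
        ranked_trace.append(best_score)
        # stop only when neither fitness nor subset size is still improving
        if stopping_rule(trace, cfg.patience, cfg.epsilon) and stopping_rule(
            ranked_trace, cfg.patience, _SIZE_TIEBREAK / (2 * n_bands_total)
        ):
            break

    grid = grid if grid is not None else SpectralGrid(np.arange(n_bands_total, dtype=float))
    return BandSubset.from_mask(best_mask, grid), trace


def _tournament(scores: np.ndarray, rng: np.random.Generator, size: int = 2) -> int:
    contenders = rng.integers(scores.size, size=size)
    return int(contenders[np.argmin(scores[contenders])])


def _k_point_crossover(
    a: np.ndarray, b: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = a.size
    if n < 2:
        return a, b
    points = np.sort(rng.choice(np.arange(1, n), size=min(k, n - 1), replace=False))
    swap = np.zeros(n, dtype=bool)
    toggle = False
    prev = 0
    for pt in list(points) + [n]:
        if toggle:
            swap[prev:pt] = True
        toggle = not toggle
        prev = pt
    a2, b2 = a.copy(), b.copy()
    a2[swap], b2[swap] = b[swap], a[swap]
    return a2, b2


# ---------------------------------------------------------------------------
# binary particle swarm

def pso_select(
    fitness_fn, n_bands_total: int, cfg: PSOConfig = PSOConfig(), grid: SpectralGrid | None = None
) -> tuple[BandSubset, list[float]]:
    """Binary PSO: v <- alpha*v + c1*rand*(pbest - x) + c2*rand*(gbest - x),
    bits re-sampled as 1 with probability sigmoid(v)."""
    rng = np.random.default_rng(cfg.seed)
    fit = _CachedFitness(fitness_fn)

    x = (rng.random((cfg.n_particles, n_bands_total)) < cfg.init_density).astype(float)
    for row in x:
        if not row.any():
            row[rng.integers(row.size)] = 1.0
    v = rng.uniform(-cfg.v_max, cfg.v_max, size=x.shape)
    values = np.array([fit(row.astype(bool)) for row in x])
    scores = np.array([_ranked(val, row.astype(bool)) for val, row in zip(values, x)])

    pbest, pbest_scores = x.copy(), scores.copy()
    pbest_values = values.copy()
    g = int(scores.argmin())
    gbest, gbest_score = x[g].copy(), float(scores[g])
    gbest_value = float(values[g])
    trace = [gbest_value]
    ranked_trace = [gbest_score]

    for _ in range(cfg.iterations):
        r1 = rng.random(x.shape)
        r2 = rng.random(x.shape)
        v = cfg.alpha * v + cfg.c1 * r1 * (pbest - x) + cfg.c2 * r2 * (gbest - x)
        np.clip(v, -cfg.v_max, cfg.v_max, out=v)
        prob = 1.0 / (1.0 + np.exp(-v))
        x = (rng.random(x.shape) < prob).astype(float)
        for row in x:
            if not row.any():
                row[rng.integers(row.size)] = 1.0
        values = np.array([fit(row.astype(bool)) for row in x])
        scores = np.array([_ranked(val, row.astype(bool)) for val, row in zip(values, x)])
        improved = scores < pbest_scores
        pbest[improved] = x[improved]
        pbest_scores[improved] = scores[improved]
        pbest_values[improved] = values[improved]
        g = int(pbest_scores.argmin())
        if pbest_scores[g] < gbest_score:
            gbest_score = float(pbest_scores[g])
            gbest_value = float(pbest_values[g])
            gbest = pbest[g].copy()
        trace.append(gbest_value)
        ranked_trace.append(gbest_score)
        if stopping_rule(trace, cfg.patience, cfg.epsilon) and stopping_rule(
            ranked_trace, cfg.patience, _SIZE_TIEBREAK / (2 * n_bands_total)
        ):
            break

    grid = grid if grid is not None else SpectralGrid(np.arange(n_bands_total, dtype=float))
    return BandSubset.from_mask(gbest.astype(bool), grid), trace


# ---------------------------------------------------------------------------
# ant colony ranking

def fisher_scores(train: LabeledDataset) -> np.ndarray:
    """Per-band class-separability heuristic (pairwise Fisher ratio sum)."""
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise ValueError("need at least two classes for separability scores")
    means = np.stack([train.spectra[train.labels == c].mean(axis=0) for c in classes])
    variances = np.stack([train.spectra[train.labels == c].var(axis=0) for c in classes])
    score = np.zeros(train.n_bands)
    for i in range(classes.size):
        for j in range(i + 1, classes.size):
            score += (means[i] - means[j]) ** 2 / (variances[i] + variances[j] + 1e-12)
    return score


def aco_rank(
    train: LabeledDataset,
    cfg: ACOConfig = ACOConfig(),
    quality_fn=None,
    svm_cfg: SVMConfig = SVMConfig(),
    validation_fraction: float = 0.25,
) -> np.ndarray:
    """Rank all bands by relevance via ant-colony pheromone accumulation.

    Ants build subsets of ``cfg.subset_size`` bands; a band's selection
    probability combines pheromone with a desirability heuristic (Fisher
    separability discounted by absolute correlation with bands the ant has
    already picked, discouraging redundant neighbours).  Subset quality —
    by default, SVM overall accuracy on a held-out split of ``train`` —
    is deposited as pheromone on member bands; evaporation forgets weak
    trails.  Returns every band index ordered most- to least-relevant
    (ties broken by heuristic, then index).
    """
    rng = np.random.default_rng(cfg.seed)
    heur = fisher_scores(train)
    heur = heur / (heur.max() + 1e-12) + 1e-6
    n_bands = train.n_bands
    size = min(cfg.subset_size, n_bands)

    if quality_fn is None:
        quality_fn = _holdout_quality(train, svm_cfg, validation_fraction, rng)

    corr = np.abs(np.corrcoef(train.spectra, rowvar=False))
    np.nan_to_num(corr, copy=False, nan=0.0)

    tau = np.full(n_bands, cfg.tau_max)
    for _ in range(cfg.iterations):
        deposits = np.zeros(n_bands)
        for _ant in range(cfg.n_ants):
            chosen: list[int] = []
            available = np.ones(n_bands, dtype=bool)
            for _step in range(size):
                desir = heur.copy()
                if chosen:
                    desir = desir * (1.0 - corr[:, chosen].mean(axis=1))
                weights = (tau ** cfg.pheromone_weight) * np.clip(desir, 1e-9, None) ** cfg.heuristic_weight
                weights[~available] = 0.0
                total = weights.sum()
                if total <= 0:
                    break
                pick = rng.choice(n_bands, p=weights / total)
                chosen.append(int(pick))
                available[pick] = False
            quality = float(quality_fn(np.array(sorted(chosen))))
            deposits[chosen] += quality / size
        tau = (1.0 - cfg.evaporation_rate) * tau + deposits
        np.clip(tau, cfg.tau_min, cfg.tau_max, out=tau)

    # stable lexicographic order: pheromone desc, heuristic desc, index asc
    order = np.lexsort((np.arange(n_bands), -heur, -tau))
    return order


def _holdout_quality(
    train: LabeledDataset, svm_cfg: SVMConfig, validation_fraction: float, rng: np.random.Generator
):
    """Default ACO subset quality: SVM OA on a stratified holdout of train."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(train.n_pixels)
    tr_idx, va_idx = train_test_split(
        idx,
        test_size=validation_fraction,
        stratify=train.labels,
        random_state=int(rng.integers(2**31)),
    )
    tr, va = train.subset(tr_idx), train.subset(va_idx)

    def quality(band_indices: np.ndarray) -> float:
        model = svm_cfg.make()
        model.fit(tr.spectra[:, band_indices], tr.labels)
        return float((model.predict(va.spectra[:, band_indices]) == va.labels).mean())

    return quality


def aco_topk_evaluate(ranking: np.ndarray, top_k_list, eval_harness) -> dict[int, object]:
    """Evaluate the first k ranked bands for each k via ``eval_harness``.

    ``eval_harness`` maps a sorted index array to a report (typically a
    cross-validated :class:`~hsiband.metrics.MetricsReport` aggregate).
    """
    ranking = np.asarray(ranking, dtype=int)
    out = {}
    for k in top_k_list:
        if k > ranking.size:
            raise ValueError(f"top-k {k} exceeds band count {ranking.size}")
        out[int(k)] = eval_harness(np.sort(ranking[:k]))
    return out


# ---------------------------------------------------------------------------
# wrapper fitness

def make_wrapper_fitness(
    train: LabeledDataset,
    validation: LabeledDataset,
    base_metric: str = "fom_p",
    svm_cfg: SVMConfig = SVMConfig(),
    penalty_form: str = "product",
):
    """Penalized SVM-wrapper fitness over band masks (lower is better).

    Trains on ``train`` restricted to the mask, scores on ``validation``:
    base is overall accuracy (``oa_p``) or the class-balance figure of merit
    over per-class accuracies (``fom_p``), penalized by subset size.
    """
    if base_metric not in {"oa_p", "fom_p"}:
        raise ValueError("base_metric must be 'oa_p' or 'fom_p'")
    n_total = train.n_bands

    def fitness(mask: np.ndarray) -> FitnessValue:
        idx = np.flatnonzero(np.asarray(mask, dtype=bool))
        if idx.size == 0:
            raise ValueError("empty band mask")
        model = svm_cfg.make()
        model.fit(train.spectra[:, idx], train.labels)
        predicted = model.predict(validation.spectra[:, idx])
        report = report_from_labels(validation.labels, predicted)
        if base_metric == "oa_p":
            base = report.oa
        else:
            accs = [s for s in report.sensitivity if not np.isnan(s)]
            base = fom(accs) if len(accs) >= 2 else 0.0
        return penalized(base, idx.size, n_total, which=base_metric, form=penalty_form)

    return fitness
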