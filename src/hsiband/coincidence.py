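"""Aggregation of per-fold band selections into coincidence levels.

Wrapper selection inside leave-one-patient-out cross-validation yields a
different band set per fold.  Level L_i collects the bands chosen in at
least i folds: L1 is the union of all selections, higher levels keep only
bands the folds agree on.  By construction L_{i+1} is nested inside L_i.
Contiguous selected bands are also reported as wavelength ranges, which is
how a customized reduced-band sensor would be specified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import BandSubset, SpectralGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoincidenceLevels:
    """levels[i] = bands selected in >= i of the per-fold sets (1-based)."""

    levels: dict[int, BandSubset | None]
    n_folds: int
    grid: SpectralGrid

    def nonempty_levels(self) -> dict[int, BandSubset]:
        return {i: s for i, s in self.levels.items() if s is not None}


def compute_levels(band_sets: list[BandSubset]) -> CoincidenceLevels:
    """Membership-count the per-fold selections into nested levels."""
    if not band_sets:
        raise ValueError("need at least one band set")
    grid = band_sets[0].grid
    for s in band_sets[1:]:
        if s.grid != grid:
            raise ValueError("band sets must share a common grid")
    counts = np.zeros(grid.n_bands, dtype=int)
    for s in band_sets:
        counts[s.indices] += 1
    n_folds = len(band_sets)
    levels: dict[int, BandSubset | None] = {}
    for i in range(1, n_folds + 1):
        idx = np.flatnonzero(counts >= i)
        levels[i] = BandSubset(idx, grid) if idx.size else None
    return CoincidenceLevels(levels, n_folds, grid)


def contiguous_ranges(subset: BandSubset, gap_tolerance: int = 0) -> list[tuple[float, float]]:
    """Merge selected band indices into (min nm, max nm) wavelength ranges.

    Runs separated by more than ``gap_tolerance`` unselected bands start a
    new range; a single band yields a zero-width range.
    """
    idx = subset.indices
    wl = subset.grid.wavelengths
    ranges: list[tuple[float, float]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap_tolerance + 1:
            ranges.append((float(wl[start]), float(wl[prev])))
            start = i
        prev = i
    ranges.append((float(wl[start]), float(wl[prev])))
    return ranges


def evaluate_levels(levels: CoincidenceLevels, eval_harness) -> dict[int, object]:
    """Re-run the cross-validated evaluation restricted to each level's bands.

    ``eval_harness`` maps a :class:`BandSubset` to an aggregated report.
    Empty levels are skipped with a warning.
    """
    out = {}
    for i, subset in levels.levels.items():
        if subset is None:
            logger.warning("coincidence level L%d is empty; skipped", i)
            continue
        out[i] = eval_harness(subset)
    return out


def levels_table(levels: CoincidenceLevels, reports: dict[int, dict]) -> "pd.DataFrame":
    """Table-style summary: one row per level with OA/MCC/sens/spec mean (std)."""
    import pandas as pd

    rows = []
    for i, rep in reports.items():
        subset = levels.levels[i]
        row = {
            "level": f"L{i}",
            "n_bands": subset.n_selected,
            "oa_mean": rep["oa"]["mean"],
            "oa_std": rep["oa"]["std"],
        }
        for k, cls in enumerate(("normal", "tumor", "hypervascular", "background")):
            row[f"sens_{cls}_mean"] = rep["sensitivity"][k]["mean"]
            row[f"spec_{cls}_mean"] = rep["specificity"][k]["mean"]
            row[f"mcc_{cls}_mean"] = rep["mcc_norm"][k]["mean"]
        rows.append(row)
    return pd.DataFrame(rows)
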