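"""Transcript-abundance scoring of in situ hybridization dot counts.

Each cell's dot count maps to a five-grade bin (0: no staining; 1: 1-3
dots; 2: 4-9; 3: 10-15; 4: >15) and the H-score aggregates a population as

    H = sum over bins 0-4 of (bin x percentage of cells in bin)

with percentages on the 0-100 scale, so H ranges from 0 (all cells empty)
to 400 (all cells >15 dots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_BIN_UPPER = (0, 3, 9, 15)  # inclusive upper dot count of bins 0-3


@dataclass
class HScoreResult:
    h_score: float
    bin_percentages: np.ndarray   # 5 entries summing to 100
    n_cells: int


def acd_score(dot_count: int) -> int:
    """Five-grade bin of a single cell's dot count."""
    if dot_count < 0:
        raise ValueError("dot count must be >= 0")
    for score, upper in enumerate(_BIN_UPPER):
        if dot_count <= upper:
            return score
    return 4


def _counts_array(counts) -> np.ndarray:
    arr = np.asarray(getattr(counts, "counts", counts))
    if arr.size == 0:
        raise ValueError("need at least one cell")
    if np.any(arr < 0):
        raise ValueError("dot counts must be >= 0")
    return arr


def h_score(counts) -> HScoreResult:
    """H-score of a cell population (array of dot counts or CellDotCounts)."""
    arr = _counts_array(counts)
    bins = np.digitize(arr, [b + 1 for b in _BIN_UPPER])
    pct = np.bincount(bins, minlength=5) / arr.size * 100.0
    return HScoreResult(float(np.dot(np.arange(5), pct)), pct, int(arr.size))


def h_score_by_group(counts) -> pd.DataFrame:
    """Group-level H-scores for labeled dot counts.

    Accepts a :class:`~burstlet.synthetic.CellDotCounts` or a DataFrame with
    ``dot_count`` and ``region_label`` columns; returns one row per group
    with the H-score, bin percentages and cell count.
    """
    if isinstance(counts, pd.DataFrame):
        values = counts["dot_count"].to_numpy()
        labels = counts["region_label"].to_numpy()
    else:
        values, labels = counts.counts, counts.group
    rows = []
    for label in pd.unique(labels):
        res = h_score(values[labels == label])
        rows.append({"region_label": label, "h_score": res.h_score,
                     "n_cells": res.n_cells,
                     **{f"pct_bin{i}": res.bin_percentages[i] for i in range(5)}})
    return pd.DataFrame(rows)
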