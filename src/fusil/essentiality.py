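"""Human cell-line essentiality from CRISPR proliferation scores.

Each gene carries a vector of proliferation (dependency) scores, one
per cancer cell line, with more negative values indicating stronger
essentiality. Genes are summarised by their mean score and called
essential when the mean falls at or below a threshold; the default
threshold of -0.45 is the value that maximises the F1 score against a
reference essential/non-essential labelling, and the same F1 search is
available for refitting against any reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EssentialityProfile",
    "ThresholdSearchResult",
    "DEFAULT_THRESHOLD",
    "default_grid",
    "gene_mean_scores",
    "f1_from_confusion",
    "select_threshold_f1",
    "classify_essential",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = -0.45


@dataclass(frozen=True)
class EssentialityProfile:
    gene_id: str
    scores: tuple[float, ...]
    mean_score: float


@dataclass(frozen=True)
class ThresholdSearchResult:
    grid: np.ndarray
    f1_values: np.ndarray
    selected: float


def default_grid() -> np.ndarray:
    """Threshold search grid: -1.50 to 0.00 in steps of 0.01."""
    return np.round(np.arange(-1.50, 0.005, 0.01), 10)


def gene_mean_scores(matrix: pd.DataFrame) -> list[EssentialityProfile]:
    """Per-gene mean proliferation score over non-missing cell lines.

    ``matrix`` is genes x cell lines (index = gene ids). Genes with no
    scores at all are dropped with a warning.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty score matrix")
    profiles = []
    values = matrix.to_numpy(dtype=float)
    for gene_id, row in zip(matrix.index, values):
        finite = row[np.isfinite(row)]
        if finite.size == 0:
            logger.warning("gene %s has no scores; dropped", gene_id)
            continue
        profiles.append(
            EssentialityProfile(str(gene_id), tuple(finite), float(finite.mean()))
        )
    return profiles


def f1_from_confusion(tp: int, fp: int, fn: int) -> float:
    """F1 = 2*TP / (2*TP + FP + FN); NaN (with a warning) when all zero."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        logger.warning("F1 undefined for an all-zero confusion matrix")
        return float("nan")
    return 2 * tp / denom


def select_threshold_f1(
    means: Mapping[str, float],
    reference: Mapping[str, str],
    grid: Sequence[float] | None = None,
) -> ThresholdSearchResult:
    """Choose the mean-score cut-off that maximises F1 against a
    reference labelling.

    A gene is predicted essential when its mean score is <= t;
    reference essentials are the positive class. Ties in the maximal F1
    are broken toward the grid value closest to the midpoint of the
    tied run (lower value on a residual tie), which is deterministic
    and symmetric.
    """
    grid_arr = np.asarray(default_grid() if grid is None else grid, dtype=float)
    if grid_arr.size == 0:
        raise ValueError("empty threshold grid")
    genes = [g for g in means if g in reference]
    labels = np.array([reference[g] == "essential" for g in genes])
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("reference must contain >= 2 genes of each class")
    m = np.array([means[g] for g in genes], dtype=float)
    pred = m[None, :] <= grid_arr[:, None]  # thresholds x genes
    tp = (pred & labels[None, :]).sum(axis=1)
    fp = (pred & ~labels[None, :]).sum(axis=1)
    fn = (~pred & labels[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        f1 = 2 * tp / (2 * tp + fp + fn)
    best = np.nanmax(f1)
    tied = np.flatnonzero(f1 == best)
    mid = (grid_arr[tied[0]] + grid_arr[tied[-1]]) / 2.0
    selected_idx = tied[np.argmin(np.abs(grid_arr[tied] - mid))]
    return ThresholdSearchResult(grid_arr, f1, float(grid_arr[selected_idx]))


def classify_essential(mean: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Essential iff mean score <= threshold (boundary is essential)."""
    if not math.isfinite(mean):
        raise ValueError(f"non-finite mean score: {mean}")
    return "essential" if mean <= threshold else "non_essential"
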