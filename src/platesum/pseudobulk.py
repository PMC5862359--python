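"""Collapsing single-cell counts to per-plate pseudobulk sums.

Summing the counts of all cells on a plate yields one observation per
plate; plates (not cells) are then treated as the replicate samples in the
DE analysis, which matches the level at which the confounded plate effect
is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import PlateDesign

__all__ = ["SummedCounts", "sum_by_plate", "residual_df", "filter_low_abundance"]


@dataclass(frozen=True)
class SummedCounts:
    """Gene x plate count sums with per-plate group labels."""

    counts: np.ndarray
    plates: np.ndarray
    plate_group: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape[1] != self.plates.size or self.plates.size != self.plate_group.size:
            raise ValueError("counts, plates and plate_group disagree on plate count")


def sum_by_plate(counts: np.ndarray, design: PlateDesign) -> SummedCounts:
    """Sum counts over all cells of each plate.

    Column ``k`` of the result is the elementwise sum of the input columns
    belonging to plate ``k``; plate order is first-appearance order in the
    design. Per-gene totals are conserved exactly.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be a gene x cell matrix")
    if counts.shape[1] != design.n_cells:
        raise ValueError(
            f"counts has {counts.shape[1]} cells but the design describes {design.n_cells}"
        )
    plate_idx = design.plate_index()
    summed = np.zeros((counts.shape[0], design.n_plates), dtype=counts.dtype)
    np.add.at(summed.T, plate_idx, counts.T)
    return SummedCounts(counts=summed, plates=design.plates, plate_group=design.plate_group)


def residual_df(n_samples: int, n_coefficients: int) -> int:
    """Residual degrees of freedom of a linear model fit.

    ``n_samples - n_coefficients``; this is what governs how much
    information is available to estimate variances. Treating 300 cells as
    replicates in a two-group layout claims 298 residual d.f., whereas the
    six per-plate sums of the same experiment provide only 4.
    """
    if n_coefficients < 1:
        raise ValueError("n_coefficients must be at least 1")
    if n_samples <= n_coefficients:
        raise ValueError(
            f"no residual degrees of freedom with {n_samples} samples and "
            f"{n_coefficients} coefficients; the model is saturated"
        )
    return n_samples - n_coefficients


def filter_low_abundance(
    counts: np.ndarray, min_mean: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Drop genes whose average count across samples is below ``min_mean``.

    The boundary is kept: a gene with mean exactly ``min_mean`` survives
    (only means strictly below the threshold are filtered). Returns the
    filtered matrix and the integer indices of the kept rows.
    """
    counts = np.asarray(counts)
    if min_mean < 0:
        raise ValueError("min_mean must be non-negative")
    keep = np.flatnonzero(counts.mean(axis=1) >= min_mean)
    return counts[keep], keep
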