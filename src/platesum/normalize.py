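"""Per-sample scaling normalization and (log-)CPM computation.

Two size-factor flavours are provided: raw library sizes (column sums),
the sufficient estimate of the per-cell scaling factor in the simulation
model, and median-of-ratios (DESeq-style) factors for plate-level count
sums, which are robust to composition differences between plates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gmean

__all__ = [
    "NormalizationFactors",
    "library_sizes",
    "cpm",
    "median_ratio_size_factors",
    "libsize_factors",
    "effective_library_sizes",
]


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample scaling factors and the method that produced them."""

    size_factor: np.ndarray
    method: str  # "libsize" or "median_ratio"

    def __post_init__(self) -> None:
        if np.any(self.size_factor <= 0) or not np.all(np.isfinite(self.size_factor)):
            raise ValueError("size factors must be finite and strictly positive")


def library_sizes(counts: np.ndarray) -> np.ndarray:
    """Column totals of the count matrix; errors on empty (zero-total) samples."""
    counts = np.asarray(counts)
    totals = counts.sum(axis=0, dtype=np.float64)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(f"samples with zero total counts: columns {bad.tolist()}")
    return totals


def cpm(
    counts: np.ndarray,
    size_factors: np.ndarray,
    log: bool = False,
    prior_count: float = 0.5,
) -> np.ndarray:
    """Counts per million against effective library sizes.

    Non-log: ``count / L * 1e6``. Log: ``log2((count + prior) / (L + 2*prior)
    * 1e6)`` — the prior keeps zeros finite and the damped library size keeps
    the transform consistent between samples.
    """
    counts = np.asarray(counts, dtype=np.float64)
    lib = np.asarray(size_factors, dtype=np.float64)
    if np.any(lib <= 0):
        raise ValueError("effective library sizes must be strictly positive")
    if not log:
        return counts / lib * 1e6
    return np.log2((counts + prior_count) / (lib + 2.0 * prior_count) * 1e6)


def median_ratio_size_factors(counts: np.ndarray) -> NormalizationFactors:
    """Median-of-ratios size factors (the DESeq estimator).

    For each gene positive in every sample, form the ratio of each sample's
    count to the gene's geometric mean across samples; the factor of a
    sample is the median of its ratios. Factors are rescaled to geometric
    mean 1 so effective library sizes stay on the library-size scale.
    """
    counts = np.asarray(counts, dtype=np.float64)
    all_positive = np.all(counts > 0, axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter low-abundance "
            "genes before computing median-of-ratios factors"
        )
    ref = counts[all_positive]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / gmean(factors)
    return NormalizationFactors(size_factor=factors, method="median_ratio")


def effective_library_sizes(counts: np.ndarray, factors: NormalizationFactors) -> np.ndarray:
    """Effective library size per sample for CPM and GLM offsets.

    ``libsize`` factors are the library sizes themselves; ``median_ratio``
    factors (geometric mean 1) are rescaled by the geometric mean of the
    raw library sizes so downstream CPM values remain interpretable.
    """
    if factors.method == "libsize":
        return factors.size_factor
    return factors.size_factor * gmean(library_sizes(counts))


def libsize_factors(counts: np.ndarray) -> NormalizationFactors:
    """Library-size normalization factors (column totals)."""
    return NormalizationFactors(size_factor=library_sizes(counts), method="libsize")
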