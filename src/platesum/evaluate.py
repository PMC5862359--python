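"""Benchmark metrics and the multi-iteration simulation harness.

The core question the harness answers: when every plate holds cells of a
single group, does an analysis that treats cells as replicates keep its
nominal type I error rate, and does summing counts to one observation per
plate restore it? Observed error rates are the proportion of (truly null)
genes with p below the nominal level; power runs add observed FDR at a
BH-adjusted threshold and ROC curves against the spiked ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import de_linear, de_nb, normalize, pseudobulk, sim
from .designs import one_way_design
from .multitest import bh_adjust
from .result import DEResult

__all__ = [
    "observed_error_rate",
    "bh_adjust",
    "observed_fdr",
    "roc_points",
    "tpr_at_fpr",
    "run_de",
    "run_benchmark",
    "BenchmarkSummary",
    "ENGINES",
    "MODES",
]

ENGINES = ("voom", "ql", "lrt")
MODES = ("single", "summed")


def observed_error_rate(pvalues: np.ndarray, alpha: float) -> float:
    """Proportion of genes with a p-value strictly below ``alpha``."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return float(np.mean(p < alpha))


def observed_fdr(adjusted_pvalues: np.ndarray, true_de: np.ndarray, threshold: float) -> float:
    """Fraction of rejections that are truly non-DE; 0 when nothing is rejected."""
    adj = np.asarray(adjusted_pvalues, dtype=np.float64)
    truth = np.asarray(true_de, dtype=bool)
    if adj.shape != truth.shape:
        raise ValueError("adjusted p-values and truth labels differ in length")
    rejected = adj < threshold
    if not rejected.any():
        return 0.0
    return float(np.mean(~truth[rejected]))


def roc_points(pvalues: np.ndarray, true_de: np.ndarray) -> np.ndarray:
    """(FPR, TPR) pairs from sweeping the p-value threshold.

    One point per distinct p-value (ties grouped), with (0, 0) prepended
    and (1, 1) appended; both coordinates are non-decreasing.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    truth = np.asarray(true_de, dtype=bool)
    if p.shape != truth.shape:
        raise ValueError("p-values and truth labels differ in length")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both DE and non-DE genes are required for a ROC curve")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    tp = np.cumsum(truth[order])
    fp = np.cumsum(~truth[order])
    # keep the last index of each tied run so ties move together
    last_of_run = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    tpr = tp[last_of_run] / n_pos
    fpr = fp[last_of_run] / n_neg
    pts = np.column_stack([np.r_[0.0, fpr, 1.0], np.r_[0.0, tpr, 1.0]])
    return pts


def tpr_at_fpr(points: np.ndarray, fpr: float) -> float:
    """Linear interpolation of the ROC curve at a given false positive rate."""
    pts = np.asarray(points, dtype=np.float64)
    return float(np.interp(fpr, pts[:, 0], pts[:, 1]))


def run_de(
    counts: np.ndarray,
    groups: np.ndarray,
    engine: str,
    effective_lib: np.ndarray,
    dispersion: np.ndarray | None = None,
) -> DEResult:
    """Run one DE engine on a count matrix with a two-group one-way design.

    ``effective_lib`` supplies per-sample effective library sizes (from
    either normalization flavour); NB engines receive their log as offsets.
    ``dispersion`` accepts a precomputed :class:`~platesum.de_nb.DispersionEstimates`
    so the APL grid pass can be shared between the NB engines: the LRT
    consumes the gene-wise (tagwise) estimates directly (per-gene, no
    shrinkage), while the QL engine consumes the abundance trend, so
    gene-specific variability is captured by the EB-squeezed
    quasi-dispersions rather than absorbed into the NB dispersion.
    """
    X, labels = one_way_design(groups)
    if labels.size != 2:
        raise ValueError("run_de expects exactly two groups")
    if engine == "voom":
        return de_linear.voom_pipeline(counts, effective_lib, X, contrast=1)
    offsets = np.log(effective_lib)
    if dispersion is None:
        dispersion = de_nb.estimate_dispersions(
            counts, X, offsets, tagwise=(engine == "lrt"), trended=(engine == "ql")
        )
    if engine == "ql":
        return de_nb.ql_ftest(counts, X, offsets, dispersion.trended, coef=1)
    if engine == "lrt":
        X_null = np.delete(X, 1, axis=1)
        return de_nb.lrt(counts, X, X_null, offsets, dispersion.tagwise, coef=1)
    raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")


@dataclass(frozen=True)
class BenchmarkSummary:
    """Aggregated and per-iteration benchmark metrics.

    ``summary`` has one row per (scenario, engine, mode, metric) with the
    aggregate value and a standard error; error rates are aggregated as
    geometric means with the SE computed on the log rates (zero rates get a
    continuity correction of half a reciprocal gene count before logging),
    FDR/TPR arithmetically. ``detail`` keeps every iteration's value.
    """

    summary: pd.DataFrame
    detail: pd.DataFrame
    roc: dict = field(default_factory=dict)

    def value(self, scenario: str, engine: str, mode: str, metric: str) -> float:
        rows = self.summary
        sel = rows[
            (rows.scenario == scenario)
            & (rows.engine == engine)
            & (rows["mode"] == mode)
            & (rows.metric == metric)
        ]
        if len(sel) != 1:
            raise KeyError((scenario, engine, mode, metric))
        return float(sel.value.iloc[0])


def _iteration_seed(root_seed: int, scenario_idx: int, iteration: int) -> int:
    """Deterministic per-iteration seed: a counter-keyed SeedSequence draw."""
    ss = np.random.SeedSequence(entropy=[int(root_seed), scenario_idx, iteration])
    return int(ss.generate_state(1)[0] % (2**31))


def _geo_mean_with_se(rates: np.ndarray, floor: float) -> tuple[float, float]:
    logs = np.log(np.maximum(rates, floor))
    se = float(logs.std(ddof=1) / math.sqrt(logs.size)) if logs.size > 1 else 0.0
    return float(np.exp(logs.mean())), se


def run_benchmark(
    scenarios=("default",),
    engines=("ql", "voom"),
    modes=MODES,
    n_iterations: int = 10,
    alpha: float = 0.01,
    seed: int = 0,
    n_genes: int | None = None,
    de_fraction: float | None = None,
    de_log2fc: float | None = None,
    fdr_threshold: float = 0.05,
    keep_roc: bool = False,
) -> BenchmarkSummary:
    """Simulate, analyse and score a grid of scenarios x engines x modes.

    Each iteration simulates a fresh dataset (per-iteration seeds derived
    deterministically from ``seed`` by a counter scheme), filters genes with
    average count below 1 across cells, and analyses the single-cell matrix
    (cells as replicates, library-size normalization) and/or the per-plate
    count sums (median-of-ratios normalization) with each engine. The same
    kept-gene set is used in both modes so comparisons are gene-matched,
    and the Cox–Reid dispersion estimate is shared between the NB engines
    within an (iteration, mode) cell.
    """
    for engine in engines:
        if engine not in ENGINES:
            raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    for mode in modes:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")

    records = []
    roc_store: dict = {}
    for s_idx, scen in enumerate(scenarios):
        overrides = {}
        if n_genes is not None:
            overrides["n_genes"] = n_genes
        if de_fraction is not None:
            overrides["de_fraction"] = de_fraction
        if de_log2fc is not None:
            overrides["de_log2fc"] = de_log2fc
        for it in range(n_iterations):
            cfg = sim.scenario(scen, seed=_iteration_seed(seed, s_idx, it), **overrides)
            ds = sim.simulate_dataset(cfg)
            counts, kept = pseudobulk.filter_low_abundance(ds.counts, min_mean=1.0)
            true_de = ds.true_de[kept]
            spiked = bool(cfg.de_fraction > 0)

            for mode in modes:
                if mode == "single":
                    mat = counts
                    groups = ds.design.cell_group
                    eff = normalize.library_sizes(mat)
                else:
                    summed = pseudobulk.sum_by_plate(counts, ds.design)
                    mat = summed.counts
                    groups = summed.plate_group
                    factors = normalize.median_ratio_size_factors(mat)
                    eff = normalize.effective_library_sizes(mat, factors)

                dispersion = None
                if "ql" in engines or "lrt" in engines:
                    X, _ = one_way_design(groups)
                    dispersion = de_nb.estimate_dispersions(
                        mat, X, np.log(eff),
                        tagwise=("lrt" in engines), trended=("ql" in engines),
                    )
                for engine in engines:
                    res = run_de(mat, groups, engine, eff, dispersion=dispersion)
                    row = {
                        "scenario": scen,
                        "engine": engine,
                        "mode": mode,
                        "iteration": it,
                        "n_genes": mat.shape[0],
                    }
                    if spiked:
                        null_p = res.pvalue[~true_de]
                        row["error_rate"] = observed_error_rate(null_p, alpha)
                        row["fdr"] = observed_fdr(res.fdr, true_de, fdr_threshold)
                        pts = roc_points(res.pvalue, true_de)
                        row["tpr_at_fpr_0.01"] = tpr_at_fpr(pts, 0.01)
                        if keep_roc:
                            roc_store.setdefault((scen, engine, mode), []).append(pts)
                    else:
                        row["error_rate"] = observed_error_rate(res.pvalue, alpha)
                    records.append(row)

    detail = pd.DataFrame.from_records(records)
    metric_cols = [c for c in ("error_rate", "fdr", "tpr_at_fpr_0.01") if c in detail]
    summaries = []
    for (scen, engine, mode), block in detail.groupby(
        ["scenario", "engine", "mode"], sort=False
    ):
        for metric in metric_cols:
            vals = block[metric].dropna().to_numpy()
            if vals.size == 0:
                continue
            if metric == "error_rate":
                floor = 0.5 / float(block["n_genes"].mean())
                value, se = _geo_mean_with_se(vals, floor)
            else:
                value = float(vals.mean())
                se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
            summaries.append(
                {
                    "scenario": scen,
                    "engine": engine,
                    "mode": mode,
                    "metric": metric,
                    "value": value,
                    "se": se,
                    "n_iter": int(vals.size),
                }
            )
    return BenchmarkSummary(
        summary=pd.DataFrame.from_records(summaries), detail=detail, roc=roc_store
    )
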