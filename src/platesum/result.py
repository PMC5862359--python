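"""Common per-gene differential-expression result container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multitest import bh_adjust

__all__ = ["DEResult"]


@dataclass(frozen=True)
class DEResult:
    """Per-gene effect sizes, test statistics and (adjusted) p-values."""

    log2fc: np.ndarray
    stat: np.ndarray
    pvalue: np.ndarray
    fdr: np.ndarray = field(default=None)  # type: ignore[assignment]
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fdr is None:
            object.__setattr__(self, "fdr", bh_adjust(self.pvalue))
        n = self.pvalue.size
        for name in ("log2fc", "stat", "fdr"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match pvalue length")
        if self.gene_ids is not None and len(self.gene_ids) != n:
            raise ValueError("gene_ids length does not match pvalue length")

    @property
    def n_genes(self) -> int:
        return self.pvalue.size

    def to_frame(self) -> pd.DataFrame:
        idx = self.gene_ids if self.gene_ids is not None else np.arange(self.n_genes)
        return pd.DataFrame(
            {
                "gene": idx,
                "log2fc": self.log2fc,
                "stat": self.stat,
                "pvalue": self.pvalue,
                "fdr": self.fdr,
            }
        )
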