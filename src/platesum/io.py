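"""Reading and writing count matrices, designs and fixtures.

TSV dialect: tab-separated, header row, gene ids in the first column,
UTF-8, no quoting. MTX: MatrixMarket coordinate integer format with
sidecar ``genes.tsv`` / ``cells.tsv`` id files in the same directory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .pseudobulk import SummedCounts
from .sim import PlateDesign, SimulatedDataset, scenario, simulate_dataset

__all__ = [
    "AnnotatedMatrix",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "write_truth",
    "make_fixture",
]


@dataclass(frozen=True)
class AnnotatedMatrix:
    """Integer gene x sample matrix with unique row/column identifiers."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        g, s = self.values.shape
        if len(self.gene_ids) != g or len(self.sample_ids) != s:
            raise ValueError("id lengths do not match matrix dimensions")
        if len(set(self.gene_ids)) != g or len(set(self.sample_ids)) != s:
            raise ValueError("gene and sample ids must be unique")


def _validate_integer(values: np.ndarray, gene_ids, sample_ids) -> np.ndarray:
    arr = np.asarray(values)
    bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.round(arr))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer or negative count at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}: {arr[i, j]!r}"
        )
    return arr.astype(np.int64)


def read_counts(path: str | Path, format: str | None = None) -> AnnotatedMatrix:
    """Read a gene x sample count matrix from TSV or MTX.

    The format is inferred from the extension unless given. MTX files must
    sit next to ``genes.tsv`` and ``cells.tsv`` sidecars holding one id per
    line, matching the matrix dimensions.
    """
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = _validate_integer(df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy())
        return AnnotatedMatrix(
            values=values,
            gene_ids=df.index.to_numpy(dtype=object),
            sample_ids=df.columns.to_numpy(dtype=object),
        )
    if fmt == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        genes = np.loadtxt(path.parent / "genes.tsv", dtype=str, ndmin=1)
        cells = np.loadtxt(path.parent / "cells.tsv", dtype=str, ndmin=1)
        if len(genes) != values.shape[0] or len(cells) != values.shape[1]:
            raise ValueError(
                f"id files ({len(genes)} genes, {len(cells)} cells) do not match "
                f"matrix dimensions {values.shape}"
            )
        return AnnotatedMatrix(
            values=_validate_integer(values, genes, cells),
            gene_ids=genes.astype(object),
            sample_ids=cells.astype(object),
        )
    raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")


def write_counts(path: str | Path, matrix: AnnotatedMatrix, format: str | None = None) -> None:
    """Write a count matrix as TSV or MTX (with id sidecars)."""
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
        df.index.name = "gene"
        df.to_csv(path, sep="\t")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(matrix.values), field="integer")
        np.savetxt(path.parent / "genes.tsv", matrix.gene_ids, fmt="%s")
        np.savetxt(path.parent / "cells.tsv", matrix.sample_ids, fmt="%s")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'mtx'")


def read_design(path: str | Path) -> PlateDesign:
    """Read a per-cell design table (columns ``cell``, ``plate``, ``group``).

    Validation enforces the confounded-plate assumption: a plate whose
    cells span two groups is rejected.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"cell", "plate", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"design table lacks columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("design table is empty")
    return PlateDesign(
        cell_plate=df["plate"].to_numpy(dtype=object),
        cell_group=df["group"].to_numpy(dtype=object),
    )


def write_design(path: str | Path, design: PlateDesign, cell_ids=None) -> None:
    if cell_ids is None:
        cell_ids = [f"C{j + 1:04d}" for j in range(design.n_cells)]
    pd.DataFrame(
        {"cell": cell_ids, "plate": design.cell_plate, "group": design.cell_group}
    ).to_csv(path, sep="\t", index=False)


def write_truth(path: str | Path, dataset: SimulatedDataset, gene_ids=None) -> None:
    if gene_ids is None:
        gene_ids = [f"gene{i + 1:05d}" for i in range(dataset.counts.shape[0])]
    pd.DataFrame(
        {
            "gene": gene_ids,
            "true_de": dataset.true_de.astype(int),
            "true_log2fc": dataset.true_log2fc,
        }
    ).to_csv(path, sep="\t", index=False)


def dataset_to_annotated(dataset: SimulatedDataset) -> AnnotatedMatrix:
    """Wrap a simulated count matrix with generated gene/cell identifiers."""
    g, c = dataset.counts.shape
    return AnnotatedMatrix(
        values=dataset.counts,
        gene_ids=np.array([f"gene{i + 1:05d}" for i in range(g)], dtype=object),
        sample_ids=np.array([f"C{j + 1:04d}" for j in range(c)], dtype=object),
    )


def summed_to_annotated(summed: SummedCounts, gene_ids) -> AnnotatedMatrix:
    return AnnotatedMatrix(
        values=summed.counts,
        gene_ids=np.asarray(gene_ids, dtype=object),
        sample_ids=summed.plates.astype(object),
    )


#: deterministic seeds for the named fixtures
_FIXTURE_SEEDS = {name: 7_000 + i for i, name in enumerate(
    ("default", "no_plate_effect", "half_plate_effect", "variable_libsizes",
     "variable_cell_numbers", "more_plates", "zinb")
)}


def make_fixture(name: str, out_dir: str | Path, n_genes: int = 500) -> SimulatedDataset:
    """Write a small deterministic dataset for tests and documentation.

    Produces ``counts.tsv``, ``design.tsv`` and ``truth.tsv`` under
    ``out_dir`` from the named scenario, scaled to ``n_genes`` genes and
    10–20 cells per plate; regenerating a fixture is byte-identical.
    """
    if name not in _FIXTURE_SEEDS:
        raise ValueError(f"unknown fixture {name!r}; valid names: {sorted(_FIXTURE_SEEDS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = scenario(
        name,
        n_genes=n_genes,
        cells_per_plate_range=(10, 20),
        de_fraction=0.1,
        seed=_FIXTURE_SEEDS[name],
    )
    ds = simulate_dataset(cfg)
    am = dataset_to_annotated(ds)
    write_counts(out_dir / "counts.tsv", am)
    write_design(out_dir / "design.tsv", ds.design, cell_ids=am.sample_ids)
    write_truth(out_dir / "truth.tsv", ds, gene_ids=am.gene_ids)
    return ds
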