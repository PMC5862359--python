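"""File-based workflow: counts + design in, per-plate DE table out.

Mirrors what the CLI does: read a gene x cell matrix and a cell/plate/group
table, filter low-abundance genes, sum within plates, normalize the sums by
median-of-ratios and test with the quasi-likelihood NB engine.
"""

import tempfile
import warnings
from pathlib import Path

import platesum as ps
import platesum.io as pio
import platesum.normalize as nz

workdir = Path(tempfile.mkdtemp())
pio.make_fixture("default", workdir, n_genes=400)
print(f"wrote counts.tsv / design.tsv / truth.tsv under {workdir}")

am = pio.read_counts(workdir / "counts.tsv")
design = pio.read_design(workdir / "design.tsv")
counts, kept = ps.filter_low_abundance(am.values, min_mean=1.0)
print(f"{counts.shape[0]} of {am.values.shape[0]} genes pass the "
      f"mean-count >= 1 abundance filter")

summed = ps.sum_by_plate(counts, design)
factors = nz.median_ratio_size_factors(summed.counts)
eff = nz.effective_library_sizes(summed.counts, factors)
print(f"per-plate size factors (median-of-ratios): "
      f"{', '.join(f'{f:.2f}' for f in factors.size_factor)}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = ps.run_de(summed.counts, summed.plate_group, "ql", eff)
table = res.to_frame()
table["gene"] = am.gene_ids[kept]
top = table.sort_values("pvalue").head(5)
print("\ntop 5 genes by p-value (plates as replicate samples):")
print(top.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\ncolumns: log2 fold change (group 2 vs 1), F statistic, p-value and "
      "BH-adjusted p-value")
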