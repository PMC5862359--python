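"""Observed type I error: cells as replicates vs per-plate summation.

All genes are null, so every gene with p < 0.01 is a false positive. The
single-cell analysis (plates ignored) rejects a large fraction; summing
counts within plates and treating the six plate sums as replicate samples
brings the rate back to the nominal level.
"""

import warnings

import platesum as ps

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    out = ps.run_benchmark(
        scenarios=("default", "no_plate_effect"),
        engines=("ql", "voom"),
        modes=("single", "summed"),
        n_iterations=3,
        n_genes=1000,
        alpha=0.01,
        seed=1,
    )

print(out.summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
single = out.value("default", "ql", "single", "error_rate")
summed = out.value("default", "voom", "summed", "error_rate")
print(f"with a plate effect, the single-cell QL analysis rejects "
      f"{single:.1%} of null genes at alpha = 1% "
      f"({single / 0.01:.0f}x the nominal level);")
print(f"the summed moderated-linear-model analysis rejects {summed:.2%}, "
      f"i.e. control is restored; without a plate effect all rates sit near 1%")
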