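"""Two-step normalization: CPM scaling, then log2 ratios vs euploid controls.

A monosomic chromosome (one of two copies lost) should sit near
log2(1/2) = -1 in the normalized profile; a balanced chromosome near 0.
"""

import numpy as np

from gbskaryo import demo_config, normalize_counts, simulate_cohort

config = demo_config(seed=1)
matrix, sheet, _ = simulate_cohort(config)
norm = normalize_counts(matrix, sheet)

print(f"per-sample CPM sum (should be 1e6): "
      f"{norm.scaled.sum(axis=1)[0]:.3f}")
print(f"masked bins (control coverage < 1 CPM): {int(norm.masked.sum())}")

row = norm.sample_row("mono_4B", "log2ratio")
sl = norm.grid.chrom_slice("4B")
print(f"mono_4B: median log2 ratio on 4B    = {np.nanmedian(row[sl]):+.3f}"
      f"   (expected ~ log2(1/2) = -1)")
other = np.ones(norm.grid.n_bins, bool)
other[sl] = False
print(f"mono_4B: median log2 ratio elsewhere = {np.nanmedian(row[other]):+.3f}"
      f"   (expected ~ 0)")
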