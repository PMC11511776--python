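"""Windowed diversity and differentiation statistics.

Computes per-10 Mb-window nucleotide diversity (pi), absolute divergence
(dxy) and Hudson FST with its Z-transform, then contrasts the low- and
high-recombination classes.
"""

import numpy as np

from ryescan import (
    SimulationConfig,
    classify_windows,
    compute_window_stats,
    generate_recombination_track,
    simulate_variants,
)

cfg = SimulationConfig(
    n_chromosomes=6, chromosome_length=100_000_000,
    n_samples_pop1=40, n_samples_pop2=30, seed=2,
)
track, windows = generate_recombination_track(cfg)
matrix, pops, truth = simulate_variants(cfg, track)

stats = compute_window_stats(matrix, pops.pop1, pops.pop2, windows)
stats["rho"] = track["rho"].to_numpy()
stats["rec_class"] = classify_windows(stats["rho"].to_numpy()).classes

print(stats.head(8)[["chrom", "start", "n_snvs", "pi_avg", "dxy", "fst", "z_fst", "rec_class"]]
      .to_string(index=False))
low = stats.rec_class == "low"
print(f"\nmean FST  low-rec: {np.nanmean(stats.loc[low, 'fst']):.3f}   "
      f"other: {np.nanmean(stats.loc[~low, 'fst']):.3f}")
print(f"mean dxy  low-rec: {np.nanmean(stats.loc[low, 'dxy']):.2e}   "
      f"other: {np.nanmean(stats.loc[~low, 'dxy']):.2e}")
print("\nDifferentiation is elevated and absolute divergence reduced where "
      "recombination is low - the classic footprint of linked selection.")
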