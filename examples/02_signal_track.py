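"""Build a binned methylation-ratio track, a meta-profile, and check replicates.

The bulk signal of a footprinting run is the per-bin methylation ratio
(flagged m6A calls / all adenine calls, 50-bp bins sliding 5 bp). The
meta-profile averages that ratio around a set of centers — here the
center of a simulated protein footprint, where the signal should peak.
"""

import numpy as np

from modfoot import io, simulate, threshold, track

FOOTPRINT = (20_000, 21_000)
cfg = simulate.SimConfig(genome_length=40_000, footprints=(FOOTPRINT,), depth=20, seed=3)
molecules, _ = simulate.simulate_molecules(cfg)
molecules, _, _ = threshold.binarize_calls(molecules, 0.53)

bins = track.make_bins({cfg.chrom: cfg.genome_length}, width=50, step=5)
sig = track.ratio_track(molecules, bins)
inside = sig[(sig["start"] >= FOOTPRINT[0]) & (sig["end"] <= FOOTPRINT[1])]
outside = sig[(sig["end"] < FOOTPRINT[0]) | (sig["start"] > FOOTPRINT[1])]
print(f"{len(sig)} sliding bins; mean ratio inside footprint "
      f"{inside['ratio'].mean():.3f} vs outside {outside['ratio'].mean():.3f}")

io.write_bedgraph(sig, "scratch_track.bedgraph", value_col="ratio", allow_overlap=True)
print("wrote scratch_track.bedgraph (4-column, 6-decimal values)")

center = (FOOTPRINT[0] + FOOTPRINT[1]) // 2
prof = track.center_profile(molecules, [(cfg.chrom, center)], flank=1000, bin_width=100)
peak_row = prof.loc[prof["mean_ratio"].idxmax()]
print(f"meta-profile peak: offset {int(peak_row['offset'])} bp, "
      f"mean ratio {peak_row['mean_ratio']:.3f} "
      "(the footprint spans offsets -500..500, so the maximum sits there)")

# replicate concordance: same conditions, independent seed
rep_cfg = simulate.with_seed(cfg, 4)
rep, _ = simulate.simulate_molecules(rep_cfg)
rep, _, _ = threshold.binarize_calls(rep, 0.53)
sig_rep = track.ratio_track(rep, bins)
r = track.replicate_correlation(sig, sig_rep)
print(f"replicate Pearson r of log2 ratios: {r:.3f} "
      "(positive: both replicates share the footprint layout; background "
      "bins are independent sampling noise, which caps r well below 1 here)")
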