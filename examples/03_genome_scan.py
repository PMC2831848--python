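"""Sliding-window Svd scan of a simulated chromosome with a planted sweep.

Simulates one recombining chromosome (~1,000 SNPs) carrying an ongoing
sweep at its centre, scans it with a 51-SNP window, assigns chromosome-wide
empirical p-values and reports the top-percentile clusters.
"""

from hacsweep import (
    ScenarioConfig,
    Selection,
    empirical_pvalues,
    flagged_clusters,
    simulate_sweep,
    sliding_scan,
)

cfg = ScenarioConfig(
    seed=23, rho_background=111.5, selection=Selection(s=0.15, f=0.75)
)
chrom = simulate_sweep(cfg, 1, min_flank=101).replicates[0]
print(f"chromosome: {chrom.n} haplotypes x {chrom.S} SNPs; "
      f"true selected SNP at index {chrom.evaluated_index}")

track = empirical_pvalues(sliding_scan(chrom, 51))
t = track.table
sel = t.loc[chrom.evaluated_index]
print(f"Svd at the selected SNP: {sel.svd:.3f} (empirical p = {sel.empirical_p:.4f})")
print(f"defined Svd values along the track: {int(t.defined.sum())}")
print(f"SNPs flagged in the top 1% of positive values: {int(t.top_percentile_flag.sum())}")

clusters = flagged_clusters(track, max_gap=20)
print("\nflagged clusters (bp intervals):")
print(clusters.to_string(index=False))
print()
print(
    "Clusters of top-percentile SNPs - not the single argmax - are the scan\n"
    "signal; linked high-frequency SNPs share the sweep's Svd elevation."
)
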