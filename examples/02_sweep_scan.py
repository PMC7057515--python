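"""Selective-sweep scan: windowed pi, Weir-Cockerham FST and log2 pi-ratio.

A swept region is emulated by homogenizing the case haplotype pool around
the causal span; windows jointly in the top 5% of FST and the log2
pi-ratio are flagged.
"""

from vertebramark import SimConfig, select_sweep_windows, simulate_cohort, tile_windows
from vertebramark.popstats import sweep_scan

cfg = SimConfig(seed=2, n_loci_per_chrom=1500, sweep_halo=20_000, missing_rate=0.0)
cohort = simulate_cohort(cfg)
windows = tile_windows(cfg.chrom_lengths, size=50_000, step=10_000)
table = sweep_scan(cohort.matrix, cohort.manifest, ["YC"], ["ZC", "GY"],
                   windows, min_sites=2)
table = select_sweep_windows(table, top_fraction=0.05)

flagged = table[table["selected_for"] == "case"]
print(f"windows scanned: {len(table)}, flagged for case-direction sweep: {len(flagged)}")
print(f"thresholds: {table.attrs['thresholds']}")
print(flagged[["chrom", "start", "end", "pi_case", "pi_control",
               "fst", "log2_pi_ratio"]].to_string(index=False))
print(f"\nplanted causal span: {cfg.causal.chrom}:{cfg.causal.start}-{cfg.causal.end}")
# Flagged windows cluster on the causal span: the case group lost diversity
# there (high log2 pi-ratio) while differentiating from the controls (high FST).
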