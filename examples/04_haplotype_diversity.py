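"""Haplotype diversity around candidate markers and quartile classes.

Counts distinct phased haplotype strings in +/-5 kb windows around each
marker, per population group; low-diversity (preferred) markers tag stable
local haplotypes, high-diversity ones are avoided.
"""

from vertebramark import SimConfig, screen_candidate_markers, simulate_cohort
from vertebramark.haplodiv import (
    diversity_for_markers,
    diversity_quartiles,
    diversity_summary,
    diversity_to_frame,
)

cohort = simulate_cohort(SimConfig(seed=4, n_loci_per_chrom=1000, missing_rate=0.0))
markers = screen_candidate_markers(cohort.matrix, cohort.manifest, "YC", ["ZC", "GY"])
focal = [m.locus_id for m in markers]

groups = {"YC-ZC": ["YC", "ZC"], "YC": ["YC"], "ZC": ["ZC"]}
records = diversity_for_markers(cohort.matrix, cohort.manifest, focal, groups)
classified = []
for label in groups:
    classified.extend(
        diversity_quartiles([r for r in records if r.population == label])
    )

print("per-group diversity summary (distinct haplotypes per marker window):")
print(diversity_summary(classified).to_string(index=False))
frame = diversity_to_frame(classified)
pooled = frame[frame["population"] == "YC-ZC"]
print("\nclass counts in the pooled YC-ZC group:")
print(pooled["class"].value_counts().to_string())
# The pooled group of 10 diploids can show at most 20 distinct haplotypes;
# markers at or below the lower quartile are 'preferred' for breeding.
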