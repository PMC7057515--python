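"""Population structure: (1-IBS) distances, neighbor-joining tree and PCA."""

from vertebramark import SimConfig, ibs_distance, neighbor_joining, pca_genotypes, simulate_cohort

cohort = simulate_cohort(SimConfig(seed=3, n_loci_per_chrom=800, drift_f=0.1,
                                   missing_rate=0.0))
dist = ibs_distance(cohort.matrix)
print("(1-IBS) distances, first rows:")
print(dist.iloc[:4, :4].round(3).to_string())

print("\nneighbor-joining tree (GY1 as outgroup):")
print(neighbor_joining(dist, outgroup="GY1"))

result = pca_genotypes(cohort.matrix, n_components=2)
print("\nPC coordinates with variance fractions "
      f"PC1={result.variance_fractions[0]*100:.2f}% "
      f"PC2={result.variance_fractions[1]*100:.2f}%:")
print(result.coordinates.round(2).to_string())
# Samples of one population share pool haplotypes, so they cluster in the
# tree and along the leading components.
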