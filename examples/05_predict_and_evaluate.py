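"""End to end: screen, rank, score a 51-animal validation cohort, evaluate.

Scoring: at each discriminative locus a query animal adds +3/+2/+1
(genotype probability >= 0.9 / >= 0.8 / rest) to the phenotype whose panel
major genotype it matches; the phenotype is called when the score
difference strictly exceeds the contrast's diff threshold.
"""

import json

from vertebramark import (
    SimConfig,
    emit_validation_cohort,
    predict_cohort,
    screen_candidate_markers,
    simulate_cohort,
)
from vertebramark.evaluate import evaluate_calls

cfg = SimConfig(seed=5, n_loci_per_chrom=1000)
cohort = simulate_cohort(cfg)
markers = screen_candidate_markers(cohort.matrix, cohort.manifest, "YC", ["ZC", "GY"])
loci = [m.locus_id for m in markers][:13]  # genotyping shortlist

query, qman = emit_validation_cohort(cohort)
for contrast, diff in (("total", 1), ("thoracic", 4)):
    groups = cohort.manifest.phenotype_groups(contrast)
    calls = predict_cohort(cohort.matrix, groups, query, loci, diff_threshold=diff)
    observed = dict(zip(qman.table["sample_id"], qman.table[contrast].astype(str)))
    report = evaluate_calls(calls, observed)
    print(f"--- contrast: {contrast} (diff > {diff}) ---")
    print("confusion:", json.dumps(report["confusion"]))
    print("accuracy of prediction:   ", report["accuracy_of_prediction"])
    print("representative capacity:  ", report["representative_capacity"])
# Accuracy of prediction = correct calls / calls of that phenotype
# (precision); representative capacity = correct calls / animals truly of
# that phenotype (recall; 'unknown' calls count against it).
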