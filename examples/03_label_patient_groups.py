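"""Apply the cluster-labelling rule to the packaged reference prevalence table.

The reference table gives the per-group prevalence (%) of 30 conditions in
ten patient groups of a large hospital multimorbidity cohort.  Conditions
with prevalence >= 50% within a group form the group's condition cluster;
the label comes from the most prevalent condition (ties joined with "/").
"""

from mmclust import label_clusters
from mmclust.profiling import PrevalenceTable
from mmclust.simulate import reference_group_sizes, reference_prevalence_table

ref = reference_prevalence_table()
P = PrevalenceTable(table=ref.drop(columns="overall_pct"),
                    group_sizes=reference_group_sizes())
labels = label_clusters(P, bold_threshold=50, feature_min_ratio=1.25)

for g in P.table.columns:
    cluster = ", ".join(labels.cluster_conditions[g])
    print(f"{g} (n={P.group_sizes[g]}): {labels.labels[g]}")
    print(f"    cluster conditions: {cluster}")
    if labels.feature_conditions[g]:
        print(f"    feature conditions: {', '.join(labels.feature_conditions[g])}")
# Expect ten distinct labels, including the "Chronic kidney disease/diabetes"
# group (both at 100%) alongside a plain "Chronic kidney disease" group.
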