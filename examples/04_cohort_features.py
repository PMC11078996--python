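"""Assemble the 50-column feature table from a cohort-structured dataset.

A cohort is the set of oocytes retrieved in one stimulation cycle.  Beyond
the per-oocyte descriptors and inter-region ratios, each relative feature
also enters as its cohort average and as the oocyte's deviation from that
average (cohort-relative) — a negative cohort-relative value marks an
oocyte below its own cohort's average.
"""

from oomorph import assemble_feature_table, generate_cohort_dataset

records = generate_cohort_dataset(n_patients=30, seed=5)
table = assemble_feature_table(records)

print(f"{len(table.data)} oocytes, {len(table.feature_columns)} feature columns")
for group in ("ooplasm", "relative", "cohort_avg", "cohort_rel", "clinical"):
    cols = table.columns_of_group(group)
    print(f"  group {group:10s}: {len(cols):2d} columns, e.g. {cols[0]}")

rel_cols = [c for c, m in table.schema.items() if m["group"] == "cohort_rel"]
sums = table.data.groupby("cycle_id")[rel_cols].sum()
print(f"\nmax |per-cohort sum| over all cohort-relative columns: "
      f"{sums.abs().max().max():.2e}")
# Exactly zero by construction: each cohort-relative value is the feature
# minus its own cohort's mean.

reduced = table.drop_groups(["zp"])
print(f"after dropping every ZP-involving column: "
      f"{len(reduced.feature_columns)} features remain")
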