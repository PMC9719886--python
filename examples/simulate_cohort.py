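"""Generate a calibrated synthetic cohort and inspect its group structure.

The generator's defaults reproduce the published group summaries: node
attenuation at 40 keV of 247 +/- 38 HU (metastatic) vs 204 +/- 45 HU
(non-metastatic), a 39/137 metastasis prevalence, and a lesion-node Spearman
correlation near 0.65 in the metastasis group vs near 0.14 otherwise.
"""

from dectrod import default_cohort_config, derive_columns, generate_cohort, spearman

cohort = generate_cohort(default_cohort_config(n_patients=2000, seed=42))
df = derive_columns(cohort)

print(f"patients: {len(df)}, metastatic: {df['group'].sum()} "
      f"({df['group'].mean():.1%})")
for g, label in ((1, "metastasis"), (0, "non-metastasis")):
    sub = df[df["group"] == g]
    rho, _ = spearman(sub["lesion_att40_hu"], sub["node_att40_hu"])
    print(f"{label:15s} node att40 {sub['node_att40_hu'].mean():5.0f} +/- "
          f"{sub['node_att40_hu'].std():2.0f} HU | rod_att40 "
          f"{sub['rod_att40'].mean():.3f} | lesion-node Spearman {rho:.2f}")

print()
print("Metastatic nodes are both more enhancing and far more similar to")
print("their primary lesion (smaller ROD, higher rank correlation).")
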