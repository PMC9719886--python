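"""Forward logistic modeling and ROC analysis of the marker panel.

Fits the head-to-head model of node size + raw 40-keV attenuation +
transformed ROD similarity, then evaluates every marker's AUC and
Youden-optimal threshold in the full cohort and the small-node subgroup
(shortest diameter < 5 mm), where size itself is uninformative.
"""

import pandas as pd

from dectrod import (
    default_cohort_config,
    derive_columns,
    evaluate_markers,
    fit_logistic,
    generate_cohort,
    rod_transform,
)

df = derive_columns(generate_cohort(default_cohort_config(10_000, seed=3)))

design = pd.DataFrame({
    "node_short_mm": df["node_short_mm"],
    "node_att40_hu": df["node_att40_hu"],
    "rod_att40_similarity": rod_transform(df["rod_att40"].to_numpy()),
})
fit = fit_logistic(design, df["group"].to_numpy(float))
print("DECT-with-node-size model (OR per unit, 95% CI):")
for _, r in fit.summary_frame().iloc[1:].iterrows():
    print(f"  {r['term']:22s} OR {r['odds_ratio']:5.2f} "
          f"({r['ci_low']:.2f}, {r['ci_high']:.2f})  p={r['p_value']:.3g}")

print("\nROC, full cohort vs small nodes (<5 mm):")
full = {r.marker: r for r in evaluate_markers(df)}
small = {r.marker: r for r in evaluate_markers(
    df, subgroup=df["node_short_mm"] < 5, stratum="small")}
for name in ("Attenuation at 40 keV", "ROD of attenuation at 40 keV"):
    f, s = full[name], small[name]
    print(f"  {name:30s} AUC {f.auc:.2f} (thr {f.threshold:6.3f}) | "
          f"small-node AUC {s.auc:.2f}")

print("\nThe similarity marker keeps its discrimination among small nodes,")
print("where size-based assessment is unavailable by construction.")
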