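"""Group statistics and MRI-histology regression on a simulated cohort.

Draws a two-group ROI table (sham n=6, mTBI n=8; anisotropy index AI, cell
density CD, plus FA and AD per region/hemisphere/level), runs the unpaired
t-tests with Benjamini-Hochberg FDR, and fits the regression
DTI ~ AI + CD over single and pooled region families. Prints the contrasts
that reach q < 0.05 and the strongest regression fits.
"""

import pandas as pd

from histotensor import CohortSpec, analyze_cohort, gen_cohort

pd.set_option("display.width", 120)

table = gen_cohort(CohortSpec(seed=0))
report = analyze_cohort(table)

g = report["group_tests"]
sig = g[g.significant].copy()
sig["t"] = sig["t"].round(2)
sig["q"] = sig["q"].map("{:.2e}".format)
print("group contrasts with q < 0.05:")
print(sig[["level", "region", "hemisphere", "measure", "t", "q"]]
      .to_string(index=False))

r = report["regressions"].copy()
best = r.sort_values("r2_adj", ascending=False).head(5)
best = best[["level", "family", "response", "r2_adj", "f_stat", "t_ai", "t_cd"]]
print("\nstrongest DTI ~ AI + CD fits (by adjusted R^2):")
print(best.round(3).to_string(index=False))

print("\nSignificant contrasts concentrate at the lesion level (-3.60 mm) "
      "in the ipsilateral hemisphere, and pooled white-matter families show "
      "the tightest DTI-histology coupling -- the pattern the generator "
      "encodes. Individual cohorts can add or drop a borderline contrast.")
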