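"""Cross-sectional post-infarct analysis: infarct vs remote regions.

Simulates the baseline cohort plus three post-AMI cohorts (1-2 days,
1-2 weeks, 4 weeks; low-flow anteroseptal infarct), then compares resting
regional MBF at each timepoint against baseline with one-way ANOVA and
Holm-Sidak-adjusted pairwise tests.  No tSNR exclusion is applied here:
the infarcted segment is known in advance and low tSNR is part of its
phenotype.
"""

import pandas as pd

from myoasl.pipeline import cohort_table
from myoasl.stats import cross_sectional_compare
from myoasl.synth import scenario_config, simulate_cohort

tables = []
for name in ["baseline", "ami_day1", "ami_week1", "ami_week4"]:
    tables.append(cohort_table(simulate_cohort(scenario_config(name), seed=5)))
table = pd.concat(tables, ignore_index=True)

for region in ("infarct", "remote"):
    res = cross_sectional_compare(table, region)
    print(f"\n{region} region: ANOVA F = {res.anova_f:.2f}, p = {res.anova_p:.2e}")
    for _, row in res.comparisons.iterrows():
        star = " (*)" if row["significant"] else ""
        print(f"  {row['timepoint']:>8} vs baseline: diff {row['mean_diff']:+.2f} "
              f"ml/g/min, adjusted p = {row['p_adjusted']:.3g}{star}")

# Expected pattern: significantly reduced MBF in the infarcted
# (anteroseptal) region at every timepoint, no systematic change in the
# remote (inferior/inferolateral/anterolateral) region.
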