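"""Paired rest/stress cohort: vasodilator response and perfusion reserve.

Simulates the paired scenario (25 slices over 13 subjects; rest MBF
1.08 +/- 0.54, stress 1.47 +/- 0.62 ml/g/min), quantifies every scan,
drops segments excluded at either rest or stress, and runs the paired
t-test and the myocardial perfusion reserve (MPR = stress/rest) summary.
"""

from myoasl.pipeline import cohort_table
from myoasl.stats import filter_paired, mpr, paired_ttest
from myoasl.synth import scenario_config, simulate_cohort

table = cohort_table(simulate_cohort(scenario_config("stress"), seed=1))
paired = filter_paired(table, "rest", "stress")
t, p = paired_ttest(paired.b, paired.a)
reserve = mpr(paired.a, paired.b)

print(f"kept {paired.n_kept} segment pairs, dropped {paired.n_dropped} "
      "(tSNR < 2 at rest or stress)")
print(f"rest   MBF {paired.a.mean():.2f} +/- {paired.a.std(ddof=1):.2f} ml/g/min")
print(f"stress MBF {paired.b.mean():.2f} +/- {paired.b.std(ddof=1):.2f} ml/g/min")
print(f"paired t = {t:.1f}, p = {p:.1e}")
print(f"MPR {reserve.mean:.2f} +/- {reserve.sd:.2f} "
      f"({100 * (paired.b.mean() / paired.a.mean() - 1):.0f}% MBF increase)")

# A significant positive t confirms the vasodilator response; MPR near 1.5
# means stress raises regional flow by about half over rest.
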