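"""Kaplan-Meier curves and a log-rank test on a simulated cohort.

Compares the highest and lowest irradiated dose groups of the sensitive
strain, mirroring the study's survival reporting.
"""

from braintox import default_config, km_curve, logrank_test, simulate_cohort

table = simulate_cohort(default_config(seed=1)).for_strain("C3H/He")
groups = {
    dose: [t.survival_record() for t in table if t.dose == dose]
    for dose in (40.0, 80.0)
}

for dose, recs in groups.items():
    print(f"{dose:g} Gy Kaplan-Meier curve (week, survival):")
    for t, s in km_curve(recs):
        print(f"  {t:5.1f}  {s:.3f}")

stat, p = logrank_test(groups[80.0], groups[40.0])
print(f"log-rank 80 Gy vs 40 Gy: chi² = {stat:.2f}, p = {p:.4f}")
print()
print("All 80 Gy animals are sacrificed around week 9-10 while the 40 Gy")
print("group survives to the 26-week horizon; with n=3 per group the")
print("log-rank difference is already significant at the 5 % level.")
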