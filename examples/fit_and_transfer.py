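"""Fit the model to one strain and transfer it to the other.

Reproduces the full modelling workflow on a simulated cohort: onset
regression and global growth-law fit on the sensitive strain, out-of-sample
onset validation on the resistant strain, then a one-parameter transfer in
which only the growth exponent b is refitted.
"""

from braintox import analyze_cohort, default_config, simulate_cohort

table = simulate_cohort(default_config(seed=1))
fits = analyze_cohort(table, train_strain="C3H/He", transfer_strain="C57BL/6")

onset = fits["onset_fit"]
print(f"onset fit (sensitive strain, n={onset.n_points} mice):")
print(f"  t_on(D) = {onset.params.t1:.2f} {onset.params.t2:+.2f} ln(D/Gy)   "
      f"R² = {onset.r_squared:.3f}")
print(f"  validation on resistant strain: R² = {fits['onset_validation'].r_squared:.3f}")

vol = fits["volume_fit"]
p = vol.params
print(f"growth-law fit (sensitive strain, n={vol.n_points} volume points):")
print(f"  log10 V = {p.a:.4f} (D - {p.d0:.1f} Gy) t^{p.b:.3f}   R² = {vol.r_squared:.3f}")

tr = fits["transfer_fit"]
print(f"transfer (resistant strain, only b refitted, n={tr.n_points}):")
print(f"  b = {tr.params.b:.3f}   R² = {tr.r_squared:.3f}")
print()
print("The generating values are a=0.0155/Gy, D0=30 Gy, b=0.40 (sensitive)")
print("and b=0.28 (resistant); estimates wander around them with the")
print("simulated measurement noise, and the smaller transferred b captures")
print("the resistant strain's slower lesion progression.")
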