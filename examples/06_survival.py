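"""Prognostic value of the colocalisation score in a simulated cohort.

Draws a 200-dog cohort from a proportional-hazards model in which each
point of coloc100 multiplies the hazard by 0.98 (protective), screens the
covariates by VIF, fits the multivariate Cox model, and compares survival
after dichotomising colocalisation at its lower quartile.
"""

from panmorph import (
    SurvivalSpec,
    dichotomize_lower_quartile,
    fit_cox,
    gen_survival,
    km,
    survival_frame,
    vif,
)

spec = SurvivalSpec(n=200)
df = survival_frame(gen_survival(spec, seed=9))
print(f"cohort: n = {len(df)}, events = {int(df['event'].sum())}")

vrep = vif(df)
print("\nVIF screen (keep < 5):")
print(vrep.table.round(3).to_string())

fit = fit_cox(df, vrep.retained)
print("\nmultivariate Cox fit:")
print(fit.table.round(4).to_string())
print(f"(generating truth: HR per coloc100 point = {2.7182818**spec.b_coloc:.3f})")

labels, cutoff = dichotomize_lower_quartile(df["coloc100"])
curves = km(df, labels)
print(f"\ndichotomised at lower quartile (cutoff = {cutoff:.1f}):")
for g, c in curves.items():
    median = next((t for t, s in zip(c.times, c.survival) if s <= 0.5), float("nan"))
    print(f"  {g:4s} group: n = {c.n}, events = {c.n_events}, median survival ~ {median:.0f} d")
print(
    "\nThe fitted coloc100 HR should sit near its generating value of 0.98,"
    "\nand the low-colocalisation quartile should show shorter survival."
)
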