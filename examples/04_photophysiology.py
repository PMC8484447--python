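"""Optical traits of photosymbionts under heat stress.

Simulates per-fragment physiology records (reflectance at 675 nm,
symbiont density, Fv/Fm) for three species with different bleaching
severities, derives the estimated absorbance De675 = log10(1/R675) and
the per-cell absorption cross-section a*_sym = (De675/density)*ln(10),
and tests the control-vs-treatment density change per species.
"""

from holoeve.photophysiology import annotate_physiology
from holoeve.simulate import SpeciesPhysioEffect, simulate_physiology
from holoeve.variants import welch_t_test

effects = {
    # mild bleaching: small cell loss, small reflectance rise
    "S_radians": SpeciesPhysioEffect(
        r675_control=0.25, r675_shift=+0.05,
        density_control=1.2e10, density_shift_frac=-0.15,
        fv_fm_control=0.62, fv_fm_shift=-0.05),
    # severe bleaching: large cell loss
    "O_faveolata": SpeciesPhysioEffect(
        r675_control=0.25, r675_shift=+0.20,
        density_control=1.0e10, density_shift_frac=-0.65,
        fv_fm_control=0.60, fv_fm_shift=-0.10),
    "P_clivosa": SpeciesPhysioEffect(
        r675_control=0.28, r675_shift=+0.10,
        density_control=0.9e10, density_shift_frac=-0.35,
        fv_fm_control=0.58, fv_fm_shift=-0.20),
}
records = simulate_physiology(seed=11, effects=effects, n_fragments=5)
traits = annotate_physiology(records)

print("mean derived optical traits per species and condition:")
summary = traits.groupby(["species", "condition"])[
    ["de675", "density", "a_sym", "fv_fm"]].mean()
print(summary.to_string(float_format=lambda x: f"{x:.3g}"))

print("\ncontrol vs treatment symbiont density (two-sided Welch t-test):")
for sp, grp in traits.groupby("species"):
    c = grp.loc[grp.condition == "control", "density"]
    t = grp.loc[grp.condition == "treatment", "density"]
    tstat, p = welch_t_test(c, t)
    print(f"  {sp}: t = {tstat:+.2f}, p = {p:.2g}")

print(
    "\nCell loss raises a*_sym (less self-shading, more light per "
    "remaining cell): the species with the largest density drop shows "
    "the sharpest rise in per-cell light absorption, compounding its "
    "photodamage (lower Fv/Fm)."
)
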