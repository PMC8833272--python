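"""Build, robustly optimize and normalize a small-spot SFUD plan.

Places spots over the CTV for two axis-aligned fields, optimizes the spot
weights against the nominal geometry plus the 12 setup/range scenarios,
and normalizes so that 99% of the CTV receives 6930 cGy(RBE) (99% of the
7000 cGy(RBE) prescription).  A reduced 56^3 phantom keeps the run short.
"""

from spotlab import (NOMINAL, OptimizationSettings, PhantomConfig,
                     compute_dvh, dose_at_volume, generate_phantom,
                     homogeneity_index, normalize_d99, place_spots,
                     plan_dose, robust_optimize, small_beam_model)

phantom = generate_phantom(PhantomConfig(shape=(56, 56, 56),
                                         gtv_radius_mm=12.0), seed=1)
beam = small_beam_model()

plan = place_spots(phantom, beam, ((0.0, 1.0, 0.0), (-1.0, 0.0, 0.0)))
print(f"placed {plan.n_spots} spots in "
      f"{[len(f.layers) for f in plan.fields]} energy layers per field")

result = robust_optimize(plan, beam, phantom,
                         OptimizationSettings(iterations=400))
print(f"optimizer: {result.status}, "
      f"nominal D99 before normalization = {result.nominal_ctv_d99_cgy:.0f} cGy(RBE)")

dose = plan_dose(result.plan, beam, phantom.reference_grid, NOMINAL)
plan_norm, scale = normalize_d99(result.plan, dose, phantom.masks["CTV"])
dose = dose.like(dose.values * scale)
print(f"D99 normalization scale factor: {scale:.4f}")

dvh = compute_dvh(dose, phantom.masks["CTV"], "CTV")
print(f"CTV D99% = {dose_at_volume(dvh, percent=99):.0f} cGy(RBE) "
      "(normalized to 6930)")
print(f"CTV D95% = {dose_at_volume(dvh, percent=95):.0f} cGy(RBE)")
print(f"CTV homogeneity index D99%/D1% = {homogeneity_index(dvh):.3f} "
      "(1 = perfectly uniform)")
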