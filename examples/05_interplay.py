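"""Interplay simulation: timed delivery over a breathing cycle, with and
without alternating-order volumetric repainting.

Spots are delivered on a timeline (1 s layer switches, 4 ms/MU spot
delivery, 250 cm/s scanning); each spot lands in the breathing phase
active at its start time; per-phase doses are mapped to the reference
phase through the phantom's analytic displacement fields and accumulated.
"""

from spotlab import (NOMINAL, OptimizationSettings, PhantomConfig,
                     build_timeline, compute_dvh, dose_at_volume,
                     generate_phantom, make_volumetric_repainting,
                     normalize_d99, place_spots, plan_dose, robust_optimize,
                     simulate_interplay, small_beam_model)

phantom = generate_phantom(PhantomConfig(shape=(56, 56, 56),
                                         gtv_radius_mm=12.0,
                                         amplitude_mm=10.0), seed=1)
beam = small_beam_model()
plan = place_spots(phantom, beam, ((0.0, 1.0, 0.0), (-1.0, 0.0, 0.0)))
plan = robust_optimize(plan, beam, phantom,
                       OptimizationSettings(iterations=400)).plan
dose = plan_dose(plan, beam, phantom.reference_grid, NOMINAL)
plan, scale = normalize_d99(plan, dose, phantom.masks["CTV"])
d99_static = dose_at_volume(
    compute_dvh(dose.like(dose.values * scale), phantom.masks["CTV"]),
    percent=99)
print(f"static CTV D99% = {d99_static:.0f} cGy(RBE)")

for label, p in (("no repainting", plan),
                 ("5 paintings", make_volumetric_repainting(plan, 5))):
    tl = build_timeline(p)
    print(f"\n{label}: {len(tl.events)} delivery events, "
          f"beam-on time {tl.total_time_s:.0f} s")
    for start in ("T0", "T50"):
        res = simulate_interplay(p, beam, phantom, start)
        loss = 100.0 * (d99_static - res.metrics["CTV_D99%"]) / d99_static
        print(f"  start {start}: interplay D99 = "
              f"{res.metrics['CTV_D99%']:.0f} cGy(RBE) "
              f"({loss:+.1f}% vs static), HI = {res.metrics['CTV_HI']:.3f}")

print("\nWithout repainting, spot-phase clustering carves hot/cold spots;")
print("five alternating-order paintings spread each spot over the cycle")
print("and recover the static coverage.")
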