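# Methods

This note documents the models behind `spotlab`, the defaults and why
they were chosen, and what the synthetic setting can and cannot say about
clinical data.

## Synthetic 4D thorax phantom

The phantom is a voxel grid (default 80×80×80 at 3 mm isotropic, patient
axes x = RL, y = AP, z = SI) of piecewise densities: body ellipsoid
(1.0 g/cc), two lung ellipsoids (0.25 g/cc) sized so the chest wall is
15–25 mm thick as in an adult thorax, ellipsoid heart and cylindrical
esophagus and spinal cord (1.0 g/cc), air outside (0.001 g/cc).  A
spherical gross tumor (default radius 20 mm) sits in the right lung; a
seeded generator jitters its position by up to ±3 mm and organ sizes by
±5% so different seeds give distinct but comparable anatomies.

**Motion.**  The tumor translates along an SI-dominant direction
(configurable AP/RL fractions) with waveform f(p) = cos²(πp/10) over ten
phases T0…T90: end-inhale T0 is the extreme, end-exhale T50 the rest
position and default accumulation reference.  Peak-to-peak excursion
equals the configured amplitude (default 10 mm; valid range 0–15 mm,
matching the clinical selection criterion of sub-15 mm lung tumor
motion).  Breathing period defaults to 4.0 s, 0.4 s per phase bin.

**Displacement fields.**  u_p(x) = A·f(p)·w(|x−c₀|)·m̂ with w = 1 inside
a rigid core (GTV radius + 2 mm) and a cos² taper to zero over 10 mm.
The taper is deliberately short: lung tissue slides around a moving
tumor, and a wide envelope that rigidly translated the IGTV-plus-margin
region would drag CTV-margin tissue out of the dose plateau in every
phase — a systematic 4D blur that has nothing to do with delivery timing
and would mask the interplay effect.  With the short taper, the IGTV+5 mm
margin recipe compensates the modeled motion exactly as clinical margins
are designed to, and residual coverage loss in a time-resolved simulation
is attributable to delivery-phase clustering.  The fields are analytic
and invertible (fixed-point inversion to <0.01 mm), so phase-to-reference
dose mapping has no registration error.  The slope bound A·π/(2·taper)
stays below 1 for all valid amplitudes, guaranteeing invertibility.

**Targets.**  IGTV = union of tumor spheres over the cycle (a capsule
along the motion path), overridden to water density in every phase, as in
clinical practice for the planning CT; the consequence is that phase
density grids are identical and phases differ only through their
displacement fields.  CTV = IGTV expanded isotropically by 5 mm
(analytically, so the voxelized volume tracks the exact capsule volume).
The default GTV radius gives a CTV of ≈85 cc, near the mean target size
of the clinical cohort the study conditions emulate (which spans roughly
22–366 cc); `total_lung` is both lungs minus the CTV.

## Dose engine

Each spot deposits dose(x) = MU · IDD(E, d_w(x)/s_R) · G₂(r_⊥; σ(E, d_w)),
with d_w the water-equivalent depth (WED) by cumulative radiological path
length along the beam axis, s_R the scenario range-scale factor, and G₂ a
normalized 2D Gaussian.  Beams are restricted to axis-aligned directions,
which makes WED an exact cumulative sum and matches the slab-like phantom
geometry; lateral heterogeneity correction is omitted (a documented
limitation shared with the pencil-beam family of algorithms).

**Depth dose.**  The pristine Bragg curve is the Bragg–Kleeman power-law
stopping term (R−d)^(1/p−1) (p = 1.77, R = 0.022·E^1.77 mm) with a linear
nuclear fluence loss (0.1%/mm), convolved with Gaussian range spread:
straggling σ = 0.012·R^0.935 (cm) plus a beamline energy-spread term
p·R·σ_E/E with σ_E = 1.8 MeV, combined in quadrature.  The energy-spread
term is what a clinical energy-selection system produces; without it,
shallow-energy peaks are millimetres wide and no physically deliverable
layer weighting could produce a flat spread-out Bragg peak at the layer
spacing used.  Curves are normalized to unit entrance dose, tabulated at
0.5 mm and linearly interpolated.

**Lateral width.**  σ_iso(E) = σ_ref·(226.5/E)^0.6, anchored at
σ_ref = 3 mm (small model) or 8 mm (large model) at 226.5 MeV.  The 0.6
exponent reproduces the ≈2×–2.3× growth from 226.5 to 70 MeV reported for
dedicated PBS nozzles.  The large model is a pure width scaling of the
small one; IDDs and absolute output are identical.  In-patient growth is
a linear multiple-Coulomb-scattering term (2.5% of WED) added in
quadrature.  Energy layers span 40–226.5 MeV in 2 mm water-range steps.
The 40 MeV floor (R ≈ 15 mm) substitutes for the range shifter a clinical
machine would insert for shallow lung targets (range shifters are out of
scope); 2 mm layer spacing keeps the per-field layer count in the spirit
of clinical lung plans (tens to >100 layers), which matters for both SOBP
flatness and the interplay time structure (below).

**Units and output.**  Dose is cGy(RBE) with a constant RBE 1.1 folded
into the output factor (15 cGy·mm²/MU at entrance).  That calibration
puts per-fraction spot MUs in the clinical range (medians of a few MU),
which matters because the 0.015 MU deliverability floor must bind only
rarely for five-painting repainting to be a faithful five-way split.
Spot MU is stored per fraction; the engine reports course dose
(fractions × per-fraction dose).

**Scenarios.**  An isocenter shift s is applied by translating the
density grid (trilinear) before computing dose and evaluating the result
back in the patient frame — the standard "shift the patient" model of a
rigid setup error, which reduces to translating the dose grid on a
homogeneous phantom.  Range uncertainty multiplies the water-equivalent
depth (equivalently the range) by 1±3.5%, not a CT recalibration.

## Planning

**Placement.**  Per field, energy layers cover the CTV's WED extent
expanded by ±3.5% plus a 4 mm margin; the lateral lattice (pitch = 1
σ_ref) covers the per-layer CTV projection expanded by the 5 mm setup
margin plus one σ at the layer energy.  The expansion is load-bearing:
robust optimization can only build dose shoulders where spots exist, so
the lattice must already cover every perturbed target position.  Spots
are ordered boustrophedon within a layer.

**Robust optimization.**  Fields are optimized independently
(single-field uniform dose), each to target t = prescription / n_fields
on the CTV, by minimizing

F(w) = ‖A₀w − t‖²_CTV/(n t²) + (w_rob/12)·Σ_s ‖min(0, A_s w − t)‖²_CTV/(n t²)
     + w_sh‖max(0, A w − 0.55t)‖²_shell/(n_sh t²) + w_oar‖A w‖²_OAR/(n_oar t²)

over w ≥ 0, where A_s are influence matrices for the nominal and the
twelve evaluation scenarios.  Scenario terms penalize underdose only:
overdose under a perturbation is tolerated (it surfaces in worst-case
hot-spot metrics), whereas symmetric scenario terms for opposite shifts
cancel each other instead of building shoulders.  The shell ring starts
beyond the 5 mm setup margin (5–15 mm) and the OAR samples likewise
exclude that ring, so neither penalty fights the robust shoulder.  The
solver is FISTA (projected accelerated gradient with restart, 700
iterations, Lipschitz constant by power iteration) on float32 stacked
matrices; spots ending below 0.015 MU are pruned and recorded.

The default worst-case weight (w_rob = 32) is strong, emulating a minimax
optimizer.  This is where the spot-size physics enters: a small spot can
raise a shoulder 5 mm outside the CTV with little leakage into the CTV
interior or the lung, so it can be robust *and* homogeneous; a large spot
(σ ≈ 13–21 mm at these energies) leaks most of any shoulder into the CTV
edge and the OARs, so coverage under perturbation trades directly against
homogeneity and lung dose.  With a weak worst-case weight both models
drift to a lax equilibrium and the wide spot's intrinsic blur masquerades
as robustness; the strong weight exposes the difference, which is the
mechanism the comparison is about.

**Normalization and repainting.**  After optimization, all MUs are scaled
so CTV D99% = 99% of the prescription (6930 cGy(RBE)); spots pushed below
the MU floor are reported, never dropped.  Volumetric repainting splits
each spot's MU into five equal passes; painting 1 runs distal→proximal,
painting 2 proximal→distal, alternating, and the turnaround repeats the
same layer without an energy switch.  A spot that cannot support five
passes at ≥0.015 MU is delivered in floor(MU/0.015) equal passes assigned
to the earliest paintings, conserving its MU exactly.  The repainted
plan's static dose is bitwise identical to the unpainted plan's.

## Metrics, robustness, radiobiology

Cumulative DVHs use 1 cGy bins; Dx% inverts the curve with linear
interpolation; Dmean and D(v cc) are computed from the exact voxel doses
(D(v cc) reads the k-th hottest voxel, k = whole voxels in v, so a
sub-voxel request reads the hottest voxel).  HI = D99%/D1%.  The twelve
scenarios are {±5 mm on each axis}×{range ×0.965, ×1.035}; worst case is
the minimum over scenarios for coverage metrics (CTV Dx%, HI) and the
maximum for hot spots and OARs; the pass count is the number of scenarios
with CTV D95% ≥ 98% of prescription.  EUD/NTCP: per-voxel EQD2 with the
organ's α/β and the course's 35 fractions, power-mean EUD, logistic NTCP.
Organ parameters ship as a YAML registry of photon-derived literature
defaults (lung pneumonitis a=1, α/β=3, TD50=24.5 Gy, γ₅₀=2; heart
pericarditis 3/3/48/3; esophagus esophagitis 19/10/68/4); they are
configuration, not claims.  A two-point log-odds solver recovers
(TD50, γ₅₀) exactly from two (EUD, NTCP) pairs, or by least squares from
more; it is used in validation to show a published per-patient table is
internally consistent.

## Interplay simulation

The timeline expands a plan into events: spot duration = MU × 4 ms,
travel between spots at 250 cm/s, 1 s per energy switch, fields
sequential with a 30 s gap.  Each event is assigned whole to the phase
active at its start (spot durations are milliseconds, phase bins 0.4 s).
Per-phase dose is computed on that phase's geometry, pulled back to the
reference phase by trilinear sampling at x + u_p(x) and rescaled so the
integral dose (dose × mass) of each mapped phase matches the unmapped one
(conservation to machine precision in the audits), then accumulated and
scaled to course dose — single-fraction interplay, matching a per-plan
evaluation with a fixed starting phase (T0 or T50).

Repainting mitigates interplay by revisiting every layer five times at
different cycle times.  Two desk-scale artifacts are worth knowing.
First, the layer count sets the clustering scale: with few, heavy layers
a single layer's MU lands in a narrow phase window, which is why the 2 mm
layer spacing (tens of layers per field) is the default.  Second,
repainting can *resonate*: if a painting's repeat interval is close to a
multiple (or half-multiple) of the breathing period, a layer's five
passes sample only one or two phase bins and the averaging fails.  This
is a real phenomenon of strictly periodic breathing; the unit suite pins
it on a mini phantom whose 5-painting timing sits near such a resonance,
and the default-scale acceptance checks run in a non-resonant regime.
Irregular breathing, which would smear these resonances, is out of scope.

## Problem sizes and what the tests show

The default experiment (80³ phantom, two fields, both beam models, 13
dose recomputations each, 8 interplay simulations) runs in about six
minutes on one CPU; unit tests use a 48³ phantom.  The acceptance
pipeline uses a 56³ phantom for the normalization target, which exercises
the identical code path at reduced cost.

Passing tests show that the *mechanisms* reproduce: the small-spot plan
achieves higher worst-case coverage, more passing scenarios and better
homogeneity; the large-spot plan is insensitive to interplay without
repainting; five alternating paintings recover most of the small-spot
interplay loss (from ≈14% of D99 to ≈2% on the default phantom).  The
residual ≈2% gap between the repainted models is larger than the ≈0.4%
cohort average reported clinically: a desk-scale plan has far fewer
(spot, phase) samples per voxel for the averaging to work with, and the
alternating order delivers each turnaround layer's five passes at only
about three distinct times — with the distal turnaround layer exactly
where D99 lives.  Absolute values
(e.g. worst-case D95% deficits of a few hundred cGy, nominal HI ≈
0.90–0.94) are poorer than clinical plans: the desk-scale machine has no
range shifter, beams are axis-aligned rather than angle-optimized, and a
single synthetic phantom replaces a 13-patient cohort.  Nothing in the
suite asserts clinical absolute values; the normalization target
(D99 = 6930 cGy(RBE)) and the published-table NTCP consistency checks are
exact by construction and arithmetic, respectively.

## Known limitations

No Monte Carlo transport, nuclear halo, aperture or range-shifter
modelling; no lateral-heterogeneity correction in WED; axis-aligned beams
only; strictly periodic breathing with a single analytic displacement
mode; organ radiobiological parameters are photon-derived defaults; no
inter-fraction effects or rotational setup errors.
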