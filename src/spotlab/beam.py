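"""Analytic pencil-beam dose engine.

Each spot deposits dose as (integrated depth dose along the beam axis) x
(normalized 2D lateral Gaussian).  The depth-dose is an analytic pristine
Bragg curve: a Bragg-Kleeman power-law stopping term with a linear nuclear
fluence loss, convolved with Gaussian range straggling — a documented
stand-in shape for a measured IDD library.  Range-energy follows
R(E) = alpha * E^1.77.

Two beam models are provided: `small` (1 sigma = 3 mm at isocenter for
226.5 MeV) and `large` (8 mm), the large profile being a pure width scaling
of the small one; IDDs and absolute output are identical between models.
The lateral sigma grows with depth by a linear multiple-Coulomb-scattering
term added in quadrature.

Scenario perturbations: a rigid isocenter shift (applied by translating the
density grid, i.e. a patient setup error) and a multiplicative range-scale
factor (applied to the water-equivalent depth).  Output units are cGy(RBE)
with a constant RBE of 1.1 folded in; physical dose is available via
``rbe=1.0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import DoseGrid

# Bragg-Kleeman range-energy: R[mm water] = ALPHA_MM * E[MeV]^P_EXP
ALPHA_MM = 0.022
P_EXP = 1.77
E_REF_MEV = 226.5            # anchor energy for sigma at isocenter
RBE = 1.1
MIN_MU = 0.015               # machine deliverability threshold per spot pass


def range_from_energy(energy_mev) -> np.ndarray:
    """Water range R80-style (mm) from proton energy (MeV)."""
    return ALPHA_MM * np.asarray(energy_mev, dtype=float) ** P_EXP


def energy_from_range(range_mm) -> np.ndarray:
    """Inverse of :func:`range_from_energy`."""
    return (np.asarray(range_mm, dtype=float) / ALPHA_MM) ** (1.0 / P_EXP)


@dataclass(frozen=True)
class Scenario:
    """One robustness perturbation: rigid shift (mm) + range scale factor."""

    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    range_scale: float = 1.0
    label: str = "nominal"

    @property
    def is_nominal(self) -> bool:
        return self.range_scale == 1.0 and not any(self.shift_mm)


NOMINAL = Scenario()


@dataclass
class BeamModel:
    """Spot-size model: lateral sigma(E), IDD(E, depth), energy list."""

    name: str = "small"
    sigma_iso_ref_mm: float = 3.0       # 1 sigma at isocenter, 226.5 MeV
    sigma_energy_exponent: float = 0.6  # sigma(E) = sigma_ref * (E_ref/E)^exp
    mcs_fraction: float = 0.025         # in-patient sigma growth per mm WED
    layer_spacing_mm: float = 2.0       # water-range spacing of the energy list
    e_min_mev: float = 40.0   # low floor in lieu of a range-shifter model
    e_max_mev: float = E_REF_MEV
    output_cgy_mm2_per_mu: float = 15.0   # entrance dose-area per MU, RBE folded in
    mu_per_spot_min: float = MIN_MU
    straggling_fraction: float = 0.012    # sigma_R = 0.012 * R^0.935 (cm)
    energy_spread_mev: float = 1.8        # 1-sigma beamline energy spread
    nuclear_loss_per_mm: float = 0.001    # linear fluence loss along depth
    depth_step_mm: float = 0.5
    energy_list: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.energy_list is None:
            r = np.arange(range_from_energy(self.e_min_mev),
                          range_from_energy(self.e_max_mev) + 1e-9,
                          self.layer_spacing_mm)
            energies = np.round(energy_from_range(r), 3)
            if energies[-1] < self.e_max_mev:  # keep the anchor energy
                energies = np.append(energies, self.e_max_mev)
            self.energy_list = energies
        self.energy_list = np.asarray(self.energy_list, dtype=float)
        self._idd_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    # -- lateral ------------------------------------------------------------
    def sigma_iso_mm(self, energy_mev) -> np.ndarray:
        """In-air 1-sigma spot width at the isocenter plane (mm)."""
        e = np.asarray(energy_mev, dtype=float)
        return self.sigma_iso_ref_mm * (E_REF_MEV / e) ** self.sigma_energy_exponent

    def sigma_mm(self, energy_mev, wed_mm) -> np.ndarray:
        """Depth-dependent sigma: isocenter width + MCS growth in quadrature."""
        s0 = self.sigma_iso_mm(energy_mev)
        return np.sqrt(s0 ** 2 + (self.mcs_fraction * np.asarray(wed_mm)) ** 2)

    # -- depth --------------------------------------------------------------
    def _check_energy(self, energy_mev: float) -> float:
        match = self.energy_list[np.isclose(self.energy_list, energy_mev,
                                            rtol=0, atol=1e-3)]
        if match.size == 0:
            raise ValueError(f"energy {energy_mev} MeV not in the {self.name} "
                             "beam model's energy list")
        return float(match[0])

    def idd_curve(self, energy_mev: float) -> tuple[np.ndarray, np.ndarray]:
        """Depth grid (mm) and IDD (cGy(RBE) mm^2 / MU) for one energy."""
        e = self._check_energy(energy_mev)
        if e not in self._idd_cache:
            r = float(range_from_energy(e))
            d = np.arange(0.0, r + 30.0, self.depth_step_mm)
            with np.errstate(invalid="ignore"):
                bragg = np.where(d < r, (r - d) ** (1.0 / P_EXP - 1.0), 0.0)
            bragg *= 1.0 - self.nuclear_loss_per_mm * d
            # peak width: range straggling + beamline energy spread in quadrature
            sigma_strag = 10.0 * self.straggling_fraction * (r / 10.0) ** 0.935
            sigma_espread = P_EXP * r / e * self.energy_spread_mev
            sigma_r_mm = float(np.hypot(sigma_strag, sigma_espread))
            bragg = ndimage.gaussian_filter1d(
                bragg, sigma_r_mm / self.depth_step_mm, mode="nearest")
            bragg /= bragg[0]  # normalize to unit entrance dose
            self._idd_cache[e] = (d, bragg * self.output_cgy_mm2_per_mu)
        return self._idd_cache[e]

    def idd(self, energy_mev: float, depth_mm) -> np.ndarray:
        """Integrated depth dose per MU at water-equivalent depth (mm)."""
        d, curve = self.idd_curve(energy_mev)
        return np.interp(np.asarray(depth_mm, dtype=float), d, curve,
                         left=curve[0], right=0.0)

    def bragg_peak_depth_mm(self, energy_mev: float) -> float:
        d, curve = self.idd_curve(energy_mev)
        return float(d[np.argmax(curve)])


def beam_model_to_yaml(beam: BeamModel) -> str:
    """Serialize a beam model (scalar parameters + energy list) to YAML."""
    import yaml
    from dataclasses import asdict
    doc = asdict(beam)
    doc["energy_list"] = [float(e) for e in beam.energy_list]
    return yaml.safe_dump(doc, sort_keys=False)


def beam_model_from_yaml(text: str) -> BeamModel:
    import yaml
    doc = yaml.safe_load(text)
    if doc.get("energy_list") is not None:
        doc["energy_list"] = np.asarray(doc["energy_list"], dtype=float)
    return BeamModel(**doc)


def small_beam_model(**kw) -> BeamModel:
    return BeamModel(name="small", sigma_iso_ref_mm=3.0, **kw)


def large_beam_model(**kw) -> BeamModel:
    return BeamModel(name="large", sigma_iso_ref_mm=8.0, **kw)


BEAM_MODELS = {"small": small_beam_model, "large": large_beam_model}


# ---------------------------------------------------------------------------
# geometry helpers

def beam_axis(direction) -> tuple[int, int, tuple[int, int]]:
    """Validate an axis-aligned beam direction.

    Returns (axis, sign, lateral_axes).  Directions must be +-unit vectors
    along a patient axis; oblique gantry angles are out of scope for the
    slab-like phantom geometry.
    """
    d = np.asarray(direction, dtype=float)
    if d.shape != (3,) or not np.isclose(np.linalg.norm(d), 1.0):
        raise ValueError("field direction must be a 3D unit vector")
    axis = int(np.argmax(np.abs(d)))
    if not np.isclose(np.abs(d[axis]), 1.0):
        raise ValueError("field direction must be axis-aligned (+-x, +-y, +-z)")
    sign = 1 if d[axis] > 0 else -1
    lat = tuple(a for a in range(3) if a != axis)
    return axis, sign, lat


def wed_grid(density: DoseGrid, axis: int, sign: int) -> np.ndarray:
    """Water-equivalent depth (mm) of every voxel center by cumulative
    radiological path length along the beam axis (entering at the grid face)."""
    rho = np.asarray(density.values, dtype=float)
    step = density.spacing[axis]
    if sign < 0:
        rho = np.flip(rho, axis=axis)
    wed = (np.cumsum(rho, axis=axis) - 0.5 * rho) * step
    if sign < 0:
        wed = np.flip(wed, axis=axis)
    return wed


def shifted_density(density: DoseGrid, scenario: Scenario) -> DoseGrid:
    """Density as seen in the beam frame when the isocenter is shifted.

    An isocenter shift s relative to the patient is the patient translated
    by -s in the beam frame: rho_beam(x) = rho_patient(x + s)."""
    if not any(scenario.shift_mm):
        return density
    shift_vox = [-s / sp for s, sp in zip(scenario.shift_mm, density.spacing)]
    vals = ndimage.shift(np.asarray(density.values, float), shift_vox,
                         order=1, mode="nearest")
    return density.like(vals)


def _to_patient_frame(dose_beam: np.ndarray, grid: DoseGrid,
                      scenario: Scenario) -> np.ndarray:
    """Sample the beam-frame dose back at patient coordinates x - s."""
    if not any(scenario.shift_mm):
        return dose_beam
    shift_vox = [-s / sp for s, sp in zip(scenario.shift_mm, grid.spacing)]
    return ndimage.shift(dose_beam, [-v for v in shift_vox], order=1,
                         mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# dose deposition

def _deposit_spots(out: np.ndarray, grid: DoseGrid, wed: np.ndarray,
                   axis: int, lat: tuple[int, int], beam: BeamModel,
                   energy: float, spots: np.ndarray, range_scale: float,
                   trunc_sigma: float = 3.5) -> None:
    """Accumulate dose of one energy layer's spots (in the beam frame).

    `spots` is an (n, 3) array of (u_mm, v_mm, mu) with u, v offsets from
    the isocenter along the two lateral axes.
    """
    wed_eff = wed / range_scale
    idd_vals = beam.idd(energy, wed_eff)
    sig = beam.sigma_mm(energy, wed_eff)
    u_coords = grid.axis_coords(lat[0])
    v_coords = grid.axis_coords(lat[1])
    sig_max = float(np.max(sig))
    win = trunc_sigma * sig_max
    # move the beam axis last so the lateral window is a leading slice
    order = (lat[0], lat[1], axis)
    idd_t = np.transpose(idd_vals, order)
    sig_t = np.transpose(sig, order)
    out_t = np.transpose(out, order)  # view; writes land in `out`

    for u0, v0, mu in spots:
        if mu <= 0.0:
            continue
        iu = np.searchsorted(u_coords, (u0 - win, u0 + win))
        iv = np.searchsorted(v_coords, (v0 - win, v0 + win))
        su, sv = slice(iu[0], iu[1]), slice(iv[0], iv[1])
        du = u_coords[su] - u0
        dv = v_coords[sv] - v0
        s2 = sig_t[su, sv, :] ** 2
        lateral = np.exp(-(du[:, None, None] ** 2 + dv[None, :, None] ** 2)
                         / (2.0 * s2)) / (2.0 * np.pi * s2)
        out_t[su, sv, :] += mu * idd_t[su, sv, :] * lateral


def spot_dose(spot, beam: BeamModel, density: DoseGrid,
              scenario: Scenario = NOMINAL,
              direction=(0.0, 1.0, 0.0)) -> DoseGrid:
    """Dose grid (cGy(RBE) per delivery of `spot.mu`) for a single spot.

    `spot` is (u_mm, v_mm, energy_MeV, mu).  Linear in MU.  The returned
    dose is in the patient frame under the given scenario.
    """
    u, v, energy, mu = spot
    if mu < 0:
        raise ValueError("MU must be >= 0")
    beam._check_energy(energy)
    axis, sign, lat = beam_axis(direction)
    dens = shifted_density(density, scenario)
    wed = wed_grid(dens, axis, sign)
    out = np.zeros(density.shape, dtype=np.float64)
    _deposit_spots(out, density, wed, axis, lat, beam, energy,
                   np.array([[u, v, mu]], dtype=float), scenario.range_scale)
    return density.like(_to_patient_frame(out, density, scenario))


def plan_dose(plan, beam: BeamModel, density: DoseGrid,
              scenario: Scenario = NOMINAL) -> DoseGrid:
    """Course dose (cGy(RBE)) of a full spot plan: fractions x sum of
    per-fraction spot doses over all fields and layers (SFUD additivity)."""
    if plan.beam_model_name != beam.name:
        raise ValueError(f"plan references beam model '{plan.beam_model_name}' "
                         f"but got '{beam.name}'")
    dens = shifted_density(density, scenario)
    out = np.zeros(density.shape, dtype=np.float64)
    for f in plan.fields:
        axis, sign, lat = beam_axis(f.direction)
        wed = wed_grid(dens, axis, sign)
        for layer in f.layers:
            spots = np.array([[s.x_mm, s.y_mm, s.mu] for s in layer.spots],
                             dtype=float)
            if len(spots):
                _deposit_spots(out, density, wed, axis, lat, beam,
                               layer.energy_mev, spots, scenario.range_scale)
    out *= plan.fractions
    return density.like(_to_patient_frame(out, density, scenario))


def spot_dose_matrix(points_mm: np.ndarray, field_direction, layers,
                     beam: BeamModel, density: DoseGrid,
                     scenario: Scenario = NOMINAL,
                     trunc_sigma: float = 4.0) -> np.ndarray:
    """Influence matrix: per-fraction dose per unit MU at sample points.

    `layers` is a sequence of (energy_MeV, spot_uv) with spot_uv (n, 2).
    Returns an array (n_points, n_spots) with spots ordered as given.
    Points are patient-frame coordinates; the scenario shift and range
    scale are applied internally.
    """
    axis, sign, lat = beam_axis(field_direction)
    dens = shifted_density(density, scenario)
    wed3 = wed_grid(dens, axis, sign)
    pts_beam = np.asarray(points_mm, dtype=float) - np.asarray(scenario.shift_mm)
    idx = density.world_to_index(pts_beam)
    wed_pts = ndimage.map_coordinates(wed3, idx.T, order=1, mode="nearest")
    wed_eff = wed_pts / scenario.range_scale
    u_pts = pts_beam[:, lat[0]]
    v_pts = pts_beam[:, lat[1]]

    n_spots = sum(len(uv) for _, uv in layers)
    out = np.zeros((len(pts_beam), n_spots), dtype=np.float32)
    col = 0
    for energy, spot_uv in layers:
        idd_vals = beam.idd(energy, wed_eff)
        s2 = beam.sigma_mm(energy, wed_eff) ** 2
        active = idd_vals > 0
        pref = np.where(active, idd_vals / (2.0 * np.pi * s2), 0.0)
        inv2s2 = 0.5 / s2
        for u0, v0 in np.asarray(spot_uv, dtype=float):
            r2 = (u_pts - u0) ** 2 + (v_pts - v0) ** 2
            cut = r2 < (trunc_sigma ** 2) * s2
            vals = np.zeros(len(pts_beam), dtype=np.float32)
            m = cut & active
            vals[m] = pref[m] * np.exp(-r2[m] * inv2s2[m])
            out[:, col] = vals
            col += 1
    return out
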