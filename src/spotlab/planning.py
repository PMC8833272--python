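"""SFUD spot plans: placement, volumetric repainting, D99 normalization.

A plan prescribes 7000 cGy(RBE) in 35 fractions (2 Gy(RBE)/fraction with
RBE 1.1 folded into the dose units).  Spot MU values are per fraction, the
convention used by delivery systems; the dose engine multiplies by the
fraction count to report course dose.  Every machine-delivered spot pass
must carry at least 0.015 MU.

Volumetric repainting delivers the whole field several times at reduced MU,
traversing energy layers distal-to-proximal on the first painting and
reversing direction on each subsequent painting (alternating order).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .beam import (BeamModel, MIN_MU, beam_axis, energy_from_range,
                   range_from_energy, wed_grid)
from .grid import DoseGrid
from .phantom import Phantom4D


@dataclass
class Spot:
    x_mm: float   # lateral offset along the lower-index lateral axis
    y_mm: float   # lateral offset along the higher-index lateral axis
    mu: float     # per-fraction monitor units


@dataclass
class Layer:
    energy_mev: float
    spots: list[Spot] = field(default_factory=list)


@dataclass
class Field:
    direction: tuple[float, float, float]
    layers: list[Layer] = field(default_factory=list)  # descending energy

    @property
    def n_spots(self) -> int:
        return sum(len(l.spots) for l in self.layers)


@dataclass
class PaintingPass:
    """One full traversal of a field's layers at reduced MU.

    `events` is the ordered spot sequence: (layer_index, spot_index, mu).
    """
    field_index: int
    events: list[tuple[int, int, float]]


@dataclass
class SpotPlan:
    fields: list[Field]
    beam_model_name: str = "small"
    prescription_cgy: float = 7000.0
    fractions: int = 35
    paintings: list[PaintingPass] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu for f in self.fields
                         for l in f.layers for s in l.spots))

    @property
    def n_spots(self) -> int:
        return sum(f.n_spots for f in self.fields)

    def spot_mus(self) -> np.ndarray:
        return np.array([s.mu for f in self.fields
                         for l in f.layers for s in l.spots])

    def scale_mu(self, factor: float) -> "SpotPlan":
        """New plan with every spot (and painting pass) MU scaled."""
        import copy
        plan = copy.deepcopy(self)
        for f in plan.fields:
            for l in f.layers:
                for s in l.spots:
                    s.mu *= factor
        if plan.paintings:
            for p in plan.paintings:
                p.events = [(li, si, mu * factor) for li, si, mu in p.events]
        return plan

    # -- JSON ---------------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "beam_model": self.beam_model_name,
            "prescription_cGy": self.prescription_cgy,
            "fractions": self.fractions,
            "fields": [{
                "direction": list(f.direction),
                "layers": [{"energy_MeV": l.energy_mev,
                            "spots": [{"x_mm": s.x_mm, "y_mm": s.y_mm,
                                       "mu": s.mu} for s in l.spots]}
                           for l in f.layers],
            } for f in self.fields],
            "paintings": ([{"field_index": p.field_index,
                            "events": [list(e) for e in p.events]}
                           for p in self.paintings]
                          if self.paintings is not None else None),
            "meta": self.meta,
        }
        return json.dumps(doc, indent=1)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "SpotPlan":
        doc = json.loads(text)
        fields = [Field(tuple(fd["direction"]),
                        [Layer(l["energy_MeV"],
                               [Spot(s["x_mm"], s["y_mm"], s["mu"])
                                for s in l["spots"]]) for l in fd["layers"]])
                  for fd in doc["fields"]]
        paintings = None
        if doc.get("paintings") is not None:
            paintings = [PaintingPass(p["field_index"],
                                      [tuple(e) for e in p["events"]])
                         for p in doc["paintings"]]
        return cls(fields, doc["beam_model"], doc["prescription_cGy"],
                   doc["fractions"], paintings, doc.get("meta", {}))

    @classmethod
    def load(cls, path) -> "SpotPlan":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# spot placement

def _serpentine(order_u: np.ndarray, order_v: np.ndarray):
    """Boustrophedon ordering of lattice points: rows of v, u reversing."""
    idx = np.lexsort((order_u, order_v))
    out = []
    for v in np.unique(order_v):
        row = idx[order_v[idx] == v]
        row = row[np.argsort(order_u[row])]
        if len(out) % 2 == 1:
            row = row[::-1]
        out.extend(row.tolist())
    return out


def place_spots(phantom: Phantom4D, beam: BeamModel, field_directions,
                spot_spacing_sigma: float = 1.0,
                lateral_margin_mm: float | None = None,
                depth_margin_mm: float = 4.0,
                setup_margin_mm: float = 5.0,
                range_margin_fraction: float = 0.035,
                initial_mu: float = 1.0) -> SpotPlan:
    """Cover the CTV with energy layers and a lateral spot lattice per field.

    Layers are spaced by the beam model's water-range layer spacing and span
    the CTV's water-equivalent depth extent plus margins; the lateral
    lattice pitch is `spot_spacing_sigma` x the model's isocenter sigma at
    the reference energy.  The lateral footprint is the per-layer CTV
    projection expanded by the setup margin plus one sigma at the layer
    energy, and the depth extent by the range uncertainty plus one layer —
    robust optimization can only build shoulders where spots exist, so the
    lattice must already cover every perturbed target position.
    """
    directions = list(field_directions)
    if not 1 <= len(directions) <= 3:
        raise ValueError("plans use 1-3 fields")
    density = phantom.reference_grid
    ctv = phantom.masks["CTV"]
    pitch = spot_spacing_sigma * beam.sigma_iso_ref_mm

    def layer_margin(energy: float) -> float:
        # setup margin + one actual spot sigma at the layer energy: edge
        # spots must exist wherever a shifted CTV edge can land, and the
        # sigma term lets them hold up the lateral penumbra there
        if lateral_margin_mm is not None:
            return lateral_margin_mm
        return setup_margin_mm + float(beam.sigma_iso_mm(energy))

    layer_spacing = beam.layer_spacing_mm
    e_max_range = float(range_from_energy(beam.energy_list.max()))
    fields = []
    for direction in directions:
        axis, sign, lat = beam_axis(direction)
        wed = wed_grid(density, axis, sign)
        wed_ctv = wed[ctv]
        if wed_ctv.min() - depth_margin_mm > e_max_range:
            raise ValueError("CTV is beyond the reachable proton range "
                             f"for field direction {direction}")
        w_lo = max(wed_ctv.min() * (1.0 - range_margin_fraction)
                   - depth_margin_mm, layer_spacing)
        w_hi = min(wed_ctv.max() * (1.0 + range_margin_fraction)
                   + depth_margin_mm, e_max_range)
        n_layers = int(np.ceil((w_hi - w_lo) / layer_spacing)) + 1
        layer_weds = w_hi - layer_spacing * np.arange(n_layers)  # distal first
        layer_energies = [float(beam.energy_list[
            np.argmin(np.abs(range_from_energy(beam.energy_list) - w_k))])
            for w_k in layer_weds]
        margin_max = max(layer_margin(e) for e in layer_energies)

        u_coords = density.axis_coords(lat[0])
        v_coords = density.axis_coords(lat[1])
        # lateral lattice covering the full CTV projection + margin;
        # removing the beam axis keeps the two lateral axes in index order
        proj = np.any(ctv, axis=axis)
        uu = u_coords[proj.any(axis=1)]
        vv = v_coords[proj.any(axis=0)]
        u_min, u_max = uu.min() - margin_max, uu.max() + margin_max
        v_min, v_max = vv.min() - margin_max, vv.max() + margin_max
        nu = int(np.floor((u_max - u_min) / pitch)) + 1
        nv = int(np.floor((v_max - v_min) / pitch)) + 1
        u_grid = u_min + (u_max - u_min - (nu - 1) * pitch) / 2 + pitch * np.arange(nu)
        v_grid = v_min + (v_max - v_min - (nv - 1) * pitch) / 2 + pitch * np.arange(nv)

        layers = []
        half_slab = 0.5 * layer_spacing + 2.0
        Ug, Vg = np.meshgrid(u_grid, v_grid, indexing="ij")
        for w_k, energy in zip(layer_weds, layer_energies):
            if layers and np.isclose(layers[-1].energy_mev, energy):
                continue  # snapped onto the previous layer's energy
            slab = ctv & (np.abs(wed - w_k) <= half_slab)
            if not slab.any():
                # still place the distal/proximal margin layers on the CTV shadow
                slab = ctv & (np.abs(wed - np.clip(w_k, wed_ctv.min(),
                                                   wed_ctv.max())) <= half_slab)
            proj2 = np.any(slab, axis=axis)
            # metric dilation of the 2D projection by the lateral margin
            dist = ndimage.distance_transform_edt(
                ~proj2, sampling=(density.spacing[lat[0]],
                                  density.spacing[lat[1]]))
            proj2 = dist <= layer_margin(energy)
            iu = np.clip(np.round((Ug - u_coords[0]) / density.spacing[lat[0]])
                         .astype(int), 0, proj2.shape[0] - 1)
            iv = np.clip(np.round((Vg - v_coords[0]) / density.spacing[lat[1]])
                         .astype(int), 0, proj2.shape[1] - 1)
            keep = proj2[iu, iv]
            us, vs = Ug[keep], Vg[keep]
            if us.size == 0:
                continue
            order = _serpentine(us, vs)
            layers.append(Layer(energy, [Spot(float(us[i]), float(vs[i]),
                                              initial_mu) for i in order]))
        fields.append(Field(tuple(float(c) for c in direction), layers))
    return SpotPlan(fields, beam_model_name=beam.name)


# ---------------------------------------------------------------------------
# volumetric repainting

def make_volumetric_repainting(plan: SpotPlan, n_paintings: int = 5,
                               min_mu: float = MIN_MU) -> SpotPlan:
    """Split every spot's MU across `n_paintings` alternating-order passes.

    Painting 1 traverses energy layers distal to proximal, painting 2
    proximal to distal, and so on.  A spot whose MU cannot support the full
    painting count at the deliverability threshold is delivered in
    floor(MU / min_mu) equal passes assigned to the earliest paintings
    (never silently dropped); its total MU is conserved exactly.
    """
    if plan.paintings is not None:
        raise ValueError("plan already has a painting structure")
    import copy
    plan = copy.deepcopy(plan)
    paintings: list[PaintingPass] = []
    for fi, f in enumerate(plan.fields):
        n_layers = len(f.layers)
        # per-spot pass count: n_paintings, or fewer to honour min MU
        pass_count = {}
        for li, layer in enumerate(f.layers):
            for si, s in enumerate(layer.spots):
                k = n_paintings
                if s.mu / n_paintings < min_mu:
                    k = max(1, int(np.floor(s.mu / min_mu)))
                pass_count[(li, si)] = k
        for j in range(n_paintings):
            layer_order = range(n_layers) if j % 2 == 0 \
                else range(n_layers - 1, -1, -1)
            events = []
            for li in layer_order:
                spot_iter = enumerate(f.layers[li].spots)
                for si, s in spot_iter:
                    k = pass_count[(li, si)]
                    if j < k:
                        events.append((li, si, s.mu / k))
            if events:
                paintings.append(PaintingPass(fi, events))
    plan.paintings = paintings
    plan.meta["n_paintings"] = n_paintings
    return plan


def painting_mu_by_spot(plan: SpotPlan) -> dict[tuple[int, int, int], float]:
    """Summed painting-pass MU per (field, layer, spot) for audits."""
    totals: dict[tuple[int, int, int], float] = {}
    for p in plan.paintings or []:
        for li, si, mu in p.events:
            key = (p.field_index, li, si)
            totals[key] = totals.get(key, 0.0) + mu
    return totals


# ---------------------------------------------------------------------------
# normalization

def normalize_d99(plan: SpotPlan, dose: DoseGrid, ctv_mask: np.ndarray,
                  target_cgy: float | None = None,
                  min_mu: float = MIN_MU) -> tuple[SpotPlan, float]:
    """Scale all MUs so the CTV D99% equals 99% of the prescription.

    Returns (scaled plan, scale factor).  Spots pushed below the minimum
    deliverable MU by the scaling are reported via ``plan.meta`` and a
    warning, never silently dropped.
    """
    from .metrics import compute_dvh, dose_at_volume
    if target_cgy is None:
        target_cgy = 0.99 * plan.prescription_cgy
    d99 = dose_at_volume(compute_dvh(dose, ctv_mask, "CTV"), percent=99)
    if d99 <= 0:
        raise ValueError("CTV D99% must be positive before normalization")
    factor = target_cgy / d99
    scaled = plan.scale_mu(factor)
    scaled.meta["d99_scale_factor"] = factor
    low = [i for i, mu in enumerate(scaled.spot_mus()) if mu < min_mu]
    if low:
        scaled.meta["spots_below_min_mu"] = low
        warnings.warn(f"{len(low)} spots fall below the {min_mu} MU "
                      "deliverability threshold after D99 normalization")
    return scaled, factor
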