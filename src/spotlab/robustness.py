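"""Worst-case robustness evaluation over 12 setup/range scenarios.

The evaluation set combines an isocenter shift of 5 mm along each patient
axis (both signs) with a range uncertainty of +-3.5%: {+-5 mm SI, +-5 mm AP,
+-5 mm RL} x {range scale 0.965, 1.035} = 12 perturbed scenarios; the
nominal scenario is reported separately and excluded from the worst case.

The worst-case-scenario (WCS) value is the minimum over scenarios for
coverage-type metrics (CTV Dx%, HI) and the maximum for hot-spot and OAR
metrics (D0.03cc, Dmean, Vd).  The pass count is the number of scenarios
with CTV D95% at or above 98% of the prescription (6860 cGy(RBE) for
7000 cGy(RBE)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beam import BeamModel, NOMINAL, Scenario, plan_dose
from .grid import DoseGrid
from .metrics import (compute_dvh, dose_at_volume, homogeneity_index,
                      mean_dose, volume_at_dose)
from .phantom import Phantom4D
from .planning import SpotPlan

SETUP_SHIFT_MM = 5.0
RANGE_UNCERTAINTY = 0.035
_AXIS_LABEL = {0: "RL", 1: "AP", 2: "SI"}

# metric -> (worst-case direction) ; "min" = coverage-type, "max" = hot-spot/OAR
WCS_DIRECTION = {
    "CTV_D95%": "min", "CTV_D96%": "min", "CTV_D97%": "min",
    "CTV_D98%": "min", "CTV_D99%": "min", "CTV_HI": "min",
    "CTV_D0.03cc": "max",
    "total_lung_Dmean": "max", "total_lung_V20Gy": "max",
    "total_lung_V5Gy": "max", "heart_Dmean": "max",
    "esophagus_Dmean": "max", "spinal_cord_D0.03cc": "max",
}


def make_scenarios(shift_mm: float = SETUP_SHIFT_MM,
                   range_uncertainty: float = RANGE_UNCERTAINTY
                   ) -> list[Scenario]:
    """The 12 perturbed scenarios: {3 axes} x {+-shift} x {+-range}."""
    scenarios = []
    for axis in (2, 1, 0):           # SI, AP, RL
        for sign in (+1, -1):
            shift = [0.0, 0.0, 0.0]
            shift[axis] = sign * shift_mm
            for rs in (1.0 + range_uncertainty, 1.0 - range_uncertainty):
                label = (f"{_AXIS_LABEL[axis]}{'+' if sign > 0 else '-'}"
                         f"{shift_mm:g}mm/"
                         f"{'+' if rs > 1 else '-'}{range_uncertainty:.1%}")
                scenarios.append(Scenario(tuple(shift), rs, label))
    return scenarios


def delta(metric_large_spot: float, metric_small_spot: float) -> float:
    """Spot-size difference of a metric: large-spot minus small-spot."""
    return metric_large_spot - metric_small_spot


def scenario_metrics(dose: DoseGrid, masks: dict[str, np.ndarray],
                     prescription_cgy: float = 7000.0) -> dict[str, float]:
    """All evaluation metrics of one dose distribution."""
    out: dict[str, float] = {}
    if "CTV" in masks:
        dvh = compute_dvh(dose, masks["CTV"], "CTV")
        for x in (95, 96, 97, 98, 99):
            out[f"CTV_D{x}%"] = dose_at_volume(dvh, percent=x)
        out["CTV_D0.03cc"] = dose_at_volume(dvh, cc=0.03)
        out["CTV_HI"] = homogeneity_index(dvh)
    for organ, prefix in (("total_lung", "total_lung"), ("heart", "heart"),
                          ("esophagus", "esophagus"),
                          ("spinal_cord", "spinal_cord")):
        if organ not in masks or not np.any(masks[organ]):
            warnings.warn(f"mask '{organ}' missing; its metrics are skipped")
            continue
        dvh = compute_dvh(dose, masks[organ], organ)
        if organ == "spinal_cord":
            out[f"{prefix}_D0.03cc"] = dose_at_volume(dvh, cc=0.03)
        else:
            out[f"{prefix}_Dmean"] = mean_dose(dvh)
        if organ == "total_lung":
            out["total_lung_V20Gy"] = volume_at_dose(dvh, 2000.0)
            out["total_lung_V5Gy"] = volume_at_dose(dvh, 500.0)
    return out


@dataclass
class RobustnessReport:
    """Per-metric nominal, per-scenario and worst-case values."""

    table: pd.DataFrame              # rows = metrics; columns nominal, S1.., WCS
    scenarios: list[Scenario]
    pass_count: int                  # scenarios with CTV D95% >= 98% Rx
    pass_threshold_cgy: float
    doses: dict[str, DoseGrid] | None = None

    def wcs(self, metric: str) -> float:
        return float(self.table.loc[metric, "WCS"])

    def nominal(self, metric: str) -> float:
        return float(self.table.loc[metric, "nominal"])

    def save_csv(self, path) -> None:
        self.table.to_csv(path, index_label="metric")

    def save_json(self, path) -> None:
        import json
        doc = {
            "pass_count": self.pass_count,
            "pass_threshold_cgy": self.pass_threshold_cgy,
            "scenario_labels": [s.label for s in self.scenarios],
            "metrics": {m: {c: float(v) for c, v in row.items()}
                        for m, row in self.table.iterrows()},
        }
        from pathlib import Path
        Path(path).write_text(json.dumps(doc, indent=1))


def evaluate_robustness(plan: SpotPlan, beam: BeamModel, phantom: Phantom4D,
                        scenarios: list[Scenario] | None = None,
                        keep_doses: bool = False) -> RobustnessReport:
    """Recompute dose for the nominal and 12 perturbed scenarios and
    aggregate all evaluation metrics with their worst-case values."""
    scenarios = scenarios if scenarios is not None else make_scenarios()
    density = phantom.reference_grid
    masks = phantom.masks
    rx = plan.prescription_cgy
    rows: dict[str, dict[str, float]] = {}
    doses = {}

    def record(col: str, dose: DoseGrid):
        for metric, value in scenario_metrics(dose, masks, rx).items():
            rows.setdefault(metric, {})[col] = value
        if keep_doses:
            doses[col] = dose

    record("nominal", plan_dose(plan, beam, density, NOMINAL))
    scen_cols = []
    for i, sc in enumerate(scenarios, start=1):
        col = f"S{i}"
        scen_cols.append(col)
        record(col, plan_dose(plan, beam, density, sc))

    table = pd.DataFrame.from_dict(rows, orient="index")
    wcs = []
    for metric in table.index:
        vals = table.loc[metric, scen_cols].to_numpy(dtype=float)
        direction = WCS_DIRECTION.get(metric, "max")
        wcs.append(vals.min() if direction == "min" else vals.max())
    table["WCS"] = wcs

    threshold = 0.98 * rx
    d95 = table.loc["CTV_D95%", scen_cols].to_numpy(dtype=float)
    pass_count = int(np.sum(d95 >= threshold))
    return RobustnessReport(table, scenarios, pass_count, threshold,
                            doses if keep_doses else None)
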