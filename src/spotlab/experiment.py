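"""Orchestration of the full small-vs-large spot comparison experiment.

One run generates a seeded 4D phantom, then for each beam model (small
sigma = 3 mm, large sigma = 8 mm at isocenter, 226.5 MeV): places spots,
robustly optimizes the SFUD weights, normalizes CTV D99% to 99% of the
prescription, derives the five-painting alternating-order repainted plan,
evaluates 12-scenario robustness, EUD/NTCP for lung/heart/esophagus, and
the interplay effect for T0 and T50 delivery starts with and without
repainting.  Outputs are CSV/JSON tables, NRRD dose grids and a markdown
summary, with a provenance manifest of file hashes; a run is reproducible
from config + seed alone.

Plan variants follow the study nomenclature: SSNR/LSNR = small/large spot,
no repainting; SSVR/LSVR = small/large spot with five volumetric
repaintings (identical static dose to the NR plans by construction).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .beam import NOMINAL, large_beam_model, plan_dose, small_beam_model
from .interplay import simulate_interplay
from .metrics import compute_dvh, dose_at_volume
from .optimize import OptimizationSettings, robust_optimize
from .phantom import Phantom4D, PhantomConfig, generate_phantom
from .planning import make_volumetric_repainting, normalize_d99, place_spots
from .radiobio import evaluate_radiobio, load_organ_registry
from .robustness import delta, evaluate_robustness

log = logging.getLogger("spotlab")


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    field_directions: tuple = ((0.0, 1.0, 0.0), (-1.0, 0.0, 0.0))
    optimization: OptimizationSettings = field(default_factory=OptimizationSettings)
    n_paintings: int = 5
    start_phases: tuple = ("T0", "T50")
    seed: int = 0
    organ_registry_path: str | None = None
    save_doses: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "phantom" in doc:
            ph = dict(doc["phantom"])
            if "shape" in ph:
                ph["shape"] = tuple(ph["shape"])
            if ph.get("gtv_center_mm"):
                ph["gtv_center_mm"] = tuple(ph["gtv_center_mm"])
            kw["phantom"] = PhantomConfig(**ph)
        if "optimization" in doc:
            kw["optimization"] = OptimizationSettings(**doc["optimization"])
        for key in ("n_paintings", "seed", "organ_registry_path", "save_doses"):
            if key in doc:
                kw[key] = doc[key]
        if "field_directions" in doc:
            kw["field_directions"] = tuple(tuple(d) for d in doc["field_directions"])
        if "start_phases" in doc:
            kw["start_phases"] = tuple(doc["start_phases"])
        return cls(**kw)

    def to_yaml(self) -> str:
        doc = asdict(self)
        return yaml.safe_dump(doc, sort_keys=False)


def build_plan_pair(phantom: Phantom4D, config: ExperimentConfig):
    """Optimized + D99-normalized NR plan and dose per beam model."""
    out = {}
    for maker, name in ((small_beam_model, "small"), (large_beam_model, "large")):
        t0 = time.perf_counter()
        beam = maker()
        plan = place_spots(phantom, beam, config.field_directions)
        opt = robust_optimize(plan, beam, phantom, config.optimization)
        dose = plan_dose(opt.plan, beam, phantom.reference_grid, NOMINAL)
        plan_nr, scale = normalize_d99(opt.plan, dose, phantom.masks["CTV"])
        dose = dose.like(dose.values * scale)
        log.info("%s-spot plan: %d spots, optimizer %s, D99 scale %.4f "
                 "(%.1f s)", name, plan_nr.n_spots, opt.status, scale,
                 time.perf_counter() - t0)
        out[name] = {"beam": beam, "plan_nr": plan_nr, "dose": dose,
                     "optimizer_status": opt.status}
    return out


def run_experiment(config: ExperimentConfig, outdir) -> dict:
    """Run the full comparison; returns the report bundle as a dict.

    Any stage failure is recorded in the bundle's stage status (the bundle
    stays partial rather than vanishing); callers treat a non-ok status as
    a nonzero exit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    bundle: dict = {"config": yaml.safe_load(config.to_yaml()),
                    "stages": {}, "results": {}}
    registry = load_organ_registry(config.organ_registry_path)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
                bundle["stages"][name] = {
                    "status": "ok", "seconds": round(time.perf_counter() - t0, 2)}
            except Exception as exc:  # noqa: BLE001 - partial bundles by contract
                log.exception("stage %s failed", name)
                bundle["stages"][name] = {"status": "failed", "error": repr(exc)}
        return deco

    state: dict = {}

    @stage("phantom")
    def _phantom():
        state["phantom"] = generate_phantom(config.phantom, config.seed)
        state["phantom"].save(outdir / "phantom")

    @stage("planning")
    def _planning():
        state["pair"] = build_plan_pair(state["phantom"], config)
        for name, d in state["pair"].items():
            tag = "SS" if name == "small" else "LS"
            d["plan_vr"] = make_volumetric_repainting(
                d["plan_nr"], config.n_paintings)
            d["plan_nr"].save(outdir / f"plan_{tag}NR.json")
            d["plan_vr"].save(outdir / f"plan_{tag}VR.json")
            if config.save_doses:
                d["dose"].save_nrrd(outdir / f"dose_{tag}_nominal.nrrd")

    @stage("robustness")
    def _robustness():
        phantom = state["phantom"]
        for name, d in state["pair"].items():
            tag = "SS" if name == "small" else "LS"
            rep = evaluate_robustness(d["plan_nr"], d["beam"], phantom,
                                      keep_doses=True)
            rep.save_csv(outdir / f"robustness_{tag}VR.csv")
            d["robustness"] = rep
            log.info("%s robustness: pass count %d/12", tag, rep.pass_count)

    @stage("radiobio")
    def _radiobio():
        phantom = state["phantom"]
        rows = []
        for name, d in state["pair"].items():
            rep = d["robustness"]
            d["radiobio"] = {}
            for organ_name in ("total_lung", "heart", "esophagus"):
                organ = registry[organ_name]
                dvh_nom = compute_dvh(rep.doses["nominal"],
                                      phantom.masks[organ_name], organ_name)
                dvh_sc = [compute_dvh(rep.doses[f"S{i}"],
                                      phantom.masks[organ_name], organ_name)
                          for i in range(1, 13)]
                rb = evaluate_radiobio(dvh_nom, dvh_sc, organ,
                                       d["plan_nr"].fractions)
                d["radiobio"][organ_name] = rb
        for organ_name in ("total_lung", "heart", "esophagus"):
            ss = state["pair"]["small"]["radiobio"][organ_name]
            ls = state["pair"]["large"]["radiobio"][organ_name]
            rows.append({
                "organ": organ_name, "endpoint": ss.endpoint,
                "EUD_SSVR_cGy": round(ss.eud_wcs_cgy),
                "EUD_LSVR_cGy": round(ls.eud_wcs_cgy),
                "EUD_delta_cGy": round(delta(ls.eud_wcs_cgy, ss.eud_wcs_cgy)),
                "NTCP_SSVR_pct": ss.ntcp_wcs_pct,
                "NTCP_LSVR_pct": ls.ntcp_wcs_pct,
                "NTCP_delta_pct": round(
                    delta(ls.ntcp_wcs_pct, ss.ntcp_wcs_pct), 2),
            })
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "radiobio_wcs.csv", index=False)
        bundle["results"]["radiobio_wcs"] = df.to_dict(orient="records")

    @stage("interplay")
    def _interplay():
        phantom = state["phantom"]
        rows = []
        for name, d in state["pair"].items():
            tag = "SS" if name == "small" else "LS"
            nominal = d["robustness"].doses["nominal"]
            dvh = compute_dvh(nominal, phantom.masks["CTV"], "CTV")
            d99_nom = dose_at_volume(dvh, percent=99)
            d95_nom = dose_at_volume(dvh, percent=95)
            for label, plan in (("NR", d["plan_nr"]), ("VR", d["plan_vr"])):
                for start in config.start_phases:
                    res = simulate_interplay(plan, d["beam"], phantom, start)
                    rows.append({
                        "variant": f"{tag}{label}", "start": start,
                        "CTV_D95%": res.metrics["CTV_D95%"],
                        "CTV_D99%": res.metrics["CTV_D99%"],
                        "CTV_HI": res.metrics["CTV_HI"],
                        "D95_loss_pct": 100 * (d95_nom - res.metrics["CTV_D95%"])
                        / d95_nom,
                        "D99_loss_pct": 100 * (d99_nom - res.metrics["CTV_D99%"])
                        / d99_nom,
                    })
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "interplay.csv", index=False)
        bundle["results"]["interplay"] = df.to_dict(orient="records")

    @stage("summary")
    def _summary():
        rows = []
        reps = {t: state["pair"][n]["robustness"]
                for n, t in (("small", "SS"), ("large", "LS"))}
        for metric in reps["SS"].table.index:
            rows.append({
                "metric": metric,
                "SSVR_nominal": reps["SS"].nominal(metric),
                "SSVR_WCS": reps["SS"].wcs(metric),
                "LSVR_nominal": reps["LS"].nominal(metric),
                "LSVR_WCS": reps["LS"].wcs(metric),
                "delta_WCS": delta(reps["LS"].wcs(metric),
                                   reps["SS"].wcs(metric)),
            })
        df = pd.DataFrame(rows)
        df.to_csv(outdir / "wcs_summary.csv", index=False)
        bundle["results"]["wcs_summary"] = df.to_dict(orient="records")
        bundle["results"]["pass_count"] = {
            t: reps[t].pass_count for t in ("SS", "LS")}
        md = ["# spotlab experiment summary", "",
              f"seed: {config.seed}", "",
              f"pass count (CTV D95% >= 6860 cGy(RBE)): "
              f"SS {reps['SS'].pass_count}/12, LS {reps['LS'].pass_count}/12",
              "", df.to_string(index=False)]
        (outdir / "summary.md").write_text("\n".join(md))

    ok = all(s["status"] == "ok" for s in bundle["stages"].values())
    bundle["status"] = "ok" if ok else "partial"

    # provenance manifest with content hashes of every artifact
    manifest = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "provenance.json":
            manifest[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    bundle["provenance"] = manifest
    (outdir / "bundle.json").write_text(json.dumps(bundle, indent=1,
                                                   default=float))
    (outdir / "provenance.json").write_text(json.dumps(manifest, indent=1))
    return bundle
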