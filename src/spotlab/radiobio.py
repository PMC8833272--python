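"""EUD/NTCP radiobiology: fractionation correction, Niemierko power-mean
EUD, and the EUD-based logistic NTCP.

Model chain, applied to an organ DVH of a course of ``n_f`` fractions:

  EQD_i  = D_i * (alpha/beta + D_i / n_f) / (alpha/beta + 2)        (per bin)
  EUD    = ( sum_i v_i * EQD_i^a )^(1/a)                            (a != 0)
  NTCP   = 1 / ( 1 + (TD50 / EUD)^(4 * gamma50) )

EQD is the biologically equivalent dose delivered at 2 Gy per fraction
(linear-quadratic model); `a` is the organ's volume-effect exponent (1 =
mean dose, large = serial/max-dominated); TD50 the uniform EQD2 giving 50%
complication probability and gamma50 the slope of the dose-response curve.

Organ parameters are configuration (a YAML registry with photon-derived
literature defaults ships with the package); a two-point/least-squares
fitting utility recovers (TD50, gamma50) from printed (EUD, NTCP) pairs in
log-odds space for validation work.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .metrics import DVH

ENDPOINTS = {"total_lung": "pneumonitis", "heart": "pericarditis",
             "esophagus": "esophagitis"}


@dataclass
class OrganModel:
    """Radiobiological parameter set of one organ/endpoint."""

    organ: str
    endpoint: str
    a: float               # unitless volume-effect exponent
    alpha_beta_gy: float
    td50_gy: float         # tolerance EQD2 for 50% complication rate
    gamma50: float         # unitless slope of the dose-response curve

    def __post_init__(self):
        if self.td50_gy <= 0 or self.gamma50 <= 0:
            raise ValueError("TD50 and gamma50 must be > 0")
        if self.a == 0:
            raise ValueError("volume-effect exponent a must be nonzero")


def load_organ_registry(path=None) -> dict[str, OrganModel]:
    """Load the organ parameter registry (package default or a YAML file)."""
    if path is None:
        text = (importlib.resources.files("spotlab") / "data"
                / "organ_models.yaml").read_text()
    else:
        from pathlib import Path
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return {organ: OrganModel(organ=organ, endpoint=p["endpoint"], a=p["a"],
                              alpha_beta_gy=p["alpha_beta_gy"],
                              td50_gy=p["td50_gy"], gamma50=p["gamma50"])
            for organ, p in doc.items()}


def eqd(dose_gy, n_fractions: int, alpha_beta_gy: float) -> np.ndarray:
    """Equivalent dose at 2 Gy/fraction for a total dose delivered in
    `n_fractions` (linear-quadratic fractionation correction)."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if alpha_beta_gy <= 0:
        raise ValueError("alpha/beta must be > 0")
    d = np.asarray(dose_gy, dtype=float)
    return d * (alpha_beta_gy + d / n_fractions) / (alpha_beta_gy + 2.0)


def eud(eqd_gy, volumes, a: float) -> float:
    """Generalized power-mean EUD over (dose, partial-volume) bins.

    `volumes` are fractional partial volumes summing to 1; `a` the organ's
    volume-effect exponent.  a = 1 gives the mean dose; a -> +inf the
    maximum.  a = 0 (geometric-mean limit) is rejected.
    """
    if a == 0:
        raise ValueError("a = 0 is undefined in the power-mean EUD")
    d = np.asarray(eqd_gy, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if d.shape != v.shape:
        raise ValueError("dose and volume arrays must align")
    vs = v.sum()
    if not np.isclose(vs, 1.0, atol=1e-6):
        raise ValueError("partial volumes must sum to 1")
    if a < 0 and np.any(d <= 0):
        d = np.maximum(d, 1e-12)  # negative exponents blow up at zero dose
    return float((v @ d ** a) ** (1.0 / a))


def eud_from_dvh(dvh: DVH, organ: OrganModel, n_fractions: int) -> float:
    """EUD (Gy, EQD2 space) of a course DVH: per-voxel fractionation
    correction followed by the power mean.  Dose bins are the exact voxel
    doses (cGy) carried by the DVH."""
    doses_gy = dvh.voxel_doses_sorted / 100.0
    v = np.full(doses_gy.size, 1.0 / doses_gy.size)
    return eud(eqd(doses_gy, n_fractions, organ.alpha_beta_gy), v, organ.a)


def ntcp(eud_gy: float, organ: OrganModel) -> float:
    """EUD-based logistic NTCP, returned as a fraction in [0, 1]."""
    if eud_gy < 0:
        raise ValueError("EUD must be >= 0")
    if eud_gy == 0:
        return 0.0
    return 1.0 / (1.0 + (organ.td50_gy / eud_gy) ** (4.0 * organ.gamma50))


def fit_ntcp_params(pairs) -> tuple[float, float]:
    """Recover (TD50, gamma50) from (EUD, NTCP-fraction) pairs.

    The logistic model is linear in log-odds space:
    ln((1-N)/N) = 4 * gamma50 * (ln TD50 - ln EUD).  Two pairs give the
    exact 2x2 solution; more give the least-squares fit.  Pairs with
    NTCP of exactly 0 or 1 carry no log-odds information and are excluded
    with a warning.
    """
    pairs = [(float(e), float(n)) for e, n in pairs]
    kept = [(e, n) for e, n in pairs if 0.0 < n < 1.0]
    if len(kept) < len(pairs):
        warnings.warn("NTCP values of exactly 0 or 1 were excluded from the fit")
    if len(kept) < 2:
        raise ValueError("need at least 2 pairs with distinct EUD and "
                         "NTCP strictly between 0 and 1")
    e = np.array([p[0] for p in kept])
    n = np.array([p[1] for p in kept])
    if np.unique(e).size < 2:
        raise ValueError("EUD values must be distinct")
    y = np.log((1.0 - n) / n)
    x = np.log(e)
    slope, intercept = np.polyfit(x, y, 1)   # y = slope*x + intercept
    four_gamma = -slope
    if four_gamma <= 0:
        raise ValueError("pairs imply a non-increasing dose-response")
    td50 = float(np.exp(intercept / four_gamma))
    return td50, float(four_gamma / 4.0)


@dataclass
class RadiobioResult:
    """EUD/NTCP summary of one organ across scenarios."""

    organ: str
    endpoint: str
    eud_nominal_cgy: float
    ntcp_nominal_pct: float
    eud_scenarios_cgy: np.ndarray
    ntcp_scenarios_pct: np.ndarray

    @property
    def eud_wcs_cgy(self) -> float:
        return float(np.max(self.eud_scenarios_cgy)) \
            if self.eud_scenarios_cgy.size else self.eud_nominal_cgy

    @property
    def ntcp_wcs_pct(self) -> float:
        return float(np.max(self.ntcp_scenarios_pct)) \
            if self.ntcp_scenarios_pct.size else self.ntcp_nominal_pct


def evaluate_radiobio(dvh_nominal: DVH, dvh_scenarios: list[DVH],
                      organ: OrganModel, n_fractions: int,
                      ndigits: int = 2) -> RadiobioResult:
    """EUD (cGy EQD2) and NTCP (%) for nominal and scenario DVHs of one
    organ; NTCP is rounded to `ndigits` decimals in percent."""
    def one(dvh):
        e = eud_from_dvh(dvh, organ, n_fractions)
        return e * 100.0, round(100.0 * ntcp(e, organ), ndigits)
    e0, n0 = one(dvh_nominal)
    es, ns = [], []
    for dvh in dvh_scenarios:
        e, n = one(dvh)
        es.append(e)
        ns.append(n)
    return RadiobioResult(organ.organ, organ.endpoint, e0, n0,
                          np.asarray(es), np.asarray(ns))
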