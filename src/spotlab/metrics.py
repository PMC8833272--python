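"""Cumulative DVHs and the dose metrics used for plan evaluation.

Conventions: Dx% is the minimum dose received by the hottest x% of the
structure; D<v>cc the minimum dose of the hottest v cc (computed from the
sorted voxel tail, not the binned curve, to avoid bin-resolution bias);
Vd the percent volume receiving at least d; Dmean the exact voxel mean;
HI = D99% / D1% (1 for a perfectly uniform dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import DoseGrid


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    organ: str
    dose_cgy: np.ndarray          # bin edges (left), starting at 0
    volume_fraction: np.ndarray   # fraction of volume receiving >= dose
    volume_cc: float
    bin_width_cgy: float
    voxel_doses_sorted: np.ndarray = field(default=None, repr=False)  # descending

    def __post_init__(self):
        v = self.volume_fraction
        if v[0] != 1.0 or v[-1] != 0.0 or np.any(np.diff(v) > 1e-12):
            raise ValueError("cumulative DVH must fall monotonically from 1 to 0")


def compute_dvh(dose: DoseGrid, mask: np.ndarray, organ: str = "",
                bin_width_cgy: float = 1.0) -> DVH:
    """Cumulative DVH of the voxel doses inside a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError("mask shape does not match the dose grid")
    if not mask.any():
        raise ValueError(f"empty mask for organ '{organ}'")
    doses = np.asarray(dose.values)[mask].astype(float)
    volume_cc = mask.sum() * dose.voxel_volume_cc
    top = float(doses.max())
    edges = np.arange(0.0, top + 2 * bin_width_cgy, bin_width_cgy)
    counts, _ = np.histogram(doses, bins=edges)
    # volume_fraction[k] = fraction of voxels with dose >= edges[k]
    vf = 1.0 - np.concatenate(([0.0], np.cumsum(counts))) / doses.size
    return DVH(organ, edges, np.clip(vf, 0.0, 1.0), volume_cc, bin_width_cgy,
               np.sort(doses)[::-1])


def dose_at_volume(dvh: DVH, percent: float | None = None,
                   cc: float | None = None) -> float:
    """Dx% / D<cc>cc by inverse-DVH lookup with linear interpolation."""
    if (percent is None) == (cc is None):
        raise ValueError("give exactly one of percent= or cc=")
    if cc is not None:
        if not 0 < cc <= dvh.volume_cc:
            raise ValueError(f"requested {cc} cc exceeds organ volume "
                             f"{dvh.volume_cc:.3f} cc")
        frac = cc / dvh.volume_cc
    else:
        if not 0 < percent <= 100:
            raise ValueError("percent must be in (0, 100]")
        frac = percent / 100.0
    if cc is not None and dvh.voxel_doses_sorted is not None:
        # sorted-voxel-tail convention: the dose of the k-th hottest voxel,
        # k = number of whole voxels inside the requested volume (a request
        # within one voxel reads the hottest voxel)
        d = dvh.voxel_doses_sorted
        voxel_cc = dvh.volume_cc / d.size
        k = max(1, int(np.floor(cc / voxel_cc + 1e-9)))
        return float(d[min(k, d.size) - 1])
    # invert the monotone cumulative curve
    v = dvh.volume_fraction[::-1]
    dd = dvh.dose_cgy[::-1]
    return float(np.interp(frac, v, dd))


def volume_at_dose(dvh: DVH, dose_cgy: float) -> float:
    """Vd: percent of the structure receiving at least `dose_cgy`."""
    if dose_cgy < 0:
        raise ValueError("dose must be >= 0")
    return 100.0 * float(np.interp(dose_cgy, dvh.dose_cgy, dvh.volume_fraction))


def mean_dose(dvh: DVH) -> float:
    """Dmean, computed exactly from the voxel doses."""
    return float(np.mean(dvh.voxel_doses_sorted))


def homogeneity_index(dvh: DVH) -> float:
    """HI = D99% / D1%; 1.0 for a uniform dose."""
    d1 = dose_at_volume(dvh, percent=1)
    if d1 <= 0:
        raise ValueError("D1% must be > 0 for the homogeneity index")
    return dose_at_volume(dvh, percent=99) / d1


def save_dvh_csv(dvh: DVH, path) -> None:
    arr = np.column_stack([dvh.dose_cgy, dvh.volume_fraction])
    header = "dose_cGy,volume_fraction"
    np.savetxt(path, arr, delimiter=",", header=header, comments="",
               fmt="%.6g")


def load_dvh_csv(path, organ: str = "", volume_cc: float = float("nan")) -> DVH:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    bw = float(np.median(np.diff(arr[1:, 0]))) if len(arr) > 2 else 1.0
    return DVH(organ, arr[:, 0], arr[:, 1], volume_cc, bw)
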