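"""Synthetic 4D thorax phantom with analytically known respiratory motion.

The phantom stands in for a patient 4DCT: a voxelized thorax (body, two
lungs, heart, esophagus, spinal cord) with a lung tumor that translates
along a dominant superior-inferior axis over a 10-phase breathing cycle.
The tumor follows a sin^2-type waveform with end-exhale (T50) as the rest
position and end-inhale (T0) as the extreme; peak-to-peak excursion is the
configured motion amplitude.  The displacement field is analytic — rigid
translation inside an envelope around the tumor with a smooth cosine^2
falloff to zero — so dose mapping between phases is exact and invertible,
unlike image-based deformable registration.

Following clinical practice for PBS lung planning, the internal gross tumor
volume (IGTV, the swept union of tumor positions) is overridden with water
density in every phase, and the CTV is the IGTV expanded isotropically by
5 mm.  With the override in place the phase density grids are identical;
phases differ through their displacement fields only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import DoseGrid

N_PHASES = 10
MAX_AMPLITUDE_MM = 15.0  # phantoms emulate tumors moving < 15 mm
CTV_MARGIN_MM = 5.0      # CTV = IGTV + isotropic 5 mm

MASK_NAMES = ("CTV", "IGTV", "total_lung", "heart", "esophagus",
              "spinal_cord", "external")


@dataclass
class PhantomConfig:
    """Geometry and motion settings for :func:`generate_phantom`.

    Defaults describe the study conditions: a 3 mm isotropic 80^3 grid
    (240 mm cube), a 20 mm-radius gross tumor in the right lung (CTV about
    85 cc, near the clinical cohort's mean target size) moving 10 mm
    peak-to-peak (mid-to-high end of the 2.2-13.2 mm clinical motion
    range), breathing period 4 s.
    """

    shape: tuple[int, int, int] = (80, 80, 80)
    spacing_mm: float = 3.0
    amplitude_mm: float = 10.0
    period_s: float = 4.0
    reference_phase: int = 5          # T50, end-exhale
    gtv_radius_mm: float = 20.0
    gtv_center_mm: tuple[float, float, float] | None = None  # None -> default by site
    mediastinum_involved: bool = False
    # motion direction: SI-dominant, with small AP/RL fractions
    ap_fraction: float = 0.2
    rl_fraction: float = 0.1
    falloff_taper_mm: float = 10.0    # taper length from rigid core to zero
    lung_density: float = 0.25
    body_density: float = 1.0
    air_density: float = 0.001
    jitter_mm: float = 3.0            # seeded random offset of the tumor center

    def __post_init__(self):
        if not (0.0 <= self.amplitude_mm < MAX_AMPLITUDE_MM):
            raise ValueError(
                f"motion amplitude must be in [0, {MAX_AMPLITUDE_MM}) mm "
                f"(phantoms emulate lung tumor motion of less than 15 mm); "
                f"got {self.amplitude_mm}")
        if self.spacing_mm <= 0:
            raise ValueError("grid spacing must be > 0")
        if not 0 <= self.reference_phase < N_PHASES:
            raise ValueError("reference phase must be in 0..9")


def phase_fraction(phase: int | np.ndarray) -> np.ndarray:
    """Waveform factor f(p) in [0, 1]: displacement from rest at phase p.

    f(p) = cos^2(pi p / 10): 1 at T0 (end-inhale), 0 at T50 (end-exhale),
    symmetric over the cycle — a sin^2 breathing waveform with T50 rest.
    """
    return np.cos(np.pi * np.asarray(phase) / N_PHASES) ** 2


@dataclass
class Phantom4D:
    """10-phase thorax phantom with analytic displacement fields."""

    phases: list[DoseGrid]
    reference_phase_index: int
    masks: dict[str, np.ndarray]
    motion_amplitude_mm: float
    breathing_period_s: float
    tumor_center_mm: np.ndarray          # at the reference phase
    motion_direction: np.ndarray         # unit vector
    flat_radius_mm: float
    falloff_radius_mm: float
    config: PhantomConfig = None
    seed: int = 0

    # -- motion -------------------------------------------------------------
    def _falloff(self, r: np.ndarray) -> np.ndarray:
        """1 inside flat core, cos^2 taper to 0 at the falloff radius."""
        rf, re = self.flat_radius_mm, self.falloff_radius_mm
        t = np.clip((r - rf) / max(re - rf, 1e-9), 0.0, 1.0)
        return np.cos(0.5 * np.pi * t) ** 2

    def displacement_at(self, phase: int, points: np.ndarray) -> np.ndarray:
        """Displacement u_p (mm) at reference-phase points (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts - self.tumor_center_mm, axis=1)
        f = phase_fraction(phase) - phase_fraction(self.reference_phase_index)
        return (self.motion_amplitude_mm * f * self._falloff(r))[:, None] \
            * self.motion_direction

    def displacement_field(self, phase: int) -> np.ndarray:
        """Vector field (3, nx, ny, nz), mm, reference phase -> given phase."""
        ref = self.reference_grid
        X, Y, Z = ref.meshgrid()
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        u = self.displacement_at(phase, pts)
        return u.T.reshape((3,) + ref.shape)

    def tumor_centroid(self, phase: int) -> np.ndarray:
        f = phase_fraction(phase) - phase_fraction(self.reference_phase_index)
        return self.tumor_center_mm + self.motion_amplitude_mm * f \
            * self.motion_direction

    @property
    def reference_grid(self) -> DoseGrid:
        return self.phases[self.reference_phase_index]

    @property
    def displacement_fields(self) -> list[np.ndarray]:
        return [self.displacement_field(p) for p in range(N_PHASES)]

    # -- serialization ------------------------------------------------------
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p, grid in enumerate(self.phases):
            grid.save_nrrd(outdir / f"phase_T{p * 10:02d}.nrrd")
        ref = self.reference_grid
        for name, mask in self.masks.items():
            ref.like(mask.astype(np.uint8)).save_nrrd(outdir / f"mask_{name}.nrrd")
        manifest = {
            "phase_order": [f"T{p * 10:02d}" for p in range(N_PHASES)],
            "reference_phase_index": self.reference_phase_index,
            "motion_amplitude_mm": self.motion_amplitude_mm,
            "breathing_period_s": self.breathing_period_s,
            "tumor_center_mm": list(self.tumor_center_mm),
            "motion_direction": list(self.motion_direction),
            "flat_radius_mm": self.flat_radius_mm,
            "falloff_radius_mm": self.falloff_radius_mm,
            "seed": self.seed,
            "config": asdict(self.config) if self.config else None,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def content_hash(self) -> str:
        """Deterministic digest of all phase grids, masks and motion params."""
        h = hashlib.sha256()
        for grid in self.phases:
            h.update(np.ascontiguousarray(grid.values))
        for name in sorted(self.masks):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.masks[name]))
        h.update(np.asarray([self.motion_amplitude_mm, self.breathing_period_s,
                             self.flat_radius_mm, self.falloff_radius_mm]))
        h.update(np.ascontiguousarray(self.tumor_center_mm))
        h.update(np.ascontiguousarray(self.motion_direction))
        return h.hexdigest()


def load_phantom(indir) -> Phantom4D:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    phases = [DoseGrid.load_nrrd(indir / f"phase_{tag}.nrrd")
              for tag in manifest["phase_order"]]
    masks = {name: DoseGrid.load_nrrd(indir / f"mask_{name}.nrrd").values.astype(bool)
             for name in MASK_NAMES}
    cfg = PhantomConfig(**{**manifest["config"],
                           "shape": tuple(manifest["config"]["shape"]),
                           "gtv_center_mm": (tuple(manifest["config"]["gtv_center_mm"])
                                             if manifest["config"]["gtv_center_mm"]
                                             else None)}) \
        if manifest.get("config") else None
    return Phantom4D(
        phases=phases,
        reference_phase_index=manifest["reference_phase_index"],
        masks=masks,
        motion_amplitude_mm=manifest["motion_amplitude_mm"],
        breathing_period_s=manifest["breathing_period_s"],
        tumor_center_mm=np.asarray(manifest["tumor_center_mm"]),
        motion_direction=np.asarray(manifest["motion_direction"]),
        flat_radius_mm=manifest["flat_radius_mm"],
        falloff_radius_mm=manifest["falloff_radius_mm"],
        config=cfg,
        seed=manifest.get("seed", 0),
    )


# ---------------------------------------------------------------------------
# generation

def _ellipsoid(X, Y, Z, center, semi) -> np.ndarray:
    return (((X - center[0]) / semi[0]) ** 2
            + ((Y - center[1]) / semi[1]) ** 2
            + ((Z - center[2]) / semi[2]) ** 2) <= 1.0


def _cylinder_z(X, Y, Z, cx, cy, radius, z_half, cz=0.0) -> np.ndarray:
    return (((X - cx) ** 2 + (Y - cy) ** 2) <= radius ** 2) \
        & (np.abs(Z - cz) <= z_half)


def _capsule_mask(X, Y, Z, a, b, radius) -> np.ndarray:
    """Voxels within `radius` of the segment a-b (swept-sphere / capsule)."""
    return _capsule_distance(X, Y, Z, a, b) <= radius


def _capsule_distance(X, Y, Z, a, b):
    a = np.asarray(a, float)
    d = np.asarray(b, float) - a
    dd = float(d @ d)
    px, py, pz = X - a[0], Y - a[1], Z - a[2]
    if dd < 1e-12:
        return np.sqrt(px ** 2 + py ** 2 + pz ** 2)
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / dd, 0.0, 1.0)
    return np.sqrt((px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
                   + (pz - t * d[2]) ** 2)


def dilate_mm(mask: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """Isotropic dilation by a metric margin via Euclidean distance transform."""
    if margin_mm <= 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> Phantom4D:
    """Build a seeded 10-phase thorax phantom.

    The seed jitters the tumor position (within `jitter_mm`) and organ sizes
    by a few percent, giving distinct but statistically comparable anatomies.
    Identical config + seed yields a bitwise-identical phantom.
    """
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)

    nx, ny, nz = cfg.shape
    sp = float(cfg.spacing_mm)
    # grid centered on the isocenter (world origin at the grid center)
    origin = tuple(-sp * (n - 1) / 2 for n in cfg.shape)
    ref = DoseGrid(np.zeros(cfg.shape, dtype=np.float32), (sp, sp, sp), origin)
    X, Y, Z = ref.meshgrid()
    half = [sp * (n - 1) / 2 for n in cfg.shape]

    scale = 1.0 + 0.05 * rng.uniform(-1, 1, size=4)  # organ size jitter
    body_semi = (0.92 * half[0], 0.82 * half[1], 1.02 * half[2])
    external = _ellipsoid(X, Y, Z, (0, 0, 0), body_semi)

    # lungs sized so the chest wall is 15-25 mm thick, as in an adult thorax
    lung_semi = np.array([0.29 * half[0], 0.50 * half[1], 0.70 * half[2]]) * scale[0]
    lung_r = _ellipsoid(X, Y, Z, (+0.43 * half[0], -0.05 * half[1], 0), lung_semi)
    lung_l = _ellipsoid(X, Y, Z, (-0.43 * half[0], -0.05 * half[1], 0), lung_semi)

    heart_semi = np.array([0.30 * half[0], 0.26 * half[1], 0.33 * half[2]]) * scale[1]
    heart = _ellipsoid(X, Y, Z, (-0.10 * half[0], 0.12 * half[1], -0.30 * half[2]),
                       heart_semi) & external
    cord = _cylinder_z(X, Y, Z, 0.0, 0.62 * half[1], 5.0 * scale[2],
                       z_half=0.95 * half[2]) & external
    eso = _cylinder_z(X, Y, Z, 0.04 * half[0], 0.32 * half[1], 5.0 * scale[3],
                      z_half=0.95 * half[2]) & external
    lung_r &= ~(heart | cord | eso)
    lung_l &= ~(heart | cord | eso)
    lungs = lung_r | lung_l

    # tumor center at reference phase (T50 rest position)
    if cfg.gtv_center_mm is not None:
        c0 = np.asarray(cfg.gtv_center_mm, dtype=float)
    elif cfg.mediastinum_involved:
        c0 = np.array([0.20 * half[0], 0.15 * half[1], 0.05 * half[2]])
    else:
        c0 = np.array([0.43 * half[0], -0.08 * half[1], 0.10 * half[2]])
    c0 = c0 + rng.uniform(-cfg.jitter_mm, cfg.jitter_mm, size=3)

    direction = np.array([cfg.rl_fraction, cfg.ap_fraction, 1.0])
    direction /= np.linalg.norm(direction)
    f_ref = phase_fraction(cfg.reference_phase)
    # swept tumor path endpoints: rest (f=0) and end-inhale extreme (f=1)
    c_lo = c0 + cfg.amplitude_mm * (0.0 - f_ref) * direction
    c_hi = c0 + cfg.amplitude_mm * (1.0 - f_ref) * direction

    # IGTV = union of tumor spheres over the cycle = capsule along the path;
    # the CTV is its exact isotropic 5 mm expansion (same capsule, +5 mm)
    dist_path = _capsule_distance(X, Y, Z, c_lo, c_hi)
    igtv = dist_path <= cfg.gtv_radius_mm
    ctv = dist_path <= cfg.gtv_radius_mm + CTV_MARGIN_MM
    if np.any(ctv & ~external):
        raise ValueError("CTV extends outside the external contour; "
                         "move the tumor or enlarge the body")

    total_lung = lungs & ~ctv
    masks = {
        "CTV": ctv, "IGTV": igtv, "total_lung": total_lung, "heart": heart,
        "esophagus": eso, "spinal_cord": cord, "external": external,
    }

    density = np.full(cfg.shape, cfg.air_density, dtype=np.float32)
    density[external] = cfg.body_density
    density[lungs] = cfg.lung_density
    density[heart | cord | eso] = cfg.body_density
    density[igtv] = 1.0  # water override, applied in every phase
    phases = [ref.like(density.copy()) for _ in range(N_PHASES)]

    # rigid core covers the gross tumor only; the surrounding lung slides
    # around the moving tumor, so the falloff to zero is short — translating
    # the whole IGTV-plus-margin region would drag the (static) CTV margin
    # tissue out of the dose plateau in every phase
    flat_radius = cfg.gtv_radius_mm + 2.0
    falloff = flat_radius + cfg.falloff_taper_mm
    return Phantom4D(
        phases=phases,
        reference_phase_index=cfg.reference_phase,
        masks=masks,
        motion_amplitude_mm=cfg.amplitude_mm,
        breathing_period_s=cfg.period_s,
        tumor_center_mm=c0,
        motion_direction=direction,
        flat_radius_mm=flat_radius,
        falloff_radius_mm=falloff,
        config=cfg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# point mapping

def displace_point(phantom: Phantom4D, phase: int, point) -> np.ndarray:
    """Map a reference-phase point (mm) to its position in `phase`."""
    if not 0 <= phase < N_PHASES:
        raise ValueError("phase must be in 0..9")
    pt = np.asarray(point, dtype=float)
    single = pt.ndim == 1
    pts = np.atleast_2d(pt)
    inside = phantom.reference_grid.contains(pts)
    if not np.all(inside):
        raise ValueError("point outside grid bounds")
    out = pts + phantom.displacement_at(phase, pts)
    return out[0] if single else out


def inverse_displace_point(phantom: Phantom4D, phase: int, point,
                           tol_mm: float = 1e-6, max_iter: int = 60) -> np.ndarray:
    """Invert the phase mapping by fixed-point iteration (< 0.01 mm)."""
    if not 0 <= phase < N_PHASES:
        raise ValueError("phase must be in 0..9")
    y = np.atleast_2d(np.asarray(point, dtype=float))
    x = y.copy()
    for _ in range(max_iter):
        x_new = y - phantom.displacement_at(phase, x)
        if np.max(np.abs(x_new - x)) < tol_mm:
            x = x_new
            break
        x = x_new
    return x[0] if np.asarray(point).ndim == 1 else x
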