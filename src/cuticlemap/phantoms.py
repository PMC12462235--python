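"""Synthetic µCT-like phantoms with analytic ground truth.

The study system is the cephalothorax of an endoparasitic strepsipteran
female: a thin, curved cuticle shell with an invaginated paragenital pouch
whose ventral wall is markedly thicker than its dorsal wall, and a brood
canal whose cuticle thins from anterior to posterior.  No scans are
deposited, so these phantoms supply every geometric and statistical feature
the downstream analysis assumes, each with exact analytic truth:

* ``slab`` — an axis-aligned (optionally rotated) plate of constant wall
  thickness; the basic recovery target for both thickness measures.
* ``spherical_shell`` — a hollow sphere of constant wall thickness; the
  curved-wall case where tangential ray runs scale with thickness.
* ``solid_cube`` — a body thicker than any search radius; the saturation
  (cap) case.
* ``capsule_pouch`` — a cylindrical capsule (cephalothorax analogue) with a
  cylindrical pouch bored into its anterior face.  The pouch's ventral wall
  is ``ventral_dorsal_factor`` times thicker than its dorsal wall, the bore
  depth is ``pouch_depth_fraction`` of the capsule length, and a ventral
  strip of the capsule wall thins linearly toward the posterior end (brood
  canal analogue).

A voxel is foreground iff its centre lies inside the analytic surface; the
grayscale volume is the mask at ``fg_gray`` over ``bg_gray`` plus seeded
Gaussian noise, and the mask never depends on the noise.

Morphometric cohorts (`make_cohort`) draw species-level trait quartets
(DP, CL, PL, LA) from a seeded multivariate Gaussian whose correlation
structure emulates the reported covariation of pouch depth with penis and
acumen length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .morphometrics import MorphometricRecord
from .volume_io import GrayscaleVolume, RegionLabelMap, SegmentationMask

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "MorphometricCohortSpec",
    "make_phantom",
    "make_cohort",
    "REGION_LEGEND",
]

MARGIN = 2  # background voxels required around every phantom

REGION_LEGEND = {
    1: "ventral pouch wall",
    2: "dorsal pouch wall",
    3: "brood canal analogue",
    4: "control",
    5: "ventral-dorsal transition",
}

_KINDS = ("slab", "spherical_shell", "capsule_pouch", "solid_cube")


@dataclass
class PhantomSpec:
    kind: str
    grid_shape: tuple[int, int, int]
    wall_thickness: float = 5.0
    spacing: float = 1.0
    outer_radius: Optional[float] = None
    pouch_depth_fraction: Optional[float] = None
    ventral_dorsal_factor: float = 1.0
    fg_gray: float = 200.0
    bg_gray: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0
    rotation_deg: float = 0.0  # slab only, about the x index axis

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.fg_gray == self.bg_gray:
            raise ValueError("fg_gray must differ from bg_gray")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kind in ("spherical_shell", "capsule_pouch"):
            if self.outer_radius is None or self.outer_radius <= 0:
                raise ValueError(f"{self.kind} requires a positive outer_radius")
            if self.wall_thickness >= self.outer_radius:
                raise ValueError("wall_thickness must be smaller than outer_radius")
        if self.kind == "capsule_pouch":
            f = self.pouch_depth_fraction
            if f is None or not (0.0 < f < 1.0):
                raise ValueError("capsule_pouch requires pouch_depth_fraction in (0, 1)")
            if self.ventral_dorsal_factor < 1.0:
                raise ValueError("ventral_dorsal_factor must be >= 1")


@dataclass
class GroundTruth:
    """Analytic truth accompanying a phantom.

    ``true_thickness`` is the local wall thickness in voxels (0 on
    background); ``region_labels`` marks ventral/dorsal pouch walls, the
    brood-canal analogue and control cuticle; ``true_DP``/``true_CL`` are
    the pouch depth and capsule length in voxels along the z axis.
    """

    true_thickness: np.ndarray
    region_labels: RegionLabelMap
    true_DP: float
    true_CL: float

    def __post_init__(self) -> None:
        if self.true_DP < 0 or self.true_CL <= 0 or self.true_DP > self.true_CL:
            raise ValueError("require 0 <= true_DP <= true_CL and true_CL > 0")


def _grids(shape):
    z, y, x = np.indices(shape, dtype=np.float64)
    return z, y, x


def _margin_error(kind: str, axis: str, needed: int, have: int):
    return ValueError(
        f"{kind} phantom does not fit: needs {needed} voxels along {axis} "
        f"(geometry + {MARGIN}-voxel background margin) but grid has {have}"
    )


def _build_slab(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    t = spec.wall_thickness
    ti = int(round(t))
    if ti + 2 * MARGIN > nz:
        raise _margin_error("slab", "z", ti + 2 * MARGIN, nz)
    mask = np.zeros(spec.grid_shape, dtype=bool)
    if spec.rotation_deg == 0.0:
        z0 = (nz - ti) // 2
        mask[z0 : z0 + ti, MARGIN : ny - MARGIN, MARGIN : nx - MARGIN] = True
    else:
        theta = math.radians(spec.rotation_deg)
        c = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
        z, y, x = _grids(spec.grid_shape)
        d = (z - c[0]) * math.cos(theta) + (y - c[1]) * math.sin(theta)
        inside = np.abs(d) < t / 2.0
        box = (
            (z >= MARGIN) & (z <= nz - 1 - MARGIN)
            & (y >= MARGIN) & (y <= ny - 1 - MARGIN)
            & (x >= MARGIN) & (x <= nx - 1 - MARGIN)
        )
        mask = inside & box
    thickness = np.where(mask, float(t), 0.0)
    labels = np.where(mask, 4, 0).astype(np.int16)
    zs = np.flatnonzero(mask.any(axis=(1, 2)))
    cl = float(zs[-1] - zs[0] + 1) if zs.size else float(ti)
    return mask, thickness, labels, 0.0, cl


def _build_shell(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    R, t = float(spec.outer_radius), float(spec.wall_thickness)
    need = int(math.ceil(2 * R)) + 2 * MARGIN + 1
    for axis, n in zip("zyx", spec.grid_shape):
        if need > n:
            raise _margin_error("spherical_shell", axis, need, n)
    c = [(n - 1) / 2.0 for n in spec.grid_shape]
    z, y, x = _grids(spec.grid_shape)
    r = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
    mask = (r <= R) & (r > R - t)
    thickness = np.where(mask, t, 0.0)
    labels = np.where(mask, 4, 0).astype(np.int16)
    return mask, thickness, labels, 0.0, 2.0 * R


def _build_cube(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    if min(spec.grid_shape) <= 2 * MARGIN:
        raise _margin_error("solid_cube", "zyx", 2 * MARGIN + 1, min(spec.grid_shape))
    mask = np.zeros(spec.grid_shape, dtype=bool)
    mask[MARGIN : nz - MARGIN, MARGIN : ny - MARGIN, MARGIN : nx - MARGIN] = True
    side = float(min(spec.grid_shape) - 2 * MARGIN)
    thickness = np.where(mask, side, 0.0)
    labels = np.where(mask, 4, 0).astype(np.int16)
    return mask, thickness, labels, 0.0, float(nz - 2 * MARGIN)


def _build_capsule(spec: PhantomSpec):
    """Cylindrical capsule with a ventrally-thickened pouch bore.

    Geometry (z anterior->posterior, y ventral->dorsal):
      * capsule: tube wall of thickness t at radius R plus flat end discs;
      * pouch: cylindrical bore of lumen radius ~R/5 from the anterior disc
        to depth DP = pouch_depth_fraction * CL, closed by an end cap; the
        bore's annular wall has thickness t_v = factor * t on the ventral
        sector, t on the dorsal sector, blending linearly in between;
      * brood canal analogue: ventral strip of the capsule tube wall whose
        thickness decays linearly from t_v (anterior) to t (posterior).
    """
    nz, ny, nx = spec.grid_shape
    R, t = float(spec.outer_radius), float(spec.wall_thickness)
    t_v = spec.ventral_dorsal_factor * t
    frac = float(spec.pouch_depth_fraction)
    r_l = max(3.0, round(R / 5.0))

    z0 = MARGIN
    CL = nz - 2 * MARGIN
    z1 = z0 + CL - 1
    DP = int(round(frac * CL))
    zD = z0 + DP

    yc, xc = (ny - 1) / 2.0, (nx - 1) / 2.0
    for axis, n, half in (("y", ny, yc), ("x", nx, xc)):
        if R > half - MARGIN:
            raise _margin_error("capsule_pouch", axis, int(math.ceil(2 * R)) + 2 * MARGIN + 1, n)
    if CL < 2 * int(round(t)) + 4:
        raise _margin_error("capsule_pouch", "z", 2 * int(round(t)) + 4 + 2 * MARGIN, nz)
    if r_l + t_v >= R - t_v - 1:
        raise ValueError(
            "capsule_pouch: pouch bore (lumen + ventral wall) touches the capsule "
            f"wall; need lumen {r_l} + 2*{t_v} + 1 < outer_radius {R}"
        )
    ti = int(round(t))
    if zD + ti > z1 - ti:
        raise ValueError(
            "capsule_pouch: pouch depth leaves no room for its end cap before the "
            f"posterior disc (depth {DP} of length {CL})"
        )
    if DP < ti + 2:
        raise ValueError(f"capsule_pouch: pouch depth {DP} shallower than the wall {ti}")

    z, y, x = _grids(spec.grid_shape)
    rho = np.sqrt((y - yc) ** 2 + (x - xc) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_psi = np.where(rho > 0, -(y - yc) / np.maximum(rho, 1e-12), 0.0)
    psi = np.degrees(np.arccos(np.clip(cos_psi, -1.0, 1.0)))

    # angular thickness profile of the bore wall
    tau = np.where(
        psi <= 60.0, t_v, np.where(psi >= 120.0, t, t_v + (psi - 60.0) / 60.0 * (t - t_v))
    )

    mask = np.zeros(spec.grid_shape, dtype=bool)
    thickness = np.zeros(spec.grid_shape, dtype=np.float64)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    in_z = (z >= z0) & (z <= z1)
    side = in_z & (rho <= R) & (rho > R - t)
    disc_a = (z >= z0) & (z <= z0 + ti - 1) & (rho <= R) & (rho > r_l)
    disc_p = (z >= z1 - ti + 1) & (z <= z1) & (rho <= R)
    shell = side | disc_a | disc_p
    mask |= shell
    thickness[shell] = t
    labels[shell] = 4

    # brood canal: ventral strip of the tube wall, thickness decaying in z
    zb0, zb1 = z0 + ti, z1 - ti
    with np.errstate(invalid="ignore"):
        tau_bc = t_v + (z - zb0) / max(zb1 - zb0, 1) * (t - t_v)
    strip = (
        (z >= zb0) & (z <= zb1) & (psi <= 30.0) & (rho <= R) & (rho > R - tau_bc)
    )
    mask |= strip
    thickness[strip] = tau_bc[strip]
    labels[strip] = 3

    # pouch bore wall + end cap; anterior-disc portion keeps its shell label
    wall = (z >= z0) & (z <= zD - 1) & (rho > r_l) & (rho <= r_l + tau)
    cap = (z >= zD) & (z <= zD + ti - 1) & (rho <= r_l + tau)
    new_wall = wall & ~mask
    new_cap = cap & ~mask
    mask |= wall | cap
    thickness[new_wall] = tau[new_wall]
    thickness[new_cap] = t
    lab_wall = np.where(psi <= 60.0, 1, np.where(psi >= 120.0, 2, 5)).astype(np.int16)
    labels[new_wall] = lab_wall[new_wall]
    labels[new_cap] = 4

    return mask, thickness, labels, float(DP), float(CL)


_BUILDERS = {
    "slab": _build_slab,
    "spherical_shell": _build_shell,
    "solid_cube": _build_cube,
    "capsule_pouch": _build_capsule,
}


def make_phantom(spec: PhantomSpec) -> tuple[GrayscaleVolume, SegmentationMask, GroundTruth]:
    """Build (grayscale volume, mask, ground truth) for a phantom spec.

    The mask is purely geometric; the grayscale volume is fg_gray/bg_gray
    plus independent Gaussian noise drawn from ``spec.seed``, so identical
    specs are bit-identical and noise never moves the mask.
    """
    mask, thickness, labels, dp, cl = _BUILDERS[spec.kind](spec)
    gray = np.where(mask, float(spec.fg_gray), float(spec.bg_gray))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        gray = gray + rng.normal(0.0, spec.noise_sd, size=mask.shape)
    spacing = (spec.spacing,) * 3
    volume = GrayscaleVolume(data=gray, spacing=spacing)
    seg = SegmentationMask(data=mask, spacing=spacing)
    truth = GroundTruth(
        true_thickness=thickness,
        region_labels=RegionLabelMap(data=labels, legend=dict(REGION_LEGEND)),
        true_DP=dp,
        true_CL=cl,
    )
    return volume, seg, truth


# ---------------------------------------------------------------------------
# Morphometric cohorts
# ---------------------------------------------------------------------------


@dataclass
class MorphometricCohortSpec:
    """Species cohort with target correlation of pouch depth (DP) with penis
    length (PL) and acumen length (LA).  corr(PL, LA) is taken as rho**2,
    the value induced by the latent model PL, LA = rho*DP + independent
    noise, which keeps the correlation matrix positive semi-definite for
    every rho in [-1, 1]."""

    n: int
    mean_DP: float = 200.0
    mean_PL: float = 210.0
    mean_LA: float = 60.0
    sd_DP: float = 40.0
    sd_PL: float = 40.0
    sd_LA: float = 12.0
    rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.n = int(self.n)
        if self.n < 3:
            raise ValueError("cohort needs n >= 3")
        for name in ("mean_DP", "mean_PL", "mean_LA", "sd_DP", "sd_PL", "sd_LA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")

    def correlation_matrix(self) -> np.ndarray:
        r = self.rho
        return np.array([[1.0, r, r], [r, 1.0, r * r], [r, r * r, 1.0]])

    def covariance(self) -> np.ndarray:
        sd = np.array([self.sd_DP, self.sd_PL, self.sd_LA])
        cov = self.correlation_matrix() * np.outer(sd, sd)
        if np.linalg.eigvalsh(cov).min() < -1e-9 * sd.max() ** 2:
            raise ValueError("infeasible correlation matrix (not positive semi-definite)")
        return cov


# Pouch depth across the well-developed Stylopidae runs ~20% of
# cephalothorax length, so cohorts fix CL at 5x DP.
_CL_OVER_DP = 5.0


def make_cohort(spec: MorphometricCohortSpec) -> list[MorphometricRecord]:
    """Draw a seeded cohort of species trait records.

    Rows violating positivity or LA <= PL are redrawn (rejection sampling);
    with the default means such rejections are rare, so the target
    correlations are essentially untouched.
    """
    mean = np.array([spec.mean_DP, spec.mean_PL, spec.mean_LA])
    cov = spec.covariance()
    rng = np.random.default_rng(spec.seed)

    rows = np.empty((0, 3))
    while rows.shape[0] < spec.n:
        draw = rng.multivariate_normal(
            mean, cov, size=spec.n - rows.shape[0], check_valid="ignore", method="svd"
        )
        ok = (draw > 0).all(axis=1) & (draw[:, 2] <= draw[:, 1])
        rows = np.vstack([rows, draw[ok]])
    rows = rows[: spec.n]

    records = []
    for i, (dp, pl, la) in enumerate(rows):
        records.append(
            MorphometricRecord(
                id=f"sp{i:03d}", DP=float(dp), CL=float(dp) * _CL_OVER_DP,
                PL=float(pl), LA=float(la),
            )
        )
    return records
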