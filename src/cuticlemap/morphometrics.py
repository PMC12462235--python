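"""Scalar morphometrics and trait covariation.

Descriptors computed here mirror the comparative analysis of the female
paragenital organ: pouch depth expressed as a percentage of cephalothorax
length, mean encoded cuticle thickness per anatomical region (ventral vs
dorsal pouch wall, penetration site vs control cuticle), and correlation of
pouch depth (DP) with penis length (PL) and acumen length (LA) across
species — the lock-and-key covariation expected under traumatic
insemination.  PL/DP is reported as a scalar fit index, with 1.0 encoding a
geometrically perfect fit.

Thickness inputs are the relative encoded counts produced by
:mod:`cuticlemap.voxel_thickness` or :mod:`cuticlemap.mesh_thickness`;
ratios of regional means are therefore relative contrasts, not micrometre
ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume_io import RegionLabelMap, SegmentationMask, ThicknessField

logger = logging.getLogger(__name__)

__all__ = [
    "MorphometricRecord",
    "CorrelationResult",
    "RegionContrast",
    "pouch_depth_percent",
    "region_contrast",
    "mesh_region_contrast",
    "correlate",
    "fit_ratio",
    "records_to_frame",
    "frame_to_records",
]


@dataclass
class MorphometricRecord:
    """One species: pouch depth DP, cephalothorax length CL, penis length
    PL and acumen length LA (consistent units, µm or voxels)."""

    id: str
    DP: float
    CL: float
    PL: float
    LA: float

    def __post_init__(self) -> None:
        for name in ("DP", "CL", "PL", "LA"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{self.id}: {name} must be positive and finite, got {v}")
        if self.DP > self.CL:
            raise ValueError(f"{self.id}: DP ({self.DP}) exceeds CL ({self.CL})")
        if self.LA > self.PL:
            raise ValueError(f"{self.id}: LA ({self.LA}) exceeds PL ({self.PL})")


@dataclass
class CorrelationResult:
    method: str
    r: float
    n: int
    ci95: tuple[float, float]
    p: float

    def __post_init__(self) -> None:
        if not (self.ci95[0] - 1e-12 <= self.r <= self.ci95[1] + 1e-12):
            raise ValueError("ci95 must contain r")


@dataclass
class RegionContrast:
    mean_by_region: Mapping[int, float]
    ratio_ventral_dorsal: float
    ratio_site_control: float
    legend: Mapping[int, str] = field(default_factory=dict)


def pouch_depth_percent(DP: float, CL: float) -> float:
    """Pouch depth as a percentage of cephalothorax length (100 * DP / CL)."""
    if CL <= 0:
        raise ValueError(f"CL must be positive, got {CL}")
    if DP < 0 or DP > CL:
        raise ValueError(f"require 0 <= DP <= CL, got DP={DP}, CL={CL}")
    return 100.0 * DP / CL


def region_contrast(field_: ThicknessField, labels: RegionLabelMap) -> RegionContrast:
    """Mean encoded thickness per labelled region plus the two headline
    ratios: ventral/dorsal pouch wall and penetration-site/control.

    The penetration site is the pouch wall pair (labels 1 and 2, pooled by
    voxel count); control is label 4.  Regions without any voxels are
    excluded with a warning.
    """
    if field_.data.shape != labels.data.shape:
        raise ValueError("thickness field and label map shapes differ")
    lab = labels.data
    present = [int(l) for l in np.unique(lab) if l != 0]
    if not present:
        raise ValueError("label map contains no labelled foreground")
    means: dict[int, float] = {}
    counts: dict[int, int] = {}
    for l in present:
        sel = lab == l
        n = int(sel.sum())
        if n == 0:  # pragma: no cover - unique() precludes this
            continue
        means[l] = float(field_.data[sel].mean())
        counts[l] = n
    for l, name in labels.legend.items():
        if l != 0 and l not in means:
            logger.warning("region %d (%s) has no voxels; excluded", l, name)
    return _assemble_contrast(means, counts, labels.legend)


def _assemble_contrast(means, counts, legend) -> RegionContrast:
    def pooled(labels_):
        ls = [l for l in labels_ if l in means]
        if not ls:
            return math.nan
        return float(np.average([means[l] for l in ls], weights=[counts[l] for l in ls]))

    vd = means[1] / means[2] if 1 in means and 2 in means else math.nan
    site, control = pooled([1, 2]), pooled([4])
    sc = site / control if control and not math.isnan(control) and not math.isnan(site) else math.nan
    return RegionContrast(
        mean_by_region=means,
        ratio_ventral_dorsal=float(vd),
        ratio_site_control=float(sc),
        legend=dict(legend),
    )


def mesh_region_contrast(mesh, labels: RegionLabelMap, mask: SegmentationMask) -> RegionContrast:
    """Regional contrast of per-vertex mesh thickness.

    Each vertex is assigned the label of its nearest foreground voxel
    (Euclidean distance transform on the mask), then per-region means are
    taken over vertices.
    """
    if mesh.scalars is None:
        raise ValueError("mesh carries no thickness scalars; run vertex_thickness first")
    fg = mask.data
    if not fg.any():
        raise ValueError("mask has no foreground")
    # indices of the nearest foreground voxel for every grid position
    _, idx = ndimage.distance_transform_edt(~fg, return_indices=True)
    vi = np.clip(np.rint(mesh.vertices).astype(int), 0, np.array(fg.shape) - 1)
    nearest = tuple(idx[k][vi[:, 0], vi[:, 1], vi[:, 2]] for k in range(3))
    vlab = labels.data[nearest]
    present = [int(l) for l in np.unique(vlab) if l != 0]
    if not present:
        raise ValueError("no vertex maps to a labelled voxel")
    means = {l: float(mesh.scalars[vlab == l].mean()) for l in present}
    counts = {l: int((vlab == l).sum()) for l in present}
    return _assemble_contrast(means, counts, labels.legend)


def correlate(
    records: Sequence[MorphometricRecord],
    x: str,
    y: str,
    method: str = "pearson",
    n_boot: int = 2000,
    seed: int = 0,
) -> CorrelationResult:
    """Correlation of two trait fields across a cohort.

    Pearson (primary) carries a Fisher-z 95% CI; Spearman's CI comes from a
    seeded bootstrap over species.  Cohorts here are typically small
    (n <= 8 species in comparative work), so intervals are wide and should
    be read as underpowered.
    """
    xs = np.array([getattr(r, x) for r in records], dtype=float)
    ys = np.array([getattr(r, y) for r in records], dtype=float)
    n = len(xs)
    if n < 3:
        raise ValueError("need at least 3 records")
    if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
        raise ValueError("non-finite trait values")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError(f"zero variance in {x if np.ptp(xs) == 0 else y}")

    if method == "pearson":
        r, p = stats.pearsonr(xs, ys)
        r = float(r)
        if n > 3 and abs(r) < 1.0:
            zr = math.atanh(r)
            half = 1.959963984540054 / math.sqrt(n - 3)
            ci = (math.tanh(zr - half), math.tanh(zr + half))
        else:
            # Fisher z is undefined at |r| = 1 or n = 3; report the widest
            # honest interval that still contains the estimate.
            ci = (min(r, -1.0), max(r, 1.0))
    elif method == "spearman":
        r, p = stats.spearmanr(xs, ys)
        r = float(r)
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            i = rng.integers(0, n, size=n)
            if np.ptp(xs[i]) == 0 or np.ptp(ys[i]) == 0:
                continue
            boots.append(stats.spearmanr(xs[i], ys[i]).statistic)
        lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (r, r)
        ci = (float(min(lo, r)), float(max(hi, r)))
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(method=method, r=r, n=n, ci95=ci, p=float(p))


def fit_ratio(PL: float, DP: float) -> float:
    """Penis-length to pouch-depth ratio; 1.0 encodes a perfect mechanical
    fit of the male intromittent organ into the female pouch."""
    if DP <= 0:
        raise ValueError(f"DP must be positive, got {DP}")
    return float(PL) / float(DP)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------


def records_to_frame(records: Iterable[MorphometricRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": r.id, "DP": r.DP, "CL": r.CL, "PL": r.PL, "LA": r.LA} for r in records]
    )


def frame_to_records(frame: pd.DataFrame) -> list[MorphometricRecord]:
    required = {"id", "DP", "CL", "PL", "LA"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"morphometric table missing columns {sorted(missing)}")
    return [
        MorphometricRecord(
            id=str(row.id), DP=float(row.DP), CL=float(row.CL),
            PL=float(row.PL), LA=float(row.LA),
        )
        for row in frame.itertuples(index=False)
    ]
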