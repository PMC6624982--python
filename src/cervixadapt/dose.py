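"""Idealized conformal dose engine.

Replaces VMAT optimization with a fixed monotone function of the signed
Euclidean distance d(x) to the PTV surface (negative inside):

    dose(x) = Rx * h * Phi((s - d(x)) / sigma)

where Phi is the standard normal CDF, h the hotspot cap, sigma the penumbra
fall-off scale and s the shoulder.  The normalization pins the 95% isodose
exactly s mm outside the PTV surface, so target conformity is controlled by
the shoulder alone and the dose is pointwise monotone in the PTV
(nested PTVs give pointwise nested dose distributions).  One global
parameter set is used per experiment, so between-strategy OAR differences
arise solely from target-volume differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .grid import Mask, VoxelGrid

__all__ = ["Prescription", "DoseGrid", "PenumbraParams", "PlanningError",
           "plan_dose", "calibrate_penumbra"]


class PlanningError(RuntimeError):
    """The dose model cannot satisfy the planning goals on the given input."""


@dataclass(frozen=True)
class Prescription:
    """Course prescription: 45 Gy in 25 fractions, 95% reference dose."""

    total_dose: float = 45.0
    n_fractions: int = 25
    reference_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.total_dose <= 0:
            raise ValueError("total_dose must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def reference_dose(self) -> float:
        """The reference (conformity) dose level in Gy: 95% of prescription."""
        return self.reference_fraction * self.total_dose

    @property
    def fraction_dose(self) -> float:
        return self.total_dose / self.n_fractions


@dataclass(frozen=True)
class PenumbraParams:
    """Fall-off scale (mm), 95%-isodose shoulder (mm) and hotspot cap."""

    sigma: float = 6.0
    shoulder: float = 3.0
    max_hotspot: float = 1.04

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.max_hotspot < 1.0:
            raise ValueError("max_hotspot must be >= 1")


@dataclass
class DoseGrid:
    """Full-course absorbed dose (Gy) on a voxel grid."""

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != self.grid.shape:
            raise ValueError("dose shape does not match grid")
        if not np.all(np.isfinite(self.data)) or float(self.data.min()) < 0:
            raise ValueError("dose must be finite and non-negative")

    def fraction_dose(self, rx: Prescription) -> "DoseGrid":
        return DoseGrid(self.grid, self.data / rx.n_fractions)


def signed_distance_mm(ptv: Mask, pad_mm: float) -> tuple[np.ndarray, tuple]:
    """Signed distance to the PTV surface on a padded bounding subgrid.

    Negative inside.  Returns (distance array, bounding slices).
    """
    g = ptv.grid
    pad_vox = int(np.ceil(pad_mm / min(g.spacing))) + 1
    sl = ptv.bounding_slices(pad_voxels=pad_vox)
    sub = ptv.data[sl]
    outside = ndimage.distance_transform_edt(~sub, sampling=g.spacing)
    inside = ndimage.distance_transform_edt(sub, sampling=g.spacing)
    return (outside - inside).astype(np.float32), sl


def _falloff_fraction(d_mm: np.ndarray, pen: PenumbraParams) -> np.ndarray:
    """Dose as fraction of prescription vs signed distance to PTV surface.

    Normalized so the curve crosses exactly 95% at d = shoulder.
    """
    z95 = norm.ppf(0.95 / pen.max_hotspot)
    return pen.max_hotspot * norm.cdf(z95 + (pen.shoulder - d_mm) / pen.sigma)


def plan_dose(ptv: Mask, rx: Prescription, pen: PenumbraParams,
              check_goals: bool = True) -> DoseGrid:
    """Course dose for one PTV under the conformal fall-off model.

    Planning goals (checked unless disabled): PTV D98% >= 95% of the
    prescription and PTV V95% > 98%.
    """
    if ptv.is_empty():
        raise ValueError("PTV is empty")
    pad = pen.shoulder + 6.0 * pen.sigma
    dist, sl = signed_distance_mm(ptv, pad)
    dose = np.zeros(ptv.grid.shape, dtype=np.float32)
    dose[sl] = rx.total_dose * _falloff_fraction(dist, pen)
    out = DoseGrid(ptv.grid, dose)
    if check_goals:
        ptv_dose = dose[ptv.data]
        d98 = float(np.quantile(ptv_dose, 0.02))
        v95 = float(np.mean(ptv_dose >= rx.reference_dose))
        if d98 < 0.95 * rx.total_dose or not v95 > 0.98:
            raise PlanningError(
                f"planning goals not met: D98={d98 / rx.total_dose:.1%}, "
                f"V95={v95:.1%} (sigma={pen.sigma}, shoulder={pen.shoulder})"
            )
    return out


def calibrate_penumbra(
    ptvs,
    rx: Prescription,
    ci_target_range: tuple[float, float] = (1.05, 1.30),
    sigma: float = 6.0,
    max_hotspot: float = 1.04,
) -> PenumbraParams:
    """Choose the shoulder so the mean conformity index hits the target range.

    With the 95% crossing pinned at the shoulder the reference-dose region is
    exactly the PTV expanded by s mm, so CI(s) per PTV is the cumulative
    distribution of the outside distances; the mean CI over the
    representative PTVs is inverted for the range midpoint.  Deterministic
    and idempotent.
    """
    ptvs = list(ptvs)
    if not ptvs:
        raise ValueError("need at least one representative PTV")
    lo, hi = ci_target_range
    if not (1.0 <= lo < hi):
        raise PlanningError(f"infeasible CI range {ci_target_range}")
    s_grid = np.arange(0.0, 25.0 + 1e-9, 0.05)
    ci_curves = []
    for ptv in ptvs:
        dist, _ = signed_distance_mm(ptv, pad_mm=30.0)
        n_target = int(ptv.voxel_count())
        outside = np.sort(dist[dist > 0])
        # CI(s) = (|PTV| + #outside voxels within s) / |PTV|; target fully covered
        counts = np.searchsorted(outside, s_grid, side="right")
        ci_curves.append((n_target + counts) / n_target)
    mean_ci = np.mean(ci_curves, axis=0)
    target = 0.5 * (lo + hi)
    # CI is quantized by the voxel grid: take the closest achievable value
    # (ties toward the smaller shoulder)
    idx = int(np.argmin(np.abs(mean_ci - target)))
    shoulder = float(s_grid[idx])
    achieved = float(mean_ci[idx])
    if not (lo <= achieved <= hi):
        raise PlanningError(
            f"calibration infeasible: best mean CI {achieved:.3f} outside {ci_target_range}"
        )
    return PenumbraParams(sigma=sigma, shoulder=shoulder, max_hotspot=max_hotspot)
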