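"""Dose-volume histograms, dose metrics, conformity and constraint reports.

Conventions: D_p% is the greatest dose received by at least p% of the
structure volume, read off the cumulative DVH with linear interpolation
between bins (default bin width 0.05 Gy); percent-of-prescription metrics
use the full-course prescription as denominator; the bowel constraints use
the strict "<" convention (a mean exactly at the limit counts as a
violation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .dose import DoseGrid, Prescription
from .grid import Mask

__all__ = [
    "DVHRecord",
    "ConstraintSpec",
    "compute_dvh",
    "metric",
    "conformity_index",
    "reference_volume_cm3",
    "reference_volume_average",
    "constraint_report",
    "coverage_table",
]

DEFAULT_BIN_WIDTH_GY = 0.05


@dataclass
class DVHRecord:
    """Cumulative DVH of one structure: volume fraction >= dose per bin edge."""

    structure: str
    edges_gy: np.ndarray  # (n+1,) bin edges, starting at 0
    cum_fraction: np.ndarray  # (n+1,) fraction of volume with dose >= edge
    total_cm3: float

    def __post_init__(self) -> None:
        self.edges_gy = np.asarray(self.edges_gy, dtype=float)
        self.cum_fraction = np.asarray(self.cum_fraction, dtype=float)
        if np.any(np.diff(self.cum_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")

    def cum_cm3(self) -> np.ndarray:
        return self.cum_fraction * self.total_cm3

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.edges_gy,
                             "volume_cm3": self.cum_cm3(),
                             "volume_fraction": self.cum_fraction})


def compute_dvh(dose: DoseGrid, mask: Mask, bin_width: float = DEFAULT_BIN_WIDTH_GY,
                structure: str = "") -> DVHRecord:
    """Cumulative DVH over the structure voxels, exact at bin resolution."""
    if dose.grid != mask.grid:
        raise ValueError("dose and mask are on different grids")
    if mask.is_empty():
        raise ValueError(f"empty structure {structure or '<unnamed>'}")
    vals = dose.data[mask.data].astype(float)
    dmax = float(vals.max())
    n_bins = int(np.ceil((dmax + bin_width) / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(vals, bins=edges)
    # fraction of voxels with dose >= edge[i]; doses within a bin count as >=
    # its lower edge
    cum = np.concatenate([[len(vals)], len(vals) - np.cumsum(hist)]) / len(vals)
    return DVHRecord(
        structure=structure,
        edges_gy=edges,
        cum_fraction=cum,
        total_cm3=mask.volume_cm3(),
    )


def _d_at_volume_fraction(dvh: DVHRecord, frac: float) -> float:
    """Inverse cumulative DVH with linear interpolation between bin edges."""
    cum = dvh.cum_fraction
    edges = dvh.edges_gy
    if frac >= cum[0]:
        return float(edges[0])
    idx = int(np.searchsorted(-cum, -frac, side="right")) - 1
    idx = min(idx, len(cum) - 2)
    c0, c1 = cum[idx], cum[idx + 1]
    if c0 == c1:
        return float(edges[idx + 1])
    t = (c0 - frac) / (c0 - c1)
    return float(edges[idx] + t * (edges[idx + 1] - edges[idx]))


def metric(dvh: DVHRecord, which: str, rx: Optional[Prescription] = None,
           units: Optional[str] = None) -> float:
    """Evaluate a named DVH metric.

    ``which``: "D98%", "D0.1%", "Dmean" or "V40Gy" (any percent / dose level).
    ``units`` for D metrics: "Gy" (default) or "%" (percent of prescription,
    requires ``rx``); for V metrics: "%" (default) or "cm3".
    """
    w = which.strip()
    if w.lower() == "dmean":
        mids = 0.5 * (dvh.edges_gy[:-1] + dvh.edges_gy[1:])
        dv = dvh.cum_fraction[:-1] - dvh.cum_fraction[1:]
        val = float((mids * dv).sum())
        if units == "%":
            if rx is None:
                raise ValueError("percent units require a prescription")
            return 100.0 * val / rx.total_dose
        return val
    if w.startswith(("D", "d")) and w.endswith("%"):
        p = float(w[1:-1])
        if not 0 < p <= 100:
            raise ValueError(f"volume percentage out of range in {which!r}")
        val = _d_at_volume_fraction(dvh, p / 100.0)
        if units == "%":
            if rx is None:
                raise ValueError("percent units require a prescription")
            return 100.0 * val / rx.total_dose
        return val
    if w.startswith(("V", "v")) and w.lower().endswith("gy"):
        x = float(w[1:-2])
        if x < 0:
            raise ValueError(f"dose level out of range in {which!r}")
        frac = float(np.interp(x, dvh.edges_gy, dvh.cum_fraction))
        if units == "cm3":
            return frac * dvh.total_cm3
        return 100.0 * frac
    raise ValueError(f"unknown metric {which!r}")


def reference_volume_cm3(dose: DoseGrid, rx: Prescription) -> float:
    """Volume (cm^3) receiving at least the reference dose (95% of Rx)."""
    n = int((dose.data >= rx.reference_dose).sum())
    return n * dose.grid.voxel_volume_mm3 / 1000.0


def conformity_index(dose: DoseGrid, target: Mask, rx: Prescription) -> float:
    """CI = V(ref dose) / V(target covered by ref dose); >= 1 when the
    reference region covers the whole target.  NaN if no target voxel is
    covered."""
    if target.is_empty():
        raise ValueError("target is empty")
    ref = dose.data >= rx.reference_dose
    if not ref.any():
        raise ValueError("no voxel reaches the reference dose")
    covered = int((ref & target.data).sum())
    if covered == 0:
        return float("nan")
    return float(ref.sum()) / covered


@dataclass(frozen=True)
class ConstraintSpec:
    """Bowel-bag acute-toxicity limits (Fiorino): V40 < 350, V30 < 500 cm^3."""

    v40_limit: float = 350.0
    v30_limit: float = 500.0

    def __post_init__(self) -> None:
        if self.v40_limit <= 0 or self.v30_limit <= 0:
            raise ValueError("constraint limits must be positive")


def reference_volume_average(evals: Iterable, strategy: str) -> float:
    """Patient-level mean reference-dose volume for one strategy.

    Library strategy: selection-count weighted mean over the distinct
    selected plans (algebraically the per-fraction mean); online strategies:
    plain mean over the per-fraction plans.
    """
    rows = [e for e in evals if e.strategy == strategy]
    if not rows:
        raise ValueError(f"no evaluations for strategy {strategy!r}")
    if strategy == "LOP":
        weights: Dict[str, List[float]] = {}
        for e in rows:
            weights.setdefault(str(e.selected_label), []).append(e.reference_volume_cm3)
        num = sum(len(v) * v[0] for v in weights.values())
        den = sum(len(v) for v in weights.values())
        return num / den
    return float(np.mean([e.reference_volume_cm3 for e in rows]))


def constraint_report(evals: Iterable, spec: ConstraintSpec = ConstraintSpec()) -> pd.DataFrame:
    """Per-patient mean bowel-bag V40/V30 (cm^3) with violation flags.

    A mean not strictly below the limit is flagged as a violation.
    """
    rows = list(evals)
    if not rows:
        raise ValueError("no evaluations")
    df = pd.DataFrame(
        {
            "patient": [e.patient_id for e in rows],
            "strategy": [e.strategy for e in rows],
            "v40_cm3": [e.metrics["bowel_bag"]["V40Gy_cm3"] for e in rows],
            "v30_cm3": [e.metrics["bowel_bag"]["V30Gy_cm3"] for e in rows],
        }
    )
    out = df.groupby(["patient", "strategy"], as_index=False).mean()
    out["v40_violated"] = ~(out["v40_cm3"] < spec.v40_limit)
    out["v30_violated"] = ~(out["v30_cm3"] < spec.v30_limit)
    return out


def coverage_table(evals: Iterable, structure: str, threshold_pct: float = 95.0) -> pd.DataFrame:
    """Per patient and strategy: minimum D98% and count of adequate fractions.

    Mirrors the per-patient reporting of minimum D98% (as % of prescription)
    with the number of fractions reaching the threshold out of the total.
    Fractions flagged for an empty structure are excluded from the counts.
    """
    recs = []
    for e in evals:
        m = e.metrics.get(structure)
        if m is None or m.get("flagged"):
            continue
        recs.append((e.patient_id, e.strategy, m["D98_pct"]))
    if not recs:
        raise ValueError(f"no evaluations carry structure {structure!r}")
    df = pd.DataFrame(recs, columns=["patient", "strategy", "d98_pct"])
    out = df.groupby(["patient", "strategy"], as_index=False).agg(
        min_d98_pct=("d98_pct", "min"),
        n_adequate=("d98_pct", lambda v: int((v >= threshold_pct).sum())),
        n_fractions=("d98_pct", "size"),
    )
    return out
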