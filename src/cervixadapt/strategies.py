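"""Treatment strategies: plan library (plan of the day) and online replanning.

Three strategies are compared on the same simulated fractions:

* ``LOP`` — a pretreatment library of plans built from interpolations of the
  low-risk CTV between the full- and empty-bladder states, with an
  anisotropic ITV margin (10 mm AP, 5 mm LR/SI, 0 below the vagina) and a
  5 mm PTV margin; the best fitting member is selected on the pre-delivery
  (t0) anatomy.
* ``MRI_3mm`` / ``MRI_5mm`` — online replanning on the t0 anatomy with an
  isotropic 3 or 5 mm PTV margin on the low-risk CTV and 3 mm on the nodal
  CTV.

All delivered plans are evaluated on the post-interval (t1) anatomy with the
course-dose convention (fraction dose x number of fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import anatomy as _anat
from .anatomy import (AnatomyInstance, FractionPair, PatientTemplate,
                      ground_truth_dvf, render_anatomy)
from .dose import DoseGrid, PenumbraParams, Prescription, plan_dose
from .evaluation import compute_dvh, metric, reference_volume_cm3
from .geometry import MarginSpec, expand, interpolate_structure, min_interpolation_count
from .grid import Mask, VoxelGrid

__all__ = [
    "StrategyConfig",
    "PlanLibrary",
    "LibraryMember",
    "Plan",
    "FractionEvaluation",
    "CohortEntry",
    "lop_config",
    "mri_config",
    "build_lop",
    "select_plan",
    "build_online_plan",
    "run_strategy",
]

STRATEGIES = ("LOP", "MRI_3mm", "MRI_5mm")

# SI level of the top of the vagina: ITV margins vanish inferior to it
VAGINAL_TOP_Z = float(_anat._CERVIX_BASE[2])


def default_itv_spec() -> MarginSpec:
    """10 mm AP / 5 mm LR+SI ITV margin, zero below the vaginal plane."""
    return MarginSpec(left=5.0, right=5.0, anterior=10.0, posterior=10.0,
                      inferior=5.0, superior=5.0,
                      zero_margin_si_plane=VAGINAL_TOP_Z)


@dataclass(frozen=True)
class StrategyConfig:
    strategy: str
    ctv_lr_ptv_margin: float
    ln_ptv_margin: float
    itv_spec: Optional[MarginSpec] = None
    interpolation_max_gap: float = 10.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.ctv_lr_ptv_margin < 0 or self.ln_ptv_margin < 0:
            raise ValueError("margins must be >= 0")


def lop_config() -> StrategyConfig:
    return StrategyConfig("LOP", ctv_lr_ptv_margin=5.0, ln_ptv_margin=5.0,
                          itv_spec=default_itv_spec())


def mri_config(margin_mm: float) -> StrategyConfig:
    name = f"MRI_{margin_mm:g}mm"
    return StrategyConfig(name, ctv_lr_ptv_margin=float(margin_mm), ln_ptv_margin=3.0)


@dataclass
class LibraryMember:
    """One plan of the library, labelled by interpolation percentage
    (0 = empty-bladder anatomy, 100 = full-bladder anatomy)."""

    label_pct: float
    ctv_lr: Mask
    itv: Mask
    encompassing_ctv: Mask
    ptv: Mask
    dose: DoseGrid
    reference_volume_cm3: float
    oar_bookkeeping: Dict[str, Mask] = field(default_factory=dict)

    @property
    def itv_volume_cm3(self) -> float:
        return self.itv.volume_cm3()


@dataclass
class PlanLibrary:
    patient_id: str
    members: List[LibraryMember]
    version: int = 0

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a plan library needs at least the two endpoint members")
        for m in self.members:
            if not m.ptv.contains(m.itv):
                raise ValueError("every member PTV must contain its ITV")


@dataclass
class Plan:
    """A single (online) plan: PTV plus its course dose grid."""

    strategy: str
    ptv: Mask
    dose: DoseGrid
    reference_volume_cm3: float
    oar_bookkeeping: Dict[str, Mask] = field(default_factory=dict)


@dataclass
class FractionEvaluation:
    """DVH metrics of one delivered fraction, computed on the t1 anatomy."""

    patient_id: str
    fraction_index: int
    strategy: str
    selected_label: str
    metrics: Dict[str, Dict[str, float]]
    reference_volume_cm3: float


@dataclass
class CohortEntry:
    """One simulated patient: template, planning fills and fraction pairs."""

    template: PatientTemplate
    pairs: List[FractionPair]
    fill_full: float = 350.0
    fill_empty: float = 30.0
    rebuild_week: Optional[int] = None


def build_lop(
    template: PatientTemplate,
    cfg: StrategyConfig,
    rx: Prescription,
    pen: PenumbraParams,
    grid: Optional[VoxelGrid] = None,
    fill_full: float = 350.0,
    fill_empty: float = 30.0,
    week: int = 0,
    store_oars: bool = True,
) -> PlanLibrary:
    """Construct the library of plans from the two planning anatomies.

    The interpolation count is the least number keeping consecutive
    surface gaps within ``cfg.interpolation_max_gap`` (1 cm).  Each member:
    ITV = anisotropic expansion of its interpolated low-risk CTV, then union
    with the nodal CTV and a 5 mm isotropic PTV expansion, then dose.
    """
    if cfg.strategy != "LOP":
        raise ValueError("build_lop requires a LOP strategy config")
    if grid is None:
        from .grid import default_grid
        grid = default_grid()
    itv_spec = cfg.itv_spec or default_itv_spec()
    empty_inst = render_anatomy(template, fill_empty, week=week, grid=grid)
    ln = empty_inst.mask("CTV_LN_Pelvic")
    rectum = empty_inst.mask("rectum")
    bowel_empty = empty_inst.mask("bowel_bag")
    dvf = ground_truth_dvf(template, fill_full, fill_empty, week=week)
    k = min_interpolation_count(dvf, cfg.interpolation_max_gap)
    alphas = np.linspace(0.0, 1.0, k + 2)
    members: List[LibraryMember] = []
    ptv_margin = MarginSpec.isotropic(cfg.ctv_lr_ptv_margin)
    for alpha in alphas:
        ctv = interpolate_structure(dvf, float(alpha), grid)
        itv = expand(ctv, itv_spec)
        enc = itv.union(ln)
        ptv = expand(enc, ptv_margin)
        dose = plan_dose(ptv, rx, pen)
        oars: Dict[str, Mask] = {}
        if store_oars:
            fill_a = fill_full + alpha * (fill_empty - fill_full)
            inst_a = render_anatomy(template, fill_a, week=week, grid=grid)
            bladder_a = inst_a.mask("bladder")
            oars = {
                "bladder": bladder_a,
                "bowel_bag_opt": bowel_empty.subtract(rectum).subtract(ctv).subtract(bladder_a),
            }
        members.append(
            LibraryMember(
                label_pct=round(100.0 * (1.0 - float(alpha)), 1),
                ctv_lr=ctv,
                itv=itv,
                encompassing_ctv=enc,
                ptv=ptv,
                dose=dose,
                reference_volume_cm3=reference_volume_cm3(dose, rx),
                oar_bookkeeping=oars,
            )
        )
    members.sort(key=lambda m: m.label_pct)
    return PlanLibrary(patient_id=template.patient_id, members=members, version=week)


def select_plan(library: PlanLibrary, daily_ctv_lr: Mask) -> int:
    """Plan-of-the-day selection on the pre-delivery low-risk CTV.

    Returns the index of the smallest-ITV member fully containing the daily
    CTV; if none contains it, the member with the greatest covered fraction.
    Ties break toward the smaller ITV, then the lower interpolation label.
    """
    if daily_ctv_lr.is_empty():
        raise ValueError("daily CTV is empty")
    containing = [i for i, m in enumerate(library.members)
                  if m.itv.contains(daily_ctv_lr)]
    if containing:
        return min(containing, key=lambda i: (library.members[i].itv_volume_cm3,
                                              library.members[i].label_pct))
    n_daily = daily_ctv_lr.voxel_count()
    def coverage(i: int) -> float:
        return library.members[i].itv.intersect(daily_ctv_lr).voxel_count() / n_daily
    return min(range(len(library.members)),
               key=lambda i: (-coverage(i), library.members[i].itv_volume_cm3,
                              library.members[i].label_pct))


def build_online_plan(
    t0: AnatomyInstance,
    cfg: StrategyConfig,
    rx: Prescription,
    pen: PenumbraParams,
) -> Plan:
    """Online replanning on the pre-delivery anatomy.

    PTV = isotropic expansion of the low-risk CTV (3 or 5 mm) union a 3 mm
    expansion of the nodal CTV.
    """
    if cfg.strategy not in ("MRI_3mm", "MRI_5mm"):
        raise ValueError("build_online_plan requires an online strategy config")
    ptv = expand(t0.mask("CTV_T_LR"), MarginSpec.isotropic(cfg.ctv_lr_ptv_margin)).union(
        expand(t0.mask("CTV_LN_Pelvic"), MarginSpec.isotropic(cfg.ln_ptv_margin))
    )
    dose = plan_dose(ptv, rx, pen)
    bowel_opt = t0.mask("bowel_bag").subtract(t0.mask("CTV_T_LR")).subtract(t0.mask("rectum"))
    return Plan(
        strategy=cfg.strategy,
        ptv=ptv,
        dose=dose,
        reference_volume_cm3=reference_volume_cm3(dose, rx),
        oar_bookkeeping={"bowel_bag_opt": bowel_opt},
    )


_TARGET_STRUCTS = ("CTV_T_LR", "CTV_T_HR", "CTV_LN_Pelvic")


def evaluate_fraction(
    dose: DoseGrid,
    t1: AnatomyInstance,
    rx: Prescription,
    strategy: str,
    fraction_index: int,
    selected_label: str,
    reference_volume: float,
) -> FractionEvaluation:
    """Course-scale DVH metrics of a delivered plan on the t1 structures."""
    metrics: Dict[str, Dict[str, float]] = {}
    for name in _TARGET_STRUCTS:
        m = t1.mask(name)
        if m.is_empty():
            metrics[name] = {"flagged": True}
            continue
        dvh = compute_dvh(dose, m, structure=name)
        metrics[name] = {"D98_pct": metric(dvh, "D98%", rx, units="%")}
    for name in ("bladder", "rectum"):
        m = t1.mask(name)
        if m.is_empty():
            metrics[name] = {"flagged": True}
            continue
        dvh = compute_dvh(dose, m, structure=name)
        metrics[name] = {
            "Dmean_gy": metric(dvh, "Dmean"),
            "V40Gy_pct": metric(dvh, "V40Gy"),
        }
    bowel = t1.mask("bowel_bag")
    if bowel.is_empty():
        metrics["bowel_bag"] = {"flagged": True}
    else:
        dvh = compute_dvh(dose, bowel, structure="bowel_bag")
        metrics["bowel_bag"] = {
            "V40Gy_cm3": metric(dvh, "V40Gy", units="cm3"),
            "V30Gy_cm3": metric(dvh, "V30Gy", units="cm3"),
            "V45Gy_cm3": metric(dvh, "V45Gy", units="cm3"),
        }
    return FractionEvaluation(
        patient_id=t1.template.patient_id,
        fraction_index=fraction_index,
        strategy=strategy,
        selected_label=selected_label,
        metrics=metrics,
        reference_volume_cm3=reference_volume,
    )


def run_strategy(
    cohort: Sequence[CohortEntry],
    cfg: StrategyConfig,
    rx: Prescription,
    pen: PenumbraParams,
) -> List[FractionEvaluation]:
    """Run one strategy over a cohort of fraction pairs.

    LOP: select the plan of the day on t0 and evaluate its dose on t1;
    online: build the plan on t0 and evaluate on t1.  Deterministic for a
    given cohort.
    """
    if not cohort:
        raise ValueError("empty cohort")
    out: List[FractionEvaluation] = []
    for entry in cohort:
        grid = entry.pairs[0].t0.grid if entry.pairs else None
        library = None
        if cfg.strategy == "LOP":
            library = build_lop(entry.template, cfg, rx, pen, grid=grid,
                                fill_full=entry.fill_full, fill_empty=entry.fill_empty)
        for fx, pair in enumerate(entry.pairs):
            if cfg.strategy == "LOP":
                if (entry.rebuild_week is not None
                        and pair.t0.week_index >= entry.rebuild_week
                        and library.version < entry.rebuild_week):
                    library = build_lop(entry.template, cfg, rx, pen, grid=grid,
                                        fill_full=entry.fill_full,
                                        fill_empty=entry.fill_empty,
                                        week=entry.rebuild_week)
                idx = select_plan(library, pair.t0.mask("CTV_T_LR"))
                member = library.members[idx]
                out.append(
                    evaluate_fraction(member.dose, pair.t1, rx, cfg.strategy, fx,
                                      selected_label=f"{member.label_pct:g}%",
                                      reference_volume=member.reference_volume_cm3)
                )
            else:
                plan = build_online_plan(pair.t0, cfg, rx, pen)
                out.append(
                    evaluate_fraction(plan.dose, pair.t1, rx, cfg.strategy, fx,
                                      selected_label="online",
                                      reference_volume=plan.reference_volume_cm3)
                )
    return out
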