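"""End-to-end cohort experiment: generate, plan, deliver, evaluate, report.

``run_experiment`` simulates a seeded cohort, runs the three strategies over
every fraction pair and emits the report bundle: the planned-dose table with
Kruskal-Wallis p-values, per-patient coverage tables for the three targets,
reference-dose volumes per strategy, bowel-bag constraint reports, paired
Wilcoxon summaries for the OAR metrics and the V40-benefit regressions.
All outputs are deterministic functions of the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .anatomy import make_patient, sample_fraction_pair
from .dose import PenumbraParams, Prescription, calibrate_penumbra
from .evaluation import (ConstraintSpec, constraint_report, coverage_table,
                         conformity_index, reference_volume_average)
from .grid import VoxelGrid, default_grid
from .stats import kruskal_wallis, regress_v40_benefit, wilcoxon_paired
from .strategies import (CohortEntry, FractionEvaluation, build_lop,
                         build_online_plan, lop_config, mri_config)
from .evaluation import compute_dvh, metric

__all__ = ["ExperimentConfig", "ExperimentResult", "build_cohort", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Cohort, grid, prescription and strategy settings of one experiment.

    Defaults mirror the demonstration cohort shape: 14 patients with 4
    weekly fraction pairs each, a 10-minute selection-to-delivery interval,
    45 Gy in 25 fractions on a 2.5 mm grid.
    """

    n_patients: int = 14
    fractions_per_patient: int = 4
    seed: int = 1
    delta_t_min: float = 10.0
    zero_motion: bool = False
    fill_full: float = 350.0
    fill_empty: float = 30.0
    prescription: Prescription = field(default_factory=Prescription)
    penumbra: Optional[PenumbraParams] = None  # None -> calibrate on patient 1
    ci_target_range: tuple = (1.05, 1.30)
    alpha_level: float = 0.05
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.fractions_per_patient < 1:
            raise ValueError("cohort must contain at least one patient and fraction")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    evaluations: List[FractionEvaluation]
    planned_dose: pd.DataFrame
    planned_dose_tests: pd.DataFrame
    coverage: Dict[str, pd.DataFrame]
    reference_volumes: pd.DataFrame
    bowel_constraints: pd.DataFrame
    oar_wilcoxon: pd.DataFrame
    regressions: pd.DataFrame
    penumbra: PenumbraParams

    def evaluation_frame(self) -> pd.DataFrame:
        """Flat per-fraction metric table (stable column names)."""
        rows = []
        for e in self.evaluations:
            row = {
                "patient": e.patient_id,
                "fraction": e.fraction_index,
                "strategy": e.strategy,
                "selected_plan": e.selected_label,
                "reference_volume_cm3": e.reference_volume_cm3,
            }
            for struct, metrics in e.metrics.items():
                for name, val in metrics.items():
                    row[f"{struct}.{name}"] = val
            rows.append(row)
        return pd.DataFrame(rows)


def _patient_seed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31 - 1))


def build_cohort(cfg: ExperimentConfig, grid: Optional[VoxelGrid] = None) -> List[CohortEntry]:
    """Seeded cohort of patient templates with weekly fraction pairs."""
    g = grid if grid is not None else default_grid()
    cohort = []
    for i in range(cfg.n_patients):
        pseed = _patient_seed(cfg.seed, i)
        overrides = {"patient_id": f"P{i + 1:02d}"}
        if cfg.zero_motion:
            overrides["setup_rotation_sd"] = 0.0
        tpl = make_patient(pseed, overrides=overrides)
        delta_t = 0.0 if cfg.zero_motion else cfg.delta_t_min
        pairs = [
            sample_fraction_pair(tpl, week=w + 1, delta_t=delta_t,
                                 seed=cfg.seed, grid=g)
            for w in range(cfg.fractions_per_patient)
        ]
        cohort.append(CohortEntry(template=tpl, pairs=pairs,
                                  fill_full=cfg.fill_full, fill_empty=cfg.fill_empty))
    return cohort


def _planned_row(patient: str, strategy: str, plan_label: str, dose, ptv, rx) -> dict:
    dvh = compute_dvh(dose, ptv, structure="PTV")
    return {
        "patient": patient,
        "strategy": strategy,
        "plan": plan_label,
        "ptv_d98_pct": metric(dvh, "D98%", rx, units="%"),
        "ptv_d0p1_pct": metric(dvh, "D0.1%", rx, units="%"),
        "ci": conformity_index(dose, ptv, rx),
    }


_OAR_METRICS = [
    ("bladder", "Dmean_gy"), ("bladder", "V40Gy_pct"),
    ("rectum", "Dmean_gy"), ("rectum", "V40Gy_pct"),
    ("bowel_bag", "V40Gy_cm3"), ("bowel_bag", "V30Gy_cm3"),
]


def run_experiment(cfg: ExperimentConfig, grid: Optional[VoxelGrid] = None) -> ExperimentResult:
    """Simulate the cohort and produce the full report bundle."""
    g = grid if grid is not None else default_grid()
    rx = cfg.prescription
    cohort = build_cohort(cfg, grid=g)
    strategy_cfgs = {"LOP": lop_config(), "MRI_3mm": mri_config(3), "MRI_5mm": mri_config(5)}
    pen = cfg.penumbra
    if pen is None:
        first = cohort[0]
        lib0 = build_lop(first.template, strategy_cfgs["LOP"], rx,
                         PenumbraParams(shoulder=0.0), grid=g,
                         fill_full=first.fill_full, fill_empty=first.fill_empty,
                         store_oars=False)
        rep_ptvs = [lib0.members[0].ptv, lib0.members[-1].ptv]
        for scfg in (strategy_cfgs["MRI_3mm"], strategy_cfgs["MRI_5mm"]):
            rep_ptvs.append(build_online_plan(first.pairs[0].t0, scfg, rx,
                                              PenumbraParams(shoulder=0.0)).ptv)
        pen = calibrate_penumbra(rep_ptvs, rx, ci_target_range=cfg.ci_target_range)

    # one pass per patient: build each plan exactly once, use it both for the
    # planned-dose table and for the delivered-fraction evaluations
    from .strategies import evaluate_fraction, select_plan
    evaluations: List[FractionEvaluation] = []
    planned_rows: List[dict] = []
    for entry in cohort:
        pid = entry.template.patient_id
        lib = build_lop(entry.template, strategy_cfgs["LOP"], rx, pen, grid=g,
                        fill_full=entry.fill_full, fill_empty=entry.fill_empty,
                        store_oars=False)
        for m in lib.members:
            planned_rows.append(_planned_row(pid, "LOP", f"{m.label_pct:g}%",
                                             m.dose, m.ptv, rx))
        for fx, pair in enumerate(entry.pairs):
            idx = select_plan(lib, pair.t0.mask("CTV_T_LR"))
            member = lib.members[idx]
            evaluations.append(
                evaluate_fraction(member.dose, pair.t1, rx, "LOP", fx,
                                  selected_label=f"{member.label_pct:g}%",
                                  reference_volume=member.reference_volume_cm3))
            for online in ("MRI_3mm", "MRI_5mm"):
                plan = build_online_plan(pair.t0, strategy_cfgs[online], rx, pen)
                planned_rows.append(_planned_row(pid, online, f"fx{fx}",
                                                 plan.dose, plan.ptv, rx))
                evaluations.append(
                    evaluate_fraction(plan.dose, pair.t1, rx, online, fx,
                                      selected_label="online",
                                      reference_volume=plan.reference_volume_cm3))
    evaluations.sort(key=lambda e: (e.strategy, e.patient_id, e.fraction_index))
    planned = pd.DataFrame(planned_rows)
    kw_rows = []
    for col in ("ptv_d98_pct", "ptv_d0p1_pct", "ci"):
        gs = [planned.loc[planned.strategy == s, col].to_numpy() for s in strategy_cfgs]
        p, h = kruskal_wallis(*gs)
        kw_rows.append({"metric": col, "H": h, "p_value": p,
                        "significant": p < cfg.alpha_level})
    planned_tests = pd.DataFrame(kw_rows)

    coverage = {s: coverage_table(evaluations, s)
                for s in ("CTV_T_LR", "CTV_T_HR", "CTV_LN_Pelvic")}

    ref_rows = []
    for entry in cohort:
        pid = entry.template.patient_id
        p_evals = [e for e in evaluations if e.patient_id == pid]
        for s in strategy_cfgs:
            ref_rows.append({"patient": pid, "strategy": s,
                             "reference_volume_cm3": reference_volume_average(p_evals, s)})
    reference_volumes = pd.DataFrame(ref_rows)

    bowel = constraint_report(evaluations, ConstraintSpec())

    frame = ExperimentResult(cfg, evaluations, planned, planned_tests, coverage,
                             reference_volumes, bowel, pd.DataFrame(),
                             pd.DataFrame(), pen).evaluation_frame()
    wil_rows = []
    for online in ("MRI_3mm", "MRI_5mm"):
        for struct, mname in _OAR_METRICS:
            col = f"{struct}.{mname}"
            lop_v = frame[frame.strategy == "LOP"].sort_values(["patient", "fraction"])[col]
            onl_v = frame[frame.strategy == online].sort_values(["patient", "fraction"])[col]
            diffs = onl_v.to_numpy() - lop_v.to_numpy()
            p, summ = wilcoxon_paired(diffs)
            wil_rows.append({"comparison": f"{online} - LOP", "structure": struct,
                             "metric": mname, "median_difference": summ["median_difference"],
                             "n": summ["n"], "p_value": p,
                             "significant": p < cfg.alpha_level})
    oar_wilcoxon = pd.DataFrame(wil_rows)

    reg_cols = ["comparison", "slope", "intercept", "p_value", "r_squared",
                "n", "orientation"]
    reg_rows = []
    lop_v40 = frame[frame.strategy == "LOP"].sort_values(["patient", "fraction"])[
        "bowel_bag.V40Gy_cm3"].to_numpy()
    if lop_v40.size >= 3:  # the regression needs at least 3 fraction pairs
        for online in ("MRI_3mm", "MRI_5mm"):
            onl_v40 = frame[frame.strategy == online].sort_values(
                ["patient", "fraction"])["bowel_bag.V40Gy_cm3"].to_numpy()
            res = regress_v40_benefit(lop_v40, onl_v40)
            reg_rows.append({"comparison": online, "slope": res.slope,
                             "intercept": res.intercept, "p_value": res.p_value,
                             "r_squared": res.r_squared, "n": res.n,
                             "orientation": res.orientation})
    regressions = pd.DataFrame(reg_rows, columns=reg_cols)

    result = ExperimentResult(
        config=cfg, evaluations=evaluations, planned_dose=planned,
        planned_dose_tests=planned_tests, coverage=coverage,
        reference_volumes=reference_volumes, bowel_constraints=bowel,
        oar_wilcoxon=oar_wilcoxon, regressions=regressions, penumbra=pen,
    )
    if cfg.out_dir is not None:
        _write_outputs(result, Path(cfg.out_dir))
    return result


def _write_outputs(result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.evaluation_frame().to_csv(out / "fraction_evaluations.csv", index=False)
    result.planned_dose.to_csv(out / "planned_dose.csv", index=False)
    result.planned_dose_tests.to_csv(out / "planned_dose_tests.csv", index=False)
    for s, df in result.coverage.items():
        df.to_csv(out / f"coverage_{s}.csv", index=False)
    result.reference_volumes.to_csv(out / "reference_volumes.csv", index=False)
    result.bowel_constraints.to_csv(out / "bowel_constraints.csv", index=False)
    result.oar_wilcoxon.to_csv(out / "oar_wilcoxon.csv", index=False)
    result.regressions.to_csv(out / "regressions.csv", index=False)
    cfg = result.config
    summary = {
        "seed": cfg.seed,
        "n_patients": cfg.n_patients,
        "fractions_per_patient": cfg.fractions_per_patient,
        "delta_t_min": cfg.delta_t_min,
        "zero_motion": cfg.zero_motion,
        "prescription_gy": cfg.prescription.total_dose,
        "n_fractions": cfg.prescription.n_fractions,
        "penumbra": asdict(result.penumbra),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
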