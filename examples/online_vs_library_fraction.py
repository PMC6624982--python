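"""Deliver one simulated fraction under all three strategies.

A fraction pair consists of the pre-delivery anatomy t0 (plan selection /
online replanning) and the post-interval anatomy t1 ten minutes later
(evaluation), mimicking the sagittal/transversal scan pair of a weekly MRI
session.
"""

from cervixadapt import (PenumbraParams, Prescription, build_lop,
                        build_online_plan, lop_config, make_patient,
                        mri_config, sample_fraction_pair, select_plan)
from cervixadapt.strategies import evaluate_fraction

template = make_patient(seed=1)
rx = Prescription()
pen = PenumbraParams(sigma=6.0, shoulder=2.5)

pair = sample_fraction_pair(template, week=1, delta_t=10.0, seed=1)
print(f"bladder fill t0 -> t1: {pair.t0.bladder_fill:.0f} -> "
      f"{pair.t1.bladder_fill:.0f} ml over {pair.delta_t:.0f} min")
print(f"top-of-uterus intrafraction displacement: "
      f"{pair.landmark_displacement:.1f} mm")

library = build_lop(template, lop_config(), rx, pen, grid=pair.t0.grid)
idx = select_plan(library, pair.t0.mask("CTV_T_LR"))
member = library.members[idx]
print(f"\nplan of the day: member {member.label_pct:.0f}% "
      f"(ITV {member.itv_volume_cm3:.0f} cm^3)")

rows = [("LOP", member.dose, member.reference_volume_cm3)]
for margin in (3, 5):
    plan = build_online_plan(pair.t0, mri_config(margin), rx, pen)
    rows.append((plan.strategy, plan.dose, plan.reference_volume_cm3))

print(f"\n{'strategy':>8s} {'LR D98%':>9s} {'HR D98%':>9s} {'LN D98%':>9s} "
      f"{'bowel V40 cm^3':>15s} {'ref vol cm^3':>13s}")
for name, dose, refvol in rows:
    ev = evaluate_fraction(dose, pair.t1, rx, name, 0, "demo", refvol)
    m = ev.metrics
    print(f"{name:>8s} {m['CTV_T_LR']['D98_pct']:9.1f} "
          f"{m['CTV_T_HR']['D98_pct']:9.1f} "
          f"{m['CTV_LN_Pelvic']['D98_pct']:9.1f} "
          f"{m['bowel_bag']['V40Gy_cm3']:15.1f} {refvol:13.0f}")
print("\nD98% is evaluated on the t1 anatomy: a value below 95% means the")
print("10-minute anatomical change moved the target out of the planned dose.")
print("The online strategies buy their lower bowel V40 with tighter margins.")
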