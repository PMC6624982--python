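"""Build a library of plans (plan of the day) for one patient.

Interpolations of the low-risk CTV between the full- and empty-bladder
states are spaced so consecutive surfaces are at most 1 cm apart; each
member gets an anisotropic ITV margin (10 mm AP, 5 mm elsewhere, 0 below
the vagina), the nodal CTV union, a 5 mm PTV margin and an idealized
conformal dose.
"""

from cervixadapt import (PenumbraParams, Prescription, build_lop,
                        ground_truth_dvf, lop_config, make_patient,
                        min_interpolation_count)

template = make_patient(seed=1)
rx = Prescription()          # 45 Gy in 25 fractions
pen = PenumbraParams(sigma=6.0, shoulder=2.5)

dvf = ground_truth_dvf(template, fill_full=350.0, fill_empty=30.0)
print(f"max surface displacement full->empty: {dvf.max_displacement:.1f} mm")
print(f"interpolations needed (1 cm rule):    {min_interpolation_count(dvf)}")

library = build_lop(template, lop_config(), rx, pen)
print(f"\nlibrary of {len(library.members)} plans "
      "(label 0% = empty bladder, 100% = full):")
print(f"{'label':>8s} {'ITV cm^3':>10s} {'PTV cm^3':>10s} {'ref-dose cm^3':>14s}")
for m in library.members:
    print(f"{m.label_pct:7.0f}% {m.itv_volume_cm3:10.1f} "
          f"{m.ptv.volume_cm3():10.1f} {m.reference_volume_cm3:14.1f}")
print("\nThe reference-dose volume (>= 95% of 45 Gy) grows with the ITV: the")
print("library treats an envelope of anatomies, which is what the online")
print("strategies avoid.")
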