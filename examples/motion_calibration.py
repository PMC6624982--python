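"""Check the intrafraction-motion calibration of the synthetic cohort.

Over many simulated patients the 10-minute top-of-uterus displacement
should have a median near 3.1 mm and a 90th percentile near 7.8 mm — the
cervix-uterus motion statistics reported for comparable scan intervals.
"""

import numpy as np

from cervixadapt import make_patient, sample_fraction_pair
from cervixadapt.experiment import _patient_seed

disps = []
for i in range(200):
    template = make_patient(_patient_seed(1, i))
    for week in range(1, 5):
        pair = sample_fraction_pair(template, week=week, delta_t=10.0, seed=1)
        disps.append(pair.landmark_displacement)
disps = np.asarray(disps)

print(f"{len(disps)} fraction pairs (200 patients x 4 weeks, 10 min interval)")
print(f"median displacement: {np.percentile(disps, 50):.2f} mm  (target ~3.1)")
print(f"90th percentile:     {np.percentile(disps, 90):.2f} mm  (target ~7.8)")
print("\nHalf of all fractions move only ~3 mm in 10 minutes, but the upper")
print("tail approaches 8 mm or more — this tail decides whether a 3 mm or a")
print("5 mm online margin is sufficient.")
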