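"""Run the full strategy comparison on a small demonstration cohort.

Generates a seeded cohort, runs the plan library and both online
strategies over every fraction pair, and prints the report bundle:
coverage, reference-dose volumes, bowel constraints and the V40-benefit
regression.  (The full-size 14 x 4 cohort takes a few minutes; this demo
uses 4 x 2.)
"""

from cervixadapt import ExperimentConfig, run_experiment

cfg = ExperimentConfig(n_patients=4, fractions_per_patient=2, seed=1,
                       out_dir="scratch/demo_experiment")
res = run_experiment(cfg)

print("planned-dose quality (means per plan set):")
print(res.planned_dose.groupby("strategy")[["ptv_d98_pct", "ptv_d0p1_pct", "ci"]]
      .mean().round(2).to_string())

print("\nlow-risk CTV coverage per patient (min D98% on the t1 anatomy):")
print(res.coverage["CTV_T_LR"].to_string(index=False))

print("\nreference-dose volume per patient (cm^3):")
print(res.reference_volumes.pivot(index="patient", columns="strategy",
                                  values="reference_volume_cm3")
      .round(0).to_string())

print("\nbowel-bag constraints (V40 < 350, V30 < 500 cm^3, patient means):")
print(res.bowel_constraints.round(1).to_string(index=False))

print("\nbowel V40 benefit regression (difference online - library vs library V40):")
print(res.regressions[["comparison", "slope", "p_value", "r_squared"]]
      .round(3).to_string(index=False))

print("\nCSV tables were written to", cfg.out_dir)
print("A negative slope with p < 0.05 means the online benefit grows with")
print("the library strategy's bowel dose, i.e. replanning helps most exactly")
print("where the bowel is most exposed.")
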