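# cervixadapt

Simulated dosimetric comparison of a **library-of-plans (LOP, "plan of the
day")** strategy against **online replanned** external-beam radiotherapy of
cervical cancer, in the presence of ~10 minutes of intrafraction anatomical
change.

## The problem

Definitive EBRT of cervical cancer (45 Gy in 25 fractions to the
cervix-uterus, parametria, upper vagina and pelvic lymph nodes) must cope
with a target that moves and deforms from day to day, mostly driven by
bladder filling. The state-of-the-art answer is a pretreatment *library of
plans*: interpolated target shapes between an empty- and a full-bladder
planning scan, each wrapped in an internal target volume (ITV) and planned
separately, with the best-fitting plan selected at each fraction. Online
replanning on an MRI-linac promises much tighter margins — but a new plan
takes ~10 minutes to create, during which the anatomy keeps moving, so the
margin must still cover *intrafraction* motion.

The patient imaging behind the original comparison is not public.
`cervixadapt` therefore rebuilds the comparison as a fully synthetic,
seeded simulation: a parametric deformable pelvic anatomy (bent-capsule
cervix-uterus whose fundus is pushed anterior-superiorly by bladder
filling, a volume-matched superellipsoid bladder, rectum, bowel bag and
bony-fixed nodal targets) plus an idealized conformal dose engine in place
of the commercial VMAT optimizer. Within a fraction, the anatomy at plan
selection/creation (t0) and at delivery (t1, 10 minutes later) differ by
continued bladder filling; plans are always evaluated on t1.

Strategies compared, as in clinical practice:

* **LOP** — ITV margin 10 mm AP / 5 mm LR+SI (0 mm below the vagina) on
  each interpolated low-risk CTV, consecutive interpolations ≤ 1 cm apart,
  union with the nodal CTV, 5 mm PTV margin; plan of the day selected on t0.
* **MRI_3mm / MRI_5mm** — online plan on t0 with an isotropic 3 or 5 mm PTV
  margin on the low-risk CTV and 3 mm on the nodal CTV.

Metrics: D98% of the three CTVs (as % of prescription, evaluated on t1),
the conformity index CI = V(95% isodose)/V(target ∩ 95% isodose),
reference-dose volumes, OAR DVH metrics, and the bowel-bag acute-toxicity
constraints V40Gy < 350 cm³ and V30Gy < 500 cm³, with Wilcoxon
signed-rank, Kruskal-Wallis and OLS regression at cohort level.

## Worked example

`python examples/online_vs_library_fraction.py` simulates one fraction:

```
bladder fill t0 -> t1: 144 -> 179 ml over 10 min
top-of-uterus intrafraction displacement: 5.6 mm

plan of the day: member 33% (ITV 332 cm^3)

strategy   LR D98%   HR D98%   LN D98%  bowel V40 cm^3  ref vol cm^3
     LOP     103.6     103.8     103.1           281.8           825
 MRI_3mm      95.1     103.1     103.0           166.6           516
 MRI_5mm     102.6     103.7     103.0           188.1           580
```

In this fraction the uterine fundus moved 5.6 mm during the 10-minute
replanning interval. The low-risk CTV D98% (first column, % of the 45 Gy
prescription) shows the 3 mm online margin scraping the 95% adequacy limit
while the 5 mm margin and the library plan hold comfortably — but the
online plans irradiate 130–160 cm³ less bowel at the 40 Gy level and
~300 cm³ less at the reference dose. That margin-versus-OAR-sparing
trade-off is the package's subject.

Other examples: `build_anatomy.py` (the deformable anatomy),
`plan_library.py` (library construction and the 1 cm interpolation rule),
`motion_calibration.py` (the cohort motion statistics),
`cohort_experiment.py` (the full report bundle on a small cohort; the
default 14-patient × 4-fraction experiment is
`run_experiment(ExperimentConfig())` and takes a few minutes).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from a fresh 200-patient × 4-fraction synthetic cohort at the
given seed, the median (t1) and 90th percentile (t2) of the 10-minute
top-of-uterus displacement in millimetres, and writes them as JSON. These
are the quantities the synthetic motion model is calibrated to reproduce.

## Layout

```
src/cervixadapt/
  grid.py        voxel grids, masks, Boolean ops, volumes, rigid rotation
  geometry.py    margin expansion, deformation fields, contour interpolation
  anatomy.py     synthetic patients, paired-fraction sampling, ground-truth DVF
  dose.py        idealized conformal dose engine and penumbra calibration
  evaluation.py  DVHs, dose metrics, conformity, constraint/coverage reports
  strategies.py  LOP construction and selection, online replanning, runs
  stats.py       Wilcoxon, Kruskal-Wallis, the V40-benefit regression
  experiment.py  cohort generation and the end-to-end report bundle
  io.py          NIfTI mask/dose export-import, JSON landmark sidecar
```

See `docs/methods.md` for the model, its assumptions and its limitations.
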