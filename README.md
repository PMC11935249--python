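# letimpt

Desk-scale comparison of dose-optimized and LET-optimized intensity-
modulated proton therapy (IMPT) plans under two different dose-calculation
engines.

## The problem

Inverse LET optimization ("LET painting") re-optimizes the spot weights of
an IMPT plan so that the dose-averaged linear energy transfer (LET_d) — a
surrogate for elevated biological effectiveness near the Bragg peak — is
pushed into the target. Doing so replaces the flat, target-stopping fields
of conventional robust planning with ramp-like fields that patch distally
inside the target. Those patched distal edges sit exactly where analytical
pencil-beam (PB) dose algorithms are weakest (distal fall-off,
heterogeneity along the path, the nuclear low-dose halo of narrow fields),
so a plan optimized with one engine can look clinically unacceptable when
recalculated with another. This package reproduces that workflow and its
mechanism at desk scale for researchers in radiotherapy physics:

1. a voxelized, mostly water-equivalent prostate-like phantom (ellipsoidal
   CTV, anterior bladder, posterior rectum, lateral femoral-bone-like
   heterogeneities), with the scanning target volume (STV) built by
   anisotropic CTV expansion (12 mm lateral / 6 anterior / 4 posterior /
   5 superior-inferior margins) and a prescription of 78 Gy(RBE) in 39
   fractions at constant RBE 1.1;
2. two physically consistent dose engines sharing one Bragg-Kleeman beam
   model (R = alpha E^p): an analytical PB engine (central-axis
   radiological depth, single-Gaussian lateral with Fermi-Eyges multiple
   scattering) and a stochastic engine that transports individual protons
   with range straggling, Highland angular diffusion and a wide-Gaussian
   nuclear-halo surrogate, scoring dose and dose x LET per voxel;
3. scenario-based *selective* robust optimization of spot weights
   (targets evaluated on their worst of nominal + 8 setup/range scenarios,
   organs at risk on the nominal), followed by LET-incorporated
   re-optimization with hinge-quadratic penalties on the voxelwise ratio
   LET_d(w) = sum_j w_j c_ij / sum_j w_j d_ij;
4. evaluation: exact (unbinned) DVH indices D98/D2/D1cc/Dmean, gEUD
   (mean d^a)^(1/a) with a = -10 (CTV), 11.11 (rectum), 2 (bladder), CTV
   LET_d indices, cross-engine percentage deltas, per-beam mid-STV dose
   profiles, and an exact (2^n enumeration) Wilcoxon signed-rank test for
   cohort comparisons.

## Worked example

```python
from letimpt import WorkflowConfig, run_workflow, report_summary

config = WorkflowConfig(plan_ids=(1,), master_seed=7)  # 2-field, 270/90
bundle = run_workflow(config)                           # ~8 min on 1 CPU
_, report = report_summary(bundle)
print(report)
```

prints (numbers from this exact run):

```
# Plan comparison summary

## Plan 1 (2 beams)
- CTV mean LET_d enhancement: +69.4% (raised)
- Cross-engine D98 deltas: doseopt -2.02%, letopt -5.05% (|letopt| > 2x|doseopt|: yes)
- DoseOpt per-beam profiles flat (max CV 0.050); LETOpt ramp-like (min |rank corr| 1.00)
- MC statistical uncertainty (CTV): doseopt 0.392%, letopt 0.696%
```

Reading it: the LET-optimized plan raises the CTV mean LET_d by ~70% (from
about 2.2 to 3.7 keV/um) while its dose, recalculated with the *other*
engine, degrades more than twice as much in CTV D98 as the conventional
plan's does — conventional dose optimization is robust to the engine swap,
LET optimization is not. The same `run_workflow` call accepts
`plan_ids=(1,2,3,4)` for the 2/4/6/9-beam arrangements, and
`out_dir="..."` to write NRRD dose/LET_d maps, CSV index/delta tables, DVH
and profile figures, and JSON provenance. A command-line entry point wraps
the same pipeline:

```bash
letimpt run --plans 1 --seed 7 --out results/
letimpt phantom-build --out phantom/
letimpt report --bundle results/
```

Cohort-style statistics over seeded phantom variants are available through
`letimpt.generate_cohort` / `letimpt.cohort_statistics`.

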