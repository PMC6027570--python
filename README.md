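# myoasl

Myocardial arterial-spin-labeling (ASL) perfusion quantification for
cardiac MR, with a synthetic FAIR-ASL cohort generator for validation.

ASL-CMR measures myocardial blood flow (MBF) without gadolinium: arterial
blood water is magnetically labeled and the tiny control-minus-label
signal difference is converted to flow.  This package implements the full
regional analysis workflow for FAIR-labeled short-axis scans — the kind
used to study vasodilator response and microvascular obstruction after
acute myocardial infarction (AMI) in large-animal models — for
researchers who need a reproducible, testable reference pipeline.

Each scan is a base image `B`, a noise image, and six control/label pairs
`(C_i, L_i)`.  MBF is recovered with the single-compartment general
kinetic model

    F = (C − L) / (2 · B · T_D · exp(−T_D / T1_blood)),

with post-labeling delay `T_D` equal to two cardiac RR intervals and
`T1_blood = 1650 ms`.  The pipeline provides:

- **Segmentation** — AHA 6-segment partition of the LV myocardium about
  the RV insertion angle, with the fixed infarct (anteroseptal) / remote
  (inferior, inferolateral, anterolateral) region map, and a
  mask-restricted spatial-temporal smoothing filter for display maps.
- **Quantification** — per-segment MBF from the six repeats,
  physiological noise (PN = SD of the repeats), tSNR = MBF/PN with the
  tSNR < 2 exclusion flag, and pixelwise MBF maps.
- **Group statistics** — paired rest/stress t-test with both-condition
  exclusion, myocardial perfusion reserve (MPR = stress/rest), one-way
  ANOVA across post-AMI timepoints with Holm-Šidák-adjusted pairwise
  comparisons against baseline, and regional summaries.
- **Synthetic cohorts** — a forward simulator with known ground truth,
  whose defaults emulate the swine study conditions (41 baseline slices
  with MBF 1.08 ± 0.62 ml/g/min, paired rest/stress at 1.47 ± 0.62,
  three post-AMI cohorts with a low-flow anteroseptal infarct, SNR
  98 ± 31, PN 0.15 ml/g/min).
- **I/O and orchestration** — NIfTI + JSON-sidecar readers/writers, CSV
  results tables, a YAML-configured end-to-end study driver, and a thin
  `myoasl` CLI (`simulate`, `segment`, `quantify`, `stats`, `report`,
  `run-study`).

See `docs/methods.md` for the model, noise calibration and design
decisions, and `examples/` for narrative scripts.

## Worked example

`examples/02_rest_stress_reserve.py` simulates the paired rest/stress
cohort, quantifies every scan, drops segment pairs excluded at either
condition, and tests the vasodilator response:

```
kept 134 segment pairs, dropped 16 (tSNR < 2 at rest or stress)
rest   MBF 1.23 +/- 0.49 ml/g/min
stress MBF 1.63 +/- 0.60 ml/g/min
paired t = 9.4, p = 2.4e-16
MPR 1.46 +/- 0.76 (33% MBF increase)
```

Stress raises regional flow by roughly half over rest (MPR ≈ 1.5), and
the paired t-test rejects no-response decisively.
`examples/03_post_infarct_cross_sectional.py` shows the post-AMI pattern:
significantly reduced resting MBF in the infarcted region at every
timepoint (adjusted p < 0.05) and no systematic change in the remote
region.

The same study runs from the shell:

```sh
myoasl run-study --seed 7 --out study_out/
```

writing `results.csv`, `truth.csv`, `stats.json`, `report.md` and plots
(MBF maps on a shared color scale, rest/stress box plot, regional bars).

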