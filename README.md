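# rmdv

Differentiating hemorrhagic transformation (HT) from contrast extravasation
on non-contrast head CT (NCCT) taken immediately after mechanical
thrombectomy is hard: fresh blood and leaked iodinated contrast look alike.
The maximum-density-ratio approach resolves the ambiguity with an internal
reference — the contrast-opacified venous sinuses. This package implements
that method end to end, together with a synthetic cohort and CT phantom
generator so the whole diagnostic evaluation is reproducible without any
patient data.

For a post-interventional cerebral hyperdensity (PCHD), the statistic is

```
RMDV = max HU of the PCHDs / max HU of the venous sinuses
```

measured on the immediate post-procedure scan. Opacified venous blood is
the densest pure-contrast compartment, so a lesion denser than the sinus
maximum (RMDV > 1) must contain blood products and is read as HT; RMDV ≤ 1
is read as contrast extravasation (CE). Ground truth is adjudicated from
the 24 h follow-up scan: contrast washes out within a day, so an
eliminated hyperdensity is CE and a persistent one is HT.

The package covers, as separate modules:

- `rmdv.cohort` — seeded synthetic study population: screening/exclusion
  flow, PCHD and HT prevalences, per-group covariates drawn from published
  marginal summaries;
- `rmdv.phantom` — paired immediate/follow-up axial phantom slices
  (elliptical skull, mirror-symmetric parenchyma, posterior venous-sinus
  band, disc lesion with radial HU falloff, optional noise and artifacts);
- `rmdv.densitometry` — the measurement procedure: PCHD detection by the
  ≥ 5 HU contralateral-excess rule, maximal circular/elliptical ROI
  placement confined to the highest-density area, sinus maximum with
  skull/artifact exclusion;
- `rmdv.core` — the RMDV ratio, the > 1 decision rule, and follow-up
  adjudication;
- `rmdv.diagnostics` / `rmdv.tableone` — Se/Sp/PPV/NPV, Youden index,
  single-threshold ROC AUC with a Hanley–McNeil CI, uncorrected Pearson
  χ², Welch t, Mann–Whitney U, and the full baseline comparison table;
- `rmdv.pipeline` / `rmdv.cli` — orchestration with seeding, YAML config,
  and machine-readable outputs.

## Worked example

A noise-free phantom with a planted lesion peak of 115 HU and sinus peak
of 75 HU (the canonical basal-ganglia example):

```python
from rmdv import PatientRecord, PhantomSpec, render_case, measure_case, adjudicate_followup

rec = PatientRecord("EX", enrolled=True, has_pchd=True,
                    true_outcome="HT", rmdv_positive=True)
case = render_case(rec, PhantomSpec(lesion_peak_hu=115, noise_sd=0), seed=1)
measurement, region = measure_case(case)
print(measurement.lesion_max_hu, measurement.sinus_max_hu,
      round(measurement.rmdv, 3), measurement.predicted)
print(adjudicate_followup(case, region).outcome)
```

prints

```
115.0 75.0 1.533 HT
HT
```

The measured lesion maximum (115 HU) and sinus maximum (75 HU) recover the
planted peaks exactly; their ratio 1.533 exceeds 1, so the case is
predicted HT, and the persistent hyperdensity on the follow-up slice
confirms it.

A full study-sized run from the shell:

```sh
rmdv run --seed 1 --out out/study
```

writes `out/study/report.json` containing, among others, sensitivity
0.8966, specificity 0.7556, PPV 0.8254, NPV 0.8500, Youden 0.652, AUC
0.826 and χ² 45.364 for the RMDV > 1 test on a 103-case PCHD cohort
(table a=52, b=6, c=11, d=34), plus the cohort CSV, per-case measurement
and classification CSVs, the baseline comparison table, and the ROC
points. `rmdv simulate` / `measure` / `classify` / `evaluate` run the
stages separately; `rmdv evaluate` also accepts user-supplied HU
measurements.

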