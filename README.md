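# octbias

Cross-sectional morphometry of intravascular OCT pullbacks for quantifying
imaging-catheter (guidewire) bias, coregistering pre/post-procedure pullbacks,
and testing how well the bias indices discriminate procedure-related intimal
dissection.

The package consumes segmented contours (intima, optional media/EEM) plus a
catheter pose per frame — never raw OCT pixels — and provides:

- **`octbias.geometry`** — per-frame indices: catheter-to-intima and
  catheter-to-media distances along the bias direction and its opposite
  (d_cib, d_cio, d_cmb, d_cmo), touch angle (catheter–intima contact arc),
  lumen area, min/max lumen diameter, lumen eccentricity, EEM area, average
  vessel diameter, burr-to-vessel ratio, and the 90° bias quadrant.
- **`octbias.coregistration`** — fiduciary-landmark alignment of paired
  pullbacks, nearest-frame pairing on a common 1-mm grid, bias-quadrant /
  dissection-arc coincidence and catheter-entrapment rates.
- **`octbias.stats`** — rank correlation, Mann–Whitney U, empirical ROC with
  trapezoidal AUC and DeLong confidence intervals, Youden-optimal cutoffs,
  DeLong comparison of correlated AUCs, ICC(2,1), Cohen's kappa, and a
  cluster bootstrap (within-patient resampling) sensitivity analysis.
- **`octbias.synthetic`** — a seeded generator of paired pre/post pullbacks
  with ground truth: noisy-elliptical lumens, offset media/EEM, an eccentric
  catheter, and a dissection mechanism driven by d_cmb and touch angle
  (threshold or logistic mode), with dissection flaps placed inside the bias
  quadrant.
- **`octbias.pipeline` / CLI** — generate → measure → pair → analyze → report.

## CLI

```bash
# full synthetic pipeline (study JSON, measurement CSV, paired CSV, report)
octbias reproduce --seed 1 --out runs/demo

# or step by step
octbias generate --seed 1 --out runs/study
octbias measure runs/study/P001_pre.json --out runs/measurements.csv
octbias pair --pre runs/study/P001_pre.json --post runs/study/P001_post.json \
    --out runs/paired.csv
octbias analyze runs/paired.csv --patients runs/study/patients.csv \
    --out runs/analysis --seed 1
octbias report runs/analysis/report.json
```

Pullback files use a versioned JSON schema (see `octbias/io.py`):
`{schema_version, patient_id, phase, landmark_z_mm, analysis_span_mm, frames:
[{frame_id, z_mm, catheter: {cx, cy, r}, contours: {intima, media?, eem?},
calcium_arcs?, dissection?}]}` with coordinates in mm and angles in degrees
counterclockwise from +x.

A generator config JSON can override any `GeneratorConfig` field, with nested
sections for `lumen`, `wall`, `calcium`, `bias`, `dissection`, `flap`,
`observer`:

```json
{"n_patients": 10, "dissection": {"mode": "logistic"}}
```

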