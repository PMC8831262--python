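# shearhist

Co-localization of carotid wall-shear-stress (WSS) metrics with
histology-derived plaque composition, as a tested, reusable pipeline:

- **hemodynamics** — analytic Womersley pulsatile velocity / wall-shear
  solution, Carreau–Yasuda shear-thinning viscosity, scaling of an inflow
  waveform to a target cycle-averaged wall shear (default 0.9 Pa in a
  common-carotid tube), and a stenosis-degree based ICA/ECA outflow split.
- **wss_metrics** — per-vertex TAWSS and OSI from time-resolved WSS vectors
  over one cardiac cycle (periodic trapezoidal quadrature).
- **colocalization** — axial ±0.3 mm window averaging along a centerline,
  assignment to eight 45° sectors about an explicit per-section angular
  reference, and assembly of the per-(section, sector) bin table.
- **histology** — necrotic-core / fibrin / macrophage / intima areas and
  minimum cap thickness per sector from class-coded label masks
  (TIFF + JSON sidecar), with artifact-based bin exclusion.
- **registration_qc** — Dice coefficient, symmetric average Hausdorff
  distance (max-Hausdorff reported alongside), and rigid 2D contour
  alignment.
- **stats** — patient-specific TAWSS/OSI tertiles, 3×3 co-occurrence
  tables, linear mixed-effects models with a per-patient random intercept
  (REML, Wald-z contrasts, Bonferroni adjustment), including the combined
  TAWSS×OSI cell-means model.
- **synthetic** — fully synthetic studies with known ground truth:
  straight / stenotic / bifurcation lumen geometries with flow extensions,
  WSS fields that match the analytic Womersley solution exactly on straight
  segments, and label masks whose per-sector composition follows
  programmable tertile effects with per-patient random intercepts.
- **pipeline** — end-to-end orchestration with strict-keyed YAML config,
  section/bin exclusion bookkeeping, registration-QC summaries, and a JSON
  run report.

## CLI

```sh
shearhist simulate --config config.yaml --outdir study/   # write a synthetic study
shearhist metrics  --study-dir study/                     # TAWSS/OSI maps
shearhist bin      --study-dir study/ --out bins.csv      # sector bin table
shearhist histo    --study-dir study/ --out plaque.csv    # per-sector plaque measures
shearhist qc       --fixed f.csv --moving m.csv           # contour alignment QC
shearhist stats    --bin-table bins.csv --out lmm.csv     # mixed-model contrasts
shearhist run      --config config.yaml --outdir out/     # all stages + report
shearhist report   --outdir out/                          # print report.json
```

Minimal `config.yaml` (unknown keys are rejected; defaults shown):

```yaml
seed: 0
n_patients: 11
sections_per_patient: 8       # int, or a list with one entry per patient
inflow: {target_tawss: 0.9}
binning: {n_bins: 8, half_window_mm: 0.3}
artifact_threshold: 0.5
section_exclusions: {deformation: 0, stenotic-gradient: 0, low-snr: 0}
bin_exclusions: {artifact: 0, registration_mismatch: 0}
effects:
  - {component: nc, driver: tawss, group_means: [1.0, 1.2, 2.0],
     patient_sd: 0.3, residual_sd: 0.5}
```

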