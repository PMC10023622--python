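# trimorph

Quantitative machinery of an ex-vivo right-heart bench model, re-implemented
as a tested, reusable Python pipeline and exercisable end-to-end on synthetic
phantoms with analytic ground truth:

* **Valve morphometry** (`trimorph.morphometry`) — long-axis definition, 18
  rotational half-planes (20°), landmark ingestion, 4th-order Fourier annulus
  fitting, best-fit-plane projection, perimeters (L2D/L3D), enclosed areas
  (A2D/A3D), centroid chords (Dmax/Dmin), Delaunay leaflet-surface
  reconstruction and tenting volume.
* **RV volumetry** (`trimorph.rv_seg`) — ROI crop, threshold speed image in
  [−1, 1], seeded region growing, scripted refinement, voxel volume.
* **Hemodynamics** (`trimorph.hemodynamics`) — 10-cycle ensemble averaging,
  tricuspid regurgitant fraction, cardiac output, pulmonary regurgitant
  volume, steady-state backflow readout.
* **Synthetic generators** (`trimorph.synth_valve`, `trimorph.synth_hemo`) —
  saddle-shaped annuli with tented leaflet surfaces voxelized into echo-like
  NIfTI volumes plus JSON landmark annotations; ellipsoidal RV cavities;
  pump/pulmonary/tricuspid waveforms with prescribed regurgitation; a
  three-element Windkessel (RK4) pressure simulator; a Bernoulli orifice
  model for the steady bench; paired fresh/defrosted cohort sampling.
* **Cohort statistics** (`trimorph.cohort`) — Shapiro–Wilk check, paired
  t-test, per-sample mean variation, summary tables (CSV/Markdown).
* **Replica driver** (`trimorph.replica`) — generates a calibrated paired
  cohort (n = 10 by default), measures every sample with the full pipelines
  and reports recovered vs generator-truth statistics, byte-reproducibly
  under a fixed seed.

Every geometric and hemodynamic quantity has an independent oracle
(`synth_valve.analytic_truth`, closed forms, dense quadrature) that shares no
code with the measurement path.

## CLI

```sh
trimorph synth valve --kind circle --radius 20 --profile paraboloid \
    --tenting-depth 9.549 --out v.nii --annotation a.json
trimorph morph --annotation a.json --out morpho.json

trimorph synth flow --trf 67.1 --prv 7.9 --rp 1.0 --cycles 10 --out w.csv
trimorph hemo --waveforms w.csv --hr 60 --sv 70 --out indexes.json

trimorph synth rv --semi-axes 50,40,22.2 --spacing 0.5 --out rv.nii
trimorph rvseg --volume rv.nii --seeds "i,j,k" --thresholds 15,45 --out mask.nii

trimorph cohort --measurements long.csv --out table.md
trimorph replica --seed 7 --out report_dir/
```

Exit codes: 0 success, 2 invalid parameters/config, 3 replica stage failure.

## Notes

* Volumes are NIfTI (RAS+, mm, isotropic spacing); annotations are JSON with
  one record per diametric image plane; waveforms are single-header CSV at
  200 Hz (`t_s, pap_mmHg, q_pulm_mls, q_tv_mls`); cohort measurements are
  long-format CSV (`metric,sample_id,condition,value`).
* Cardiac output is not an independent dial of the waveform generator: with
  the stroke volume imposed by the pump and per-cycle volume conservation,
  CO follows from the regurgitant fraction.
* The steady orifice model uses a constant effective area calibrated per
  pressure point; measured fresh/defrosted benches show a steeper
  pressure dependence than the orifice √Δp law.
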