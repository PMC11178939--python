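# flagwave

Quantification of planar flagellar waveforms from manually traced
high-speed video, plus a ground-truth waveform simulator that makes every
stage verifiable by parameter recovery.

Given head→tip coordinate traces of a beating (or statically bent)
flagellum, the pipeline computes, per flagellum:

- **tangent-angle profiles** θ(s): tangent direction vs arc length from the
  head, sampled every 10 px with a 20-px total-least-squares window
  (~0.4 / 0.8 μm at the default 0.04 μm/px scale);
- **basal curvature**: the slope (rad/μm) of a single ordinary-least-squares
  line through the pooled tangent angles of ≥5 frames spanning one beat
  cycle — the static component of the waveform. Subtracting the fitted line
  leaves the dynamic (propagating) component;
- **signed curvature profiles** κ(s) = ±1/r from sliding algebraic (Kåsa)
  circle fits over the same windows;
- **asymmetry index**: |stronger bend| / |weaker bend| of the curvature
  extremes at a fixed arc position (10 μm) over one cycle, with P-/R-bend
  labeling;
- **beat frequency** from the tangent angle probed at mid-flagellum
  (Hann-windowed periodogram with parabolic peak refinement), including an
  explicit motile/immotile triage; immotile flagella get a single-frame
  basal-curvature fit on a seeded random frame;
- **group statistics**: mean ± SE summaries, unpaired two-tailed Welch
  t tests (pooled-variance Student optional) with Holm–Bonferroni
  adjustment over an explicit comparison list.

The `synthetic` module generates pixel-quantized noisy traces from a
traveling curvature wave κ(s,t) = κ₀(s) + A(s)·sin(2π(s/λ − f·t) + φ) with
named presets for the phenotypes of interest (symmetric low-calcium
beating, calcium-induced asymmetric beating, biphasic proximal-only
beating, statically curved immotile flagella), so recovery of κ₀, A, f and
the asymmetry index can be tested against known ground truth.

## CLI

```sh
# render a labeled synthetic cohort (traces + ground truth + sidecar config)
flagwave simulate --preset wt_egta --preset wt_pca4 --n 8 --seed 1 --out runs/sim

# analyze every trace table; writes results.csv, per-flagellum plot-ready
# profiles, run_config.yaml and a log
flagwave analyze --input runs/sim --out runs/ana

# Welch + Holm-Bonferroni over named group pairs (groups are genotype:condition)
flagwave compare --results runs/ana/results.csv --metric basal_curvature \
    --pairs "WT:EGTA=WT:pCa4" --out runs/cmp.csv

# mean + SE tables per metric (and optional comparisons)
flagwave report --results runs/ana/results.csv --pairs "WT:EGTA=WT:pCa4" \
    --out runs/report
```

Exit codes: 0 success, 2 input error, 3 analysis error.

Real traces are ingested from CSV (`flagellum_id,frame,x,y`, rows in
head→tip order) or ImageJ ROI zips (one polyline per frame named
`<flagellum_id>_<frame>`); frame rate and pixel size always come from the
sidecar `config.yaml`, never from the data.

## Conventions

Image coordinates (origin top-left, y down), 0-based continuous pixels.
Tangent angles are measured against the +x image axis and unwrapped along
the arc; curvature is positive where the tangent angle increases along the
arc. Basal curvature is invariant to rotation/translation of the traces and
flips sign under mirroring.
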