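# glxquant

Quantitative imaging pipeline for glomerular endothelial glycocalyx (GEnGlx)
measurements:

- **Fluorescence peak-to-peak profiling** — extract a capillary-loop membrane
  contour from a two-channel micrograph (glycocalyx-lectin + membrane
  channel), place perpendicular profile lines (automated: 200 equally spaced
  lines per loop; manual: annotator-drawn ROI segments, typically 3 per
  loop), fit a Gaussian to each channel's intensity profile, and report the
  signed peak-to-peak distance as a thickness index. Loops are excluded when
  the per-loop SD exceeds 7.5 (in the declared report unit) and/or the
  signal-to-noise ratio falls below 15; results aggregate as unweighted
  mean-of-means loop → glomerulus → subject → group.
- **TEM morphometry** — glycocalyx thickness and coverage (a measurement
  ≤ 10 nm counts as uncovered), GBM / foot-process / slit widths, and
  fenestration and foot-process densities from grid-intersection annotation
  CSVs.
- **Permeability** — the fractional rate of fluorescence decline over the
  first minute after a perfusate switch, converted to an apparent albumin
  permeability via the cylindrical volume-to-surface ratio
  (`ps_alb = k · r/2`). Linear (first-minute slope) and exponential fitting
  modes are provided.
- **Synthetic data** — every input kind can be generated with known ground
  truth: PSF-blurred two-channel ring images (exact Bessel-form rendering of
  a blurred circle), multi-subject cohorts with group effects, TEM
  annotation tables with a controllable uncovered fraction, and
  one-compartment washout decay traces. All generators are deterministic in
  their seed.

## CLI

```sh
# synthesize inputs
glxquant simulate cohort --out data/cohort --seed 1
glxquant simulate tem    --out data/tem.csv --seed 1
glxquant simulate perm   --out data/perm --seed 1

# run the pipelines (config is YAML; defaults are materialized and echoed)
glxquant p2p  --config p2p.yaml  --out results/p2p
glxquant tem  --config tem.yaml  --out results/tem
glxquant perm --config perm.yaml --out results/perm

# log2 fold-change table relative to a reference group
glxquant report --subjects results/p2p/subjects.csv \
    --reference-group control --out results/fc.csv
```

A minimal `p2p.yaml`:

```yaml
inputs:
  manifest: data/cohort/manifest.csv
  seeds: data/cohort/seeds.csv   # lumen seed points (automated mode)
mode: auto        # or "manual" with inputs.rois
line: {n_lines: 200, length_um: 2.0, step_um: 0.05}
qc: {sd_max: 7.5, snr_min: 15.0}
```

Every output CSV starts with a comment line carrying the package version and
a hash of the fully materialized config; reruns with identical inputs and
config are byte-identical, and summaries are written atomically.

## Package layout

| module | contents |
| --- | --- |
| `glxquant.synthetic` | ground-truth generators (loop images, cohorts, TEM tables, decay traces) |
| `glxquant.profiles` | contour extraction, line placement, sub-pixel profile sampling |
| `glxquant.peaks` | Gaussian fits, peak-to-peak, SNR, QC exclusion, hierarchical aggregation |
| `glxquant.tem` | TEM thickness/coverage/width/density computations and annotation CSV I/O |
| `glxquant.permeability` | decline fitting and permeability conversion |
| `glxquant.pipeline_cli` | runners, config handling, normalization formulas, click CLI |
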