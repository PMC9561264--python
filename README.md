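# afm-dnacomplex

Quantitative single-molecule analysis of protein–DNA complexes in atomic
force microscopy (AFM) topographs, built for the kind of experiment in
which a base-excision-repair glycosylase (hOGG1) and a transcription
factor (Myc, optionally quantum-dot labelled) are imaged on a linear
505 bp DNA substrate carrying an oxidised-guanine (oxoG) lesion at 49.8%
of the contour and an E-box motif at 51.8%.

The package covers the whole desk side of such a study:

* **Synthetic scenes** — 2D-equilibrated worm-like-chain (WLC) DNA
  deposited on a flat surface, decorated with protein blobs of defined
  volume and height, quantum-dot labels, Gaussian tip broadening and
  pixel noise, with full ground truth; plus a fast tabular mode that
  samples per-complex measurement records directly.
* **Tracing** — scanline flattening, segmentation, skeleton-based
  contour tracing with sub-pixel smoothing, end extrapolation, and QC
  (closed loops, branched/crossing molecules, border clipping, length
  filter).
* **Complex measurement** — fractional position along the contour
  folded to [0, 50]% (the two DNA ends are indistinguishable), DNA bend
  angle from tangent-line fits to both arms, complex volume above the
  local background, and quantum-dot classification by the ≥ 3 nm height
  criterion.
* **Statistics** — position histograms normalised per DNA, Gaussian
  site fits over a flat nonspecific background, binding specificity
  *S* = *N*(*A*<sub>sp</sub>/*A*<sub>nsp</sub>) + 1 with *N* = 505
  available sites, occupancy of the 45–50% bin per DNA, bend-state
  decomposition (0°/35°/70° states; half-Gaussian at 0°), and pooled
  two-tailed t-tests between triplicates (df = 4).
* **Binding curves** — single-Hill fits
  *P*(*c*) = *P*₀ + Δ*P*·*c*ⁿ/(K<sub>D</sub>ⁿ + *c*ⁿ) of fluorescence-
  polarisation titrations, accepted at *R*² ≥ 0.95, with replicate
  averaging.

See `docs/methods.md` for the models, parameter defaults and their
rationale.

## Worked example

Run the full pipeline (simulate → measure → statistics) for the two
redox regimes of lesion binding, three replicates of 400 molecules each:

```yaml
# run.yaml
generator:
  n_molecules: 400
conditions:
  oxidising: {occupancy_specific: 0.10, nonspecific_rate: 0.14}
  reducing:  {occupancy_specific: 0.18, nonspecific_rate: 0.17}
reference_condition: oxidising
replicates: 3
mode: tabular        # "image" runs the full render/trace/measure path
```

```sh
afm-dnacomplex run --config run.yaml --seed 42 --out out/
```

`out/summary.csv` then holds one row per condition:

```text
condition  n_dna  n_complexes  occupancy_per_dna  occupancy_sd  specificity_S  specificity_sd  p_vs_reference significance
oxidising   1200          288             0.1050      0.023849        305.375         109.978             NaN          ref
 reducing   1200          400             0.1875      0.028174        532.863         102.733        0.017975            *
```

Reading the numbers: under the "reducing" condition 0.19 ± 0.03 binding
events per DNA fall in the specific 45–50% bin (the generator was set to
0.18), the fitted site peak over the nonspecific background corresponds
to a specificity of ~530 per site, and the occupancy difference between
the regimes is significant at the `*` level (p < 0.05, pooled t, df = 4)
against the oxidising reference.  Re-running with the same seed
reproduces every output byte for byte.

The same stages are available as library calls
(`generate_scene`, `trace_height_map`, `measure_traces`,
`fit_position_model`, `fit_hill`, …) and as CLI subcommands
(`simulate`, `trace`, `measure`, `stats`, `fit-binding`).

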