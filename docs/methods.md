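# Methods

This note documents the models behind `afm-dnacomplex`, the defaults
and why they were chosen, and what the synthetic data can and cannot
say about real AFM experiments.

## The measurement problem

AFM topographs of protein–DNA samples deposited on mica yield, per
molecule: where along the DNA a protein complex sits, how strongly it
bends the DNA, how large it is (volume), and — with quantum-dot (QD)
labelling — which protein it contains.  Aggregated over hundreds of
molecules these give binding specificity for a lesion site, occupancy
per DNA, and conformational state populations.  The package implements
this chain of measurements plus a generative model of the scenes so the
whole chain is testable without instrument data.

## Synthetic scenes

**DNA model.** Deposited DNA is modelled as a discrete 2D worm-like
chain: one node per base pair (rise 0.34 nm/bp, so the 505 bp substrate
has a 171.7 nm contour exactly), per-step turning angles drawn from a
zero-mean Gaussian with variance `segment_length / P`.  This gives the
2D tangent correlation exp(−s/2P) and the closed form
⟨R²⟩ = 4PL(1 − (2P/L)(1 − e^(−L/2P))), which the tests use as an
independent oracle.  The default persistence length P = 50 nm is the
standard value for B-DNA equilibrated on mica.  The chains are fully
equilibrated in 2D; kinetically trapped ("projected") deposition is not
modelled, and chains are not self-avoiding — crossing molecules occur
and are exercised as QC rejects.

**Binding model.** Each molecule carries a specific complex with
Bernoulli probability `occupancy_specific`, placed at the site fraction
(default 0.498) with Gaussian jitter of 1.5% of the contour — a proxy
for finite localisation precision that produces a fittable Gaussian
peak.  Nonspecific complexes are Poisson-distributed per molecule
(default mean 0.17) and uniform along the contour.  With the default
occupancies (0.18 specific) this reproduces a specificity of ~540, the
regime reported for lesion recognition under reducing conditions.  Bend
angles come from a Gaussian mixture over discrete states (defaults
0°/35°/70°, weights 0.3/0.4/0.3, within-state sd 8°) and are imposed on
the chain as rigid rotations of the downstream arm, preserving
arclength.

**Rendering.** The backbone deposits line mass that is spread into a
ridge (cross-section sd 1 nm); complexes are added *on top of* the
ridge as round Gaussian blobs; the whole field is convolved with an
isotropic Gaussian of sd `tip_sigma_nm` (default 3 nm) for tip
broadening, then i.i.d. Gaussian pixel noise (default sd 0.1 nm) is
added.  Because a linear blur reduces peak heights while conserving
integrals, blob and ridge shapes are pre-compensated so that *after*
the blur the ridge height is `dna_height_nm` (0.5 nm) and the complex
apex equals the configured complex height (1.5 nm protein, 4.5 nm QD)
while the integrated blob volume equals the true volume exactly.  Real
tip dilation preserves heights and inflates lateral size, which is
exactly the behaviour this compensation reproduces within a linear
forward model.  Pixel size defaults to 2 nm; these imaging constants
are package choices, since deposition/imaging calibrations vary between
instruments.

**Tabular mode.** `emit_measurement_table` samples folded positions,
bend angles, volumes, peak heights and QD flags directly from the same
distributions, in the same schema the imaging pipeline emits.  It is
the fast path for statistics at large n and the reference against which
the imaging path is compared (mode-equivalence test).

**What the generator does not emulate.** Tip asymmetry and double-tip
artefacts, sample drift, fractional humidity effects, molecule–molecule
crowding beyond simple overlap, sequence-dependent flexibility, and
kinetically trapped deposition.  Tests passing on synthetic scenes
demonstrate the estimators are correct for this forward model, not that
the model captures every property of real micrographs.

## Tracing

Scanline background removal fits a per-row polynomial (default order 1)
in two passes: a first fit on all pixels exposes molecules in the
residual, a second fit uses only background pixels (below median + 3
robust sd of the residual); rows without background pixels fall back to
a global fit with a warning.

Segmentation thresholds a lightly presmoothed copy of the map (2 nm
Gaussian) at max(3 × robust noise sd, 0.1 nm) above the median — the
floor handles noiseless synthetic maps whose MAD vanishes — fills
pinholes up to 16 px while preserving genuine loops, and flags regions
touching the image border.

Each region is skeletonised; the skeleton graph (8-connectivity with
redundant diagonal edges removed) is pruned of side branches shorter
than 12 nm.  The prune length exceeds the footprint radius of a bound
complex (~10 nm after tip broadening), which is the dominant source of
spurs; 6 nm left complex-bearing molecules branched.  Topology then
decides QC: no endpoints → closed loop, more than two → branched,
otherwise the path is walked end to end, smoothed by local quadratic
(Savitzky–Golay, 5-point window) to sub-pixel resolution and resampled
at 1 nm.  Skeletonisation erodes the chain ends by roughly the ridge
half-width, so each end is extrapolated along its tangent until the
interpolated height falls below half the local ridge height — along the
ridge axis the blurred profile crosses half-maximum exactly at the
physical end.  Contour length is the polyline sum of this path; raw
8-connected pixel steps would overestimate it.  The full-length filter
keeps traces within ±20% of 171.7 nm by default.  On noiseless scenes
the tracer recovers 200/200 molecules with a ~1% low length bias
(residual end erosion).

## Complex measurement

**Detection.** Heights are sampled along the trace; peaks must exceed
the profile median (the ridge level) by `min_peak_height_nm` (default
0.4 nm) and are non-maximum-suppressed within 10 nm.  Zero detections
is a valid outcome.

**Position.** 100 × min(d₁, d₂)/L, folded to [0, 50]% because the two
DNA ends cannot be distinguished; folding is invariant under trace
reversal.

**Bend angle.** Total-least-squares lines are fit to the contour over
an arm window (default 10 nm ≈ 29 bp) on each side of the peak; the
bend is 180° minus the angle between the outward arm directions, so
collinear arms give 0°.  Peaks closer than one arm to an end are
excluded from angle statistics but keep their position record — the
angle is geometrically undefined there, the position is not.  On traced
images the pipeline offsets the windows by a 5 nm gap from the peak:
the skeleton under the blob footprint is rounded by smoothing, and arms
fit flush against the peak underestimate kink angles by ~25%.  With the
gap, an ensemble generated in the 35° state measures 34 ± 4° (sem);
single-molecule scatter (~20° sd) reflects the WLC curvature within the
arm windows, as in real data.  Arm length is configurable; shorter arms
raise variance, longer arms average over intrinsic curvature.

**Volume.** A half-prominence threshold seeds the connected footprint
around the peak, which is dilated by 8 nm to recover the blob tails —
without dilation a Gaussian blob loses half its integral at the
half-maximum cut.  The background is the median of an annulus around
the footprint.  Where the footprint crosses the DNA, the ridge
contribution is removed: the ridge cross-section integral (nm² per nm)
is measured on perpendicular strips flanking the footprint along the
trace and multiplied by the trace length inside the footprint.
Isolated blobs recover within 2–5%; on-DNA complexes within ~5–8%
(residual tail clipping), preserving the monomer/dimer mode ordering at
100 vs 160 nm³.  Footprints containing a second detected peak are
flagged ambiguous.  No tip deconvolution and no molecular-weight
calibration are attempted.

**QD classification.** `is_qd = height ≥ 3 nm`, boundary inclusive.
With protein complexes at 1.5 ± 0.3 nm and QD complexes at 4.5 ± 0.3 nm
the cutoff sits 5 sd from both means; the theoretical error rate is
Φ(−5) ≈ 3 × 10⁻⁷ per complex.

## Statistics

Position histograms use fixed bins on [0, 50]% (2% wide for fitting;
the 45–50% bin is the occupancy statistic), with the top edge
right-inclusive, normalised per DNA molecule analysed.  The site model
is a constant background plus one Gaussian whose centre is bounded
within ±5% of the nominal site and which is folded at the 50% midline
(mass beyond 50 reflects back); fitting is bounded least squares on bin
counts, mirroring histogram-fit practice, not maximum likelihood on raw
positions.  A_sp is the Gaussian area in event counts; A_nsp is the
background level times the number of bins (total background area over
0–50%); S = N(A_sp/A_nsp) + 1 with N = 505 sites.  Whether the
background should itself be a broad Gaussian is undecidable from the
published description; the constant-background model is a declared
choice.

Occupancy is events in the 45–50% bin per DNA, averaged over
replicates with SD (reported as unavailable, not zero, for a single
replicate).  Counting molecules-with-an-event instead of events is
available as an option; events-per-DNA is the default.

Bend-angle decomposition fits k ≤ 3 reflected-at-zero Gaussians to a 5°
histogram, centres bounded ±15° of their initialisation (0/35/70 by
default).  The 0° straight-DNA state is a half-Gaussian with its centre
pinned at zero: a folded normal with centre below its sd is
statistically unidentifiable from a half-normal, so small centres near
zero are a resolution limit, not a measurement.  Fewer than 30 angles
are refused.

Replicate comparisons use the pooled-variance two-tailed t-test; two
triplicates give df = 4.  Stars: * p < 0.05, ** p < 0.01,
*** p < 0.005.  No multiple-testing correction is applied (stated in
the output metadata).  Pooled variance that is zero up to float
rounding with unequal means is flagged infinite-t rather than returning
an astronomically large statistic.

## Hill fits

P(c) = P₀ + ΔP·cⁿ/(K_Dⁿ + cⁿ), initialised from the data (baseline =
min, amplitude = range, K_D = concentration at half-range, n = 1).  The
Hill coefficient is fitted within [0.5, 4] by default — the experiment
description does not pin n — with a fix-n=1 mode provided.  Fits are
accepted at R² ≥ 0.95; K_D outside the titrated range × [0.1, 10] is
flagged unreliable.  Concentrations are treated as total ligand; with a
5 nM probe, depletion at K_D ≥ ~60 nM is below ~4% and is not
corrected.  Noiseless curves recover K_D to machine precision; 2%
multiplicative noise on 12-point titrations gives ~5% K_D scatter.

## Pipeline and reproducibility

One master seed spawns independent `numpy` SeedSequence children per
(condition, replicate); replicates are independent depositions.  Every
stage consumes and emits the documented CSV schemas and a validator
runs at each boundary; rejected molecules are logged one line per
molecule with their QC status.  Outputs contain no timestamps, so
re-running a config with the same seed reproduces every file byte for
byte.  The run report records a hash of the canonical config, the
master seed and the package version.

## Problem sizes

Default test and acceptance workloads are sized for a laptop-class
single CPU: 10,000 chains for the WLC oracle, 200-molecule noiseless
scenes for tracing accuracy, ~200 traced molecules for position
recovery, 3,000 tabular molecules for specificity, triplicates of 600
molecules for the occupancy regimes, 300 angles for bend decomposition,
40-molecule scenes per volume mode, 10⁶ draws for the QD error rate and
100 titration simulations; together they complete in a few minutes.
Larger n only narrows the Monte-Carlo error around the same estimators.

## Known limitations

* The tracer handles simple linear molecules; crossings, loops and
  border clips are rejected, not resolved, so crowded depositions lose
  molecules to QC rather than being recovered.
* Volume and bend measurements assume one complex per footprint;
  overlapping complexes are flagged, not deconvolved.
* Bend angles below ~10° are dominated by WLC curvature noise at the
  default arm length; state means are reliable, single-molecule small
  angles are not.
* The acceptance of the constant-background position model and the
  events-per-DNA occupancy convention are declared choices where the
  field's practice varies.
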