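# Methods

`fluenceforge` implements direct IMRT plan generation for nine-beam pancreas
SBRT as a two-stage image-to-image prediction problem, together with the
synthetic machinery needed to train and evaluate it without clinical data or
a commercial treatment planning system (TPS).  This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
study does and does not demonstrate.

## The planning problem

Pancreas SBRT with a standardized protocol prescribes 33 Gy in five
fractions to the planning target volume (PTV) while the luminal organs at
risk (stomach, duodenum and bowel, unioned into a single OAR) are limited to
a *maximum* of 25 Gy to 0.1 cc.  Because the OAR cap (75.8% of the
prescription) lies below the target dose — an inverted prescription — and
the OAR frequently abuts or overlaps the PTV, plans need steep dose
gradients and per-case manual effort.  The pipeline replaces inverse
optimization at planning time with two convolutional networks:

1. **FD-CNN** predicts, slice by slice, the nine per-beam ("field") dose
   distributions from the PTV/OAR contours and per-beam open-field dose
   templates.
2. Each predicted 3-D field dose is projected along its **beam's-eye view
   (BEV)** onto the isocenter plane.
3. **FM-CNN** converts each BEV dose map (plus the binary BEV PTV map) into
   that beam's fluence map — the deliverable quantity.

## Coordinate and grid conventions

Volumes are `[x, y, z]` arrays with the axial plane (x, y) and superior z;
voxel centers sit at `origin + index * spacing`.  The clinical-scale grid is
1 x 1 mm axial, 2 mm slices, with axial slices cropped to 192 x 192 pixels
centered at the isocenter (isocenter voxel at index (96, 96)).  The
isocenter is the PTV centroid snapped to a voxel center.  Gantry rotation is
about z; gantry 0 places the source anterior; the beam axis at angle t is
`(sin t, cos t, 0)`; nine equally spaced coplanar beams start at 0 degrees
(configurable).  Fluence and BEV maps share a 96 x 96 grid at 2.5 mm
isocenter-plane resolution (240 mm extent, inferred from the FM-CNN's
96-pixel top hierarchy).

A *coarse* preset scales everything down for desk-scale experiments:
48 x 48 x 16 voxels at 4 mm isotropic (same 192 mm axial extent), 32 x 32
fluence maps at 7.5 mm, and reduced-width networks.  All tests and the
acceptance script use this preset; the full-scale configuration is exercised
only for architecture/parameter-count checks and the BEV runtime contract.

## Synthetic phantom cohort

No public cohort exists for this protocol, so the generator emulates the
geometry that makes pancreas SBRT hard:

* **Body**: a water-density elliptical cylinder (half-axes 70-90 x 50-65 mm),
  air outside.  Tissue heterogeneity is deliberately omitted — the forward
  model is a surrogate anyway (below), and the networks receive only
  contours and templates.
* **PTV**: a perturbed ellipsoid (smoothed random modulation of the implicit
  surface) thresholded at a target volume drawn from a lognormal
  distribution with median 30 cc, truncated to [5, 150] cc — typical of
  pancreas SBRT targets.  The threshold is chosen by order statistics, so
  the drawn volume is hit essentially exactly before connected-component
  cleanup.
* **OAR**: a vertical tube with a wandering centerline and 6-12 mm radius,
  translated so its surface-to-PTV-surface gap matches a draw from
  U(-5, +15) mm (negative = overlap).  The translation is found by bisection
  against a signed Euclidean distance transform.  This reproduces the
  abutting/overlapping luminal-organ scenario; a gap option of 30-50 mm
  gives the "easy geometry" cases used to verify protocol recovery.

Everything is deterministic in the seed (numpy `SeedSequence` per case and
per retry).  What the generator does **not** emulate: respiratory motion,
CT texture and heterogeneity, multi-organ OAR shape detail, simultaneous
integrated boosts, and realistic patient-to-patient body-habitus variation.
Passing tests therefore demonstrate that the *pipeline machinery* learns and
reproduces plans under controlled geometry variation — not clinical-grade
performance on real patients.

## Forward dose engine

A deliberately simple linear surrogate replaces the TPS dose algorithm.
For a beam with source S and fluence map f on the isocenter plane, the dose
to voxel r is

    D(r) = f(u(r), v(r)) * exp(-mu * max(d(r), d_b) - d_b) * (SAD/|r-S|)^2

followed by a 3-D Gaussian scatter blur; `(u, v)` is the divergent
projection of the voxel through the source onto the isocenter plane
(bilinear fluence sampling), `d` the radiological depth, `d_b = 20` mm the
buildup depth, `mu = 0.004` /mm the effective attenuation, SAD = 1000 mm,
and scatter sigma = 3 mm.  These values give ~10-MV-like depth falloff in
water but are **not clinical**; all are exposed in `EngineConfig`.
Radiological depth is the cumulative density along the beam direction
computed in a rotated frame (parallel-ray approximation; the divergence
correction to depth is negligible at SAD = 1000 mm).  The operator is
linear in fluence, and its adjoint (used by the optimizer) is exact to
machine precision (verified by inner-product identity tests).

Per-beam **templates** are the engine's dose for a uniform fluence over the
conformal aperture (BEV footprint of the PTV + 5 mm), max-normalized to 1.
The 5 mm margin is a stand-in: the open-field shape used clinically is not
quantified anywhere.

Dose units: engine output is arbitrary; each benchmark plan carries a single
scalar calibration fixing its PTV mean to 100% of prescription, and the same
scalar converts that case's *predicted* fluences to % Rx, keeping
comparisons on one scale (no per-plan renormalization of predictions).

## Benchmark planner

Ground-truth plans come from projected-gradient descent on a quadratic
penalty objective (weights `w_ptv=1, w_oar=50, w_body=1, w_smooth=0.1`):
PTV mean-squared deviation from 100%, one-sided penalties above 75.76% in
the OAR and 80% in the out-of-ROI body, and mean squared first differences
of each fluence map.  The OAR weight dominates, mirroring clinical practice
where the luminal cap outweighs coverage.  Backtracking line search accepts
only decreasing steps, so the objective trace is non-increasing; iteration
cap 100, relative tolerance 1e-5.  The exact OAR D_max(0.1 cc) <= 80% Rx is
enforced at accept/reject time only (the in-objective penalty is its
differentiable surrogate); rejected phantoms are redrawn.  After
optimization, fluence pixels below 1e-3 of the per-plan maximum are zeroed
("deliverable cleanup") so each map's positive support is its real aperture
— this also makes the positive-pixel counts in the FM loss meaningful.

## FD-CNN

Input A: the query PTV slice with its six neighbors (query +- 3, zero-padded
at volume boundaries) plus the OAR query slice (8 channels).  Three strided
(k=4, s=2) convolutions encode to 1/8 resolution (widths 32/64/128 at full
scale), three strided transposed convolutions decode back (96/84/72), the
nine template slices are concatenated, and two unit-stride convolutions emit
nine dose channels.  Swish activations, linear output, negative doses
clipped at inference.  Per-block depth, kernel sizes and widths are exposed
in `FDNetConfig` (the reference architecture's internals are unpublished;
the defaults land at ~1.1 M parameters against the reported 3.35 M, the
same order of magnitude).  The coarse preset uses single-convolution blocks
(16/32/48 down, 32/24/16 up, ~8 x 10^4 parameters).

Loss: per-slice, over ROI pixels only (ROI = PTV + 1 cm),

    L_FD = [ sum_beam sum_ROI (FD_b - FD_p)^2 + mu * sum_ROI (TD_b - TD_p)^2 ] / N(ROI)

with TD the nine-channel sum and `mu = 1` by default (the reference tuned it
on validation; the config surface reproduces that procedure).  Training:
Adam, lr 1e-3, batch 16, 10% validation holdout after seeded shuffling,
early stopping with patience 8, best-validation weights restored.  Doses are
scaled to fractions of prescription inside the network.

Prediction runs every ROI-intersecting slice and stacks the outputs into
nine 3-D volumes; non-ROI slices, and non-ROI pixels within slices, are
zero — the prediction is only defined inside the ROI.

## BEV projection

For each map pixel, the divergent ray from the source through that
isocenter-plane point is marched at 1 mm steps with trilinear sampling, and
the dose samples are averaged (an integral mode is available).  The
average-dose convention keeps map values on the % Rx scale and independent
of grid resolution.  Because the FD-CNN dose exists only inside the ROI, the
pipeline averages over the **ROI-intersecting portion** of each ray, and
does so for benchmark doses too: using whole-volume benchmark projections in
training but ROI-only predicted projections at inference would hand the
FM-CNN systematically lower inputs than it was trained on (observed as a
~4% PTV mean-dose bias in the full chain; ~1.2% with consistent
projections).  PTV maps are binary ray-hit footprints.  The projection is
unweighted by depth or attenuation — a documented assumption.

## FM-CNN

A three-hierarchy U-Net (96/48/24 pixels at full scale; widths 16/32/64,
~1.5 x 10^5 parameters against the reported 2.0 x 10^5) over the
2-channel input (BEV dose, BEV PTV), with strided convolutions down,
strided transposed convolutions up, skip connections, Swish hidden
activations, and two deliberate additions:

* an **identity-initialized 1x1 input skip** on the dose channel added to
  the output pre-activation — physically, a fluence map is to first order a
  rescaled BEV dose map, and the live skip keeps output gradients informative
  while the U-Net features are still random;
* a **ReLU output** as the nonnegativity activation.  A strictly positive
  smooth activation (Softplus) cannot emit exact zeros, so the ~90% of
  pixels with zero benchmark fluence exert permanent L1 pressure that was
  observed to collapse the whole map; with ReLU, background pixels satisfy
  their target exactly and go dormant.

Loss: sign-balanced MAE

    L_FM = (1 + lambda) * sum |y_b - y_p| / N(y_b > 0),
    lambda = |N(y_b - y_p > 0.001) - N(y_b - y_p < -0.001)| / N(y_b > 0)

summed over all pixels (a positive-pixel-only variant is a config switch;
the all-pixel sum is the literal reading of the formula).  lambda is
piecewise constant in the prediction, so training uses the a.e. subgradient
`(1 + lambda) * sign(y_p - y_b) / N(y_b > 0)`.  Benchmark fluences are
normalized cohort-wide so their 99.9th percentile is ~1 (making the 0.001
threshold meaningful); BEV dose inputs are scaled to [0, 1] by the cohort
maximum; both constants are stored in the checkpoint.  Training: Adam,
lr 1e-3, patience 15, 10% holdout.

## Evaluation

All doses are compared in % Rx.  Per test case, three plan variants are
scored against the benchmark: the FD-CNN dose itself, the *FM-CNN plan*
(FM-CNN fed benchmark field doses, isolating the second network), and the
*model-predicted plan* (full chain).  Metrics:

* voxel-wise percentage dose difference `mean |D_b - D_p| / D_rx * 100`
  over PTV / OAR / ROI / ROI-minus-PTV;
* DVH endpoints: mean dose, D_max(0.1 cc) (minimum dose of the hottest
  ceil(0.1/voxel_cc) voxels; plain max with a warning for structures under
  0.1 cc), D95% as the nearest-rank 5th percentile (unambiguous,
  reproducible);
* fluence MAE (the lambda = 0 reduction of L_FM);
* 2-D gamma at 3%/3 mm between predicted and benchmark fluence maps —
  global normalization to the reference maximum, 10% low-dose cutoff,
  search over a 9 mm disk at 1/10-pixel steps with bilinear interpolation
  and two local refinement stages to sub-milli-pixel resolution.  The
  truncated search radius cannot affect pass/fail (any position beyond 3 mm
  already has a distance term above 1).  The reference work gammas optimal
  vs leaf-sequenced fluence; leaf sequencing is out of scope here, so the
  comparator is applied to predicted-vs-benchmark maps instead.

Reports are tidy per-case CSV tables plus cohort mean ± SD aggregation.

## Desk-scale experiment and what it shows

The standard experiment (tests and `scripts/acceptance.py`): 40 phantoms,
split 30 train / 10 test, coarse geometry, reduced-width networks, FD-CNN
capped at 60 epochs and FM-CNN at 200 (early stopping usually fires first).
Problem sizes were chosen so the whole experiment runs in minutes on one
CPU.  Representative results (seed 7): FD-CNN ROI voxel dose difference
~2.5% Rx; FM-CNN-plan PTV mean-dose difference ~1.2% Rx; model-predicted
plan PTV mean-dose difference ~1.2% Rx; all comfortably inside the
acceptance bands (5%, 2%, 3%).  Test loss is non-increasing with training
set size and removing the beam-template input increases FD test loss —
direction-only properties, matching the qualitative behavior reported for
the clinical-scale system.

**Known limitation — per-pixel fluence MAE.**  The projected-gradient
benchmark fluences carry pixel-scale modulation (they are optimized per
beamlet with only a mild smoothness penalty).  A network fed a smoothed,
path-averaged dose projection cannot recover that high-frequency component,
so normalized per-pixel fluence MAE plateaus near 0.07 even when the
resulting *dose* agrees with the benchmark to ~1% — the dose operator
averages the pixel noise away.  Clinical TPS fluence maps are smoother, which
is why per-pixel MAE is a much stronger statistic in the clinical setting
than in this synthetic one.  The package therefore treats dose-level
agreement as the binding quality check and bounds the per-pixel MAE at the
level the synthetic experiment actually supports.

Other limitations: the engine is non-clinical (no heterogeneity
corrections, no MLC/leaf-sequencing model, no monitor-unit computation);
benchmark "expert quality" is only as good as the quadratic-penalty
objective; the gamma comparator here measures prediction fidelity, not
deliverability.
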