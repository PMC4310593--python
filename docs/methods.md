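# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ectimetry`, in the order data flows through the package.

## The ΔLinearity statistic

The traced interface is an ordered polyline of (x, z) points in μm,
strictly increasing in lateral position x, with depth z increasing downward
from the tissue surface at z = 0. Its arc length *l* is the sum of
Euclidean segment lengths; the chord *L* is the straight-line distance
between the first and last points. The statistic is

&nbsp;&nbsp;&nbsp;&nbsp;ΔL = l − L, &nbsp;&nbsp; (ΔL)_norm = ΔL / L.

Because the chord joins the trace's own endpoints, l ≥ L always and
(ΔL)_norm ≥ 0 with equality iff the points are collinear. The statistic is
invariant under translation, and under any rigid motion of the polyline.
Reference values used by the tests: a flat interface gives exactly 0; a
semicircular interface gives π/2 − 1 ≈ 0.5708; for sinusoidal and Gaussian
rete-ridge profiles, the oracle `true_delta_linearity` integrates
√(1 + z′(x)²) with the analytic derivative on ≥ 10⁵ trapezoid samples
(relative quadrature error < 10⁻⁴ for these slope-bounded profiles; curves
with vertical tangents are outside its domain and are checked against
dense parametric polylines instead).

## Synthetic phantoms

**Boundary model.** z(x) = baseline + A·sin(2πx/λ) + Σ aᵢ·exp(−(x−cᵢ)²/2wᵢ²)
(+ optional Gaussian jitter). Positive sine crests and positive bump
amplitudes point *deeper* into the tissue, matching rete ridges protruding
down into the lamina propria. Jitter makes a model stochastic; the
quadrature oracle refuses such models.

**Cross-section rendering.** Defaults mirror the acquisition geometry the
statistic was designed for: 512×512 px at 0.625 μm/px lateral (320×320 μm
field of view), 1 μm axial steps, 8-bit intensities, a 10 μm keratin band.
The autofluorescence channel is bright keratin (220) over moderate
epithelium (110) over textured stroma (90·texture); the SHG channel is
exactly zero above the interface and a textured fibrous band (140·texture)
below it. Texture is a smooth multiplicative field (Gaussian field,
σ = 2 px correlation, sd 0.25, clipped to [0.2, 1.8]). The pixel that the
interface crosses carries the partial-volume fraction of its axial extent
below the boundary — real detector pixels integrate over their area, and
without this the rendered edge is bistable between adjacent rows and
staircase artifacts inflate ΔLinearity by ~0.02 even without noise.
Noise is additive Gaussian (sd 2 DN) plus signal-dependent shot noise
(Poisson with 0.25 DN/photon gain), both configurable. All randomness comes
from one seeded generator; identical parameters give bit-identical frames.

**En-face rendering.** Nuclei are placed by hard-core dart throwing (minimum
center distance = maximum diameter, so nuclei never overlap) at the target
count round(density · area / 100 μm²), with per-nucleus diameters uniform in
the requested range, rendered as soft-edged dark disks (55 DN) on bright
cytoplasm (200 DN). Feasibility is checked up front: a requested area
fraction above 0.45 raises a packing error (random sequential adsorption of
disks jams near 0.55, and dart throwing becomes impractical well before
that). Consequently 16–18 μm nuclei are only feasible below ≈ 0.18 per
100 μm²; the published 0.25 per 100 μm² density is feasible with 8–10 μm
nuclei.

**Cohort simulation.** Group ΔLinearity distributions are parameterized by
their published mean and SD. Normal groups default to a Gaussian truncated
at 0 with the published (mean, sd) as parent parameters — the truncated mass
is Φ(−2.75) ≈ 0.3%, so the realized moments match the targets to well under
the sampling error. Dysplastic groups default to a lognormal with log-scale
parameters moment-matched to the published mean and SD (σ² = ln(1+cv²),
μ = ln m − σ²/2): the original work reports no distributional family, and
the lognormal is the natural non-negative, right-skewed choice consistent
with SDs that exceed half the mean. Both families are switchable per group
spec, and a point-mass family exists for degenerate test cases. Per-grade
parameter sets (mild/moderate/severe) are exposed alongside the pooled
normal/dysplasia parameters; the two printed sets are not exactly
consistent for every grade and the package deliberately does not reconcile
them.

## Boundary extraction

1. **Threshold.** Otsu's between-class-variance maximum on the SHG
   histogram (a manual level is accepted). A constant channel raises a
   degenerate-histogram error.
2. **Edge detection.** The SHG channel is first *clipped at the threshold
   level*, then passed to a Canny-style detector (Gaussian-derivative
   gradient, σ = 2 px, non-maximum suppression, hysteresis at 40%/80% of
   the maximum gradient magnitude). Clipping implements "threshold, then
   edge-detect": the fibrous texture of the lamina propria saturates to a
   constant and contributes no edges, so the only strong gradient is the
   dark-to-bright transition at the interface itself — while, unlike
   binarizing, the subpixel shape of that transition survives. On raw
   channels, texture ridges just below the interface capture the edge and
   bias ΔLinearity upward by ~0.01.
3. **Topmost candidates.** Per column, the smallest edge row; isolated
   candidates more than 15 px from every adjacent candidate are speckle
   and fall through to the next edge pixel in that column (or a gap
   marker). More than 50% gap columns aborts extraction.
4. **Minimal-cost trace.** Uniform-cost (Dijkstra) search over 8-connected
   pixels with per-pixel cost ε + 1/(1 + |∇|), ε = 0.01, from the leftmost
   to the rightmost column. Seeds are the median of the nearest nine
   candidates (robust to short speckle runs at the borders). Ties are
   broken lexicographically by (cost, z, x), so results are deterministic.
   The search is restricted to a depth band (candidates ± 32 px) for
   speed. A path crossing a near-featureless run (gradient < 5% of max)
   longer than 20 px raises a tracing error — gaps wider than the
   bridging ceiling are not silently interpolated.
5. **Reduction and smoothing.** The path is made single-valued in x by
   keeping the topmost path pixel per column (the interface is the topmost
   SHG border; re-entrant folds are out of scope). Integer rows are
   refined to subpixel depth by parabolic interpolation of the gradient
   magnitude across rows, converted to μm, and smoothed with a centered
   moving average of half-width 2 samples (disabled by flag). The
   smoothing default was verified on flat phantoms: recovery under default
   noise is ≈ 10⁻⁴, far inside the 0.02 acceptance budget.

## Morphometry

**Surface.** Per column, the smallest depth where autofluorescence exceeds
20% of the channel's robust maximum (99th percentile), median-filtered over
5 columns. The surface includes the keratin band (the top of all
autofluorescent signal); subtracting a configured keratin thickness is a
flag. **Thickness** is the vertical boundary-minus-surface distance sampled
at fractions (2k−1)/(2n) of the shared width (1/8, 3/8, 5/8, 7/8 for the
default n = 4, emulating four line measurements per site) and averaged.
Vertical rather than boundary-normal distance matches a line tool drawn on
a cross-section.

**Nuclear density.** Dark blobs on bright cytoplasm are detected by
multi-scale Laplacian-of-Gaussian on the inverted image, normalized to
[0, 1] (which makes the count invariant to global intensity scaling), with
scale range σ = 0.8·r_min/√2 … 1.2·r_max/√2 from the requested diameter
range and response threshold 0.3 — nuclei have normalized contrast ≈ 0.7
versus background texture ≈ 0.15, so the detector sits well between the two
(0.25–0.35 all recover counts exactly on phantoms). Density is
count / area per 100 μm².

## Cohort statistics

ANOVA is the classical fixed-effects F test; the degenerate all-constant
case is handled explicitly (F = 0/p = 1 for equal means, F = ∞/p = 0
otherwise). Tukey HSD uses the studentized range with pooled within-group
variance. Box-plot summaries use linear-interpolation quartiles and
1.5×IQR outlier fences. The ROC is empirical over all distinct score
thresholds with "score ≥ cutoff ⇒ dysplastic"; AUC is the trapezoid area,
identical to the rank-sum concordance probability with ties counted ½. The
operating point maximizes Youden's J = sensitivity + specificity − 1
(ties → lower cutoff; a closest-to-(0,1) criterion is available), and
TP/FP/TN/FN are reported as proportions *within* each true class
(TP + FN = 1, TN + FP = 1). Imaging and histology readouts are analyzed as
separate populations keyed by a modality tag.

## What the simulations do and do not show

The Monte-Carlo cohorts reproduce the published *group-level* conditions —
sample sizes (33 normal, 27 dysplastic) and group means/SDs — not the
original animals' raw images; per-replicate ROC analysis averaged over 200
seeded replicates yields mean sensitivity ≈ 92, specificity ≈ 97, AUC
≈ 0.97 (imaging) and ≈ 0.96 (histology). These sit a few points from the
single-cohort values printed for the original data because (a) the true
per-site distribution family is unknown and (b) the Youden-optimal point on
a 60-site empirical ROC is an optimistically biased estimator. Phantom
recovery tests show the tracer reproduces analytic truth, not that it
handles every real-tissue artifact: phantoms have no depth attenuation, no
point-spread blur, no co-registration error, and their texture is
stationary.

## Problem sizes and numerical choices

The recovery grid uses 20+ analytic models (sine amplitudes 8–25 μm,
periods 64–160 μm, Gaussian bumps 25–30 μm) spanning true ΔLinearity
0.02–0.66 with interface slopes up to ≈ 2, each measured on one seeded
512×512 phantom at default noise against the quadrature oracle at
tolerance max(5% relative, 0.01 absolute). Steeper interfaces (slope ≳ 2.4,
ΔLinearity ≳ 0.9 — beyond any reported tissue value) are biased low by
≈ 5%: the topmost-pixel-per-column reduction clips near-vertical flanks
and σ = 2 px smoothing attenuates them; this is the method's resolution
envelope, not a tunable. Cohort simulations use 200 replicates; the
Dijkstra-vs-exhaustive-relaxation check uses 100 random 8×8 grids; the
ANOVA type-I-error simulation uses 1000 null replicates of 3×10 samples.
All stochastic tests and scripts derive their streams from fixed or
user-supplied seeds via `numpy.random.default_rng`.
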