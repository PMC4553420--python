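# Methods

This note documents the models, parameter choices and numerical decisions
behind `pollendep`, and what the synthetic-data generators do and do not
emulate.

## Deposition-field model

The true deposition surface λ(x, y) (pollen/cm²) is phenomenological, not
mechanistic: it reproduces the statistical signature of pollen settled on
a leaf — log-normal marginals with pronounced accumulation zones — without
modelling source strength, wind or dispersal. On the leaf rectangle
(x along the length, y across the width),

    ln λ(x, y) = ln(background_gm) + G(x, y) + ln A(y).

`G` is a mean-zero stationary Gaussian field with marginal SD
`ln(background_gsd)` and isotropic exponential covariance
`C(h) = σ² exp(−h/ℓ)`, ℓ = `correlation_length_cm`. The exponential family
is the simplest stationary choice producing patchy, rough deposition;
smoother families (Gaussian, Matérn ν ≥ 3/2) would suppress the small-
scale variability a microscope actually sees between neighbouring fields
of view.

`A(y)` collects the accumulation structures, all running the length of
the leaf as maize venation does: the midrib band (|y − W/2| ≤ 0.4 cm,
×10), parallel veins at offsets of ±k·1.0 cm from the midrib (halfwidth
0.1 cm, ×3) and the leaf-edge bands (0.3 cm, ×3). Veins are indexed from
the midrib so that no vein coincides with the midrib band or the edges;
overlapping structures multiply.

### Simulation and evaluation

`G` is simulated *exactly* on a regular 1 mm grid by two-dimensional
circulant embedding: the covariance is embedded on a torus of ≥3× the
grid extent per axis, its FFT gives the embedding eigenvalues, and one
complex-normal synthesis yields the field. Negative embedding eigenvalues
are clipped to zero; with the default ℓ = 2 cm and 3× padding the clipped
variance fraction is exactly 0 (asserted nowhere, measured during
development), so the grid marginals are exact. Eigenvalues are cached per
(grid, ℓ), making a fresh 475 × 88 field cost one FFT pair (~20 ms), which
is what keeps thousand-replicate design studies cheap. Between grid nodes
`G` is interpolated bilinearly; `A` is evaluated analytically, so band
edges stay sharp at any resolution.

`true_summary` evaluates λ on grid-cell centres (default step 1 mm,
required to be no coarser than the narrowest active structure) and
reports the geometric mean, the empirical 5%/95% quantiles and the
maximum — the truth a sampling design is trying to estimate.

### Default calibration

Defaults target the field regime observed on leaves near maize fields
during anthesis: leaf geometric means around 100–300 pollen/cm², maxima
around 1,000–5,000 pollen/cm², i.e. 10–100× the mean in accumulation
zones. With the multipliers above, this pins the background:
`background_gm = 120` and `background_gsd = 1.5` give (200 simulated
leaves) a median leaf GM of ≈197 pollen/cm² (100% within 100–300), a
median fine-grid maximum of ≈3,550 pollen/cm² and a max/GM ratio of
median ≈18 with 100% inside [10, 100]. The calibration was fixed once,
from this scan. Note the constraint runs through the *fine-grid maximum*:
because the grid maximum of a rough log-Gaussian field grows like
exp(≈4.5σ) over this many grid cells, a much larger background GSD would
push maxima far beyond the observed regime even though spot-level
*measured* spreads on real leaves can be larger; the background GSD is a
point-scale parameter and is deliberately smaller than the GSD of pooled
spot measurements, which also absorb accumulation-zone structure,
Poisson counting noise and censoring.

## Counts and censoring

A spot's grain count is Poisson with mean `λ̄ · a` (footprint-averaged
intensity × calibrated area). Poisson is the standard law for counting
discrete particles in a fixed area; leaf-scale overdispersion is carried
entirely by the spatial field, not the count law. The footprint is a disc
of the calibrated area (a square option exists, see designs); λ̄ is a
sub-grid average at 1/50 of the footprint diameter, accurate to well
under 1% even for spots straddling a band edge. A deterministic mode
returns the rounded mean and serves pilot scans and noise-free oracles.

The detection limit of a 5 mm² field is one grain, 20 pollen/cm²; zero
counts are substituted by the conventional two-thirds of the detection
limit, entered as the literal constant 14 pollen/cm² (the value used with
field data) rather than the derived 13.3 — the constant is configurable,
and the discrepancy reflects the approximate nature of the published spot
area. No censored-likelihood (Tobit-type) estimator is fitted; the
substitution rule is the method under study.

## Sampling designs

Fixed choices where the study protocol is qualitative:

* Leaf orientation: the 38-image "full lateral transect" spans the width
  at mid-length; a 200× circular footprint (⌀2.52 mm) at width/38 spacing
  (2.30 mm) overlaps marginally and overhangs the edge by 0.1 mm — both
  are recorded as provenance warnings, matching the physical reality of a
  consecutive image series; the square footprint of equal area (side
  2.24 mm) tiles cleanly and is used where strict containment matters.
* Repeated transects sit at fractions (2i+1)/2n of the length; per
  transect the five spots are midrib, 30% and 70% of the width, and both
  edges inset by half a spot diameter.
* Cluster placement needs an observable notion of high/low areas: the
  default pilot scan takes one deterministic 200× measurement per raster
  cell; cluster centres are drawn from distinct cells of the top/bottom
  decile of the pilot ranking (ties broken by cell index), with spots
  uniform within 1 cm of the centre. A truth-based pilot mode exists for
  evaluation studies.
* Spots closer than one footprint diameter are jittered by up to one
  diameter (clusters and the composed structured design only — within a
  single transect the overlap is deliberate); jittered indices are
  recorded.

Design sizes under defaults are exact: 35 (random raster), 38 (full
transect; the reference data set analysed 37, one image being unusable —
pooling uses 35+37+25+30 = 127), 25, 30, 27.

## Design evaluation

Per replicate: fresh field → pilot → designs → Poisson counts →
censoring → summaries, compared against that replicate's `true_summary`.
Metrics: bias and RMSE of the GM and of q95, and the max-capture rate
(sampled maximum ≥ half the true grid maximum). Defaults use 200
replicates; the acceptance checks use 300–1,000. All randomness derives
from one master seed through named substreams (field, pilot, design,
measurement, replicate), so any single step can be reproduced in
isolation.

A structural caveat worth knowing: the repeated-transect layout places
3 of 5 spots in accumulation bands (midrib, two edges), so transect spots
carry a *larger* positive log-offset than cluster spots, whose high and
low halves partially cancel. The structured design, being a 15:12 mixture
of transect and cluster spots, therefore shows a GM bias *between* the
two — above the clusters-only design, not below it. Designs targeting
accumulation zones buy max-capture (clusters ≈0.80 vs full transect
≈0.24–0.32 under defaults) at the price of location bias; an unbiased GM
comes from the random raster.

## Synthetic microscopy

The image generator renders what the identification-by-size logic needs
and nothing more: bright discs (grain diameters uniform on 80–120 μm) on
a dark background in a 1280 × 1024 8-bit frame whose pixel pitch derives
from the calibrated field area (area = W·H·p², p ≈ 1.95 μm at 200×).
Colour, exine texture, trichomes and leaf background are *not* modelled —
identification is by size alone, so a counter passing these tests has
only been shown to segment and size well-separated convex objects, not to
recognise pollen in field imagery. Placement enforces a 5 μm edge-to-edge
clearance by rejection sampling (1,000 attempts per grain, then a packing
error naming the achieved count). The counter thresholds globally
(midpoint for clean synthetic frames; Otsu as the adaptive option for
noisy backgrounds), labels 8-connected components and sizes them by
equivalent diameter `2√(area/π)`. The single-grain window 70–130 μm is
the true 80–120 μm range ± one-pixel-scale margin; oversized components
are apportioned by the nominal 100 μm grain area and flagged as overlap,
mirroring the practical restriction of automated counting to densities
where grains do not touch.

## Numerical conventions

* z for the 95%/5% quantiles is fixed at 1.6449 (4 decimals); the
  identity ln(q95/GM) = 1.6449·σ̂ holds to machine precision whenever q05
  is not floored.
* σ̂ uses the n−1 denominator; n ≥ 2 is required.
* Back-transform estimators carry known finite-sample factors
  (E[exp(μ̂)] = GM·exp(σ²/2n); E[exp(zσ̂)] from the χ distribution of σ̂);
  the recovery tests check Monte-Carlo means against these exact
  expectations, not against naive zero bias.
* Table values are rounded half-away-from-zero at report time only;
  internal values keep full precision. CSV output is comma-separated
  UTF-8 with "." decimals and no thousands separators.
* Degenerate inputs: constant samples give σ̂ = 0 and collapsed
  quantiles; a homogeneous noise-free field reproduces the background GM
  exactly everywhere (the multiplier algebra is exact, not sampled).

## Problem sizes

The shipped checks use 200 fields for the regime survey, 1,000 synthetic
samples of n = 127 for estimator recovery, 100 rendered images for the
counting round trip, and 300–1,000 replicates for design evaluation —
sizes at which every Monte-Carlo margin quoted above is several standard
errors wide while a full run stays around a minute on one CPU.

## Known limitations

* The field is a single-snapshot surface; temporal accumulation over
  anthesis is not modelled.
* Accumulation structures are straight, length-parallel bands of constant
  multiplier; real veins curve, and accumulation is patchy along them.
* Poisson counts given λ̄ ignore grain clumping within a spot.
* The imaging module's fidelity claims extend only to synthetic scenes
  (see above).
* The clusters column of real single-leaf reference data is not exactly
  reproducible by either quantile rule from printed summaries; both the
  fitted and empirical rules are exposed, and no check asserts against
  that column.
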