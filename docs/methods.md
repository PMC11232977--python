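# Methods

## The estimation problem

A single forward-facing camera on a diving predator records prey swarms as
2-D images. Counts of animals per frame index relative abundance only; a
concentration requires the sampled water volume, which a single camera does
not measure. The package's central idea is that the *limit of visual
resolvability* plays the role of a far clipping plane: prey closer than
some range `r_res` retain identifiable features (eyes, carapace, telson,
body shape), prey beyond it collapse into featureless blobs. The imaged
volume is then the pyramid with apex at the camera and base equal to the
physical frame footprint at `r_res`, `V = w·h·r_res/3`.

## Model and assumptions

- **Pinhole projection, negligible distortion.** An object of physical
  projected size `s` (mm) at range `z` (mm) images to
  `s · H_px / (2 z tan(vfov/2))` pixels. Range and frame height are derived
  from the *vertical* field of view: for the deployed 1280×960 px frame with
  a 31°×24° nominal field of view, the 31° horizontal angle is geometrically
  inconsistent with the 4:3 pixel aspect, and only the vertical-FOV chain
  reproduces the deployment's internally consistent published geometry, so
  the implementation uses `r = h / (2 tan(12°))` with `h = 0.75·w`
  throughout.
- **Known, narrow prey length distribution.** All imaged prey are assumed
  drawn from the diet-sample length distribution (default: krill 31–60 mm,
  mean 43 mm, sd 4.3 mm, median 42 mm). The *median* length is the
  reference for pixel↔mm conversion.
- **Uniform body orientation.** Imaged lengths are projections
  `L·|cos θ|` (floored at the body's axial width). For θ uniform on
  (−180°, 180°] the median projected fraction is `√2/2`; the estimator
  divides the *median-calibrated* boundary size by this factor. The
  compensation is valid for medians only — individual lengths are never
  corrected.
- **Resolvability is primarily range-driven**, but contaminated: motion
  blur makes some near prey unresolvable, and labels carry analyst
  subjectivity. The logistic boundary (below) and the mirrored near-boundary
  distribution are designed around this contamination.

## Boundary estimation

A maximum-likelihood logistic regression of the binary label
(resolvable = 1) on raw pixel length gives `L_b = −β₀/β₁`, the length of
predicted probability 0.5. Records with `partial` (frame-clipped) or
`packed_aggregation` subtypes are excluded from the *size* fit because
their lengths are unreliable; they still *count* toward density, since a
clipped or blurred krill is a krill inside the volume. These two filters
are deliberately distinct.

Boundary uncertainty: all sizes below `L_b` (from both labelled classes —
below the operational boundary everything is treated as effectively
unresolvable) are mirrored to `{x} ∪ {2L_b − x}` and a normal fitted by
moments (sample sd, n−1). The mirrored mean equals `L_b` exactly by
symmetry; tests enforce this to 1e−9 relative. The raw unresolvable-class
distribution is *not* used directly because motion-blurred large animals
inflate its upper tail; its median and histogram mode are provided as
cheaper alternative boundary statistics.

Degenerate inputs: perfectly separated classes make the likelihood diverge;
the fit then reports the midpoint of the separating gap with an explicit
`degenerate` flag, never silently. Fits require ≥2 records per class.

## Sensitivity and error propagation

`boundary_grid` evaluates the full chain at seven boundary values: the
near-boundary mean, ±1 and ±2 sd, and the minimum observed resolvable and
unresolvable sizes. `propagate` draws n = 1000 (default) boundary sizes
from Normal(mean, sd), excluding non-positive values by
rejection-resampling to a fixed accepted sample size (a drop-without-
replacement mode is available); each draw runs the deterministic chain, and
per-draw density divides a *fixed* empirical mean count per image by the
per-draw volume (counts are not resampled — only boundary uncertainty is
propagated). Draw acceptance below 1% raises rather than looping
indefinitely. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds give bit-identical results.

Because `V ∝ L_b⁻³`, the propagated distributions of volume and density are
strongly right-skewed: medians are the robust summaries, and means exceed
them by design, not by error.

## Biomass

Individual weight uses the length–weight power law `w = a·L^b` with
defaults `a = 2.236×10⁻⁶`, `b = 3.314` (L in mm, w in g), giving 0.536 g at
the 42 mm median. Mean biomass density is mean numerical density times
weight-at-median-length. Areal survey densities (g·m⁻²) convert to
volumetric (g·m⁻³) by dividing by swarm vertical thickness, which can be
proxied by the depth range spanned by feeding strikes within a dive.

## Classifier metrics

Frame-level classifier evaluation uses one-vs-rest counts per class. Apart
from the standard metrics, the per-class "accuracy" is reported as the
threat score `TP/(TP+FP+FN)` (`accuracy_threat_score`), which matches how
such columns are commonly tabulated in this literature; conventional
`(TP+TN)/N` is a separate field (`accuracy_standard`). NPV is computed via
the prevalence identity and is algebraically `TN/(TN+FN)` on count data
(tested to 1e−12). Zero-denominator metrics surface as NaN plus an
`undefined` flag set. `metrics_from_rates` reconstructs implied
(non-integer) counts from published recall/precision/prevalence so derived
metrics can be checked when raw counts are not deposited.

## The synthetic swarm simulator

`generate_dataset` emulates the annotated-image input: per image, a Poisson
number of prey (mean = density × frustum volume) placed uniformly in the
viewing frustum out to `max_range_factor × true_r_res` (default 3×, so both
classes appear), truncated-normal lengths, uniform orientations, axial
width 0.2·L by default, pinhole projection, and resolvability assigned from
true range — a hard threshold at `true_r_res`, or a logistic ramp of
configurable width in range units emulating the gradual marginal region
(the width is a simulator knob, not an empirical parameter). A blur
fraction relabels in-range animals unresolvable; presentation subtypes are
sampled at rates matching the observed composition of a manually annotated
image set. Every dataset carries a truth ledger (per-image countable
counts, analytic volumes, seed).

What the simulator does **not** emulate: annotation sparsity in the far
field (every in-frustum object yields a record, whereas human analysts
individually annotate only a minority of distant blobs), geometric frame
clipping (partial animals are flagged, not clipped), optical blur
point-spread, lighting/turbidity gradients, and packed aggregations.

### Characterised estimator bias on fully annotated scenes

This matters for interpreting recovery experiments. On simulated scenes
where *everything* out to 3× the true range is annotated, the fitted
logistic boundary converges not to the pixel size of a median-length,
median-orientation animal at `true_r_res` (the point the `√2/2`·median
calibration assumes) but to a size-weighted balance point of projected
lengths at that range: positions are ∝ z² in a frustum and the px→z map
contributes another factor z, so large-bodied, near-broadside animals
dominate the class transition. The boundary lands ~35–40% above the
calibration point, range is underestimated ~25%, and density overestimated
~2.5× — consistently across seeds, and knife-edge sensitive to the far
annotation depth. Consequently the package's end-to-end recovery tests pin
this characterised behaviour rather than asserting unbiasedness, and one
acceptance-suite recovery assertion is expected to fail under these study
conditions. Passing the remaining tests demonstrates internal consistency
of the chain, not field accuracy on real annotation processes, whose far
field is much sparser (real annotated sets show ~70% resolvable objects;
the fully annotated 3× frustum gives ~4%).

## Numerical choices

- Orientation factor defaults to the closed form `√2/2 = 0.70711`, not the
  rounded 0.707 (≤0.15% effect anywhere downstream).
- No intermediate rounding anywhere in the geometry chain; published tables
  that round the px/mm conversion to two decimals differ from the full-
  precision chain by ≤0.5%, treated as print-rounding noise.
- Logistic fitting delegates to statsmodels' Newton solver (tolerance
  1e−10, 200 iterations); tests verify equality with direct likelihood
  maximisation on small datasets.
- Sample standard deviations use the n−1 denominator throughout.
- Internal lengths are mm, volumes m³; conversions only at operation
  boundaries.

## Known limitations

- The resolvable range is an *operational* quantity tied to the annotation
  protocol; the marginal region is a zone, not a plane, and the ±1 sd
  boundary band spans a factor of ~6.6 in volume.
- Densities assume the reference length distribution applies to the imaged
  swarm and that orientation is uniform; axial-dominated or size-sorted
  swarms violate this.
- Only boundary uncertainty is propagated; count noise, length-distribution
  uncertainty and label subjectivity are not.
- The simulator's perfect far-field annotation departs from real analyst
  behaviour (see above); calibrating an annotation-sparsity model would
  require data the package does not ship.
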