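# Methods

## Coordinate model and geometric primitives

The scanner is modelled by four constants: the internal radius of the
circular probe array `R` (default 90 mm), the bed level `h_bed`
(default 182.5 mm), the uppermost probe position `h_uppermost`
(default 158 mm) and the vertical sampling step between scan positions
(default 5 mm). Depth is `z = h_bed − h`, so `z` increases downward and the
shallowest reachable depth is `z_min = 24.5 mm` under defaults. Each
coronal slice is a simple closed polygon with the scanner axis at the
origin of its plane; validity (≥3 distinct vertices, simplicity,
non-degeneracy) is checked with Shapely on construction, and duplicate
consecutive vertices are dropped with a warning.

Distances to the array are evaluated per vertex as `R − hypot(x, y)` and
summarised per slice as min/mean/max. The per-vertex radial form was chosen
over polygon-edge-to-circle distance because reconstructed contours are
dense vertex sets (the generator emits 180 vertices, 2° sampling) and the
proximity phenomenon is a worst-case, per-point effect; an alternative
metric can be substituted at the `distance_to_array` seam.

Areas use the shoelace formula (orientation- and start-invariant). Volumes
integrate the area-vs-depth profile with the trapezoid rule and convert
mm³ → mL. The half-slices above the first and below the last sample are not
extrapolated; at 5 mm sampling of smooth profiles the truncation is well
under the 1% calibration tolerance, and at 1 mm sampling the integrator
matches cylinder/cone/hemisphere closed forms to <0.1%.

## Large-breasts proximity filter

Slices with `d_min(z) < t` are flagged (strict inequality; equality
passes). The rejected region is the maximal contiguous flagged run starting
at the topmost scanned slice; flagged slices below a gap are ignored and
logged, since a physically meaningful rejection is a near-chest prefix.
`Δheight = z_cut − z_top`.

Two thresholds: primary `t_primary = 10 mm` and soft `t_soft = 5 mm`
(`t_soft ≤ t_primary`, so soft flags nest inside primary flags). When the
primary rejection exceeds `max_primary_fraction = 0.5` of the total scanned
extent, the decision is re-evaluated with the soft threshold — very large
breasts sit close to the array over much of their height, and rejecting
most of the scan would destroy its diagnostic value. The excessive-filtering
trigger is defined on rejected *extent* fraction, not slice count, so it is
invariant to the height step. All three values are configuration
(`large_tool.*` keys); the defaults are this package's own calibration
against its phantom family, chosen so that artifact-free phantoms across
300–1800 mL never flag (their skin stays >15 mm from the array) while
planted proximity artifacts (clearance ≤ 5 mm) always do.

## Small-breasts area-profile filter

*Area-steep-decrease.* Adjacent pairs within `top_window = 25 mm` of the
scan top whose relative drop exceeds `r_steep = 0.20` are collected; the
cut is the lower depth of the deepest pair in the topmost contiguous run.
The 20% default separates the base phantom family's largest natural
adjacent drop near the chest (≲7%) from an abrupt widening step (≥34% at
widen factor 1.3).

*Area-breakpoint.* The area profile is fitted with a segmented linear
model: breakpoints on sample boundaries, every segment spanning ≥2 samples,
the exact optimum for each segment count `k` found by dynamic programming
over segment-cost prefixes (segment costs are OLS line fits), and `k ≤ 5`
selected by a BIC-style score `n·ln(SSE/n) + 2k·ln(n)` (the SSE is floored
to keep the score finite on exact fits; ties in optimal breakpoint
placement resolve to the shallowest boundary). The indicator triggers when
the topmost segment is flat — |slope| ≤ 1% of the profile maximum area per
mm — and the next segment decreases at ≤ −2% of the maximum per mm over at
least 10 mm; the cut is the flat segment's last sample. Normalising both
slope thresholds to the profile maximum makes them scale-free across breast
sizes. The −2%/mm and 10 mm defaults sit between the natural taper of the
smooth phantom family (steepest mid-profile slope ≈ −1.4%/mm) and a ramped
widening artifact (≈ −2.7%/mm over ≥10 mm); 10 mm is the smallest extent
resolvable by three samples at the default 5 mm step.

*Routing.* Steep-decrease is evaluated first; when its rejection is absent
or shallower than `min_useful_delta = 5 mm`, the breakpoint indicator is
consulted and, if it triggers, wins. This matches the observed regime where
near-chest distortion produces a plateau rather than a single abrupt drop.

## Scan selection

`z_cut_final = max` of the two tools' cuts — the conservative combination
preserving both exclusions. A lesion annotation with `z_center <
z_cut_final` forces `override_full_scan`: the override is per-breast and
binary; partially relaxing the cut to just include the lesion is
deliberately not implemented. The size category uses the reference volume
when one is supplied (mirroring studies that prefer mammography-derived
volumes where available) and the scan-derived full volume otherwise; the
600 and 1200 mL boundaries belong to the medium class.

## Synthetic phantoms

The generator emulates what a contour-reconstruction pipeline would output
for a pendulous breast, not the breast itself. Base radius profile
(teardrop): `r(ζ) = r_max · cos(π ζ / 2L)^p` with `ζ = z − z_top`, `p =
0.7` — widest at the chest, zero-slope plateau at the top, monotone area
decrease toward the nipple; a hemisphere-cone blend is available as a
second family. Contours narrower than 2 mm are not emitted. Breast length
defaults to `1.6 · V^(1/3)` (V in mm³ → 107 mm at 300 mL, 195 mm at
1800 mL), which keeps artifact-free skin ≥15 mm clear of the array across
the whole volume range; `r_max` is then calibrated so that the stack's own
trapezoid+polygon area rule integrates to the target volume — by
construction, so the ≤1% calibration holds identically.

Artifacts: *proximity* rescales each top-`extent` contour about the scanner
axis so its closest vertex sits exactly at the requested clearance
(construction-by-design, so planted extents are exactly recoverable);
*chest widening* multiplies the top radii by a factor, either abruptly
(exercising the steep-decrease indicator) or blended linearly over a ramp
(exercising the breakpoint indicator). Noise is independent radial Gaussian
per vertex (no spatial correlation). The cohort generator draws sizes
uniformly within small/medium/large bands, caps widening so inflated
contours stay ≥4 mm from the array, and emits a ground-truth table.

What the phantoms do **not** model: non-circular or twisted contours,
reconstruction bias correlated along the surface, partial contour dropouts,
inframammary folds, and the actual dielectric physics. Passing recovery
tests therefore demonstrates that the filters detect the *geometric
signatures* they are designed for, not clinical performance on real
reconstructions.

## Statistics

Wilson score intervals (no continuity correction) for proportions, with
exact 0/1 bounds at k = 0 / k = n; Student-t intervals for means from
summary statistics. Both are reproduced in tests against
statsmodels/scipy as independent oracles. Cohort summaries report per-tool
trigger proportions over the whole cohort, per-criterion shares over each
tool's triggered cases, partial-scan selection and override proportions,
and a size-category × outcome cross-tabulation. Single-member groups report
the mean with an undefined (NaN) interval rather than erroring.

## Problem sizes and determinism

Tests and the acceptance script use phantom stacks of 20–40 slices
(180-vertex contours), cohorts of up to 124 phantoms, 200-replicate noise
studies, and exhaustive-enumeration cross-checks of the segmented fit on
profiles of ≤25 samples; all randomness flows through explicit integer
seeds (NumPy `default_rng` / `SeedSequence`), so every reported number is
bit-reproducible.

## Known limitations

* The proximity cut lands on the first slice *below* the planted artifact,
  so recovered extents carry a systematic upward bias of up to one height
  step — inherent to half-open slice rejection, and within the stated
  one-step recovery tolerance.
* The breakpoint cut snaps to the fitted segment boundary's nearest sample;
  sub-sample breakpoint interpolation is not attempted.
* Degenerate stacks (<2 slices for the proximity tool, <4 for the area
  tool) are rejected rather than guessed at.
* Threshold defaults are calibrated on the synthetic family; real
  deployments should set them from their own reconstruction pipeline via
  the YAML config.
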