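# Methods

This note documents the models, conventions and numerical choices behind
`femora`, the assumptions they rest on, and what the synthetic validation
does and does not demonstrate about real data.

## Imaging model and coordinate conventions

A specimen is a single dry femur scanned in air. Volumes are indexed
`[z, y, x]` with z proximal → distal, y posterior → anterior, x medial →
lateral. Pixel centres sit at integer indices; physical position is
`index × spacing`. Left femurs are mirrored about the sagittal axis at
load time so "lateral" means +x for every specimen; this makes the lateral
pattern taxonomy well defined when pooling sides. Sections are taken
perpendicular to the scanner z axis, assuming the bone was positioned on
its three most posterior contact points during scanning; no re-orientation
or rotation correction is applied.

Diaphyseal levels are planned between two user-supplied landmark slice
indices (lower end of the lesser trochanter; adductor tubercle). The span
is divided into nine equal segments and level positions round half-up to
the nearest slice. No sub-slice interpolation is performed: at the
0.5 mm slice thickness of the intended protocol the placement error is a
fraction of a percent of the diaphyseal length, far below the measurement
noise of the downstream parameters.

## Threshold and segmentation

The cortical threshold is derived from the pooled HU frequency table of
all ten levels, binned at 10 HU (configurable). The air peak is the
highest-count bin below −500 HU, the bone peak the highest above
+200 HU; each peak mean is refined as the count-weighted bin-centre
average over ±5 bins, which is robust to marrow/soft-tissue mass in the
mid range. The upper histogram edge is extended one spare bin beyond the
maximum so the top value is not absorbed into a right-closed final bin
(which would bias the bone peak half a bin low). The threshold is the
midpoint of the two peak means — symmetric and parameter-free — and is
recorded in every output so alternative formulas can be compared.

Segmentation per section: foreground is `HU ≥ threshold`; the cortex is
the largest 8-connected foreground component (isolated specks are
discarded); the section region fills all interior holes (4-connected
background duality, so neither region nor cavity can leak through diagonal
gaps); the medullary cavity is the largest interior hole, and smaller
holes (trabecular voids, common in dry archaeological bone) are merged
into the cortex. Sections without any cavity are flagged *solid*:
thickness is reported as undefined rather than inventing an inner surface,
and such sections are excluded from thickness statistics with a warning.

Boundary point lists are produced by Moore-neighbour tracing with Jacob's
stopping criterion — ordered, closed 8-connected loops of pixel
coordinates on the periosteal (outer) and endosteal (cavity) surfaces.

## Morphometric parameters

Areas follow the point-counting convention: pixel count × pitch². The
periosteal border length is the number of distinct traced surface points ×
pitch. This convention is kept for comparability with spreadsheet-based
implementations of the method, but it is biased for oblique boundaries:
the traced point count approximates the chessboard (L∞) perimeter, which
for a circle is 8r/√2 ≈ 0.90 × 2πr, i.e. a systematic ≈10 % undershoot.
The Crofton-formula perimeter (within ~0.5 % on a digital circle) is
logged alongside in every record as `pbl_geometric`.

Thickness at each periosteal point is the minimum Euclidean distance to
any endosteal point, between pixel centres, with no sub-pixel surface
interpolation; the per-section summaries are the mean and maximum over all
periosteal points. A k-d tree accelerates the query; it is exactly
equivalent to the brute-force all-pairs minimum (asserted in tests).
Measured thickness is accurate to about one pixel. Note that the
minimum-distance definition measures chord distances: a narrow
linea-aspera ridge is measured to its own edge, not radially, so the
maximum thickness of a bump of angular width below roughly twice its
height/radius ratio is underestimated relative to the radial profile.

Standardization divides every parameter (areas included) by a stated
reference length — femoral total length or diaphyseal length, chosen
explicitly per analysis — so standardized areas keep one leftover length
dimension (mm²/mm). CI is dimensionless and untouched. Morphometrics
default to the eight interior levels 2–9; curvature uses levels 1–9;
level 10 is extracted but excluded from curvature.

## CMD and curvature

The CMD (central mass distribution) of a section is the intersection of
the vertical and horizontal lines each splitting the section area into
equal halves, computed on the *filled* section region (configurable to
cortex pixels only). The split lines are axis-aligned, consistent with
per-axis shift reporting. Each coordinate is found by linear interpolation
of the cumulative column/row mass within the crossing column; scanning
from both ends and averaging makes the result exactly mirror-symmetric and
places the split mid-gap for tie cases (two disjoint equal blobs).

The deviation profile takes the 3-D line through the level-1 and level-9
CMDs, parameterized by z, and reports per-axis residuals dx, dy at each
level — zero at both endpoints by construction, and invariant under rigid
translation. With evenly spaced levels this per-axis 3-D reading coincides
with measuring on 2-D projections. The anterior curvature is summarized as
the maximum normalized dy over levels (the profile itself is also
emitted). Lateral classification quantizes dx at levels 2–8 with a
deadband ε (default 0.3 mm ≈ 1–2 pixels, exposed as a CLI flag): all
non-negative → primary lateral, all non-positive → primary medial, one
sign change → S-shaped named by its proximal limb, anything else (or all
zero) → indeterminate. The deadband is a declared convention; published
descriptions of the taxonomy do not state a tolerance.

## Statistics

*Normality*: chi-square goodness-of-fit against a normal with the sample
mean/SD, equal-probability bins (default `2 n^0.4`), df = bins − 3. The
test family is a documented choice; the method description names only "a
goodness-of-fit test".

*Split-plot ANOVA*: cohort is between-subject, diaphyseal level
within-subject, specimen nested in cohort as the between error stratum.
The decomposition is computed directly from cell means (sums of squares
add to the total within 1e−10; F and p agree with `pingouin.mixed_anova`
to machine precision). Sphericity is not corrected by default; a
Greenhouse–Geisser option is provided. Specimens missing any level are
excluded listwise with a warning. Scheffé contrasts compare cohort means
of the per-specimen level means against `(g−1) F(α; g−1, N−g)` using the
between-subject mean square scaled to subject means; by construction they
are never more liberal than an unadjusted pairwise F. Degenerate inputs
with a zero error stratum (noise-free synthetic cohorts) yield F = 0 or ∞
rather than a division error.

*PCA* is computed on the correlation matrix (the six parameters — five
length-standardized factors plus CI — have heterogeneous units), with each
component's sign fixed so its largest-magnitude loading is positive.
Published eigenvector tables for the original cohorts are treated as a
structural reference only (6 variables × 2 components); they cannot be
reproduced without the original specimen data.

*Chi-squared independence* on the cohort × pattern table uses the Pearson
statistic without continuity correction, dropping all-zero rows/columns
and warning when expected counts fall below 5 (they do for the published
Jomon rows; the significance statement survives by a wide margin).

*Period grouping*: each radiocarbon-dated specimen is summarized by the
midpoint of its highest-probability 68.3 % calibrated interval and cut at
6,000 cal BP — the midpoint of the gap between the two stated period
ranges; any boundary inside the gap gives the same grouping. Radiocarbon
calibration itself is out of scope; the packaged intervals are consumed
as published.

## Phantom generator

Phantoms emulate the study conditions: a bent hollow cortical tube in air
with a bimodal HU histogram (air −1000, cortical bone +1200, marrow +100,
Gaussian noise SD 50 by default), 0.2 mm in-plane pitch, 0.5 mm slices.
Slices are circular (optionally elliptical) annuli centred on a curved
centreline parameterized by `s = (z − z1)/(z9 − z1)`: the anterior bow is
`A_y sin(πs)` (a primary curve peaking mid-diaphysis) and the lateral
offset is a signed half-sine for the primary modes or a signed full sine
for the S modes, so both vanish exactly at the level-1/level-9 baseline
endpoints. A rectangular angular thickening of the cortex at the
posterior aspect emulates the linea aspera. Ground truth is evaluated
from closed forms (annulus areas, eccentric-annulus min/max thickness
`t ∓ d`, centreline CMDs and deviations), never from the rendered voxels.

The default stack is 91 slices (a 45 mm segment) rather than a full-length
femur: the pipeline is per-section, so level geometry, not physical
length, is what the validation exercises, and the smaller stacks keep the
full classification study (4 modes × 50 noisy replicates, end-to-end)
inside a couple of minutes on one CPU.

What the phantoms do *not* emulate: partial-volume blur at surfaces
(membership is decided at pixel centres, so rendered boundaries are
exact), trabecular texture, beam hardening and scanner artefacts, and
cortical porosity. Consequently, passing recovery tests shows the
geometry and bookkeeping are right, not that the pipeline is robust to
every real-scanner effect.

One knife-edge of the default HU palette is documented deliberately: the
derived threshold (midpoint of air and bone peaks, ≈100–105 HU) sits at
the marrow HU default of +100. With noise SD 50 about half the cavity
pixels cross the threshold, and under the prescribed segmentation rules
the endosteal boundary is then unrecoverable (the speckle percolates and
attaches to the cortex). Curvature and pattern classification are immune —
the CMD uses the filled section region, which is exact under this noise
level — and that is what the noisy validation tests. Thickness and area
recovery are validated on noise-free renderings; real dry-bone scans,
whose cavities contain air (≈ −1000 HU) rather than mid-range marrow, do
not sit on this knife-edge.

## Reproducibility

All randomness flows through explicit seeds; cohort rendering derives
per-specimen seeds deterministically from a master seed via
`SeedSequence.spawn`. Noise-free phantoms segment bit-identically across
runs, and the CLI writes byte-identical CSVs for a fixed configuration
and seed. Simulation sizes used by the validation: 20 random blob masks
for the CMD oracle; 50 replicates per lateral mode for classification
accuracy; 1000 null and 400 shifted replicates for ANOVA calibration;
n = 500 draws for the planted-block PCA check.
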