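# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic data does and does not emulate, and the
design decisions taken where the construction was genuinely open.

## Phantom model

A phantom is a piecewise-constant anatomy times a smooth bias field plus
white Gaussian noise, quantized to 8 bits:

* **Breast profile** — a quarter-ellipse anchored at the top-left image
  corner (canonical left orientation, chest wall at column 0) with
  configurable vertical/horizontal semi-axes.  Default canvas 256×256 px,
  semi-axes (230, 150).
* **Pectoral wedge** — the region left of the straight line from
  (row 0, col 0.45·b) tilted `pectoral_angle` degrees from vertical
  (default 30°), clipped to the breast.  Its analytic boundary is exposed
  (`pectoral_geometry`) and is the oracle for the landmark tests.
* **Lesions** — discs with one of three radial intensity profiles:
  `circumscribed` (hard disc at +contrast), `indistinct` (Gaussian falloff,
  truncated at 1.5 r), `spiculated` (disc plus eight radial spikes).  The
  truth mask is always the nominal disc.  The margin determines the keyword
  set (circumscribed → Circum/Benign/BI-RADS 2; indistinct →
  Indist/Malignant/BI-RADS 4; spiculated → Spicul/Malignant/BI-RADS 5; no
  lesion → Normal/BI-RADS 1).
* **Bias field** — a low-order polynomial surface scaled so its
  multiplicative effect peaks at `bias_amplitude` gray levels; exists so the
  contour stage faces intensity inhomogeneity.
* **Noise** — additive Gaussian, `noise_sigma` gray levels, one seeded
  generator per call (no global state; identical spec ⇒ bit-identical
  image).

Default study conditions used by the tests and the acceptance script:
segmentation accuracy is scored on a noise-free 192×192 phantom with a
single circumscribed lesion (radius 15 px, contrast 50); edge-detection
recall at noise σ = 4; transaction cohorts use 4 planted rules with
disjoint 3-item bodies over a 12-item universe, 200 training / 100 held-out
transactions, penetrance 1, noise rate 0.05.

The phantom intentionally omits: parenchymal texture, label/annotation
artifacts, skin lines, compression effects and clinically realistic lesion
morphology.  Passing tests therefore demonstrate the correctness of the
algorithms under their geometric assumptions, not clinical performance.

**Transaction generator** — each transaction picks a planted rule uniformly,
carries its full body with probability `penetrance`, is labeled with the
rule's head, and then each feature item's membership is flipped
independently with probability `noise_rate`.  Keyword labels are never
corrupted.

## Pre-processing

1. **Breast contour**: the image is divided through a heavy Gaussian blur
   (σ = max dimension / 4) to remove smooth bias, thresholded (Otsu) for
   initialization, and evolved with a two-phase morphological Chan–Vese
   region energy (≤ 200 sweeps).  The brighter phase's largest 4-connected
   component, hole-filled, is the breast mask.  If the centroid falls in the
   right half the image and mask are mirrored to canonical left orientation.
   A constant or foreground-free image raises a "no breast region" error.
2. **Landmarks**: x1/x2 are the leftmost/rightmost breast pixels on the top
   boundary row, y1/y2 the lowest breast pixels on the left/right edges (y2
   is kept for completeness but unused).  x3 (resp. y3) is the first pixel
   along the straight raster walk x1→x2 (x1→y1) whose forward intensity
   difference exceeds max(10 gray levels, 2 × median |forward difference|);
   walks follow straight segments, not the curved boundary.  If neither walk
   shows a jump the caller treats the whole breast as the AOI.
3. **Pectoral removal**: 4-connected seeded region growing from x1 with
   homogeneity |I(p) − running region mean| ≤ T (default T = 16 gray
   levels), intersected with the half-plane on x1's side of the line through
   x3 and y3, then opened with a radius-3 disc to smooth the rough corner
   edges.  AOI = breast − pectoral.  A degenerate line (x3 = y3) falls back
   to the raw SRG region with a warning.

## Edge detection

Every 3×3 window is projected on the nine outer products of the orthogonal
basis u0 = (1,1,1), u1 = (−1,0,1), u2 = (1,−2,1), normalized by ⟨O,O⟩ so
β00 of a constant image is that constant.  β01/β10 are the horizontal and
vertical gradient (AC) coefficients; β22 is the highest-order coefficient
and, under white noise with Var β22 = σ²/36, a pure noise gauge — the noise
variance is estimated as σ̂² = 36 · mean(β22²) pooled over the AOI.

A window is an edge candidate when

* the variance-ratio statistic F = 3(β01² + β10²)/σ̂² exceeds the F(2, N)
  critical value at the chosen significance (default 0.05), N the number of
  AOI windows pooled; and
* the sign of the dominant gradient coefficient agrees across the three
  windows along the edge direction (a run-type consistency check standing in
  for the Nair test, whose original statistic is not reproduced here).

The final edge set keeps candidates with magnitude E = √(β01²+β10²) ≥ t*,
where t* maximizes SNR(t) = mean(E | E ≥ t)/(std(E | E < t) + 1e−6) over the
50th–99th percentile grid of E inside the AOI.  For a noise-free image
(σ̂² = 0) any nonzero AC energy is treated as signal.  The F-stage false
positive rate is calibrated: on iid noise its candidate count matches
significance × N up to the correlation induced by overlapping windows.

## Edge refinement (DRLSE)

Closed edge regions (morphological closing radius 2, hole fill) provide
seed components; each is eroded by 2 px so the negative balloon force pushes
the front outward onto the detected edge.  Each component evolves
separately under the distance-regularized update

    φ ← φ + Δt [ μ div(d_p(|∇φ|)∇φ) + λ δ_ε(φ) div(g ∇φ/|∇φ|) + α g δ_ε(φ) ]

with the double-well potential (d_p → 1 at |∇φ| → 0), edge indicator
g = 1/(1 + |∇(G_σ * I)|²), and defaults Δt = 1, μ = 0.2 (Δt·μ < 0.25 for
stability), λ = 5, α = −3, ε = 1.5, σ = 1.5, c0 = 2, ≤ 300 iterations with
early stop when the front changes by < 0.05% of pixels per 20 iterations.
Zero-level components inside the AOI with area ≥ 30 px become ROIs.  The
signed-distance profile |∇φ| ≈ 1 is maintained on the Dirac-active band
|φ| ≤ ε; outside it the double-well deliberately keeps φ flat at ±c0, so
that is the band on which the property is asserted.

## Texture features (1037 slots)

All families crop to the mask bounding box and replace out-of-mask pixels
with the in-mask mean, making every slot invariant to content outside the
mask.  Shape statistics use the conventions: variance with ddof = 0,
skewness/excess kurtosis defined as 0 when the variance vanishes, entropy
over 16 equal-width bins of the observed range (log base 2), energy =
mean square, RMS = root mean square, MAD = mean absolute deviation.

* **A (113)** — the nine 3×3 coefficient planes restricted to the mask, 12
  statistics each (mean, variance, skewness, kurtosis, energy, entropy, min,
  max, range, median, MAD, RMS) plus 5 first-order ROI statistics.
  Requires ≥ 9×9 px.
* **B (448)** — two-level 2×2 orthonormal sub-band decomposition (basis
  (1,1)/√2, (−1,1)/√2, decimate by 2, odd trailing rows/cols cropped; each
  level-1 band decomposed again) → 16 level-2 sub-bands × (14 statistical =
  the 12 above + p10/p90, plus 14 spectral = total power, spectral entropy,
  8 radial and 4 angular band energies of the 2-D power spectrum).
  Orthonormality gives exact energy conservation across a split (checked by
  a Parseval test).  Requires ≥ 16×16 px.
* **C (336)** — 5×5 sliding-window bivariate transform on the degree-0..4
  Gram (discrete Chebyshev) basis; the DC plane is dropped and the remaining
  24 planes get the 14 statistical measures.  Every slot is exactly 0 on a
  constant region.  Requires ≥ 10×10 px.
* **D (140)** — central-difference gradient magnitude quantized to 8
  equal-width levels over the masked range; symmetric normalized GLCMs for
  4 directions × distances 1..5 counting only pairs with both endpoints in
  the mask; 7 measures each (contrast, correlation, energy, homogeneity,
  entropy, dissimilarity, maximum probability).  A degenerate point-mass
  matrix has correlation 1 by convention; an offset with < 2 valid pairs
  zeroes that matrix's measures with a warning.  Requires ≥ 8×8 px.

The four-family layout is a fixed construction chosen to hit the family
cardinalities exactly; slot names (e.g. `A.b01.energy`, `B.LHHL.radial3`,
`D.d45r2.contrast`) are stable across training and test paths, and the
train/test layouts are identical by construction.

## Discretization and selection

Per feature: candidate cuts are midpoints between consecutive distinct
sorted values whose class-label sets differ; cuts are added greedily (ties
broken toward the lower cut), each step choosing the candidate that most
decreases the single-feature inconsistency
I_f = (1/N) Σ_patterns (count − max class count), stopping at I_f = 0, no
improvement, or `max_cuts` (default 7).  A feature is selected iff
I_f ≤ mean(I) and C_f ≤ mean(C) (both criteria, since a "consistent"
feature should be both predictive and parsimonious).  Intervals are
right-open; a value equal to a cut falls right; test-time values outside the
training range warn and use the edge interval.  Class labels are whole
keyword sets treated atomically.  Inconsistency is tracked per feature
during growth; the joint pattern table is only a reporting quantity.

## Rule mining

Frequent itemsets come from an FP-tree built over items pre-pruned below
the support floor, ordered by descending support (ties lexicographic on the
item's string form), grown recursively through conditional trees; counts
are exact.  An optional `max_len` bounds the growth to itemsets of at most
that many items — the bounded portion of the tree.  This bound exists
because discretized texture vectors of same-class images share long runs of
identical (feature, interval) items, making exhaustive enumeration
exponential; the image pipeline mines with `mining_max_len = 4` and itemizes
only the `max_selected_features = 16` most consistent selected features
(lowest inconsistency, then fewest cuts, then name).  Both caps are
configurable; library users mining small transaction cohorts get the exact
(unbounded) behaviour by default.

Candidate rules split a frequent itemset into a keyword-free body and a
nonempty all-keyword head with confidence ≥ `minconf` (default 0.8;
`minsup` default 0.05).  The representative filter drops any rule inside
the cover of another candidate, cover(X→Y) = {X∪Z → V : Z ⊆ Y, ∅ ≠ V ⊆
Y∖Z}.  For class-constrained rules a cover relation forces equal bodies (a
body extension would need keyword items), so the filter is computed by
body-grouped head-maximality, which is equivalent and near-linear; the
general cover predicate is retained and the equivalence asserted in tests.
Output order is total: support desc, confidence desc, body size asc, then
lexicographic.

## AMIDE

For each distinct head h: a rule is a full match if its body ⊆ test
itemset, a partial match if the intersection is proper and nonempty, a
non-match if empty.  Condition 1 accepts at w1 = nM/(nM+nN) ≥ α; only if it
fails, Condition 2 accepts at w2 = (nM+nP)/(nM+nP+nN) ≥ δ (partial matches
count as evidence).  Zero denominators score 0 and reject — a head without
a single match cannot be suggested.  Defaults α = δ = 0.5 (configurable; no
canonical values exist).  Heads are compared by set equality, and accepted
heads are sorted by weight, Condition 1 before 2, then smaller head, then
lexicographically, so the diagnosis is deterministic.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run phantoms at 160–256 px,
image cohorts of 8–16 phantoms and transaction cohorts of 30–200 rows —
sizes chosen so the full synthetic study completes in well under a minute
while every assertion (Dice ≥ 0.90, ≥ 90% keyword recovery, exact oracle
equivalences) is made at the stated thresholds.  Every stochastic quantity
is driven by explicit seeds; reruns are bit-identical.

## Known limitations

* The Nair-test and NANO internals and the "density" FP-tree variant are
  not published in reproducible form; the run-check, the boundary-point
  greedy discretizer and the pre-pruned FP-tree are documented surrogates
  whose input/output contracts — not their internals — are asserted.
* One printed family cardinality differs between the training (336) and
  test (280) descriptions of the bivariate family; 336 is used on both
  paths so vectors align.
* Per-ROI diagnosis: an image-level result is the union of its ROI reports.
* The phantom's realism limits: results on it say nothing quantitative
  about screening mammograms.
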