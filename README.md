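# cimidx

A local, testable computer-aided diagnosis (CADx) pipeline for MLO-view
mammograms built around an associative classifier.  It is aimed at
researchers who want a transparent, fully reproducible implementation of the
classic rule-based CADx chain — from raw grayscale mammogram to a weighted
set of diagnosis keywords — without any cloud or service plumbing, and with a
synthetic phantom module so every stage can be exercised and scored without
access to clinical archives.

## What it computes

The training path turns labeled images into a rule base:

1. **Pre-processing** — a two-phase region-based level set isolates the
   breast profile; six landmarks (x1, x2, y1, y2, x3, y3) on the contour plus
   seeded region growing remove the pectoral muscle, leaving the area of
   interest (AOI).
2. **Segmentation** — every 3×3 window is projected onto an orthogonal
   polynomial basis; an F test against a pooled noise estimate and a
   sign-run consistency check separate edge from noise responses, with the
   global threshold chosen to maximize a signal-to-noise objective; a
   distance-regularized level set (DRLSE) refines closed edge regions into
   ROI masks.
3. **Features** — each ROI yields a fixed 1037-slot texture vector in four
   families: orthogonal-polynomial statistics (113), two-level sub-band
   statistical + spectral measures (448), 5×5 bivariate orthogonal-polynomial
   statistics (336), and gradient gray-level co-occurrence measures (140).
4. **Discretization + selection** — per-feature greedy boundary-point cuts
   minimize the inconsistency I_f = (1/N) Σ (pattern count − max class
   count); a feature is kept when I_f and its cut count are both no worse
   than the global averages.  Selected features become (name, interval)
   items.
5. **Rule mining** — an FP-tree over the itemized transactions yields exact
   frequent itemsets; class-constrained rules (keyword-free body → keyword
   head) at the support/confidence floors are reduced to *representative*
   rules via the cover operator.

The test path runs stages 1–4 on a new image (no keywords) and scores the
itemset with **AMIDE**: for each candidate head *h*, with nM/nP/nN the full /
partial / non-matches of the rules carrying *h*,

    w1 = nM / (nM + nN)            (Condition 1, accept when w1 >= alpha)
    w2 = (nM + nP) / (nM + nP + nN)  (Condition 2, accept when w2 >= delta)

so a head with 2 full matches and 1 non-match is accepted at weight 2/3.
AMIDE can return several keyword sets, ranked by weight.

## Worked example

```python
from cimidx.phantom import (PhantomSpec, Lesion, PlantedRule,
                            TransactionCohortSpec, generate_phantom,
                            generate_transactions)
from cimidx.pipeline import PipelineConfig, diagnose_transaction, train_from_transactions
from cimidx.preprocess import preprocess_image

# image stages on a synthetic phantom with analytic ground truth
spec = PhantomSpec(width=192, height=192, breast_profile=(170.0, 110.0),
                   lesions=(Lesion(center=(110, 55), radius=15.0,
                                   contrast=50.0),))
img, truth = generate_phantom(spec)
contour, cp, aoi = preprocess_image(img)
print(aoi.pectoral_mask.sum(), truth.pectoral_mask.sum())  # 2137 2190

# associative classification on synthetic labeled transactions
rules = (PlantedRule(body=frozenset({0, 1, 2}),
                     head=frozenset({"Circum", "Benign"})),
         PlantedRule(body=frozenset({3, 4, 5}),
                     head=frozenset({"Spicul", "Malignant"})))
cohort = TransactionCohortSpec(n_transactions=200, item_universe=8,
                               keyword_universe=frozenset(
                                   {"Circum", "Benign", "Spicul", "Malignant"}),
                               planted_rules=rules, noise_rate=0.05, seed=1)
model = train_from_transactions(generate_transactions(cohort))
diag = diagnose_transaction(frozenset({0, 1, 2}), model.rulebase)
print(diag.accepted[0].head, round(diag.accepted[0].weight, 3))
# frozenset({'Benign', 'Circum'}) 1.0
```

The pectoral mask found by the pipeline overlaps the analytic wedge almost
exactly (Dice ≈ 0.99), and a test itemset carrying a planted body is returned
with its planted keyword head at weight 1.0 (every rule for that head matched
in full).

There is also a CLI mirroring the stages:

```bash
cimidx phantom --out-dir phantoms --n-images 4 --seed 0
cimidx preprocess phantoms/phantom000.pgm --out-dir prep
cimidx segment phantoms/phantom000.pgm --aoi prep/phantom000_aoi.pgm --out-dir seg
cimidx train --images-dir phantoms --out-dir model
cimidx test --image phantoms/phantom001.pgm --scheme model/scheme.json \
            --rulebase model/rulebase.json --out report.json
```

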