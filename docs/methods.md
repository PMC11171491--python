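# Methods

`cxreval` implements the arithmetic of a two-phase evaluation of a
bounding-box AI assistant for chest radiographs (CXRs): a standalone
phase, in which an ensemble of object detectors is scored against a
multi-annotator consensus reference, and a multi-reader multi-case
(MRMC) phase, in which nine readers interpret cases with and without AI
assistance. This note describes the models and conventions the package
adopts, the places where the underlying protocol was ambiguous and a
choice had to be made, and what the synthetic study generator does and
does not emulate.

## Box geometry

All localization is done with axis-aligned boxes on an integer pixel
grid, stored corner-form `(x_min, y_min, x_max, y_max)` with the origin
at the top-left and a **half-open** convention: the box covers
`[x_min, x_max) × [y_min, y_max)`. Under this convention "at least one
pixel of overlap" is a discrete predicate — `intersection_area(a, b) >= 1`
— and boxes that merely share an edge or corner do *not* overlap. The
protocol this mirrors never states a convention; half-open was chosen
because it makes the one-pixel rule exactly testable against pixel
enumeration. Consensus box averaging rounds each mean coordinate half-up
to stay on the grid; since the coordinate-wise mean preserves the
ordering of min and max coordinates, the averaged box is always valid.

The protocol's phrase "the Jaccard distance … is non-null" plainly
intends a non-null *overlap* (Jaccard index > 0); the package implements
the overlap reading and exposes `jaccard` as the index.

## Ensemble vote

Five detector models each emit scored, labelled boxes. Per pathology,
the union of all models' boxes is partitioned into connected components
of the pairwise-overlap graph. A component is retained when its members
come from at least `min_support` (default 3) **distinct models** —
pairwise overlaps suffice; no common triple intersection is required,
which keeps the rule well defined for chains of boxes. Each retained
component contributes exactly one output box: its highest-scoring
member, with ties broken toward the lowest model id and then the
smallest corner tuple so results are deterministic. Score thresholds are
applied **after** the vote ("a last step"), so sub-threshold boxes still
contribute support; only emitted boxes are filtered.

Threshold calibration sweeps all midpoints between adjacent distinct
validation scores and maximizes Youden's J = sensitivity + specificity −
1, ties toward the higher (more conservative) threshold. The protocol
names sensitivity, specificity and mAP as calibration metrics without an
aggregation rule; J was fixed as the objective because it is the
standard single-number compromise of the first two, and mAP-based
calibration is out of scope.

## Consensus ground truth

Three annotators independently draw minimal boxes. Per pathology,
overlap components are formed over all annotators' boxes; a component
whose members come from at least ⌈(n+1)/2⌉ distinct annotators (2 of 3)
yields one reference finding whose box averages **one box per agreeing
annotator** and whose support is the distinct-annotator count. Averaging
only the agreeing annotators — not a dissenting disjoint box — was
chosen because averaging in a disjoint box could produce a consensus box
overlapping nothing. When one annotator contributed several boxes to a
component, the box with the largest total overlap against the other
annotators' boxes represents them (ties: smallest corner tuple); the
protocol is silent here and this rule is the package's own. An image is
reference-negative for a pathology iff no finding of that pathology
survives the majority; explicit absence votes are not modelled.

## Image-level confusion classification

Per pathology, each image falls into exactly one of TP / FN / FP / TN: a
reference-positive image is TP when any predicted box of the pathology
overlaps any reference finding and FN otherwise; a reference-negative
image is FP when any predicted box of the pathology is present and TN
otherwise. The precedence matters: a reference-positive image with only
stray, non-overlapping predictions is a **miss (FN), not a false
alarm** — this is the only reading under which per-pathology counts
always partition the designed 500 positive / 1000 negative images, which
the published count table satisfies row by row. Lesion-level counting
(FROC) is out of scope.

## Metric panel and intervals

From the counts: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), FPR = 1 − specificity, FNR = 1 −
sensitivity. A metric with a zero denominator is reported as undefined
(`None`) with a warning, never coerced to 0 or 1. Binomial proportions
get Wilson score intervals (z = 1.959964 at 95%); at the boundaries
(k = 0 or k = n) the closed form is exact and the implementation returns
exactly 0 or 1. ROC AUC is the rank statistic (probability a random
positive outscores a random negative, ties half) and therefore requires
scores; it is never derived from a single operating point, and the
published per-pathology AUCs are treated as score-based inputs, not
quantities reproducible from the count table. AUC intervals use the
stratified percentile bootstrap (resampling within each class, 2000
resamples by default), which also guarantees every resample contains
both classes. Study-level aggregates are unweighted macro-averages over
the six pathologies, which is the convention that reproduces every
published overall figure.

## Reader study

Per reader and condition the pipeline computes mean reading time,
per-anomaly sensitivity/specificity macro-averaged over the six
pathologies (a pathology with no positive or no negative case in a
session is excluded with a warning), and a rank AUC over per-image
confidences. Conditions are compared with a **Welch** (unequal-variance)
two-sided t-test — the protocol says only "t-test", and at the published
effect sizes the variant does not change any conclusion. Reported
per-condition dispersion is the between-reader SD, variance, and a
normal-theory 95% half-width (1.96·sd/√n), which reproduces the
published CI columns. Percent change is 100·(aided − unaided)/unaided to
two decimals; note the published specificity means give +2.96% by this
formula.

The AUC sample-size calculation finds the smallest equal per-group n
for which a two-sided z-test of the AUC against the null value reaches
the requested power, with Hanley–McNeil variance
(Q1 = A/(2−A), Q2 = 2A²/(1+A)) evaluated under the null for the
significance term and under the alternative for the power term. At
α = 0.05, β = 0.20, alternative AUC 0.80, this yields **14 positive +
14 negative cases per anomaly**. Commercial calculators that report 13
per group evaluate a slightly different variant (e.g. one-sided α or
alternative-variance-only); the package does not add ad-hoc constants to
match them.

## Synthetic study generator

The generator emulates the statistical structure of the study, not its
pixels: no images are rendered and lesion placement is uniform rather
than anatomical, so passing tests demonstrate the correctness of the
*arithmetic* under the study design, not detector performance on real
radiographs.

Design and defaults (all configurable):

* **Composition** — per pathology, 500 positive images with one lesion
  each plus a shared pool of 1000 lesion-free negatives (each
  pathology's evaluation set is its own positives plus the shared
  negatives, so every count row sums to 500/1000 by design). Image grid
  1024×1024; lesion sides log-uniform in 48–384 px, a realistic range
  from nodule-sized to effusion-sized findings relative to a standard
  radiograph matrix.
* **Detectors** — five profiles with sensitivities 0.955–0.965.
  Co-detection of the same lesion across models uses a Gaussian copula
  with correlation 0.8: a shared per-lesion difficulty latent plus
  per-model noise, thresholded so the marginal detection rate equals
  each model's sensitivity exactly for any correlation. False positives
  have two parts: per-model independent Poisson boxes (0.15/image) and
  shared "distractor" sites (Poisson 1.0/image, each fired on by each
  model with probability 0.9). The shared part is what lets a 3-of-5
  vote still produce false positives at a realistic per-pathology
  image-level rate (~13–16% of negatives), the way correlated real
  models do; with the shared rate set to zero the vote suppresses false
  positives almost completely, and the tests verify both regimes. True
  boxes are jittered (sd 6 px) and scored Beta(8, 2); false boxes score
  Beta(2, 5), giving per-pathology AUCs in the mid-0.9s.
* **Annotators** — three profiles, jitter sd 4 px, miss and spurious
  probabilities 0 by default: the reference readers *define* truth in
  this design, and noiseless-presence defaults keep the designed
  composition exactly recoverable. Non-zero miss rates are used in tests
  to verify the closed-form 2-of-3 loss rate 3p²(1−p) + p³.
* **Readers** — nine readers, two sessions over an interleaved 905-image
  pool (per-anomaly positive counts 77/60/32/16/37/43 plus 640
  normals). Each reader draws a personal operating point (between-reader
  sd 0.02), target AUC (sd 0.07 unaided / 0.05 aided), and mean reading
  time (22.9 ± 2.3 s unaided, 14.7 ± 1.3 s aided; log-normal within
  reader, CV 0.35). Calls are Bernoulli at the operating point;
  confidences come from a binormal model calibrated to the target AUC
  and are coupled to the calls only through the ground truth. This
  decoupling is deliberate: the published unaided operating point
  (0.769, 0.946) lies *above* any proper ROC curve with AUC 0.759, so no
  model in which calls are thresholded confidences can honour both
  numbers at once.
* **Metadata** — age N(49.9, 23) clipped to [0, 105], 54.5% female,
  manufacturer shares 17/11/38/28/6%.
* **Determinism** — one seed drives everything through
  `numpy.random.SeedSequence` spawns; identical config + seed gives a
  byte-identical bundle.

## Numerical and testing choices

* Component finding is union-find over the pairwise overlap matrix;
  output order is fixed (label enumeration order, then score/corners) so
  permuting inputs never changes results.
* File formats serialize boxes as COCO-style `[x, y, w, h]` and convert
  at the I/O boundary; floats are written with `%.17g` and read with
  pandas' round-trip parser so write→read is an exact identity. Parsing
  is strict by default because silently dropped records corrupt
  confusion counts.
* Stochastic recovery tests run at fixed seeds. Where a test makes
  several simultaneous interval checks (five detector sensitivities,
  eight reader-study means), per-comparison intervals are Šidák-widened
  so the *family* is a 95% check; otherwise a correct simulator would
  fail such a test in a large fraction of runs.
* The scaled-down study used in most tests keeps the full structure at
  40 positive / 80 negative images per pathology; the acceptance-level
  tests and script run the full 500/1000 design (a few seconds of
  compute).

## Known limitations

* Lesion-level (FROC) metrics, mAP, weighted box fusion, and
  non-maximum-suppression variants are not implemented.
* Annotator skill modelling (latent-truth fusion) is out of scope; the
  consensus is purely rule-based.
* The MRMC comparison uses plain Welch t-tests, matching the protocol;
  correlated-reader variance models (Obuchowski–Rockette,
  Dorfman–Berbaum–Metz) are deliberately absent.
* Reader AUC requires per-image confidences; with binary-only records
  the AUC row is skipped with a warning.
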