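# Methods

## The statistic and its decision rule

On an immediate post-thrombectomy NCCT slice, let `L` be the maximum
Hounsfield-unit (HU) value over all post-interventional cerebral
hyperdensities (PCHDs) and `S` the maximum HU of the venous sinuses on the
same scan. The maximum-density ratio is `RMDV = L / S`, and the test
predicts hemorrhagic transformation (HT) when `RMDV > 1`, contrast
extravasation (CE) when `RMDV ≤ 1` (strict inequality at 1; a lesion
exactly as dense as opacified venous blood is read as contrast). The
rationale: sinus blood carries the highest achievable pure-contrast
density, so only blood products can push a lesion above it. When a patient
has several PCHDs the single global maximum enters the ratio; per-site
analysis is deliberately out of scope.

Ground truth comes from the 24 h follow-up scan: iodinated contrast washes
out within about a day, so a hyperdensity that is eliminated at follow-up
is CE and one that persists is HT. "Eliminated" is operationalized with
the same threshold used for detection: the case is CE when no pixel of the
immediate-scan lesion footprint retains a contralateral excess of at least
5 HU on the follow-up slice.

## Measurement procedure on a raster

Detection uses the strictest reading of the clinical rule "denser than the
unaffected contralateral side": a pixel is hyperdense when it lies in the
brain mask and exceeds its mirror pixel (reflection about the midline
column) by at least `min_excess` = 5 HU. 8-connected components with at
least `min_area` = 5 pixels form PCHD regions; the area floor suppresses
single noise pixels (no clinical minimum size exists, so this is a
package choice). The midline is metadata — phantoms are constructed
symmetric — because automated midline estimation would add nothing to the
method under test.

The ROI rule mimics "as large as possible, confined to the highest-density
area": the admissible set is the region's pixels within `hu_tolerance`
= 5 HU of its maximum, and the ROI is the largest inscribed pixel disc
(center with maximal Euclidean distance-transform clearance `e`, radius
`e − 1`, which is the largest disc guaranteed inside the set; ties broken
toward the densest disc). When the disc degenerates to one pixel, the best
axis-aligned integer-semi-axis ellipse is tried; a one-pixel ROI at the
argmax always remains valid. The exhaustive placement is the algorithmic
limit of the clinical "measurements taken at multiple points".

The sinus maximum is taken over the sinus mask minus every pixel within
`exclusion_dilation` = 2 px (Euclidean) of any pixel at or above
`skull_hu_threshold` = 200 HU, operationalizing "the ROI should not
include adjacent skulls or artifacts". A fully excluded mask raises an
error signalling an unmeasurable case rather than returning a skewed
value. No clinical values exist for these two parameters; both are
exposed.

## Synthetic cohort

The generator reproduces the study flow as its defaults: 162 screened,
exclusions (3, 8, 7) for severe artifacts / missing immediate scan /
missing follow-up scan, hence 144 enrolled; PCHD prevalence 103/144;
HT prevalence 58/103 among PCHD cases; latent RMDV-positivity rates 52/58
in the HT group and 11/45 in the CE group; plus 2 enrolled HT cases
without PCHDs, which count toward overall HT prevalence (60/144) but stay
outside the PCHD analysis set. `exact_counts=True` fixes the group sizes
to these rounded expectations (membership still randomized by seed);
`False` draws them Bernoulli, which is what the large-`n` distributional
tests exercise.

Covariates are sampled independently given the outcome group — the
published summaries are marginal, so no correlation structure is imposed.
Binary covariates are Bernoulli at the published group frequencies;
age and blood pressures are truncated normal at the published mean ± SD
(bounds 18–120 y, 70–260 / 40–160 mmHg); median/IQR variables (NIHSS,
ASPECTS, time metrics) are log-normal matched to the printed median and
IQR via `mu = ln(median)`, `sigma = ln(q3/q1)/(2 z_0.75)`, clamped to
their scale ranges and rounded to integers where the scale is discrete —
the simplest distributions consistent with the printed summaries. One
published inconsistency is handled by normalization: the occluded-artery
level counts of the non-HT column sum to 46 of 45; the sampler treats
level counts as unnormalized weights.

## Phantom geometry

Each case renders as a 129×129 raster at 1.75 mm/px: air at −1000 HU, an
elliptical compact-bone skull ring at 1000 HU, mirror-symmetric parenchyma
at 35 HU inside, and a venous-sinus band (ellipse straddling the posterior
midline, peak 75 HU at its center line with linear elliptical falloff).
PCHD cases add an off-midline disc lesion (radius 10 px) with linear
radial falloff from the planted peak to background; the peak pixel equals
the planted value exactly before noise. Latent positivity is realized
geometrically: positive cases draw the peak uniformly from
(1.05–1.6) × sinus peak, negative from (0.6–0.95) ×, so the classifier's
decision is attributable to the image with a margin exceeding noise.
CE cases lose the lesion at follow-up (washout); HT cases keep it.
Validation rejects overlapping lesion/sinus geometry and out-of-range HU.

Gaussian noise (sd `noise_sd`, rounded to integer HU) is added
independently to both slices. The default is 0.75 HU: the follow-up
adjudicator takes a maximum over the ~300-pixel lesion footprint of a
difference image whose per-pixel sd is √2·`noise_sd`, so the 5 HU
elimination threshold stays reliable only while `5/(√2·noise_sd)` is
roughly 4.5 sd or more. This is the point where the qualitative clinical
criterion ("eliminated") meets its sharp algorithmic limit; real NCCT
noise is higher, but a human reader does not adjudicate persistence from
a single pixel. Replication runs that must recover planted peaks exactly
use `noise_sd=0`.

What the phantom does *not* emulate: anatomy (ventricles, gray/white
contrast), beam hardening, partial-volume effects, 3-D structure, or any
realistic lesion morphology. Passing tests therefore demonstrate the
correctness of the measurement and evaluation machinery under controlled
conditions, not reader-level performance on clinical scans.

## Statistics

From the 2×2 table (a=TP, b=FN, c=FP, d=TN): Se = a/(a+b), Sp = d/(c+d),
PPV = a/(a+c), NPV = d/(b+d), Youden = Se+Sp−1. Zero margins raise errors
naming the undefined quantity rather than returning NaN. The ROC of a
single-cutoff test has three points, so AUC = (Se+Sp)/2 exactly; its CI
uses the Hanley–McNeil standard error (Wald interval, clipped to [0,1],
method labelled in the report — other software uses different interval
constructions, so CI endpoints are not expected to match any particular
program). The association test is the uncorrected Pearson χ²
`n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` with 1 df — the form that matches the
published categorical statistics; the Yates correction sits behind a flag.
The t-test is Welch (unpooled variance, Welch–Satterthwaite df), with the
sign convention mean(group2) − mean(group1), computable from raw values or
(mean, sd, n) summaries. Mann–Whitney reports min(U₁,U₂), a tie-corrected
normal Z, and a two-sided p (exact enumeration for tie-free samples with
n₁·n₂ ≤ 400, the tie-corrected normal approximation otherwise). No
multiple-testing adjustment is applied across the baseline table.

Known published inconsistency: the hypertension row's printed χ² (3.484)
matches neither the uncorrected (6.497) nor the Yates-corrected (5.520)
statistic computed from its own printed counts (34/58 vs 15/45); that row
is reported by the table builder like any other but is not used as a
reference value anywhere.

## Determinism and problem sizes

All randomness flows from `numpy.random.default_rng` seeded explicitly;
per-case rendering uses `SeedSequence([run_seed, case_index])` substreams,
so cohort-level results are independent of rendering order. Identical
(config, seed) pairs produce byte-identical CSV/JSON outputs. The test
suite runs study-sized pipelines (103 rendered cases, ~1 s) and a
~10,000-PCHD cohort for distributional recovery (records only, no
rendering); the Monte-Carlo χ² calibration check uses 10,000 hypergeometric
replicates. `scripts/acceptance.py` uses the study-sized cohort with
noise-free rendering and finishes in a few seconds.

## Limitations

- The phantom's simplicity means the 5 HU detection rule is never stressed
  by partial-volume gradients, motion, or asymmetric normal anatomy.
- Covariate independence given group understates real-world correlations
  (e.g. age–atrial fibrillation).
- The elimination rule's pixelwise sharpness makes follow-up adjudication
  noise-sensitive by construction; it is exact only in the noise-free
  regime, mirroring the fact that the clinical criterion is qualitative.
- Multi-threshold ROC analysis of RMDV as a continuous marker is out of
  scope: the method under evaluation is the fixed > 1 cutoff.
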