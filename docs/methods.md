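# Methods

## Scope and model

The package measures the fractal geometry of binary retinal-vessel masks
and asks, on synthetic cohorts, whether such measures are associated with
cognitive ability once prior ability and vascular risk factors are
adjusted for. Real fundus photographs and cohort data are not bundled;
every analysis runs on synthetic inputs whose generating parameters are
chosen to match the published descriptive statistics of an ageing birth
cohort (~73 years old, n = 648 analysed) so that the pipeline's behaviour
can be validated end to end.

## Box-counting dimension (D_box)

The mask is covered by grids of boxes of side l; N(l) is the number of
boxes containing at least one object pixel and D_box is minus the slope of
the least-squares line of log N vs log l.

Numerical choices:

- **Size schedule**: powers of 2 from 2 up to min(H, W)/4. The fit uses
  sizes in [4, min(H, W)/8]: the single-pixel end of the schedule sits in
  a locally 2-D plateau for rasterized curves, and the largest boxes
  saturate (N approaches a handful of boxes), both of which bias the
  slope.
- **Grid offsets**: counts are taken at 4 deterministic diagonal offsets
  of the grid origin and the *minimum* count per size is used — the
  tightest covering found. Averaging over offsets is available
  (`reduce="mean"`) but biases D_box low on solid shapes, because shifted
  grids add partial edge boxes (a filled square then estimates at ~1.92
  rather than exactly 2). Partial edge boxes are counted as ordinary
  boxes.
- On the depth-7 Sierpinski gasket at 1024 px the dyadic counts are exact
  (3^k occupied boxes of side 2^(10−k) for k ≤ 7) and a fit restricted to
  the self-similar range l ∈ [8, 128] returns log 3 / log 2 to numerical
  precision; the default fit range includes l = 4 (below the 8-px base
  cell) and lands at 1.644, within the validation tolerance of ±0.08 used
  in the tests.

## Sandbox dimensions (D0, D1, D2)

Seed points are drawn uniformly from object pixels (1000 by default, with
replacement plus a warning if the mask is smaller than that). For each
point the mass M(R) — object pixels within Euclidean distance R — is
accumulated over a geometric radius schedule of 12 steps from 4 px to
min(H, W)/4, computed exactly with a k-d tree. With M0 the total object
mass and L = min(H, W):

- q ≠ 1: Dq is the slope of (1/(q−1)) · log⟨(M(R)/M0)^(q−1)⟩ vs log(R/L),
  the average taken over seed points;
- q = 1: the logarithmic-limit form, slope of ⟨log(M(R)/M0)⟩ vs log(R/L).

Border handling: a (point, radius) pair whose disc leaves the frame would
have a truncated mass, so it is excluded from the per-radius average;
excluding such points entirely is available by option. Zero masses cannot
occur at the defaults (the seed point itself is object), but are dropped
from log terms defensively. For a multifractal measure the generalized
dimensions are non-increasing in q; the estimator reproduces D0 ≥ D1 ≥ D2
within a 0.02 fit tolerance on all sufficiently homogeneous test objects
(see Limitations).

`dimension_profile` runs both estimators on the thinned skeleton by
default — fractal measures of vessel patterns are more sensitive on
skeletons than on width-bearing maps — with the map available by option.

## Vessel pipeline

Images are down-sampled to 685×584 (area averaging for intensities;
area averaging + 0.5 threshold for masks; an aspect-preserving center-crop
variant exists but the verbatim target is the default). Segmentation is a
deliberately simple stand-in for a trained vessel classifier: multiscale
Sato tubeness on the inverted green channel, hysteresis thresholding, a
darkness gate (the tubeness halo otherwise triples the vessel area), and a
dark-blob union that recovers thick trunks and the optic-disc analogue. On
noise-free phantoms it reaches Dice ≈ 0.94 against ground truth, ≈ 0.87 at
noise levels 0.05–0.10. Supplied masks are always the canonical input;
segmentation exists so the end-to-end path can be exercised. Artefact
cleanup removes object pixels in the aperture-border ring (width 5 px by
default, emulating dust-ring artefacts) and connected components below 10
px; it never adds pixels and is idempotent. Skeletonization uses standard
topology-preserving 8-connectivity thinning; component counts are
preserved and thin lines are fixed points.

## Synthetic data

**Fixtures.** The Sierpinski gasket is built from the bitwise rule
(i & j) == 0 at 2^depth resolution with solid base cells, making dyadic
box counts exactly self-similar — the sharpest available oracle for the
box counter. The Koch curve is rasterized from the analytic vertex chain.
The branching tree is a random binary tree with geometric length decay; it
has no analytic dimension and serves as a "realistic unknown".

**Phantoms.** A stochastic binary tree rooted at a disc (optic-disc
analogue) near the nasal edge, six primary branches, geometric width and
length decay, rasterized by stamping discs along curved segments, rendered
dark-on-bright with optional Gaussian noise and an optional 1-px bright
centerline (central light reflex analogue). The defaults (depth 6, length
decay 0.80, initial length 95 px, bifurcation half-angle 40°) were chosen
so that skeleton profiles land at D_box ≈ 1.46 and D0 ≈ 1.70–1.73 —
matching the scale of published skeleton measurements — and satisfy the
Dq ordering across seeds. Phantoms do not emulate fundus optics,
illumination gradients, vessel tortuosity statistics, arteriole/venule
distinction, or pathology; passing tests demonstrate correctness of the
measurement chain, not segmentation performance on real photographs.

**Cohorts.** The continuous block (childhood IQ, three latent cognitive
domains, eight fractal measures) is multivariate normal. Defaults: age
72.4 ± 0.71 y; 50.3% male; IQ 102 ± 14; fractal means/SDs of 1.42–1.68 /
0.02–0.03 per (eye, dimension); left–right correlation 0.50 and
within-eye inter-dimension correlation 0.85 (midpoints of the published
0.403–0.582 and 0.708–0.982 ranges), cross terms their product; domain–IQ
correlations 0.70/0.55/0.55 and inter-domain 0.60. Positive
semi-definiteness is checked and violations are rejected with the
offending eigenvalue. True effects are injected per (eye, dimension,
domain) as domain = √(1 − βᵀΣβ)·latent + βᵀz, keeping the domain
standardized so the model-1 standardized β̂ recovers the injected value.
An optional IQ–fractal correlation routes any fractal–cognition
association entirely through childhood IQ, reproducing the attenuation
pattern when IQ enters as a covariate. Fifteen subtests load on their
primary domain (reaction-time subtests negatively). Binary risk factors
are independent Bernoulli draws; this ignores any real covariance between
risk factors and cognition, which is acceptable because the analysis only
requires them as adjustment variables. Missingness is completely at
random: 17.5% of participants lose the whole fractal set plus 0.5%
per-measure dropout (≈ 18% lacking the full set, per-cell n ≈ 530 of
648), 6.6% missing childhood IQ, and ~1–5% per domain score. The
generator standardizes domain scores on its own sample; a study that
standardizes on a larger parent sample will show small nonzero sub-sample
means instead.

## Agreement

CR = 1.96 × SD (n−1) of paired differences; the multiplier is recorded
and configurable (2.77 × within-SD is an alternative convention). The
study harness measures both collections with the same estimator settings
and seed, so reported CRs isolate the effect of the differing masks. A
simulated second observer (independent boundary-pixel flips at rate 0.02)
yields CRs of ~0.002–0.01, comfortably below the ~0.04–0.14 scale reported
for human observers and software on real images — unsurprising, since
boundary flips barely move a skeleton.

## Association analysis

Complete-case OLS per cell with outcome and predictor z-scored on the
per-cell subsample ("per 1 SD"), covariates on their natural scale, sex
coded 0/1, smoking as a current-smoker indicator, and two-sided t-based
p-values. Exclusions apply in a fixed order (MMSE < 24, then no gradable
image) with overlap counted under the first rule. No multiplicity
correction is applied by default (the 24 tests per model are strongly
dependent through the 0.85 inter-dimension correlation). Contralateral
verification requires both eyes significant with same-signed βs.
Domain scores for analysis are the first unrotated principal component of
standardized subtests (complete-case), with smaller-is-better subtests
negated beforehand so orientation is unambiguous and permutation
invariant. Power for a correlation uses the Fisher z approximation with
the far-tail term included, so power at r = 0 equals α exactly;
power(648, 0.11, .05) = 0.801.

## Problem sizes and seeds

Test and acceptance runs use 648–100 000-row cohorts (100 000 for moment
checks, 20 000 for effect recovery, 2000 replicates of 648 for type-I
calibration), 20 phantoms for agreement, and 256–1024-px fixtures; these
sizes keep Monte-Carlo error well inside the stated tolerances. All
randomness flows through explicit integer seeds; the pipeline derives
per-stage seeds from one global seed by fixed offsets, and identical
configurations produce bit-identical outputs.

## Known limitations

- The Dq ordering D0 ≥ D1 ≥ D2 is an asymptotic property of the measure;
  on strongly inhomogeneous finite objects (a sparse single-trunk tree
  whose trunk is locally 1-D while its canopy is nearly 2-D) the fitted
  slopes can invert. The guarantee is therefore stated — and tested — on
  homogeneous fixtures and on vessel-like phantoms.
- D_box on a rasterized disk at the default schedule is ≈ 1.95, not 2.0:
  boundary boxes contribute a +O(l/r) term to log N. Larger rasters and
  smaller fit ranges reduce the bias.
- The segmenter is a contract stand-in, not a competitive vessel
  classifier; no claim is made about its behaviour on real photographs.
- Exact published regression tables cannot be reproduced without the
  original cohort's images and test scores; the package instead verifies
  the statistical machinery by parameter recovery and calibration on its
  own generator.
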