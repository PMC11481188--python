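# Methods

## Problem and model

The package asks when, over an adult lifespan, transcriptional programs in
the heart change direction. The analysis treats age as a continuous
covariate (no groups), and its core quantities are:

- **Co-expression modules.** Transcripts are clustered by correlation-network
  topology: unsigned adjacency `a_ij = |r_ij|^β` with β = 12, transformed to
  topological overlap
  `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`
  (k = connectivity, shared-neighbour sum excluding i and j), clustered by
  average linkage on `1 − TOM`. Modules smaller than 30 transcripts stay
  unassigned (label 0). Modules whose eigengenes (first principal component
  of the scaled module submatrix, sign-aligned to the mean profile) are
  closer than 0.25 in `1 − r` are merged iteratively. A module is
  age-correlated when its eigengene has |Pearson r| ≥ 0.30 with age and a
  two-tailed t-based p ≤ 0.05.
- **Trajectory model selection.** Per transcript, OLS under
  `y = B₀ + B₁x` and `y = B₀ + B₁x + B₂x²`; the quadratic is kept when the
  extra-sum-of-squares F test `F = (SSE_lin − SSE_quad)/(SSE_quad/(n−3))`
  rejects at α = 0.05 against F(1, n−3). The age effect is the t test of
  the top coefficient of the chosen model. The vertex `−B₁/(2B₂)` is the
  tipping point; a pathway's tipping point is the mean ± sample SD of its
  eligible members' vertices.
- **Directional enrichment.** Each age-correlated transcript carries a
  direction ±1: the sign of its module–age correlation, overridden by
  sign(B₂) when its chosen trajectory is quadratic (the direction *after*
  the vertex). Pathway overlap significance is the two-tailed Fisher's
  exact test against the universe of all count-filtered transcripts, with
  Benjamini–Hochberg control at 0.05 across pathways; directionality is the
  activation z-score `z = Σ xᵢ/√N`.
- **Onset estimation.** Staining fractions vs age follow
  `f(x) = b + L/(1 + e^{−k(x−x₀)})`. The tangent at the inflection (slope
  `Lk/4`) intersects the baseline and upper plateau at `x₀ ∓ 2/k` (onset /
  end of accumulation). The fast phase is the interval where the tangent
  stays within ε·L of the sigmoid (numeric scan at 0.01-year steps); for a
  logistic it is symmetric about x₀ and its half-width is ≈1/k at ε = 0.02.
- **Timeline.** Ages convert to human equivalents by a fixed ratio of 4.0
  (the ratio implied consistently by the published pairs 7.5→30, 13.0→52,
  22.1→≈88), rounded half away from zero; events sort by (start) age with
  alphabetical tie-break.

## Key parameters

| parameter | default | units | why |
| --- | --- | --- | --- |
| soft power β | 12 | – | standard unsigned-network default for bulk data |
| min module size | 30 | transcripts | small modules are not robustly screenable |
| merge threshold | 0.25 | 1 − r | conventional eigengene-merging height |
| age screen | \|r\| ≥ 0.30, p ≤ 0.05 | – | study screening rule |
| count filter | row total < 30 removed | counts | strict-less reading of the filter rule |
| TMM trims | 30 % of M, 5 % of A | – | canonical trimmed-mean recipe |
| log pseudocount | 0.5 | counts | avoids −∞; log2 CPM convention |
| F-test α | 0.05 | – | nested-model selection level |
| vertex range margin | 1.0 | years | vertices extrapolated beyond the observed ages ± margin are not lifespan tipping points and are excluded from pathway means |
| tangent tolerance ε | 0.02·L | fraction of amplitude | reproduces a visually sensible departure point and the ≈ x₀ − 1/k behaviour |
| human-age factor | 4.0 | – | see above; configurable |

## Synthetic cohorts

`synth.default_ground_truth` emulates the study design: 35 samples with
ages uniform on [7.5, 22.1] years; three quadratic modules of 40
transcripts with vertices 12.9 (downward), 13.7 and 14.6 years (upward,
curvature ±0.02 ln-units/yr²), one linear module (slope 0.07 ln-units/yr,
≈2.8-fold over the age span), and 80 independent background transcripts.
Member latent signals are `baseline + loading·shared + τ·ε` with loadings
uniform on [0.6, 1.0] and τ set so members correlate at 0.85 before count
noise. Counts are negative binomial (dispersion 0.08, i.e. ≈28 % biological
CV) around `exp(latent)` times a log-normal library factor (σ = 0.15),
exercising TMM. Staining follows a logistic with baseline 2 %, amplitude
10 %, midpoint 16.3 y and rate 0.4 /y — hence a planted accumulation window
of 11.3–21.3 years — with Gaussian image noise (sd 0.5 %) and six replicate
images per animal, which are averaged per animal before fitting to avoid
pseudo-replication.

Two generator choices deserve emphasis:

- **Age-independent co-regulation.** Every module's shared profile includes
  a random component (sd 0.6 ln-units) *orthogonalized against the
  quadratic age design*. Biologically, co-expression reflects shared
  regulation far beyond the age trend (in real data the age trend explains
  a minority of eigengene variance). Technically it is what makes the
  planted partition identifiable at all: pure parabolas with vertices 0.8
  years apart are |r| ≈ 1 collinear, and no correlation network could
  separate them. Orthogonalizing (rather than merely drawing independent
  noise) guarantees the component cannot masquerade as curvature in the
  trajectory fits.
- **What the generator does not emulate.** Real data have hockey-stick
  rather than parabolic trajectories, correlated gene–gene noise beyond
  module membership, varying module sizes into the thousands, batch
  structure, and asymmetric staining kinetics. Passing tests therefore
  demonstrate method correctness and calibration, not field performance on
  real cohorts.

## Numerical choices

- TMM: reference sample = the one whose 75th-percentile count fraction is
  closest to the mean of those fractions; weights are inverse asymptotic
  binomial variances; factors are rescaled to geometric mean 1; samples
  sharing no positively expressed transcripts with the reference are a
  degenerate-input error. The implementation is cross-checked against
  edgeR's `calcNormFactors` in the test suite.
- Per-transcript scaling uses the population (ddof = 0) convention;
  constant rows map to zero.
- Tree cut: the static-height rule is replaced by a deterministic adaptive
  cut — every merge height is a candidate, and the cut maximizing (number
  of clusters ≥ min size, members captured by them) wins, with deep-split
  breaking ties toward finer (≥2) or coarser cuts. Soft-thresholding at
  β = 12 compresses all dissimilarities into a narrow, data-dependent band
  just below 1, where any fixed-height cut is brittle.
- Eigengene sign is fixed by non-negative correlation with the module mean
  profile; merge order is closest-pair-first, which is order-stable on
  clearly separated data (asserted by permutation tests).
- Residual-free OLS fits (noiseless inputs) are handled explicitly: both
  models exact → linear preferred, F = 0, p = 1; quadratic exact only →
  F = ∞, p = 0; coefficient t tests degenerate to p ∈ {0, 1} by whether the
  coefficient is nonzero.
- The logistic fit uses bounded least squares from a deterministic 12-point
  multi-start grid (quartile midpoints × rates {0.2, 0.5, 1, 2}); fits with
  amplitude below max(0.005, 2·RMS residual) or touching a bound are
  flagged unreliable.
- The activation z-score's denominator is configurable (`sqrt`, `n`,
  `none`); √N is the default as the unit-variance convention.

## Design decisions on open points

- The Fisher universe is all transcripts passing the count filter.
- Trajectories are fitted for **all** detected-module members, not only
  members of modules passing the linear age screen: a symmetric quadratic
  trajectory with vertex near the mean age has essentially zero linear
  correlation with age, so the |r| ≥ 0.30 screen would delete exactly the
  tipping-point biology the quadratic analysis exists to find. The screen's
  statistics are still computed and reported for every module.
- Downstream regressions use log2-normalized values (not linear).
- The |r| threshold is applied to the absolute correlation (modules of both
  signs are reported as significant).
- For a symmetric logistic the fast window is symmetric about the midpoint;
  asymmetric accumulation kinetics would need a five-parameter sigmoid,
  which is out of scope and noted as a limitation.

## Problem sizes

Test-bench cohorts use 235 transcripts × 35 samples (modules of 35–40,
background 80), 26 staining animals × 6 images, 20 replicates for recovery
statistics, 1000 replicates for F-test calibration and 200 × 1000 for the
BH null — sizes chosen so the full suite and the acceptance script each run
in seconds to minutes on one CPU while keeping Monte-Carlo error well below
the asserted tolerances.

## Known limitations

Module detection is O(n²)–O(n³) in transcripts and is not blockwise; it is
intended for filtered matrices up to a few thousand transcripts, not 50k.
The dynamic-hybrid tree cut of the reference WGCNA package is not
replicated — recovery of planted structure, not bit-compatibility, is the
design goal. No multiple-testing correction is applied across transcripts
for model choice (matching the study procedure); a global BH pass over
`f_p` is available to callers via `enrich.bh_adjust` if desired.
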