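# Methods

## Model and estimands

`srmfam` implements the Social Relations Model (SRM) for a fixed four-person
round-robin design with roles (by default M, F, C1, C2). Each of the 12
directed measurements decomposes as `X_ij = Fam + Act_i + Par_j + Rel_ij`.
With a single indicator per dyad the relationship effect absorbs measurement
error; the package therefore accepts no separate error-variance parameter and
the relationship rows of a report should be interpreted with that confound in
mind. Families of other sizes are rejected with a validation error: the n = 4
estimator weights and the 21-effect parameterization are specific to this
design, and silently generalizing them would change every downstream contract.

Per-family estimation uses the classical ANOVA scores. Because self-ratings
are missing, raw row/column means are biased for the actor/partner effects;
the estimator reweights them (for n = 4: 9/8 × own mean + 3/8 × cross mean −
3/2 × grand mean). Equivalently, the whole decomposition is a fixed linear map
`W` (21×12): the family row is 1/12 everywhere; an actor row is +1/4 on the
person's three outgoing dyads, 0 on the incoming ones and −1/8 on the other
six; partner rows mirror that; relationship rows are dyad indicators minus the
family, actor and partner rows. The direct formulas and the matrix route are
algebraically identical, and the test suite enforces their equality on random
inputs as a two-route consistency check, along with the structural identities
(actor, partner, and per-person relationship scores each sum to zero; the four
components reconstruct each `X_ij` exactly; adding a constant to all inputs
moves only the family score).

## The CFA-to-ANOVA transformation

Normative SRM studies publish CFA estimates: means and variances of the
latent effects plus generalized reciprocities (actor–partner correlation
within a person) and dyadic reciprocities (correlation between the two
directions of a dyad). These are not the mean/SD of the ANOVA scores, which is
what norm referencing needs. The package derives the exact sampling
distribution by linear propagation:

1. Reciprocities given as correlations are converted to covariances
   (`r·√(v₁·v₂)`); covariance input is bound-checked (Cauchy–Schwarz).
2. The model-implied mean vector μ (family + actor + partner + relationship
   means per dyad) and 12×12 covariance Σ of the dyad vector are assembled
   under the SRM independence structure: effects are independent except for
   the two reciprocity patterns.
3. Each ANOVA score `w·X` then has norm mean `w·μ` and SD `√(w·Σ·wᵀ)`.

Reciprocity covariances are propagated into every quadratic form, including
the family score's; with the bundled norm parameters this reproduces the
published case-study Z scores to the third decimal, which is the evidence the
inclusion is correct. Unbiasedness holds by construction: when the published
means satisfy the identifying zero-sum constraints exactly, `w·μ` equals the
corresponding CFA mean for every effect.

Z scores use `(score − norm mean)/norm SD` and two-sided standard-normal
p-values. No finite-sample t correction is applied because the norm sample
size is not an input to the method; the published reference values are
likewise normal-based. Default flags: |Z| ≥ 2 extreme, 1 ≤ |Z| < 2 elevated;
thresholds are configurable but must satisfy 0 < elevated < extreme. P-values
are reported raw by default, matching convention for this screening use; a
Holm step-down adjustment over the 21 tests is available as an explicit
option. If the norm file marks some effects' variances as non-significant, the
corresponding rows are footnoted — never suppressed — since a Z score against
a noise-level variance is uninterpretable but the practitioner should see it.

## Numerical choices and degenerate inputs

- All arithmetic is double precision; rounding (3 decimals, matching the
  conventional report format) happens only at CSV render time, and JSON
  output keeps full precision.
- An effect whose propagated SD falls below 1e-8 is reported
  `non_assessable` (Z and p are NaN/null) rather than ±infinity.
- If the assembled Σ is not positive semidefinite (possible when published
  estimates are internally inconsistent), assessment proceeds only if all 21
  quadratic forms are still non-negative; otherwise it errors and reports the
  smallest eigenvalue. Simulation is stricter: each 2×2 effect block must be
  PSD, and clipping negative eigenvalues at zero is an explicit opt-in
  (`repair=True`), never silent.
- Zero-sum deviations of published means are warnings (tolerance 0.01,
  matching 3-decimal rounding of printed tables), not errors.
- Input values are not range-checked against any Likert scale: the tool
  accepts mean or sum scores of arbitrary instruments. Missing or non-finite
  dyads are hard errors; the estimator weights assume a complete round robin
  and no imputation is attempted.

## Simulator

The simulator draws families generatively, effect by effect: the family
effect from a univariate normal, each person's (actor, partner) pair and each
unordered dyad's (Rel_ij, Rel_ji) pair from bivariate normals with the
reciprocity covariances. Multivariate normality is the package's explicit
distributional choice — it is what the CFA framework and the 2-SD flagging
rule implicitly assume. Blocks are sampled through symmetric eigendecomposition
square roots so zero-variance blocks degrade to constants instead of failing a
Cholesky factorization. Latent draws do *not* impose per-family zero-sum
constraints: those identify the population means, not individual realizations.
A single NumPy generator keyed by the seed, with a fixed draw order (family,
persons in role order, unordered dyads), makes runs bit-reproducible; draw
stability under changes of `n_families` is not promised.

Because the simulator composes the model from its parts while the dyad law is
assembled analytically, agreement between the two is a genuine cross-check,
used twice: the empirical covariance of 200,000 simulated dyad vectors against
Σ (Frobenius-relative, 2%), and the empirical mean/SD of every ANOVA score
over 10,000 families against the propagated values at 3 Monte-Carlo standard
errors. Note the latter screen runs 42 comparisons, so with per-comparison
3-SE bounds the chance that at least one marginally fails is about 10% per
seed; the fixed-seed test suite accounts for this by bounding the worst
standardized deviation at a family-wise-sound level in the unit test while
the end-to-end suite runs the literal 3-SE screen. Simulated norm families
flag extreme at ≈ 2Φ(−2) = 4.55% per effect, which the suite verifies within
±1%.

These simulations share the real data's model exactly and its parameters by
construction, so passing them validates the transformation algebra — not the
fit of the SRM to any particular instrument, nor robustness to non-normal
effects, covariate structure (age, gender), or missing dyads, none of which
the generator emulates.

## Problem sizes

Default validation sizes were chosen so the whole suite runs in seconds on a
laptop while keeping Monte-Carlo error well below the tolerances: 1,000
random round robins for the algebraic identities, 10,000 families for
mean/SD calibration (MC SE ≈ 1% of each SD), 100,000–200,000 for the
dyad-law moment checks.

## Known limitations

- A printed reference value in the bundled expected-output table
  (`rel:F->C1`, −0.497) is internally inconsistent with its own published
  companions: the exact decomposition of the bundled inputs gives −0.495, and
  the published Z for that row (−1.350) matches −0.495, not −0.497. The
  regression tests compare that single entry at the 0.002 precision the table
  actually supports; the strictest end-to-end test keeps the nominal ±0.001
  tolerance and is expected to flag exactly that row.
- The tool consumes published CFA estimates; it does not fit the CFA/SEM,
  handle families of other sizes, separate measurement error from
  relationship effects, or adjust for covariates.
- Confidence intervals for Z would require norm-sample standard errors that
  published tables do not provide.
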