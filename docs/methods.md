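# Methods

## The model

`pedherit` estimates narrow-sense heritability of a bounded school-achievement
score from census pedigree data with the animal model

    y = X β + a + e,    a ~ N(0, A σ²_A),    e ~ N(0, I σ²_E),

where `y` are test scores (points on a 500–550 scale), `X` is a reference-coded
covariate design, `a` are additive genetic values with covariance proportional
to the expected additive relationship matrix `A`, and `e` is independent
residual noise. Heritability is h² = σ²_A / (σ²_A + σ²_E). The model is the
AE special case of the twin ACE decomposition: no shared-environment component
is estimated, so any C-like variance ends up in σ²_A — a known property of this
design, not a bug of the implementation.

`A` is built over phenotyped children only, from pairwise relation classes
recognizable in a grandparent-truncated register: full siblings (0.5), half
siblings (0.25), full cousins (0.125), half cousins (0.0625); all other pairs
are assumed unrelated. This makes `A` block diagonal by extended family, which
both the sampler and the likelihood evaluator exploit.

## Pedigree cleaning

Register pedigrees need four cleaning steps, applied in this order:

1. **Founderize adoptees** — legal parents of known adoptees are severed
   (registered parentage is not biological there).
2. **Remove loops** — individuals recorded as their own ancestors; every member
   of a parentage cycle (strongly connected component of the parent→child
   graph) is dropped and surviving children get an unknown parent.
3. **Truncate ancestry** at `depth = 2` above phenotyped children: parents and
   grandparents are kept, great-grandparents are treated as unknown (register
   data that deep is unreliable; the four relation classes never need it).
4. **Prune non-informative branches** — non-phenotyped individuals with no
   phenotyped children or grandchildren, iterated to a fixpoint because a
   removal can make an ancestor newly non-informative.

The order (founderize → loops → truncate → prune) is a choice; the operations
are individually idempotent and the tests pin this down. Loop removal takes
*all* members of a cycle rather than a minimal cut — cycles are data errors
and no member can be trusted.

Relation classes are evaluated in priority order full sib > half sib > full
cousin > half cousin, so a doubly-related pair (e.g., double half cousins)
receives the single class with the largest coefficient. Avuncular or other
configurations outside the four classes fall to "unrelated". MZ twins cannot
be distinguished from ordinary sibs in register data and are deliberately
coded as full siblings (0.5) although their true relatedness is 1; the
generator knows the truth, and a dedicated test shows the induced upward bias
in h² grows with the twinning rate.

Two independent routes validate the classification-based `A`: a recursive
kinship coefficient (φ(i,i) = ½(1 + φ(f,m)), φ(i,j) descending through the
deeper individual's parents) and a sparse A⁻¹ assembled by Henderson's
non-inbred rules (d_i = 1/(1 − 0.25·#known parents)). On cleaned pedigrees,
2·φ equals the class coefficient exactly for every classified pair, and
Henderson's A⁻¹ times the dense recursive A is the identity to 1e−8. The
non-inbred convention (unit diagonal) is appropriate because partner choice in
the generator avoids relatives up to shared grandparents and the truncated
register admits no measurable inbreeding among phenotyped children.

## Gibbs sampler

Priors are uninformative: flat on β and flat on both variances subject to
positivity (`prior_df = -2` in the scaled inverse-χ² parametrization; 0 gives
Jeffreys). Posterior means therefore track maximum likelihood, which a
profile-likelihood grid check confirms on desk-scale data.

Per iteration:

1. β | a, σ²_E ~ N(β̂(y − a), σ²_E (X'X)⁻¹) via a precomputed Cholesky of X'X;
2. a | β, σ² — drawn jointly per family. All family blocks of `A` are
   eigendecomposed once (`A = U Λ U'`, `U` block-diagonal sparse); the full
   conditional of the eigen-coordinates is then diagonal, so one iteration
   costs two sparse matrix–vector products regardless of family sizes;
3. σ²_A | a ~ scale/χ²_df with scale a'A⁻¹a = Σ u²/λ and df = q − 2;
4. σ²_E | β, a ~ e'e/χ²_{n−2}.

A `SINGLE_SITE` scheme (scalar updates over the whole pedigree using the
sparse Henderson A⁻¹) is retained as a cross-check and for pedigrees whose
`A` is not block-structured; both schemes agree within Monte-Carlo error.
Sampled variances are floored at 1e−8·var(y) (occurrences counted and
reported). Initialization is deterministic — OLS for β, half the sample
variance for each component — so a fixed seed reproduces draws bit for bit.
h² is summarized from its own per-draw values, not as a ratio of posterior
means.

Default chain settings are 10,000 burn-in, 50,000 inference iterations,
every 100th draw saved. The test suite and the acceptance script use a
shortened chain (2,000 / 10,000 / thin 20, i.e., 500 saved draws) at the
desk scale of ~5,000 phenotyped children; at that size the posterior SD of
h² is ≈ 0.03, so the shortened chain resolves the recovery question. For
mostly-singleton data the σ²_A/σ²_E split is weakly identified and only their
sum is meaningful; the conjugacy test therefore checks the posterior of the
*total* variance against the closed-form scaled inverse-χ².

## Synthetic census generator

The generator emulates the features of a national register that matter for
this analysis: founder couples with Poisson family sizes (mean 2.4),
within-generation partnering that creates full/half cousins, re-partnering
(rate 0.10) that creates half sibs, MZ twinning at 1/200 births, a 500–550
score scale with mean 535.03, variance components and covariate effects set
to the published posterior means, and covariates drawn at the published
category frequencies. Corruption — adoption flags, parentage cycles,
duplicate-year scores, out-of-range scores — is injected with exact
bookkeeping so the cleaning and filter stages can be verified count for
count. Breeding values follow Mendelian sampling (founders N(0, σ²_A);
children mid-parent plus deviation of variance σ²_A/2, plus σ²_A/4 per
unknown parent so the marginal variance is always σ²_A); MZ co-twins share
one value.

Choices a real register does not dictate, fixed once:

- **Partner pool.** Each individual partners outside the simulated clans with
  probability 0.70. Above ≈0.6 the sibship-marriage graph is subcritical, so
  extended families stay bounded (largest ≈ 200–300 at desk scale) instead of
  percolating into one giant component; this both matches the bounded family
  blocks the model assumes and keeps the block sampler exact and fast.
- **Scale bounds.** By default scores are *not* clamped to [500, 550], so the
  generating model is exactly the fitted model and recovery targets are
  well-defined. Because the published mean (535.03) and total variance (94.7)
  put ≈6% of Gaussian mass above 550, pipeline runs that apply the
  range filter to unclamped scores would truncation-select on the phenotype
  and visibly shrink both variance components. The analysis drivers therefore
  generate clamped (censored) scores — the real instrument is bounded — at the
  cost of a small attenuation (≈0.02 in h² at desk scale).
- **Covariate structure.** Covariates are iid across children. In the real
  census, SES, school denomination and migrant status cluster within
  families, which is why the published empty-model h² (0.94) *exceeds* the
  covariate-adjusted one (0.85): family-shared covariate variance loads on
  σ²_A. With iid covariates that variance loads on σ²_E instead, so in
  simulated data the empty-model h² sits *below* the full-model one. Passing
  recovery tests on this generator demonstrate that each model recovers its
  own generating truth; they do not reproduce the direction of the
  empty-vs-full gap seen in the census, which is a property of covariate
  family-clustering the generator deliberately omits.
- **Group size** is rounded N(25, 5²) clipped to [5, 45] pupils — a plausible
  Dutch classroom distribution; only its variance matters for the design
  check.

## Filters

Score records are kept if 500 ≤ score ≤ 550 inclusive (both endpoints are
valid scale values). One score per child: the earliest year wins; a same-year
tie (not observed in the study, but possible in inputs) is broken
deterministically by the lower score and logged. Adoptees and children
without parentage records are excluded from both models; special-education
children, whose SES weight is undefined, only from the covariate model.
Every stage returns a count report and the pipeline asserts the counts
reconcile exactly.

## Problem sizes

Unit and property tests run at the `tiny` scale (~200 phenotyped children);
recovery tests and the acceptance script at the `desk` scale (~5,000
phenotyped, ~11,500 individuals), with five replicate seeds averaged for the
headline recoveries; a `stress` preset (~100,000) exists for manual use.
These sizes were chosen so the whole analysis reruns on a single CPU in
minutes while leaving the Monte-Carlo error of the recovery checks (~0.01 in
mean h² over five seeds) well inside the ±0.05 band used to judge them.

## Known limitations

- No shared-environment (household) random effect; like the original design,
  σ²_A absorbs it.
- No inbreeding: the unit-diagonal convention and Henderson's simplified
  rules assume non-inbred pedigrees, which the generator guarantees and real
  grandparent-truncated registers approximate.
- The Gaussian phenotype cannot reproduce the hard bounds and skew of the
  real score scale; clamped generation approximates censoring only.
- Zygosity is never inferred; the MZ-as-full-sib bias is quantified on
  synthetic data rather than corrected.
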