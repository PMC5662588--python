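# pedherit

Census-scale heritability of educational achievement from pedigree data.

Twin studies estimate the heritability of school achievement from volunteer
twin registries, which raises self-selection and twin-representativeness
concerns. An alternative is to use an entire national census: every child's
end-of-primary-school test score (a standardized 500–550 scale), the register
pedigree linking children through their parents and grandparents, and
school and family covariates. `pedherit` implements that analysis end to end for
anyone who wants to run it on register-style data or study its statistical
behavior on synthetic censuses:

- **Pedigree cleaning** for register data: founderize known adoptees, remove
  parentage loops, truncate ancestry above grandparents, prune branches
  without phenotypic information.
- **Relationship structure**: classify every pair of phenotyped children as
  full sibs / half sibs / full cousins / half cousins / unrelated and build
  the sparse additive relationship matrix A (block diagonal by extended
  family), with a recursive-kinship oracle and a Henderson sparse A⁻¹ as
  independent cross-checks.
- **Animal model**: the mixed model y = Xβ + a + e with a ~ N(0, A σ²_A),
  e ~ N(0, I σ²_E), fitted by Gibbs sampling with uninformative priors;
  narrow-sense heritability h² = σ²_A / (σ²_A + σ²_E) is summarized from its
  posterior draws. An intercept-only ("empty") model and a covariate
  ("full") model — sex, SES weight, group size, migrant status, school
  denomination, reference-coded — are fitted in sequence and the variance
  explained by covariates is reported.
- **Synthetic census generator** with exact ground truth (pedigree structure,
  breeding values via Mendelian sampling, MZ twins at 1/200 births,
  covariates at published national frequencies, injectable data corruption),
  so every stage is testable without the confidential register.

See `docs/methods.md` for the model, its assumptions, and the design choices.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic census
(~5,000 phenotyped children, ~11,500 individuals) whose generating truth is
the published covariate-model estimate (σ²_A = 75.83, σ²_E = 13.21,
h² = 0.852, plus the published covariate effects):

```bash
python analysis/01_simulate_census.py --seed 1   # fixture -> scratch/census/
python analysis/02_clean_pedigree.py             # clean + export A matrix
python analysis/03_fit_models.py --seed 1        # fit both models
python analysis/04_recovery_study.py             # bias across h2 grid
```

`03_fit_models.py` prints (shortened chain, seed 1):

```
N (empty model) = 5243, N (full model) = 5233
empty model: sigma2_A =  67.49 (3.89), sigma2_E =  19.07 (2.66), h2 = 0.779 (0.033)
 full model: sigma2_A =  69.46 (4.04), sigma2_E =  14.12 (2.72), h2 = 0.831 (0.034)
generating truth: h2 = 0.852 (sigma2_A = 75.83, sigma2_E = 13.21)
variance explained by covariates: 2.97 points (3.4%)
```

Reading this: the covariate model recovers the generating h² of 0.852 within
its posterior uncertainty (0.831 ± 0.034; bounded-scale censoring accounts
for most of the small attenuation). The empty model sits lower because the
generator draws covariates independently per child, so covariate variance
loads on the residual — in the real census, family-clustered covariates load
on σ²_A instead, which is why the published empty-model estimate is *higher*
than the adjusted one (`docs/methods.md` discusses this asymmetry).

The same pipeline is available as a CLI (`pedherit simulate / clean / fit /
run / report`) for file-based inputs: a delimited pedigree
(`id, father, mother[, adopted]`), a score CSV (`child_id,year,score`) and a
covariate CSV.

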