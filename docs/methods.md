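# Methods

`longmm` implements two mixed-effects mappers for longitudinal
quantitative traits measured on unrelated individuals, plus the
synthetic testbed used to validate them.

## The longitudinal mixed model

For individual *i* with `n_i` visits at ages `t_i1 < ... < t_in_i`,

    y_i = mu 1 + X_ie beta_e + x_ig beta_g + u_i + e_i,
    u_i ~ N(0, sg2 K_i),   e_i ~ N(0, se2 I),

where `X_ie` holds the non-genetic covariates (age, age², sex,
medication, smoking by default), `x_ig` is the additive SNP dosage
(constant across an individual's visits) and `K_i` models serial
correlation between visits.  The supported `K_i` families are

* **spatial power**: `K_i[j,j'] = rho ** |t_ij - t_ij'|` — the
  continuous-time AR(1); time distance is measured in **years of age**;
* **compound symmetry**: constant correlation `rho` between visits;
* **independence**: `K_i = I`.  With `K_i = I` the split of the total
  variance into `sg2 + se2` is not identifiable, so this structure is
  fit with a single residual variance (one free covariance parameter;
  `sg2` is reported as 0).  This is also why its AIC uses k = 1 while
  the correlated structures use k = 3 (`rho, sg2, se2`).

### Null-model estimation (`longmm.covariance`)

Variance components are estimated by REML under the no-SNP model.
The variance ratio `delta = se2/sg2` is profiled on a grid of 100
intervals of `ln delta` over [−10, 10] (with bounded local refinement
of every interior peak), nested inside a 1-D profile over `rho`
(grid step 0.01, refined by bounded scalar search).  `sg2` drops out in
closed form.  `rho` is restricted to [0, 1) — no negative serial
correlation.  Structure choice is by AIC (−2·loglik + 2·k over
covariance parameters only; fixed effects are common to all
candidates), ties toward fewer parameters.  The fitted structure is
frozen into per-individual blocks `K_i` with Cholesky factors `M_i`
(`M_i M_i' = K_i`, verified to 1e−10) and reused by both mappers —
re-estimating K per SNP would be needlessly expensive, and the null
estimate is adequate unless single SNPs carry a large fraction of the
variance.

**Identifiability caveat.**  With visits ~5 years apart and a per-year
`rho` around 0.7, the implied between-visit trait correlation is only
`sg2 * rho^5 / (sg2+se2) ≈ 0.08`, and `sg2 * K(rho')` alone (with
`rho'^5` matched to that correlation and `se2 = 0`) reproduces the
covariance almost exactly.  The REML surface is then a near-flat ridge
on which only `sg2 + se2` and `sg2 * rho^5` are well determined;
point estimates of the individual components are extremely noisy and
pile on the `se2 = 0` boundary in a large fraction of replicates.
This is a property of the design (verified against exhaustive dense
2-D likelihood grids), not of the optimizer; with denser visit
schedules or stronger serial correlation the three parameters separate
cleanly (see the recovery tests).  Downstream scans are barely
affected: they depend on the fitted covariance as a whole, not on the
split.

### Single-SNP scan (`longmm.emma`)

Per SNP the hypothesis `beta_g = 0` is tested by a likelihood-ratio
test with a chi-square(1) reference.  A one-time blockwise
eigendecomposition of K rotates the data so cov(y) is diagonal for any
`delta`; each likelihood evaluation is then O(N).  Both hypotheses
re-optimize `delta` by the same grid-plus-refinement profile (full
per-SNP optimization; a `fast` flag freezes `delta` at the null
estimate, the usual approximation).  ML rather than REML likelihoods
are used because LRTs on fixed effects require a common REML error
contrast, which changes with the SNP column.  Monomorphic or
covariate-collinear SNPs return NA and the scan continues.  Negative
LRT values within −1e−8 are clipped to zero; anything more negative
raises (it would indicate an optimizer failure).  Scan output flags
p < 1e−5 as "suggestive" and p < 5e−7 as "significant".

The ML-based LRT is mildly anti-conservative in small samples: at
n = 139 unrelated individuals its true size at nominal 0.05 is ≈ 0.056
(matching exact-t theory in the iid special case).  The calibration
test therefore pools null SNPs across independent replicate cohorts,
where the binomial reference interval for the rejection rate is valid;
within a single cohort all tests share one phenotype draw and the
rejection count is over-dispersed.

### Bayesian multi-SNP mapping (`longmm.bayes`)

The multi-SNP model adds, for p preselected SNPs, all p(p−1)/2 pairwise
dosage-product (epistasis) columns and p dosage×age (SNP-age) columns;
q = p(p+3)/2 genetic terms total.  Dosages are centered before forming
products.  Latent indicators `gamma_k` select active terms.  The random
effect is reparameterized through the Cholesky factors,
`u_i = sg M_i b_i` with `b_i ~ N(0, I)`, so all conditionals are
Gaussian in `b_i`.

Priors (all exposed in `BayesConfig`):

* `gamma_k ~ Bernoulli(pi_type)` with `pi_type` = expected active count
  / number of terms of that type (defaults: 3 main, 1 epistasis,
  1 SNP-age);
* `beta_k | gamma_k=1 ~ N(0, tau2)` with
  `tau2 = h Var(y) / (total expected active)`, `h = 0.2`;
* `mu`, covariate effects: flat;
* `se2 ~ scaled-inv-chi-square(df=1, scale=0.5 Var(y))`;
* `sg ~ N+(m_g0=0, s_g0^2=Var(y))` (positive truncated normal).

One sweep updates `mu`, the covariate block (joint Gaussian draw), each
`(gamma_k, beta_k)` pair with `beta_k` integrated out of the inclusion
odds (so inclusion does not depend on a proposal draw), the `b_i`
(batched by visit count), conjugate `se2`, and `sg` by random-walk
Metropolis with reflection at zero and step-size adaptation to a
25–45% acceptance rate during burn-in only.  Indicator sweeps visit a
fresh random permutation of terms each iteration.  For large q,
epistasis and SNP-age indicators can be gated on main effects active
within a recent window (`exhaustive=False`) — an explicit tractability
device for p in the thousands; all validation runs use exhaustive
sweeps.

`iterations` counts post-burn-in sampling iterations, so the reference
schedule (400,000 iterations, 1000 burn-in, thin 40) retains exactly
10,000 states.

Posterior summaries: a term's PIP is its active fraction among retained
samples with +0.5/+0.5 pseudo-count smoothing (so PIP = 1 still yields
a finite Bayes factor); `BF = posterior odds / prior odds`.  A SNP's
combined PIP is the fraction of samples in which *any* term involving
it is active, against prior union odds
`1 − (1−pi_main)(1−pi_epi)^(p−1)(1−pi_ga)` (indicators independent
under the prior).  2·ln(BF) of 2·ln(10) ≈ 4.6 and 2·ln(30) ≈ 6.8 mark
moderate and strong evidence.

Preselection for the multi-SNP model ranks SNPs by single-SNP scan
p-value and greedily admits those with absolute dosage correlation
below 0.95 to every admitted SNP (defaults: top 3000).

## Synthetic testbed (`longmm.simulate`)

The generator emulates a longitudinal blood-pressure-style cohort of
unrelated adults: 139 individuals; visit counts uniform on {1,2,3,4};
baseline age uniform on [30, 60]; inter-visit gaps ~ N(5, 0.5²) years
truncated positive; binary covariates (sex, medication, smoking)
Bernoulli(0.5), constant within individual.  Genotypes are independent
Binomial(2, p) dosages with per-SNP allele frequency uniform on
[0.05, 0.5], placed on a uniform synthetic map (default 3000 SNPs at
100 kb).  Ten causal SNPs pairwise ≥ 10 Mb apart get roles 7 main /
2 epistatic / 1 SNP-age, all with effect size 1.0, and the trait is

    y_i = (g_1 + ... + g_7 + g_8 g_9) 1_{n_i} + g_10 * age_i + u_i + e_i

with `u_i ~ N(0, 0.8 K_i(0.7))` and `e_i ~ N(0, 1·I)` by default.
Causal columns use **raw** dosages (the analysis model centers them;
the asymmetry is intentional).  Replicate r of a study uses seed + r;
everything is bit-reproducible per seed.

What the generator does *not* emulate: linkage disequilibrium (an
optional correlated mode exists only in tests via duplicated columns),
relatedness/pedigrees, covariate effects on the trait, ascertainment,
missing-data mechanisms beyond variable visit counts, and medication
adjustments.  Passing tests therefore demonstrate internal statistical
correctness of the estimators on this design, not robustness to the
LD and confounding structure of real sequencing data.

**A consequence of the raw dosage×age term**: with ages in the 30–75
range, `g_10 * age_i` contributes between-individual variance orders
of magnitude above the other terms.  The null-model refit on such data
absorbs that variance into `sg2` with `rho → 1`, which (correctly,
given the model) shrinks between-individual contrasts and leaves the
visit-constant main effects with little power, while the SNP-age SNP
itself is detected overwhelmingly.  The ROC comparisons in the
evaluation module operate in this regime for all methods equally, with
two measurable consequences: the Bayesian mapper retains a clear
partial-AUC advantage (its explicit SNP-age and epistasis terms recover
signals the single-SNP scan cannot), while the longitudinal versus
first-visit contrast for the single-SNP scan washes out — both
analyses detect essentially only the SNP-age SNP, and their paired
partial-AUC difference is centred on zero (measured mean +0.0004,
sd 0.0036 across 40 replicates).  Extra visits add little power for
visit-constant effects once the refitted random effect absorbs the
between-individual genetic variance.

## Evaluation (`longmm.evaluate`)

A scored SNP is a true positive if it lies strictly within 1 Mb of a
causal SNP on the same chromosome.  ROC curves sweep every score
threshold (ties grouped); replicate averaging is vertical on a fixed
101-point FPR grid; methods are compared by partial AUC on FPR ≤ 0.2.
The "first-visit" comparators rerun the same scanners on each
individual's earliest measurement with an identity correlation — the
cross-sectional analysis as a special case of the longitudinal one.
Causal SNPs are themselves scored (labelable true positives), and each
significant SNP counts separately (no locus collapsing).

## Problem sizes used in validation

The validation suite scales the simulation study to desk size as its
own design choice: variance-recovery runs use 100 replicates of the
default cohort; LRT-oracle equivalence uses 50 random instances with
n ≤ 15; calibration uses 2000 null SNPs over 10 cohorts; the ROC
ordering uses meta-runs of the 200-SNP pool with a 30-SNP preselection
and a shortened (2400-iteration) chain.  The full reference schedule
(100 replicates, 3000-SNP pools, 4×10⁵-iteration chains) is available
through the same interfaces.
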