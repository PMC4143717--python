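# longmm — mixed-model association mapping for longitudinal phenotypes

`longmm` maps genetic variants that influence a quantitative trait
measured repeatedly over time (blood pressure across clinic visits is
the motivating setting) in cohorts of **unrelated** individuals.  It
provides two complementary mappers plus the quality-control, simulation
and evaluation machinery around them:

1. **A single-SNP mixed-model likelihood-ratio scan.**  The classic
   efficient mixed-model association machinery corrects for sample
   structure through a kinship matrix K; here K is replaced by a
   block-diagonal *within-individual serial-correlation* matrix
   `K = diag(K_1, ..., K_n)` with `K_i[j,j'] = rho^{|t_ij - t_ij'|}`
   (spatial-power / continuous-time AR(1); `t_ij` is visit age in
   years).  Per SNP g the model

       y_i = mu 1 + X_ie beta_e + x_ig beta_g + u_i + e_i,
       u_i ~ N(0, sg2 K_i),  e_i ~ N(0, se2 I)

   is fit by maximum likelihood through a one-time spectral
   decomposition (O(N) likelihood evaluations in the variance ratio),
   and `H0: beta_g = 0` is tested by an LRT against chi-square(1).
   `rho, sg2, se2` are estimated once by REML under the no-SNP null,
   with the structure itself chosen by AIC among independence,
   compound symmetry and spatial power.

2. **A Bayesian multi-SNP variable-selection sampler.**  For p
   preselected SNPs the model adds all pairwise epistasis products and
   SNP-age interaction columns (q = p(p+3)/2 genetic terms), selects
   terms through latent indicators updated by Gibbs sampling (with the
   random effect reparameterized via the Cholesky factors
   `u_i = sg M_i b_i`, `M_i M_i' = K_i`, and a positive truncated
   normal prior on `sg`), and reports per-term and per-SNP posterior
   inclusion probabilities and Bayes factors.  2ln(BF) thresholds of
   10 and 30 mark moderate and strong evidence.

A synthetic-cohort generator reproduces the reference study design —
139 unrelated individuals, 1–4 visits about 5 years apart, 10 causal
SNPs (7 main effects, 1 epistatic pair, 1 SNP-age interaction),
`sg2 = 0.8`, `se2 = 1.0` — and an evaluation module builds ROC curves
(true positive = scored SNP strictly within 1 Mb of a causal SNP) and
partial AUCs for method comparison.  See `docs/methods.md` for the
full model and design notes.

## Worked example

```python
import longmm as lm
from longmm.covariance import assemble_block_kinship

# one replicate of the default longitudinal design (200-SNP pool)
panels, gm, truth = lm.simulate_dataset(
    n_individuals=139, m_snps=200, spacing_bp=1_000_000, seed=7)

model = lm.select_covariance(panels)          # REML + AIC
kin = assemble_block_kinship(model, panels)   # frozen K_i, M_i blocks
scan = lm.genome_scan(panels, gm, kinship=kin)

keep = lm.preselect_snps(scan, gm, k=30)      # top SNPs, |r| < 0.95
cat = lm.build_term_catalog(gm.subset(keep).mean_impute(), panels)
cfg = lm.BayesConfig(iterations=4000, burn_in=500, thin=4, seed=7)
chain = lm.mcmc_run(panels, cat, kin, cfg)
summary = lm.summarize_posterior(chain, cat, cfg)
```

Output (seed 7):

```
chrom       pos       id      beta        lrt             p      signif
    1 149000001 snp00149 49.758868 460.160951 4.434714e-102 significant

chrom       pos       id      pip          bf  two_ln_bf signif
    1 149000001 snp00149 0.999500 8747.160981  18.152969 strong
    1 171000001 snp00171 0.905594   41.933009   7.472147 strong
```

`snp00149` is the simulated SNP-age interaction SNP: the scan flags it
far beyond the genome-wide threshold (p < 5e-7).  `snp00171` is one
member of the simulated epistatic pair — the single-SNP scan misses it
(p = 0.051 there), but the Bayesian sampler, which models epistasis
explicitly, gives it a strong combined Bayes factor (BF = 42 > 30).
That contrast — interaction effects recoverable only by the multi-SNP
model — is the point of running both mappers.

## Command line

Every step is also a `longmm` subcommand operating on TSV/VCF/JSON
files:

```bash
longmm qc       --pheno p.tsv --geno g.vcf --maf 0.05 --hwe-alpha auto --r2 0.5 --out g_qc.tsv
longmm fitcov   --pheno p.tsv --structure auto --out cov.json
longmm scan     --pheno p.tsv --geno g_qc.tsv --cov cov.json --out scan.tsv
longmm bayes    --pheno p.tsv --geno g_qc.tsv --cov cov.json --preselect scan.tsv --k 3000 --out bayes.tsv
longmm simulate --n 139 --snps 3000 --reps 100 --seed 1 --out-dir sims/
longmm evaluate --sim-dir sims/ --methods emma_all,emma_first --out roc.tsv --plot roc.png
longmm demo     --reps 20 --seed 1 --out demo/   # end-to-end reduced study
```

Phenotype TSV is long format (`id age trait sex med smoke`, one row
per visit); genotypes are VCF (GT-based, biallelic) or a dosage TSV.
If the trait should be analyzed on the log scale, transform it before
input.

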