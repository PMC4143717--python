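"""Bayesian multiple-SNP mapping with variable selection.

The model extends the single-SNP mixed model to all p preselected SNPs
simultaneously, plus their p(p-1)/2 pairwise epistatic products and p
SNP-age interaction columns:

    y_i = 1 mu + X_ie beta_e + x_i beta + sg M_i b_i + e_i,
    b_i ~ N(0, I),   e_i ~ N(0, se2 I),

where M_i is the lower Cholesky factor of the frozen within-individual
correlation block K_i (so sg M_i b_i has covariance sg2 K_i).  Latent
indicators gamma_k select which of the q = p(p+3)/2 genetic terms are in
the model; their posterior frequencies are the posterior inclusion
probabilities (PIPs), converted to Bayes factors against the prior
inclusion odds.

Sampling is componentwise Gibbs: mu and the covariate effects have flat
priors; each (gamma_k, beta_k) pair is updated jointly with beta_k
integrated out against its N(0, tau2) prior; b_i is a batched
multivariate-normal draw; se2 is conjugate scaled-inverse-chi-square;
sg takes a random-walk Metropolis step against a positive truncated
normal prior N+(m_g0, s_g02), with reflection at zero and step-size
adaptation during burn-in.

The sampling-iteration count is the number of post-burn-in iterations,
so ``iterations=400_000, burn_in=1000, thin=40`` retains exactly 10,000
states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .covariance import BlockKinship
from .data import (
    GenotypeMatrix,
    PhenotypePanel,
    covariate_matrix,
    expand_to_visits,
    stacked_ages,
    stacked_trait,
    visit_counts,
)

logger = logging.getLogger("longmm")

TERM_KINDS = ("main", "epistasis", "gene_age")
MODERATE_BF = 10.0
STRONG_BF = 30.0


# ---------------------------------------------------------------------------
# term catalog
# ---------------------------------------------------------------------------

class TermCatalog:
    """Indexed family of genetic design columns over p SNPs.

    Term order: p main effects, then p(p-1)/2 epistasis products in
    (j < k) lexicographic order, then p SNP-age interactions.  Columns
    are generated on demand from centered per-individual dosages, so the
    epistasis block is never materialized for large p.
    """

    def __init__(
        self,
        gm: GenotypeMatrix,
        panels: Sequence[PhenotypePanel],
        max_p: int = 3000,
    ):
        p = gm.n_snps
        if p < 1:
            raise ValueError("need at least one SNP")
        if p > max_p:
            raise ValueError(f"{p} SNPs exceeds the configured cap {max_p}")
        if [pp.individual_id for pp in panels] != list(gm.individual_ids):
            raise ValueError("genotype individual order != phenotype order")
        self.p = p
        self.snps = gm.snps
        centered = gm.mean_impute().dosage
        centered = centered - centered.mean(axis=0)
        cnt = visit_counts(panels)
        self._main_cols = np.repeat(centered, cnt, axis=0)  # (N, p)
        self.ages = stacked_ages(panels)
        self.n_obs = int(cnt.sum())
        # epistasis linear-index offsets: pair block for first SNP j
        self._epi_offset = np.concatenate(
            [[0], np.cumsum(np.arange(p - 1, 0, -1))]
        )
        self.n_epistasis = p * (p - 1) // 2
        self.q = p + self.n_epistasis + p

    def term_kind(self, k: int) -> str:
        if k < self.p:
            return "main"
        if k < self.p + self.n_epistasis:
            return "epistasis"
        if k < self.q:
            return "gene_age"
        raise IndexError(k)

    def term_snps(self, k: int) -> tuple[int, ...]:
        if k < self.p:
            return (k,)
        if k < self.p + self.n_epistasis:
            e = k - self.p
            j = int(np.searchsorted(self._epi_offset, e, side="right")) - 1
            return (j, int(e - self._epi_offset[j] + j + 1))
        if k < self.q:
            return (k - self.p - self.n_epistasis,)
        raise IndexError(k)

    def epistasis_index(self, j: int, k: int) -> int:
        if not (0 <= j < k < self.p):
            raise ValueError("need 0 <= j < k < p")
        return int(self.p + self._epi_offset[j] + (k - j - 1))

    def gene_age_index(self, j: int) -> int:
        return self.p + self.n_epistasis + j

    def column(self, k: int) -> np.ndarray:
        kind = self.term_kind(k)
        s = self.term_snps(k)
        if kind == "main":
            return self._main_cols[:, s[0]]
        if kind == "epistasis":
            return self._main_cols[:, s[0]] * self._main_cols[:, s[1]]
        return self._main_cols[:, s[0]] * self.ages

    def terms_for_snp(self, j: int) -> list[int]:
        """All term indices whose design column involves SNP j."""
        out = [j, self.gene_age_index(j)]
        out += [self.epistasis_index(min(j, k), max(j, k))
                for k in range(self.p) if k != j]
        return out


def build_term_catalog(
    gm: GenotypeMatrix,
    panels: Sequence[PhenotypePanel],
    max_p: int = 3000,
) -> TermCatalog:
    """Catalog of main, epistasis and SNP-age terms (q = p(p+3)/2)."""
    return TermCatalog(gm, panels, max_p=max_p)


def preselect_snps(
    scan: pd.DataFrame,
    gm: GenotypeMatrix,
    k: int = 3000,
    cor_max: float = 0.95,
) -> np.ndarray:
    """Greedy top-k SNPs by scan p-value with pairwise |r| < cor_max.

    Mirrors the usual multicollinearity guard before multi-SNP
    modelling; returns indices into ``gm`` columns.
    """
    if not (0.0 < cor_max <= 1.0):
        raise ValueError("cor_max must lie in (0, 1]")
    if len(scan) != gm.n_snps:
        raise ValueError("scan rows != genotype columns")
    p_order = np.argsort(scan["p"].to_numpy(), kind="stable")
    d = gm.mean_impute().dosage
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    ok = sd > 0
    d[:, ok] /= sd[ok]
    n = d.shape[0]
    admitted: list[int] = []
    for j in p_order:
        if not np.isfinite(scan["p"].iloc[j]) or not ok[j]:
            continue
        if admitted:
            r = d[:, admitted].T @ d[:, j] / n
            if np.max(np.abs(r)) >= cor_max:
                continue
        admitted.append(int(j))
        if len(admitted) == k:
            break
    if len(admitted) < k:
        logger.warning(
            "only %d of %d requested SNPs admissible under |r| < %g",
            len(admitted), k, cor_max,
        )
    return np.array(sorted(admitted), dtype=int)


# ---------------------------------------------------------------------------
# configuration and chain containers
# ---------------------------------------------------------------------------

@dataclass
class BayesConfig:
    """MCMC schedule and prior hyperparameters.

    ``iterations`` counts post-burn-in sampling iterations; the retained
    chain holds ``iterations // thin`` states.  Expected active-term
    counts set the Bernoulli inclusion priors per term type; ``h`` scales
    the slab variance h * Var(y) / (total expected active terms).
    ``sigma_e_scale`` and ``s_g02`` default to 0.5 * Var(y) and Var(y)
    at run time when left as None.
    """

    iterations: int = 400_000
    burn_in: int = 1000
    thin: int = 40
    seed: int = 0
    expected_main: float = 3.0
    expected_epistasis: float = 1.0
    expected_gene_age: float = 1.0
    h: float = 0.2
    sigma_e_df: float = 1.0
    sigma_e_scale: float | None = None
    m_g0: float = 0.0
    s_g02: float | None = None
    sg_step: float = 0.2
    adapt_interval: int = 50
    exhaustive: bool = True
    candidate_window: int = 50

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0:
            raise ValueError("need iterations > 0 and burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.s_g02 is not None and self.s_g02 <= 0:
            raise ValueError("s_g02 must be positive")

    @property
    def n_retained(self) -> int:
        return self.iterations // self.thin

    def prior_inclusion(self, catalog: TermCatalog) -> np.ndarray:
        """Per-term-type Bernoulli prior probabilities [main, epi, ga]."""
        p, ne = catalog.p, max(catalog.n_epistasis, 1)
        pi = np.array([
            min(self.expected_main / p, 0.9),
            min(self.expected_epistasis / ne, 0.9),
            min(self.expected_gene_age / p, 0.9),
        ])
        return pi


@dataclass
class McmcChain:
    """Retained posterior draws."""

    mu: np.ndarray
    beta_e: np.ndarray           # (R, c)
    sigma_g: np.ndarray
    sigma_e2: np.ndarray
    active: list[np.ndarray]     # per sample: sorted active term indices
    beta_active: list[np.ndarray]
    q: int
    config: BayesConfig
    sg_acceptance: float

    @property
    def n_retained(self) -> int:
        return self.mu.size

    def beta_matrix(self, terms: Sequence[int]) -> np.ndarray:
        """Dense (R, len(terms)) effect draws (zero where excluded)."""
        terms = list(terms)
        pos = {t: i for i, t in enumerate(terms)}
        out = np.zeros((self.n_retained, len(terms)))
        for r, (a, b) in enumerate(zip(self.active, self.beta_active)):
            for t, val in zip(a, b):
                if t in pos:
                    out[r, pos[t]] = val
        return out


@dataclass
class PosteriorSummary:
    """Per-term and per-SNP inclusion summaries.

    For large catalogs the term table lists all main and SNP-age terms
    but only those epistasis terms that were active at least once.
    """

    terms: pd.DataFrame
    snps: pd.DataFrame
    n_retained: int


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class _BlockRandomEffect:
    """Batched machinery for the per-individual random-effect draws."""

    def __init__(self, kinship: BlockKinship, cnt: np.ndarray):
        offsets = np.concatenate([[0], np.cumsum(cnt)])
        self.n_total = int(offsets[-1])
        self.groups = []
        for n in np.unique(cnt):
            idx = np.flatnonzero(cnt == n)
            M = np.stack([kinship.chol[i] for i in idx])      # (g, n, n)
            rows = np.stack(
                [np.arange(offsets[i], offsets[i] + n) for i in idx]
            )
            self.groups.append(
                {"n": int(n), "idx": idx, "M": M,
                 "MtM": M.transpose(0, 2, 1) @ M, "rows": rows}
            )

    def draw_b(self, r_wo_b, sigma_g, sigma_e2, rng):
        """Sample all b_i | rest; returns (b stacked as list-free dict, Mb)."""
        Mb = np.empty(self.n_total)
        b_out = {}
        c = sigma_g ** 2 / sigma_e2
        for g in self.groups:
            n, M, rows = g["n"], g["M"], g["rows"]
            A = np.broadcast_to(np.eye(n), M.shape).copy() + c * g["MtM"]
            rhs = (sigma_g / sigma_e2) * np.einsum(
                "gij,gi->gj", M, r_wo_b[rows]
            )
            mean = np.linalg.solve(A, rhs[..., None])[..., 0]
            L = np.linalg.cholesky(A)
            z = rng.standard_normal(mean.shape)
            b = mean + np.linalg.solve(
                L.transpose(0, 2, 1), z[..., None]
            )[..., 0]
            Mb[rows.ravel()] = np.einsum("gij,gj->gi", M, b).ravel()
            b_out[g["n"]] = (g["idx"], b)
        return b_out, Mb


def mcmc_run(
    panels: Sequence[PhenotypePanel],
    catalog: TermCatalog | None,
    kinship: BlockKinship,
    cfg: BayesConfig,
    covariates: np.ndarray | None = None,
    fixed_gamma: np.ndarray | None = None,
    fix_sigma_g: float | None = None,
    fix_sigma_e2: float | None = None,
) -> McmcChain:
    """Run the Gibbs/Metropolis sampler; reproducible given cfg.seed.

    ``fixed_gamma`` freezes the indicator vector (no selection moves);
    ``fix_sigma_g`` / ``fix_sigma_e2`` freeze variance parameters — both
    are for validation against conjugate oracles as much as for users.
    ``catalog=None`` runs the covariate-only model (q = 0).
    """
    rng = np.random.default_rng(cfg.seed)
    y = stacked_trait(panels)
    N = y.size
    cnt = visit_counts(panels)
    if covariates is None:
        covariates = covariate_matrix(panels)
    Xe = np.asarray(covariates, float)
    if Xe.ndim == 1:
        Xe = Xe[:, None]
    c = Xe.shape[1] if Xe.size else 0
    if kinship.total_dim != N:
        raise ValueError("kinship dimension != observations")

    var_y = float(np.var(y)) if np.var(y) > 0 else 1.0
    se_df = cfg.sigma_e_df
    se_scale = cfg.sigma_e_scale if cfg.sigma_e_scale is not None \
        else 0.5 * var_y
    s_g02 = cfg.s_g02 if cfg.s_g02 is not None else var_y
    q = catalog.q if catalog is not None else 0
    pi_by_type = cfg.prior_inclusion(catalog) if catalog is not None \
        else np.zeros(3)
    kind_code = {"main": 0, "epistasis": 1, "gene_age": 2}
    n_expected = cfg.expected_main + cfg.expected_epistasis \
        + cfg.expected_gene_age
    tau2 = cfg.h * var_y / max(n_expected, 1.0)

    # sweep list: exhaustive over all q, or mains/gene-age with
    # recently-active-main gating for epistasis terms
    exhaustive = cfg.exhaustive or catalog is None
    if catalog is not None and exhaustive and q > 200_000:
        raise ValueError(
            "exhaustive indicator sweeps are infeasible for this many "
            "terms; set exhaustive=False"
        )

    # state
    mu = float(np.mean(y))
    beta_e = np.zeros(c)
    gamma_active: dict[int, float] = {}   # term index -> beta value
    beta_arr = np.zeros(max(q, 1))        # dense mirror of gamma_active
    if fixed_gamma is not None:
        fixed_gamma = np.asarray(fixed_gamma, bool)
        if fixed_gamma.size != q:
            raise ValueError("fixed_gamma length != number of terms")
        for k in np.flatnonzero(fixed_gamma):
            gamma_active[int(k)] = 0.0
    sigma_g = fix_sigma_g if fix_sigma_g is not None \
        else abs(rng.normal(cfg.m_g0, np.sqrt(s_g02))) or np.sqrt(s_g02)
    sigma_e2 = fix_sigma_e2 if fix_sigma_e2 is not None else var_y / 2
    blocks = _BlockRandomEffect(kinship, cnt)
    Mb = np.zeros(N)  # b starts at zero

    # residual bookkeeping
    r = y - mu - (Xe @ beta_e if c else 0.0) - sigma_g * Mb

    # precomputations
    if c:
        XtX = Xe.T @ Xe
        XtX_inv = np.linalg.inv(XtX)
        XtX_inv_chol = np.linalg.cholesky(XtX_inv)
    col_cache = gram = None
    if catalog is not None and q <= 50_000:
        col_cache = np.column_stack([catalog.column(k) for k in range(q)])
        xtx_all = np.einsum("sk,sk->k", col_cache, col_cache)
        kind_all = np.empty(q, dtype=np.int64)
        kind_all[:catalog.p] = 0
        kind_all[catalog.p:catalog.p + catalog.n_epistasis] = 1
        kind_all[catalog.p + catalog.n_epistasis:] = 2
        if q <= 3000:
            # Gram matrix makes the post-flip cross-product update O(q)
            gram = col_cache.T @ col_cache

    mains_recently_active: dict[int, int] = {}

    R = cfg.n_retained
    out_mu = np.empty(R)
    out_be = np.empty((R, c))
    out_sg = np.empty(R)
    out_se2 = np.empty(R)
    out_active: list[np.ndarray] = []
    out_beta: list[np.ndarray] = []

    sg_step = cfg.sg_step * np.sqrt(s_g02)
    sg_accept = sg_try = 0
    sg_accept_total = sg_try_total = 0
    kept = 0
    total_iters = cfg.burn_in + cfg.iterations

    for it in range(total_iters):
        # --- mu (flat prior) ---
        r += mu
        mu = float(rng.normal(np.mean(r), np.sqrt(sigma_e2 / N)))
        r -= mu

        # --- covariate effects (flat prior, joint draw) ---
        if c:
            r += Xe @ beta_e
            bhat = XtX_inv @ (Xe.T @ r)
            beta_e = bhat + np.sqrt(sigma_e2) * (
                XtX_inv_chol @ rng.standard_normal(c)
            )
            r -= Xe @ beta_e

        # --- indicator/effect sweep ---
        # sequential Gibbs over terms, vectorized by maintaining the
        # cross-product vector m = C^T r with a rank-1 update whenever a
        # term's contribution to the residual changes (exact kernel)
        if q:
            if fixed_gamma is not None:
                sweep = np.flatnonzero(fixed_gamma)
            elif exhaustive:
                sweep = np.arange(q)
            else:
                sweep = list(range(catalog.p))  # all mains
                recent = {
                    j for j, t in mains_recently_active.items()
                    if it - t <= cfg.candidate_window * cfg.thin
                }
                sweep += [catalog.gene_age_index(j) for j in recent]
                sweep += [
                    catalog.epistasis_index(min(j, k), max(j, k))
                    for j in recent for k in recent if j < k
                ]
                sweep += [k for k in gamma_active if k not in set(sweep)]
                sweep = np.array(sorted(set(sweep)), dtype=int)
            sweep = rng.permutation(sweep)
            ns = len(sweep)
            full = col_cache is not None and ns == q
            karr = sweep.astype(int)
            if full:
                C = col_cache
                jarr = karr           # column/cross-product index
                m_vec = C.T @ r       # indexed by term id
                sxx_arr = xtx_all[karr]
                kind_arr = kind_all[karr]
            else:
                C = np.column_stack(
                    [catalog.column(int(k)) for k in karr]
                )
                jarr = np.arange(ns)
                m_vec = C.T @ r       # indexed by sweep position
                sxx_arr = np.einsum("sk,sk->k", C, C)
                kind_arr = np.array(
                    [kind_code[catalog.term_kind(int(k))] for k in karr]
                )
            log_u = np.log(rng.random(ns))
            normals = rng.standard_normal(ns)
            valid = sxx_arr > 0
            S_arr = np.where(valid, sxx_arr, 1.0) / sigma_e2 + 1.0 / tau2
            prior_term = (np.log(pi_by_type / (1 - pi_by_type))[kind_arr]
                          - 0.5 * np.log(tau2 * S_arr))
            # walk the permutation in vectorized stretches: decisions for
            # a run of terms that neither are active nor get included do
            # not alter the residual, so they can be evaluated in one go
            # against the current m_vec (identical kernel and RNG stream)
            pos = 0
            while pos < ns:
                mk = (m_vec[jarr[pos:]]
                      + sxx_arr[pos:] * beta_arr[karr[pos:]]) / sigma_e2
                if fixed_gamma is not None:
                    inc = valid[pos:].copy()
                else:
                    lo = prior_term[pos:] + 0.5 * mk * mk / S_arr[pos:]
                    inc = (log_u[pos:] < lo - np.logaddexp(0, lo)) \
                        & valid[pos:]
                change = inc | (beta_arr[karr[pos:]] != 0.0)
                nz = np.flatnonzero(change)
                if nz.size == 0:
                    break
                t = pos + int(nz[0])
                k, j = int(karr[t]), int(jarr[t])
                beta_old = float(beta_arr[k])
                if not valid[t]:
                    beta_arr[k] = 0.0
                    gamma_active.pop(k, None)
                    pos = t + 1
                    continue
                if inc[nz[0]]:
                    m_k = float(mk[nz[0]])
                    S = float(S_arr[t])
                    beta_new = m_k / S + normals[t] / np.sqrt(S)
                    beta_arr[k] = beta_new
                    gamma_active[k] = float(beta_new)
                    if kind_arr[t] == 0:
                        mains_recently_active[k] = it
                else:
                    beta_new = 0.0
                    beta_arr[k] = 0.0
                    gamma_active.pop(k, None)
                dbeta = beta_old - beta_new
                if dbeta != 0.0:
                    x = C[:, j]
                    r += x * dbeta
                    if full and gram is not None:
                        m_vec += gram[j] * dbeta
                    else:
                        m_vec += (x @ C) * dbeta
                pos = t + 1

        # --- random effects b ---
        r_wo_b = r + sigma_g * Mb
        b_state, Mb = blocks.draw_b(r_wo_b, sigma_g, sigma_e2, rng)
        r = r_wo_b - sigma_g * Mb

        # --- residual variance (scaled inverse chi-square) ---
        if fix_sigma_e2 is None:
            rss = float(r @ r)
            sigma_e2 = (se_df * se_scale + rss) / rng.chisquare(se_df + N)

        # --- sigma_g random-walk Metropolis with reflection at 0 ---
        if fix_sigma_g is None:
            r_base = r + sigma_g * Mb
            a = float(Mb @ r_base)
            c2 = float(Mb @ Mb)
            prop = abs(sigma_g + sg_step * rng.standard_normal())

            def log_target(s):
                quad = -0.5 * (c2 * s * s - 2 * a * s) / sigma_e2
                prior = -0.5 * (s - cfg.m_g0) ** 2 / s_g02
                return quad + prior

            sg_try += 1
            sg_try_total += 1
            if np.log(rng.random()) < log_target(prop) - log_target(sigma_g):
                sigma_g = prop
                sg_accept += 1
                sg_accept_total += 1
            r = r_base - sigma_g * Mb

            # step adaptation during burn-in only
            if it < cfg.burn_in and sg_try >= cfg.adapt_interval:
                rate = sg_accept / sg_try
                if rate < 0.25:
                    sg_step = max(sg_step * 0.5, 1e-8)
                elif rate > 0.45:
                    sg_step *= 2.0
                sg_accept = sg_try = 0

        if not np.all(np.isfinite(r)):
            raise RuntimeError(
                f"non-finite state at iteration {it}: mu={mu}, "
                f"sigma_g={sigma_g}, sigma_e2={sigma_e2}"
            )

        # --- retain ---
        n_post = it - cfg.burn_in + 1
        if n_post >= 1 and n_post % cfg.thin == 0 and kept < R:
            out_mu[kept] = mu
            if c:
                out_be[kept] = beta_e
            out_sg[kept] = sigma_g
            out_se2[kept] = sigma_e2
            act = np.array(sorted(gamma_active), dtype=int)
            out_active.append(act)
            out_beta.append(
                np.array([gamma_active[k] for k in act], dtype=float)
            )
            kept += 1

    rate_total = sg_accept_total / max(sg_try_total, 1)
    if fix_sigma_g is None and not (0.1 <= rate_total <= 0.6):
        logger.warning(
            "sigma_g Metropolis acceptance rate %.2f outside [0.1, 0.6]",
            rate_total,
        )
    return McmcChain(out_mu[:kept], out_be[:kept], out_sg[:kept],
                     out_se2[:kept], out_active, out_beta, q, cfg,
                     rate_total)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def _bf(pip: np.ndarray, prior: np.ndarray) -> np.ndarray:
    return (pip / (1 - pip)) / (prior / (1 - prior))


def summarize_posterior(
    chain: McmcChain, catalog: TermCatalog, cfg: BayesConfig | None = None
) -> PosteriorSummary:
    """PIPs and Bayes factors per term and per SNP.

    Inclusion tallies get +0.5/+0.5 pseudo-counts so a term active in
    every retained sample still yields a finite BF.  The per-SNP
    combined PIP is the posterior probability that *any* term involving
    the SNP is active, against the matching prior union odds.
    """
    cfg = cfg or chain.config
    R = chain.n_retained
    if R < 100:
        raise ValueError("need at least 100 retained samples to summarize")
    p, q = catalog.p, catalog.q
    pi_by_type = cfg.prior_inclusion(catalog)
    if np.any(pi_by_type <= 0) or np.any(pi_by_type >= 1):
        raise ValueError("prior inclusion probabilities must lie in (0, 1)")

    term_counts: dict[int, int] = {}
    snp_counts = np.zeros(p)
    for act in chain.active:
        snps_hit = set()
        for k in act:
            k = int(k)
            term_counts[k] = term_counts.get(k, 0) + 1
            snps_hit.update(catalog.term_snps(k))
        for j in snps_hit:
            snp_counts[j] += 1

    # term table: all mains and gene-age terms, plus ever-active epistasis
    term_ids = list(range(p)) + sorted(
        k for k in term_counts if catalog.term_kind(k) == "epistasis"
    ) + [catalog.gene_age_index(j) for j in range(p)]
    rows = []
    for k in term_ids:
        kind = catalog.term_kind(k)
        pip = (term_counts.get(k, 0) + 0.5) / (R + 1)
        prior = pi_by_type[TERM_KINDS.index(kind)]
        bf = float(_bf(np.array(pip), np.array(prior)))
        snp_ids = "+".join(catalog.snps["id"].iloc[list(catalog.term_snps(k))])
        rows.append((kind, k, snp_ids, pip, bf, 2 * np.log(bf)))
    terms = pd.DataFrame(
        rows, columns=["term_type", "term_id", "snps", "pip", "bf",
                       "two_ln_bf"],
    )

    pi_union = 1.0 - (
        (1 - pi_by_type[0])
        * (1 - pi_by_type[1]) ** (p - 1)
        * (1 - pi_by_type[2])
    )
    snp_pip = (snp_counts + 0.5) / (R + 1)
    snp_bf = _bf(snp_pip, np.full(p, pi_union))
    snps = catalog.snps[["chrom", "pos", "id"]].copy()
    snps["pip"] = snp_pip
    snps["bf"] = snp_bf
    snps["two_ln_bf"] = 2 * np.log(snp_bf)
    snps["signif"] = np.select(
        [snp_bf >= STRONG_BF, snp_bf >= MODERATE_BF],
        ["strong", "moderate"], default="",
    )
    return PosteriorSummary(terms, snps, R)
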