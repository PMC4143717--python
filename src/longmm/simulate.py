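"""Synthetic longitudinal GWAS cohorts.

The generator emulates a cohort of unrelated adults measured repeatedly
for a quantitative trait: by default 139 individuals with one to four
visits about five years apart, independent biallelic SNPs, and a trait
built from ten causal SNPs — seven additive main effects, one epistatic
pair (dosage product) and one SNP-age interaction — on top of a
spatial-power correlated individual random effect:

    y_i = (g_1 + ... + g_7 + g_8 * g_9) 1_{n_i} + g_10 * age_i + u_i + e_i,
    u_i ~ N(0, sg2 * K_i(rho)),   e_i ~ N(0, se2 * I).

Default variance components are sg2 = 0.8, se2 = 1.0 with rho = 0.7;
causal effect sizes are 1.0 (unweighted sums).  Causal contributions use
raw dosages; downstream analyses may center them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance import build_spatial_power_block
from .data import GenotypeMatrix, PhenotypePanel

MIN_CAUSAL_SPACING_BP = 10_000_000
N_CAUSAL = 10
ROLE_COUNTS = {"main": 7, "epistasis": 2, "gene_age": 1}


@dataclass
class VisitSpec:
    """Distribution of visit schedules.

    ``counts``/``probs`` give the visit-count distribution (default
    uniform on 1..4); baseline age is uniform on ``baseline_age`` and
    inter-visit gaps are Normal(gap_mean, gap_sd^2) truncated positive.
    """

    counts: tuple[int, ...] = (1, 2, 3, 4)
    probs: tuple[float, ...] | None = None
    baseline_age: tuple[float, float] = (30.0, 60.0)
    gap_mean: float = 5.0
    gap_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.probs is not None and len(self.probs) != len(self.counts):
            raise ValueError("probs length must match counts")
        if min(self.counts) < 1:
            raise ValueError("visit counts must be >= 1")
        if self.gap_mean <= 0 or self.gap_sd < 0:
            raise ValueError("invalid gap specification")


@dataclass
class TruthSet:
    """Identity and role of the simulated causal SNPs."""

    snp_indices: np.ndarray        # 10 column indices into the genotype pool
    roles: list[str]               # per causal SNP: main|epistasis|gene_age
    chroms: list[str]
    positions: np.ndarray
    effect_size: float = 1.0
    rho: float = 0.7
    sigma_g2: float = 0.8
    sigma_e2: float = 1.0

    def __post_init__(self) -> None:
        counts = {r: self.roles.count(r) for r in ROLE_COUNTS}
        if counts != ROLE_COUNTS:
            raise ValueError(f"role counts {counts} != {ROLE_COUNTS}")
        if len(self.snp_indices) != N_CAUSAL:
            raise ValueError("expected exactly 10 causal SNPs")

    def indices_by_role(self, role: str) -> np.ndarray:
        return np.array(
            [i for i, r in zip(self.snp_indices, self.roles) if r == role]
        )


def simulate_cohort(
    n_individuals: int = 139,
    visit_spec: VisitSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> list[PhenotypePanel]:
    """Draw visit schedules and covariates; traits are filled with zeros.

    Covariates sex/med/smoke are Bernoulli(0.5), constant within
    individual.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    spec = visit_spec or VisitSpec()
    rng = np.random.default_rng(seed)
    panels = []
    for i in range(n_individuals):
        n_visits = int(rng.choice(spec.counts, p=spec.probs))
        base = rng.uniform(*spec.baseline_age)
        gaps = rng.normal(spec.gap_mean, spec.gap_sd, size=max(n_visits - 1, 0))
        gaps = np.abs(gaps)
        gaps[gaps == 0] = spec.gap_mean
        ages = base + np.concatenate([[0.0], np.cumsum(gaps)])
        cov = pd.DataFrame(
            {c: np.repeat(rng.integers(0, 2), n_visits)
             for c in ("sex", "med", "smoke")},
            dtype=float,
        )
        panels.append(
            PhenotypePanel(f"ind{i:04d}", ages, np.zeros(n_visits), cov)
        )
    return panels


def simulate_genotypes(
    n_individuals: int,
    m_snps: int = 3000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    spacing_bp: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Independent biallelic SNPs: dosage ~ Binomial(2, p), p ~ U(maf_range).

    SNPs sit on one synthetic chromosome at ``spacing_bp`` intervals; the
    map must be able to host 10 causal SNPs pairwise >= 10 Mb apart.
    """
    if not (0.05 <= maf_range[0] <= maf_range[1] <= 0.5):
        raise ValueError("maf_range must lie within [0.05, 0.5]")
    if (m_snps - 1) * spacing_bp < (N_CAUSAL - 1) * MIN_CAUSAL_SPACING_BP:
        raise ValueError(
            f"map of {m_snps} SNPs at {spacing_bp} bp spacing cannot host "
            f"{N_CAUSAL} causal SNPs {MIN_CAUSAL_SPACING_BP} bp apart"
        )
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_range[0], maf_range[1], size=m_snps)
    dosage = rng.binomial(2, freqs, size=(n_individuals, m_snps)).astype(float)
    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 1 + spacing_bp * np.arange(m_snps),
            "id": [f"snp{j:05d}" for j in range(m_snps)],
        }
    )
    return GenotypeMatrix(
        dosage, snps, [f"ind{i:04d}" for i in range(n_individuals)]
    )


def draw_truth_set(
    gm: GenotypeMatrix,
    seed: int | np.random.Generator = 0,
    rho: float = 0.7,
    sigma_g2: float = 0.8,
    sigma_e2: float = 1.0,
    effect_size: float = 1.0,
) -> TruthSet:
    """Pick 10 causal SNPs pairwise >= 10 Mb apart and assign roles 7/2/1."""
    rng = np.random.default_rng(seed)
    pos = gm.snps["pos"].to_numpy()
    chrom = gm.snps["chrom"].to_numpy()

    def greedy(order):
        chosen: list[int] = []
        for j in order:
            ok = all(
                chrom[k] != chrom[j]
                or abs(int(pos[j]) - int(pos[k])) >= MIN_CAUSAL_SPACING_BP
                for k in chosen
            )
            if ok:
                chosen.append(int(j))
            if len(chosen) == N_CAUSAL:
                return chosen
        return None

    # left-to-right greedy realizes the maximum spaced subset; use it to
    # decide feasibility, then draw randomly until a spaced set appears
    feasible = greedy(np.lexsort((pos, chrom)))
    if feasible is None:
        raise ValueError(
            "genotype map cannot host 10 causal SNPs pairwise >= 10 Mb apart"
        )
    chosen = None
    for _ in range(1000):
        chosen = greedy(rng.permutation(gm.n_snps))
        if chosen is not None:
            break
    if chosen is None:  # extremely tight map: accept the deterministic set
        chosen = feasible
    roles = ["main"] * 7 + ["epistasis"] * 2 + ["gene_age"]
    idx = np.array(sorted(chosen))
    perm = rng.permutation(N_CAUSAL)  # random role assignment
    roles = [roles[k] for k in perm]
    return TruthSet(
        idx, roles, [str(chrom[i]) for i in idx], pos[idx].astype(int),
        effect_size=effect_size, rho=rho, sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
    )


def simulate_phenotypes(
    panels: list[PhenotypePanel],
    gm: GenotypeMatrix,
    truth: TruthSet,
    rho: float | None = None,
    sigma_g2: float | None = None,
    sigma_e2: float | None = None,
    seed: int | np.random.Generator = 0,
) -> list[PhenotypePanel]:
    """Fill trait values according to the causal model (raw dosages).

    Main and epistatic contributions are visit-constant; the SNP-age
    contribution is dosage x visit age.  u_i is drawn through the
    Cholesky factor of sg2 * K_i(rho).
    """
    rho = truth.rho if rho is None else rho
    sigma_g2 = truth.sigma_g2 if sigma_g2 is None else sigma_g2
    sigma_e2 = truth.sigma_e2 if sigma_e2 is None else sigma_e2
    if sigma_g2 < 0 or sigma_e2 <= 0:
        raise ValueError("need sigma_g2 >= 0 and sigma_e2 > 0")
    rng = np.random.default_rng(seed)

    main = truth.indices_by_role("main")
    epi = truth.indices_by_role("epistasis")
    ge = truth.indices_by_role("gene_age")
    d = gm.dosage
    base = truth.effect_size * (
        d[:, main].sum(axis=1) + d[:, epi[0]] * d[:, epi[1]]
    )
    ge_dose = truth.effect_size * d[:, ge[0]]

    out = []
    for i, p in enumerate(panels):
        K = build_spatial_power_block(rho, p.ages)
        M = np.linalg.cholesky(K)
        u = np.sqrt(sigma_g2) * (M @ rng.standard_normal(p.n_visits))
        e = np.sqrt(sigma_e2) * rng.standard_normal(p.n_visits)
        y = base[i] + ge_dose[i] * p.ages + u + e
        out.append(p.with_trait(y))
    return out


def simulate_dataset(
    n_individuals: int = 139,
    m_snps: int = 3000,
    spacing_bp: int = 100_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    visit_spec: VisitSpec | None = None,
    rho: float = 0.7,
    sigma_g2: float = 0.8,
    sigma_e2: float = 1.0,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[list[PhenotypePanel], GenotypeMatrix, TruthSet]:
    """One full replicate: cohort + genotypes + truth + phenotypes.

    Replicate r of a study conventionally uses ``seed + r``.
    """
    rng = np.random.default_rng(seed)
    panels = simulate_cohort(n_individuals, visit_spec, rng)
    gm = simulate_genotypes(n_individuals, m_snps, maf_range, spacing_bp, rng)
    truth = draw_truth_set(gm, rng, rho, sigma_g2, sigma_e2, effect_size)
    panels = simulate_phenotypes(panels, gm, truth, seed=rng)
    return panels, gm, truth
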