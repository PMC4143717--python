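"""Shared fixtures: small synthetic cohorts and dense-matrix oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla
import scipy.optimize

import longmm as lm
from longmm.covariance import build_spatial_power_block


def make_panels(n, seed=0, counts=(1, 2, 3, 4)):
    """Cohort skeleton with traits drawn from the null (no genetics)."""
    panels = lm.simulate_cohort(n, lm.VisitSpec(counts=counts), seed=seed)
    rng = np.random.default_rng(seed + 1)
    return [p.with_trait(rng.normal(size=p.n_visits)) for p in panels]


def dense_sigma(panels, rho, sg2, se2):
    K = sla.block_diag(
        *[build_spatial_power_block(rho, p.ages) for p in panels]
    )
    return sg2 * K + se2 * np.eye(K.shape[0])


def dense_ml_loglik(y, X, Sigma):
    """Exact multivariate-normal log-likelihood with GLS fixed effects."""
    N = len(y)
    Si = np.linalg.inv(Sigma)
    beta = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
    r = y - X @ beta
    return float(
        -0.5 * (N * np.log(2 * np.pi) + np.linalg.slogdet(Sigma)[1]
                + r @ Si @ r)
    )


def dense_ml_max(y, X, blocks):
    """Numerically maximize the exact ML over (sg2, se2), dense matrices.

    Independent of the spectral path: direct inversion/determinant, and
    a 2-D Nelder-Mead over log-variances from several starts.
    """
    K = sla.block_diag(*blocks)
    N = K.shape[0]
    I = np.eye(N)

    def neg(theta):
        sg2, se2 = np.exp(theta)
        return -dense_ml_loglik(y, X, sg2 * K + se2 * I)

    best = None
    for start in ([0.0, 0.0], [2.0, -2.0], [-2.0, 2.0], [-5.0, 0.5]):
        res = scipy.optimize.minimize(
            neg, start, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


@pytest.fixture(scope="session")
def toy_cohort():
    """12 individuals with mixed 1-3 visits, trait from the causal model."""
    panels = lm.simulate_cohort(12, lm.VisitSpec(counts=(1, 2, 3)), seed=4)
    gm = lm.simulate_genotypes(12, 150, spacing_bp=1_000_000, seed=4)
    truth = lm.draw_truth_set(gm, seed=4)
    panels = lm.simulate_phenotypes(panels, gm, truth, seed=5)
    return panels, gm, truth


@pytest.fixture(scope="session")
def null_cohort():
    """139-individual default-design cohort with genetic effects zeroed."""
    return lm.simulate_dataset(
        n_individuals=139, m_snps=150, spacing_bp=1_000_000,
        effect_size=0.0, seed=12,
    )


@pytest.fixture()
def pheno_tsv(tmp_path):
    path = tmp_path / "pheno.tsv"
    path.write_text(
        "id\tage\ttrait\tsex\tmed\tsmoke\n"
        "A\t40\t1.1\t1\t0\t0\n"
        "A\t45\t1.3\t1\t0\t0\n"
        "A\t50\t1.2\t1\t1\t0\n"
        "B\t38\t0.9\t0\t0\t1\n"
    )
    return path
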