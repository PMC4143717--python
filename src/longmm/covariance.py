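"""Within-individual covariance estimation for the null longitudinal model.

The trait model is

    y = 1 mu + X_e beta_e + u + e,   cov(y_i) = sg2 * K_i(rho) + se2 * I,

with block-diagonal K built per individual from visit ages.  Supported
structures:

* ``spatial_power`` — K_i[j, j'] = rho ** |age_ij - age_ij'|, the
  continuous-time AR(1) for irregular visit spacing;
* ``compound_symmetry`` — constant correlation rho between any two
  visits of the same individual;
* ``independence`` — no within-individual correlation (a single
  residual variance; the split into sg2 and se2 is not identifiable
  when K = I, so sg2 is reported as 0).

Variance components are estimated by REML, profiling the variance ratio
delta = se2/sg2 on a log grid with local refinement, inside a 1-D
profile over rho (grid step 0.01, refined by bounded scalar search).
Model choice among structures is by AIC = -2*loglik + 2*k with k the
number of free covariance parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize

from .data import PhenotypePanel, covariate_matrix, stacked_trait, visit_counts

STRUCTURES = ("independence", "compound_symmetry", "spatial_power")

#: free covariance parameters per structure (for AIC)
N_PARAMS = {"independence": 1, "compound_symmetry": 3, "spatial_power": 3}

_LN_DELTA_RANGE = (-10.0, 10.0)
_N_LN_DELTA = 101  # 100 intervals


def build_spatial_power_block(rho: float, ages: np.ndarray) -> np.ndarray:
    """Correlation block rho ** |age_j - age_j'| with unit diagonal."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    ages = np.asarray(ages, dtype=float)
    if ages.size > 1 and np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    d = np.abs(ages[:, None] - ages[None, :])
    return rho ** d if rho > 0 else np.eye(ages.size) + 0.0 * d


def build_compound_symmetry_block(rho: float, n: int) -> np.ndarray:
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    return (1.0 - rho) * np.eye(n) + rho * np.ones((n, n))


def _block(kind: str, rho: float, ages: np.ndarray) -> np.ndarray:
    if kind == "spatial_power":
        return build_spatial_power_block(rho, ages)
    if kind == "compound_symmetry":
        return build_compound_symmetry_block(rho, len(ages))
    if kind == "independence":
        return np.eye(len(ages))
    raise ValueError(f"unknown covariance structure {kind!r}")


@dataclass
class CovarianceModel:
    """Fitted null-model covariance structure."""

    kind: str
    rho: float | None
    sigma_g2: float
    sigma_e2: float
    loglik: float
    aic: float
    n_params: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CovarianceModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class BlockKinship:
    """Per-individual correlation blocks and their Cholesky factors."""

    individual_ids: list[str]
    blocks: list[np.ndarray]
    chol: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chol:
            self.chol = []
            for iid, K in zip(self.individual_ids, self.blocks):
                try:
                    self.chol.append(np.linalg.cholesky(K))
                except np.linalg.LinAlgError as exc:
                    raise ValueError(
                        f"correlation block for individual {iid!r} is not "
                        f"positive definite"
                    ) from exc
        for iid, K, M in zip(self.individual_ids, self.blocks, self.chol):
            resid = np.max(np.abs(M @ M.T - K))
            if resid > 1e-10:
                raise ValueError(
                    f"Cholesky reconstruction residual {resid:.2e} for "
                    f"individual {iid!r}"
                )

    @property
    def total_dim(self) -> int:
        return sum(K.shape[0] for K in self.blocks)

    def full(self) -> np.ndarray:
        """Dense block-diagonal K (for small problems / oracles)."""
        N = self.total_dim
        out = np.zeros((N, N))
        o = 0
        for K in self.blocks:
            n = K.shape[0]
            out[o:o + n, o:o + n] = K
            o += n
        return out


# ---------------------------------------------------------------------------
# grouped block spectral machinery
# ---------------------------------------------------------------------------

class BlockRotation:
    """Eigendecomposition of a block-diagonal K, applied blockwise.

    Rows of rotated arrays stay in the stacked visit order, so the
    eigenvalue vector is aligned with the rotated observations.
    Individuals are grouped by visit count so the per-block eigensolves
    and rotations run batched.
    """

    def __init__(self, panels: Sequence[PhenotypePanel], kind: str, rho: float):
        cnt = visit_counts(panels)
        offsets = np.concatenate([[0], np.cumsum(cnt)])
        self.n_total = int(offsets[-1])
        self.eigvals = np.empty(self.n_total)
        self._U: list[np.ndarray | None] = [None] * len(panels)
        self._offsets = offsets
        self._cnt = cnt
        for n in np.unique(cnt):
            idx = np.flatnonzero(cnt == n)
            ages = np.stack([panels[i].ages for i in idx])  # (g, n)
            if kind == "spatial_power":
                D = np.abs(ages[:, :, None] - ages[:, None, :])
                K = rho ** D if rho > 0 else np.broadcast_to(
                    np.eye(n), (len(idx), n, n)
                ).copy()
            elif kind == "compound_symmetry":
                K = np.broadcast_to(
                    build_compound_symmetry_block(rho, n), (len(idx), n, n)
                ).copy()
            else:
                K = np.broadcast_to(np.eye(n), (len(idx), n, n)).copy()
            w, U = np.linalg.eigh(K)
            if np.min(w) < -1e-10:
                raise ValueError("negative eigenvalue in correlation block")
            for g, i in enumerate(idx):
                o = offsets[i]
                self.eigvals[o:o + n] = w[g]
                self._U[i] = U[g]

    @classmethod
    def from_blocks(cls, blocks: Sequence[np.ndarray]) -> "BlockRotation":
        """Build the rotation from explicit per-individual blocks."""
        self = cls.__new__(cls)
        cnt = np.array([K.shape[0] for K in blocks], dtype=int)
        offsets = np.concatenate([[0], np.cumsum(cnt)])
        self.n_total = int(offsets[-1])
        self._offsets, self._cnt = offsets, cnt
        self.eigvals = np.empty(self.n_total)
        self._U = []
        for i, K in enumerate(blocks):
            w, U = np.linalg.eigh(K)
            if np.min(w) < -1e-10:
                raise ValueError(
                    f"negative eigenvalue in correlation block {i}"
                )
            o, n = offsets[i], cnt[i]
            self.eigvals[o:o + n] = np.maximum(w, 0.0)
            self._U.append(U)
        return self

    def rotate(self, v: np.ndarray) -> np.ndarray:
        """Apply U^T blockwise to a stacked vector or (N, p) matrix."""
        out = np.empty_like(v, dtype=float)
        for i, U in enumerate(self._U):
            o, n = self._offsets[i], self._cnt[i]
            out[o:o + n] = U.T @ v[o:o + n]
        return out

    def rotate_individual_constant(self, x: np.ndarray) -> np.ndarray:
        """Rotate a per-individual constant column (e.g. SNP dosage)."""
        if not hasattr(self, "_u1"):
            self._u1 = [U.sum(axis=0) for U in self._U]  # U^T 1
        out = np.empty(self.n_total)
        for i, u1 in enumerate(self._u1):
            o, n = self._offsets[i], self._cnt[i]
            out[o:o + n] = x[i] * u1
        return out


# ---------------------------------------------------------------------------
# profiled likelihoods on the rotated scale
# ---------------------------------------------------------------------------

def _wls_pieces(eig, ytil, Xtil, deltas):
    """Batched weighted-LS quantities over a vector of delta values.

    Returns (rss, logdet_XtWX, sum_log_w_inv) arrays, one per delta.
    """
    deltas = np.atleast_1d(deltas)
    W = 1.0 / (eig[None, :] + deltas[:, None])          # (d, N)
    XtWX = np.einsum("ds,sp,sq->dpq", W, Xtil, Xtil)
    XtWy = np.einsum("ds,sp,s->dp", W, Xtil, ytil)
    yWy = W @ (ytil ** 2)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    rss = yWy - np.einsum("dp,dp->d", beta, XtWy)
    sign, logdet = np.linalg.slogdet(XtWX)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("rank-deficient fixed-effect design")
    sum_log = np.sum(np.log(eig[None, :] + deltas[:, None]), axis=1)
    return rss, logdet, sum_log, beta


def reml_loglik(eig, ytil, Xtil, deltas):
    """Profiled (over sg2 and fixed effects) REML log-likelihood."""
    N, p = Xtil.shape
    rss, logdet, sum_log, _ = _wls_pieces(eig, ytil, Xtil, deltas)
    sg2 = rss / (N - p)
    return -0.5 * ((N - p) * (np.log(2 * np.pi) + 1 + np.log(sg2))
                   + sum_log + logdet)


def ml_loglik(eig, ytil, Xtil, deltas):
    """Profiled ML log-likelihood over a vector of delta values."""
    N, p = Xtil.shape
    rss, _, sum_log, _ = _wls_pieces(eig, ytil, Xtil, deltas)
    sg2 = rss / N
    return -0.5 * (N * (np.log(2 * np.pi) + 1 + np.log(sg2)) + sum_log)


def _maximize_over_delta(eig, ytil, Xtil, kind: str = "reml",
                         refine: bool = True):
    """Grid search on ln(delta) with bounded local refinement.

    Returns (loglik, delta).  ``refine=False`` returns the grid maximum
    (used while scanning rho, where only the argmax over rho matters).
    """
    fun = reml_loglik if kind == "reml" else ml_loglik
    lnd = np.linspace(*_LN_DELTA_RANGE, _N_LN_DELTA)
    ll = fun(eig, ytil, Xtil, np.exp(lnd))
    best_ll = float(np.max(ll))
    best_lnd = float(lnd[int(np.argmax(ll))])
    if not refine:
        return best_ll, float(np.exp(best_lnd))
    # refine every interior local maximum of the grid profile (the
    # profile can be multimodal in delta), plus the boundary maxima
    is_peak = np.zeros(len(lnd), dtype=bool)
    is_peak[1:-1] = (ll[1:-1] > ll[:-2]) & (ll[1:-1] > ll[2:])
    is_peak[int(np.argmax(ll))] = True
    for i in np.flatnonzero(is_peak):
        lo = lnd[max(i - 1, 0)]
        hi = lnd[min(i + 1, len(lnd) - 1)]
        if hi <= lo:
            continue
        res = optimize.minimize_scalar(
            lambda t: -float(fun(eig, ytil, Xtil, np.exp([t]))[0]),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun > best_ll:
            best_ll, best_lnd = float(-res.fun), float(res.x)
    return best_ll, float(np.exp(best_lnd))


def _design(panels, covariates):
    y = stacked_trait(panels)
    if covariates is None:
        covariates = covariate_matrix(panels)
    X = np.column_stack([np.ones(len(y)), covariates]) if covariates.size \
        else np.ones((len(y), 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    return y, X


def _reml_independence(y, X):
    # same likelihood definition as reml_loglik with K = I absorbed into
    # the residual variance (eig + delta == 1, sg2 == s2)
    N, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / (N - p)
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * ((N - p) * (np.log(2 * np.pi) + 1 + np.log(s2)) + logdetXtX)
    return ll, s2


def fit_null_model(
    panels: Sequence[PhenotypePanel],
    kind: str = "spatial_power",
    covariates: np.ndarray | None = None,
    rho_grid_step: float = 0.01,
) -> CovarianceModel:
    """REML fit of the null (no-SNP) longitudinal mixed model.

    For correlated structures rho is profiled on a grid in [0, 0.99]
    with step ``rho_grid_step`` followed by bounded scalar refinement;
    at each rho the variance ratio delta = se2/sg2 is itself profiled on
    a log grid, and sg2 drops out in closed form.

    Raises if the structure needs repeated measures but fewer than two
    individuals have >= 2 visits.
    """
    if kind not in STRUCTURES:
        raise ValueError(f"unknown covariance structure {kind!r}")
    y, X = _design(panels, covariates)
    N, p = X.shape

    if kind == "independence":
        ll, s2 = _reml_independence(y, X)
        k = N_PARAMS[kind]
        return CovarianceModel(kind, None, 0.0, s2, ll, -2 * ll + 2 * k, k)

    n_repeated = int(np.sum(visit_counts(panels) >= 2))
    if n_repeated < 2:
        raise ValueError(
            f"structure {kind!r} needs >= 2 individuals with repeated "
            f"measures; found {n_repeated}"
        )

    def reml_at_rho(rho: float, refine: bool = True):
        rot = BlockRotation(panels, kind, rho)
        ytil = rot.rotate(y)
        Xtil = rot.rotate(X)
        return _maximize_over_delta(rot.eigvals, ytil, Xtil, "reml",
                                    refine=refine)

    rhos = np.arange(0.0, 0.99 + 1e-12, rho_grid_step)
    lls = np.array([reml_at_rho(r, refine=False)[0] for r in rhos])
    i = int(np.argmax(lls))
    lo, hi = rhos[max(i - 1, 0)], rhos[min(i + 1, len(rhos) - 1)]
    best_rho, best_ll = rhos[i], lls[i]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda r: -reml_at_rho(float(r))[0],
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-4},
        )
        if -res.fun > best_ll:
            best_rho, best_ll = float(res.x), float(-res.fun)

    rot = BlockRotation(panels, kind, best_rho)
    ytil, Xtil = rot.rotate(y), rot.rotate(X)
    ll, delta = _maximize_over_delta(rot.eigvals, ytil, Xtil, "reml")
    rss, *_ = _wls_pieces(rot.eigvals, ytil, Xtil, np.array([delta]))
    sg2 = float(rss[0] / (N - p))
    se2 = float(delta * sg2)
    if not np.isfinite(ll):
        raise RuntimeError(
            f"REML fit for {kind!r} failed to converge "
            f"(rho={best_rho:.3f}, delta={delta:.3g})"
        )
    k = N_PARAMS[kind]
    return CovarianceModel(kind, float(best_rho), sg2, se2, ll,
                           -2 * ll + 2 * k, k)


def select_covariance(
    panels: Sequence[PhenotypePanel],
    candidates: Sequence[str] = STRUCTURES,
    covariates: np.ndarray | None = None,
) -> CovarianceModel:
    """Fit each candidate structure and return the smallest-AIC model.

    Ties break toward the structure with fewer parameters; a candidate
    whose fit fails is skipped (the call fails only if all do).
    """
    if not candidates:
        raise ValueError("no candidate structures given")
    fitted, errors = [], []
    for kind in candidates:
        try:
            fitted.append(fit_null_model(panels, kind, covariates))
        except Exception as exc:  # propagate only if everything fails
            errors.append((kind, exc))
    if not fitted:
        raise RuntimeError(f"all candidate fits failed: {errors}")
    fitted.sort(key=lambda m: (round(m.aic, 10), m.n_params))
    return fitted[0]


def assemble_block_kinship(
    model: CovarianceModel, panels: Sequence[PhenotypePanel]
) -> BlockKinship:
    """Freeze the fitted structure into per-individual K_i and M_i."""
    if model.kind == "independence":
        raise ValueError(
            "independence structure has no correlation blocks to assemble"
        )
    blocks = [
        _block(model.kind, float(model.rho), p.ages) for p in panels
    ]
    return BlockKinship([p.individual_id for p in panels], blocks)
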