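"""ROC construction and method comparison on simulated cohorts.

A scored SNP counts as a true positive when it lies strictly within
1 Mb of any causal SNP on the same chromosome; every other scored SNP
is a potential false positive.  Curves sweep all score thresholds
(ties grouped), are averaged vertically across replicates on a fixed
false-positive-rate grid, and are compared by partial AUC on the
low-FPR region (default FPR <= 0.2).

The four standard comparators rerun this package's own scanners:
the longitudinal LRT scan and the Bayesian combined-BF score on all
visits, and the same two on each individual's first visit only (the
cross-sectional analysis; with a single visit per individual the
within-individual correlation degenerates to independence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import bayes as _bayes
from . import emma as _emma
from .covariance import BlockKinship, fit_null_model, assemble_block_kinship
from .data import GenotypeMatrix, PhenotypePanel, first_visit_panels
from .simulate import TruthSet

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_FPR_CAP = 0.2
_FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class RocCurve:
    """Monotone (fpr, tpr) polyline for one method."""

    fpr: np.ndarray
    tpr: np.ndarray
    method: str = ""
    replicate_averaged: bool = False

    def partial_auc(self, fpr_cap: float = DEFAULT_FPR_CAP) -> float:
        """Trapezoidal area under the curve on [0, fpr_cap]."""
        if not (0.0 < fpr_cap <= 1.0):
            raise ValueError("fpr_cap must lie in (0, 1]")
        f = np.concatenate([[0.0], self.fpr, [1.0]])
        t = np.concatenate([[0.0], self.tpr, [self.tpr[-1]]])
        grid = np.unique(np.concatenate([f[f <= fpr_cap], [fpr_cap]]))
        tg = np.interp(grid, f, t)
        return float(np.trapezoid(tg, grid))


def label_findings(
    results: pd.DataFrame,
    truth: TruthSet,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> np.ndarray:
    """True/false labels per scored SNP (strictly < window_bp from causal)."""
    for col in ("chrom", "pos"):
        if col not in results.columns:
            raise ValueError(f"results table missing column {col!r}")
    if results["pos"].isna().any():
        raise ValueError("missing positions in results table")
    chrom = results["chrom"].astype(str).to_numpy()
    pos = results["pos"].to_numpy()
    labels = np.zeros(len(results), dtype=bool)
    for cc, cp in zip(truth.chroms, truth.positions):
        labels |= (chrom == str(cc)) & (np.abs(pos - int(cp)) < window_bp)
    return labels


def roc_from_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    larger_is_better: bool = True,
    method: str = "",
) -> RocCurve:
    """All-thresholds ROC (ties grouped); NaN scores rank last."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both true and false labels for a ROC curve")
    s = scores.copy() if larger_is_better else -scores
    worst = np.nanmin(s) - 1.0 if np.isfinite(np.nanmin(s)) else -1.0
    s[~np.isfinite(s)] = worst
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), s,
                                drop_intermediate=False)
    return RocCurve(fpr, tpr, method=method)


def average_curves(curves: Sequence[RocCurve], method: str = "") -> RocCurve:
    """Vertical average on a fixed 101-point FPR grid."""
    if not curves:
        raise ValueError("no curves to average")
    tprs = np.stack([
        np.interp(_FPR_GRID, c.fpr, c.tpr) for c in curves
    ])
    return RocCurve(_FPR_GRID.copy(), tprs.mean(axis=0),
                    method=method or curves[0].method,
                    replicate_averaged=True)


# ---------------------------------------------------------------------------
# built-in method runners
# ---------------------------------------------------------------------------

def _fit_kinship(panels) -> BlockKinship | None:
    model = fit_null_model(panels, "spatial_power")
    return assemble_block_kinship(model, panels)


def _identity_kinship(panels) -> BlockKinship:
    return BlockKinship(
        [p.individual_id for p in panels],
        [np.eye(p.n_visits) for p in panels],
    )


def emma_scores(
    panels: Sequence[PhenotypePanel], gm: GenotypeMatrix,
    first_visit: bool = False,
) -> np.ndarray:
    """-log10(p) per SNP from the LRT scan (larger = more significant)."""
    if first_visit:
        panels = first_visit_panels(panels)
        kin = _identity_kinship(panels)
    else:
        kin = _fit_kinship(panels)
    scan = _emma.genome_scan(panels, gm, kinship=kin)
    with np.errstate(divide="ignore"):
        return -np.log10(scan["p"].to_numpy())


def bayes_scores(
    panels: Sequence[PhenotypePanel], gm: GenotypeMatrix,
    first_visit: bool = False,
    preselect_k: int = 50,
    cfg: _bayes.BayesConfig | None = None,
) -> np.ndarray:
    """Combined-BF per SNP (2ln BF scale); unselected SNPs score -inf.

    Runs the LRT scan for preselection, then the variable-selection
    sampler on the top ``preselect_k`` SNPs.
    """
    if first_visit:
        panels = first_visit_panels(panels)
        kin = _identity_kinship(panels)
    else:
        kin = _fit_kinship(panels)
    scan = _emma.genome_scan(panels, gm, kinship=kin)
    keep = _bayes.preselect_snps(scan, gm, k=preselect_k)
    sub = gm.subset(keep).mean_impute()
    catalog = _bayes.build_term_catalog(sub, panels)
    cfg = cfg or _bayes.BayesConfig(iterations=4000, burn_in=500, thin=4)
    chain = _bayes.mcmc_run(panels, catalog, kin, cfg)
    summary = _bayes.summarize_posterior(chain, catalog, cfg)
    scores = np.full(gm.n_snps, -np.inf)
    scores[keep] = summary.snps["two_ln_bf"].to_numpy()
    return scores


METHODS: dict[str, Callable] = {
    "emma_all": lambda p, g: emma_scores(p, g, first_visit=False),
    "emma_first": lambda p, g: emma_scores(p, g, first_visit=True),
    "bayes_all": lambda p, g: bayes_scores(p, g, first_visit=False),
    "bayes_first": lambda p, g: bayes_scores(p, g, first_visit=True),
}


def compare_methods(
    replicates: Sequence[tuple[Sequence[PhenotypePanel], GenotypeMatrix,
                               TruthSet]],
    methods: Sequence[str] | dict[str, Callable] = ("emma_all", "emma_first"),
    fpr_cap: float = DEFAULT_FPR_CAP,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> tuple[dict[str, RocCurve], pd.DataFrame]:
    """Replicate-averaged ROC per method plus a partial-AUC table.

    ``replicates`` holds (panels, genotypes, truth) triples — typically
    from :func:`longmm.simulate.simulate_dataset`; every method scores
    every replicate.
    """
    if isinstance(methods, dict):
        runners = methods
    else:
        runners = {name: METHODS[name] for name in methods}
    per_method: dict[str, list[RocCurve]] = {m: [] for m in runners}
    for panels, gm, truth in replicates:
        labels = label_findings(gm.snps, truth, window_bp)
        for name, fn in runners.items():
            scores = fn(panels, gm)
            per_method[name].append(
                roc_from_scores(scores, labels, method=name)
            )
    curves = {m: average_curves(cs, m) for m, cs in per_method.items()}
    table = pd.DataFrame(
        {
            "method": list(curves),
            "partial_auc": [curves[m].partial_auc(fpr_cap) for m in curves],
            "fpr_cap": fpr_cap,
            "n_replicates": len(replicates),
        }
    )
    return curves, table
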