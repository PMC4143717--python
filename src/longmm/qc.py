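"""SNP quality-control filters: MAF, Hardy-Weinberg, LD pruning.

The filter chain mirrors common GWAS practice for dense sequencing
panels: drop SNPs with minor allele frequency below a threshold, then
drop SNPs failing a 1-df chi-square Hardy-Weinberg goodness-of-fit test
at a Bonferroni-corrected per-SNP level, then optionally thin the panel
by greedy LD pruning on pairwise r^2 within a sliding physical window.
A SNP failing both the MAF and HWE filters is reported under ``low_maf``
(MAF is applied first; HWE is only evaluated on MAF-passing SNPs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix


@dataclass
class QcReport:
    """Per-SNP filter outcome.

    ``table`` has columns: id, maf, hwe_p, kept, reason (one of
    ``low_maf``, ``hwe_fail``, ``ld_pruned`` or empty for kept SNPs).
    """

    table: pd.DataFrame

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_dropped(self) -> int:
        return int((~self.table["kept"]).sum())


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from additive dosages (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    obs = d[~np.isnan(d)]
    if obs.size == 0:
        raise ValueError("all dosages missing for SNP")
    p = float(np.mean(obs)) / 2.0
    return min(p, 1.0 - p)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square Hardy-Weinberg goodness-of-fit p-value.

    Observed genotype counts are compared with expectations under the
    estimated allele frequency; a monomorphic sample returns p = 1.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("need at least one genotype")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p ** 2, 2 * p * (1 - p), (1 - p) ** 2])
    stat = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(stat, df=1))


def _hwe_from_dosages(dosages: np.ndarray) -> float:
    """HWE on hard-called genotypes (dosage rounded to 0/1/2)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    g = np.clip(np.rint(d), 0, 2).astype(int)
    return hwe_test(int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2)))


def apply_filters(
    gm: GenotypeMatrix, maf_min: float = 0.05, hwe_alpha: float | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """MAF then HWE filtering.

    ``hwe_alpha`` is the Bonferroni-corrected *per-SNP* threshold; pass
    ``None`` to compute 0.05/m from the post-MAF SNP count m.
    """
    if not (0.0 <= maf_min < 0.5):
        raise ValueError("maf_min must lie in [0, 0.5)")
    if hwe_alpha is not None and not (0.0 < hwe_alpha < 1.0):
        raise ValueError("hwe_alpha must lie in (0, 1)")

    m = gm.n_snps
    maf = np.array([compute_maf(gm.dosage[:, j]) for j in range(m)])
    maf_pass = maf >= maf_min
    if hwe_alpha is None:
        n_pass = int(maf_pass.sum())
        hwe_alpha = 0.05 / max(n_pass, 1)
    hwe_p = np.ones(m)
    for j in np.flatnonzero(maf_pass):
        hwe_p[j] = _hwe_from_dosages(gm.dosage[:, j])
    hwe_fail = maf_pass & (hwe_p < hwe_alpha)
    kept = maf_pass & ~hwe_fail

    reason = np.where(~maf_pass, "low_maf", np.where(hwe_fail, "hwe_fail", ""))
    report = QcReport(
        pd.DataFrame(
            {"id": gm.snps["id"], "maf": maf, "hwe_p": hwe_p,
             "kept": kept, "reason": reason}
        )
    )
    if kept.sum() == 0:
        raise ValueError("no SNPs survive QC filters")
    return gm.subset(np.flatnonzero(kept)), report


def ld_prune(
    gm: GenotypeMatrix, r2_max: float = 0.5, window_bp: int = 1_000_000
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns kept SNP indices.

    SNPs are visited in (chrom, pos) order; a SNP is dropped when its
    squared Pearson correlation with any already-kept SNP on the same
    chromosome within ``window_bp`` exceeds ``r2_max``.
    """
    if not (0.0 < r2_max <= 1.0):
        raise ValueError("r2_max must lie in (0, 1]")
    pos = gm.snps["pos"].to_numpy()
    chrom = gm.snps["chrom"].to_numpy()
    order = np.lexsort((pos, chrom))

    # standardized dosage columns so r^2 is a plain dot product
    d = gm.mean_impute().dosage
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    nz = sd > 0
    d[:, nz] = d[:, nz] / sd[nz]
    n = d.shape[0]

    kept: list[int] = []
    for j in order:
        drop = False
        # kept follows (chrom, pos) order, so scanning backwards stops at
        # the window edge or the previous chromosome
        for k in reversed(kept):
            if chrom[k] != chrom[j] or int(pos[j]) - int(pos[k]) > window_bp:
                break
            if not nz[j] or not nz[k]:
                continue
            r = float(d[:, j] @ d[:, k]) / n
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
    return np.array(sorted(kept), dtype=int)
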