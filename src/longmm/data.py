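"""Core containers and file I/O for longitudinal association mapping.

The package works with two aligned containers: a list of
:class:`PhenotypePanel` objects (one per individual, holding visit ages,
trait values and per-visit covariates) and a :class:`GenotypeMatrix`
(individuals x SNPs additive dosages plus marker metadata).  Both share a
single canonical individual order; any reordering must be explicit.

Phenotype tables are long-format TSV with one row per visit::

    id  age  trait  sex  med  smoke

Genotypes are read from VCF (GT-based, biallelic records only) or from a
plain dosage TSV with one row per SNP (``chrom pos id`` followed by one
column per individual).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("longmm")

#: covariate columns expected in a phenotype TSV (beyond id/age/trait)
DEFAULT_COVARIATES = ("sex", "med", "smoke")


@dataclass
class PhenotypePanel:
    """Longitudinal record of one individual.

    Parameters
    ----------
    individual_id
        Sample identifier; must match the genotype container.
    ages
        Visit ages in years, strictly increasing.
    trait
        Trait value at each visit (finite).
    covariates
        Per-visit covariate table (e.g. sex, med, smoke).  ``age`` and
        ``age**2`` are derived from ``ages`` downstream, never stored here.
    """

    individual_id: str
    ages: np.ndarray
    trait: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.trait = np.asarray(self.trait, dtype=float)
        if self.ages.ndim != 1 or self.ages.size < 1:
            raise ValueError(f"{self.individual_id}: need at least one visit")
        if self.trait.shape != self.ages.shape:
            raise ValueError(f"{self.individual_id}: trait/age length mismatch")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError(
                f"{self.individual_id}: visit ages must be strictly increasing"
            )
        if not np.all(np.isfinite(self.trait)):
            raise ValueError(f"{self.individual_id}: non-finite trait value")
        if len(self.covariates) not in (0, self.n_visits):
            raise ValueError(
                f"{self.individual_id}: covariate rows != number of visits"
            )

    @property
    def n_visits(self) -> int:
        return self.ages.size

    def first_visit(self) -> "PhenotypePanel":
        """Cross-sectional restriction to the earliest measurement."""
        cov = self.covariates.iloc[:1].reset_index(drop=True)
        return PhenotypePanel(self.individual_id, self.ages[:1], self.trait[:1], cov)

    def with_trait(self, trait: np.ndarray) -> "PhenotypePanel":
        return PhenotypePanel(
            self.individual_id, self.ages.copy(), np.asarray(trait, float),
            self.covariates.copy(),
        )


@dataclass
class GenotypeMatrix:
    """Additive dosages for the cohort, individuals x SNPs.

    ``dosage`` entries lie in [0, 2] (NaN marks a missing call until
    :meth:`mean_impute` is applied).  ``snps`` carries per-marker
    ``chrom``, ``pos`` (1-based) and ``id`` columns, sorted by position
    within chromosome.
    """

    dosage: np.ndarray
    snps: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x SNPs)")
        n, m = self.dosage.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length != dosage rows")
        if len(self.snps) != m:
            raise ValueError("snps metadata length != dosage columns")
        for col in ("chrom", "pos", "id"):
            if col not in self.snps.columns:
                raise ValueError(f"snps metadata missing column {col!r}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosage, initial=0) < 0 or np.nanmax(
                self.dosage, initial=0
            ) > 2:
                raise ValueError("dosage entries must lie in [0, 2]")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def mean_impute(self) -> "GenotypeMatrix":
        """Replace missing dosages by the per-SNP mean of observed calls."""
        d = self.dosage.copy()
        if np.isnan(d).any():
            means = np.nanmean(d, axis=0)
            idx = np.where(np.isnan(d))
            d[idx] = means[idx[1]]
        return GenotypeMatrix(d, self.snps.copy(), list(self.individual_ids))

    def subset(self, snp_indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        snp_indices = np.asarray(snp_indices, dtype=int)
        return GenotypeMatrix(
            self.dosage[:, snp_indices],
            self.snps.iloc[snp_indices].reset_index(drop=True),
            list(self.individual_ids),
        )


# ---------------------------------------------------------------------------
# panel-collection helpers (the canonical stacked, visit-level view)
# ---------------------------------------------------------------------------

def visit_counts(panels: Sequence[PhenotypePanel]) -> np.ndarray:
    return np.array([p.n_visits for p in panels], dtype=int)


def stacked_trait(panels: Sequence[PhenotypePanel]) -> np.ndarray:
    return np.concatenate([p.trait for p in panels])


def stacked_ages(panels: Sequence[PhenotypePanel]) -> np.ndarray:
    return np.concatenate([p.ages for p in panels])


def expand_to_visits(
    panels: Sequence[PhenotypePanel], per_individual: np.ndarray
) -> np.ndarray:
    """Repeat a per-individual value (e.g. a SNP dosage) across visits."""
    per_individual = np.asarray(per_individual)
    return np.repeat(per_individual, visit_counts(panels))


def covariate_matrix(
    panels: Sequence[PhenotypePanel],
    names: Sequence[str] | None = None,
    include_age: bool = True,
) -> np.ndarray:
    """Visit-level fixed-effect design (no intercept column).

    By default: age, age^2, then every covariate column the panels carry
    (or the subset in ``names``).
    """
    cols: list[np.ndarray] = []
    if include_age:
        ages = stacked_ages(panels)
        cols += [ages, ages ** 2]
    if names is None:
        names = list(panels[0].covariates.columns)
    for nm in names:
        cols.append(
            np.concatenate([p.covariates[nm].to_numpy(dtype=float) for p in panels])
        )
    if not cols:
        return np.empty((sum(visit_counts(panels)), 0))
    return np.column_stack(cols)


def first_visit_panels(panels: Sequence[PhenotypePanel]) -> list[PhenotypePanel]:
    return [p.first_visit() for p in panels]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> list[PhenotypePanel]:
    """Read a long-format phenotype TSV into one panel per individual.

    Visits are sorted by age within individual; duplicate (id, age) rows
    and non-numeric traits are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    for col in ("id", "age", "trait"):
        if col not in df.columns:
            raise ValueError(f"phenotype file missing column {col!r}")
    bad = pd.to_numeric(df["trait"], errors="coerce").isna() & df["trait"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-numeric trait at data row {row} of {path}")
    df["trait"] = pd.to_numeric(df["trait"])
    df["age"] = pd.to_numeric(df["age"])
    if df.duplicated(subset=["id", "age"]).any():
        dup = df[df.duplicated(subset=["id", "age"], keep=False)].iloc[0]
        raise ValueError(
            f"duplicate visit for individual {dup['id']!r} at age {dup['age']}"
        )
    covariate_cols = [c for c in df.columns if c not in ("id", "age", "trait")]
    panels = []
    for iid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("age")
        panels.append(
            PhenotypePanel(
                str(iid),
                grp["age"].to_numpy(),
                grp["trait"].to_numpy(),
                grp[covariate_cols].reset_index(drop=True),
            )
        )
    total = sum(p.n_visits for p in panels)
    if total != len(df):
        raise AssertionError("row count not conserved while grouping")
    return panels


def write_phenotypes(panels: Sequence[PhenotypePanel], path: str | Path) -> None:
    rows = []
    for p in panels:
        for j in range(p.n_visits):
            row = {"id": p.individual_id, "age": p.ages[j], "trait": p.trait[j]}
            if len(p.covariates):
                row.update(p.covariates.iloc[j].to_dict())
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_genotypes_vcf(
    path: str | Path, phenotype_ids: Sequence[str] | None = None
) -> GenotypeMatrix:
    """Read GT-based dosages from a VCF; multiallelic records are skipped.

    If ``phenotype_ids`` is given, every VCF sample must appear in it and
    the output rows follow the phenotype order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if phenotype_ids is not None:
        missing = [s for s in samples if s not in set(phenotype_ids)]
        if missing:
            raise ValueError(
                f"VCF samples absent from phenotype table: {missing}"
            )
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s:%s", var.CHROM, var.POS
            )
            continue
        # gts012: 0/1/2 = ALT count, 3 = missing
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        rows.append(g)
        meta.append(
            {"chrom": str(var.CHROM), "pos": int(var.POS),
             "id": var.ID or f"{var.CHROM}:{var.POS}"}
        )
    vcf.close()
    dosage = np.array(rows).T if rows else np.empty((len(samples), 0))
    gm = GenotypeMatrix(dosage, pd.DataFrame(meta, columns=["chrom", "pos", "id"]),
                        samples)
    if phenotype_ids is not None:
        order = [samples.index(i) for i in phenotype_ids if i in set(samples)]
        if len(order) != len(phenotype_ids):
            absent = sorted(set(phenotype_ids) - set(samples))
            raise ValueError(f"phenotype individuals absent from VCF: {absent}")
        gm = GenotypeMatrix(gm.dosage[order], gm.snps, [samples[i] for i in order])
    return gm


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a dosage TSV: columns ``chrom pos id`` then one per individual."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    meta = df[["chrom", "pos", "id"]]
    ind = [c for c in df.columns if c not in ("chrom", "pos", "id")]
    dosage = df[ind].to_numpy(dtype=float).T
    return GenotypeMatrix(dosage, meta, ind)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.snps[["chrom", "pos", "id"]].copy()
    for i, iid in enumerate(gm.individual_ids):
        df[iid] = gm.dosage[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_scan_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a genome-scan result table (chrom, pos, id, beta, lrt, p, ...)."""
    if results is None or len(results) == 0:
        raise ValueError("refusing to write an empty result table")
    for col in ("chrom", "pos", "id", "beta", "lrt", "p"):
        if col not in results.columns:
            raise ValueError(f"result table missing column {col!r}")
    results.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scan_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})


def write_bayes_results(summary: pd.DataFrame, path: str | Path) -> None:
    """Write per-term / per-SNP posterior table (pip, bf, two_ln_bf)."""
    if summary is None or len(summary) == 0:
        raise ValueError("refusing to write an empty posterior table")
    summary.to_csv(path, sep="\t", index=False, float_format="%.17g")
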