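"""Core in-memory containers for cohort genotype/phenotype data.

Genotypes are held as additive dosages (count of the alternate allele,
0/1/2) in a dense integer matrix of shape (n_samples, n_snps); missing
calls use the sentinel :data:`MISSING`.  Phenotypes are binary disease
status (1 = case, 0 = control) plus optional numeric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1


@dataclass(frozen=True)
class SnpMeta:
    """Per-SNP metadata: identifier, genomic location and alleles.

    ``pos_bp`` is 1-based.  ``alt_allele`` is the counted allele of the
    additive coding.
    """

    id: str
    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"SNP {self.id}: pos_bp must be >= 1, got {self.pos_bp}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError(f"SNP {self.id}: alleles must be non-empty")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive-dosage matrix with row/column identity.

    Invariants (checked on construction): entries are in {0, 1, 2} or
    :data:`MISSING`; sample ids and SNP ids are unique; dimensions match
    the id lists.
    """

    values: np.ndarray
    sample_ids: list[str]
    snps: list[SnpMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snps) != p:
            raise ValueError(f"{len(self.snps)} SNP records for {p} columns")
        valid = np.isin(self.values, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.values[~valid].ravel()[0]
            raise ValueError(f"genotype entries must be 0/1/2 or missing; found {bad!r}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if len({s.id for s in self.snps}) != p:
            raise ValueError("SNP ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def take_samples(self, rows: np.ndarray | list[int]) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=int)
        return GenotypeMatrix(
            values=self.values[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            snps=list(self.snps),
        )

    def take_snps(self, cols: np.ndarray | list[int]) -> "GenotypeMatrix":
        cols = np.asarray(cols, dtype=int)
        return GenotypeMatrix(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            snps=[self.snps[j] for j in cols],
        )

    def dosages(self, impute: bool = True) -> np.ndarray:
        """Float dosage matrix; missing entries mean-imputed per SNP.

        A SNP with no observed calls imputes to 0.
        """
        X = self.values.astype(float)
        if not impute:
            X[self.values == MISSING] = np.nan
            return X
        miss = self.values == MISSING
        if miss.any():
            obs = np.where(miss, 0.0, X)
            n_obs = (~miss).sum(axis=0)
            col_mean = np.divide(
                obs.sum(axis=0), n_obs, out=np.zeros(X.shape[1]), where=n_obs > 0
            )
            X = np.where(miss, col_mean[np.newaxis, :], X)
        return X


@dataclass
class PhenotypeTable:
    """Binary disease status (1 = case, 0 = control) keyed by sample id,
    with optional numeric covariate columns (e.g. age, sex)."""

    sample_ids: list[str]
    status: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        n = len(self.sample_ids)
        if self.status.shape != (n,):
            raise ValueError("status length does not match sample ids")
        if not np.isin(self.status, (0, 1)).all():
            bad = int(self.status[~np.isin(self.status, (0, 1))][0])
            raise ValueError(f"status values must be 0/1; found {bad}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate rows do not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    def take(self, rows: np.ndarray | list[int]) -> "PhenotypeTable":
        rows = np.asarray(rows, dtype=int)
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[rows].reset_index(drop=True)
        return PhenotypeTable(
            sample_ids=[self.sample_ids[i] for i in rows],
            status=self.status[rows],
            covariates=cov,
        )


@dataclass(frozen=True)
class CohortAlignment:
    """Record of how genotype and phenotype rows were matched by id.

    ``common_ids`` is the intersection of the two id sets under a fixed
    lexicographic ordering, so alignment is deterministic across platforms.
    """

    common_ids: tuple[str, ...]
    genotype_row_index: dict[str, int]
    phenotype_row_index: dict[str, int]


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint covering working/validation partition of sample rows.

    The validation rows are set aside before any ranking or scoring and
    are only touched by the final held-out evaluation.
    """

    working_indices: tuple[int, ...]
    validation_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        w, v = set(self.working_indices), set(self.validation_indices)
        if w & v:
            raise ValueError("working and validation indices overlap")
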