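"""Pre-analysis variant QC: missingness, MAF, Hardy–Weinberg, LD pruning.

The composed stack runs in the fixed order missingness → MAF → HWE → LD;
each filter preserves the relative order of surviving SNPs and is
idempotent.  Defaults mirror a conventional common-variant GWAS setup:
MAF ≥ 0.05, HWE p ≥ 1e-12, LD pruning in 50 kb windows with step 5 and
r² ceiling 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QcConfig:
    max_missing_rate: float = 0.05
    maf_min: float = 0.05
    hwe_p_min: float = 1e-12
    ld_window_kb: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.5

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "maf_min", "hwe_p_min", "ld_r2_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ld_window_kb <= 0 or self.ld_step <= 0:
            raise ValueError("LD window and step must be positive")


@dataclass
class QcReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_removed_hwe: int
    n_removed_ld: int
    surviving_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_missing + self.n_removed_maf + self.n_removed_hwe + self.n_removed_ld
        )
        if self.n_input - removed != len(self.surviving_ids):
            raise ValueError("QC counts are inconsistent with survivor list")


def missing_rates(G: GenotypeMatrix) -> np.ndarray:
    return (G.values == MISSING).mean(axis=0)


def filter_missingness(G: GenotypeMatrix, max_missing_rate: float) -> GenotypeMatrix:
    """Drop SNPs whose per-SNP missing-call fraction exceeds the threshold."""
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    keep = np.flatnonzero(missing_rates(G) <= max_missing_rate)
    return G.take_snps(keep)


def minor_allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency; missing calls excluded from counts."""
    obs = G.values != MISSING
    alt_count = np.where(obs, G.values, 0).sum(axis=0)
    n_alleles = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.divide(
            alt_count, n_alleles, out=np.zeros(G.n_snps), where=n_alleles > 0
        )
    return np.minimum(alt_freq, 1.0 - alt_freq)


def filter_maf(G: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    keep = np.flatnonzero(minor_allele_frequencies(G) >= maf_min)
    return G.take_snps(keep)


def hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP 1-df chi-square goodness-of-fit p-value against the
    Hardy–Weinberg genotype proportions p², 2pq, q².

    Counts are pooled over all samples.  Monomorphic SNPs (or SNPs with
    no observed calls) are assigned p = 1: there is nothing to test and
    the MAF filter owns their fate.
    """
    obs = G.values != MISSING
    n0 = ((G.values == 0) & obs).sum(axis=0).astype(float)
    n1 = ((G.values == 1) & obs).sum(axis=0).astype(float)
    n2 = ((G.values == 2) & obs).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    p = np.ones(G.n_snps)
    testable = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n > 0, (n1 + 2.0 * n2) / (2.0 * n), 0.0)  # alt allele freq
        poly = testable & (q > 0) & (q < 1)
        e0, e1, e2 = n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2
        chi2 = np.zeros(G.n_snps)
        for o, e in ((n0, e0), (n1, e1), (n2, e2)):
            chi2 += np.where(poly, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
    p[poly] = stats.chi2.sf(chi2[poly], df=1)
    return p


def filter_hwe(G: GenotypeMatrix, p_min: float) -> GenotypeMatrix:
    keep = np.flatnonzero(hwe_pvalues(G) >= p_min)
    return G.take_snps(keep)


def _pairwise_r2(X: np.ndarray, i: int, j: int) -> float:
    xi, xj = X[:, i], X[:, j]
    si, sj = xi.std(), xj.std()
    if si == 0.0 or sj == 0.0:
        return 0.0
    r = float(np.corrcoef(xi, xj)[0, 1])
    return r * r


def ld_prune(
    G: GenotypeMatrix, window_kb: int, step: int, r2_max: float
) -> GenotypeMatrix:
    """Greedy windowed LD pruning on dosage correlation.

    Within each window of ``window_kb`` kilobases on the same chromosome,
    any surviving pair with squared Pearson correlation above ``r2_max``
    loses its later-positioned member.  The window start advances ``step``
    SNPs at a time and passes repeat until no further removal occurs, so
    the output contains no within-window pair above the ceiling.  Input
    must be sorted by (chrom, pos_bp).
    """
    chroms = [s.chrom for s in G.snps]
    pos = np.array([s.pos_bp for s in G.snps], dtype=np.int64)
    order = sorted(range(G.n_snps), key=lambda k: (chroms[k], pos[k]))
    if order != list(range(G.n_snps)):
        raise ValueError("SNPs must be sorted by (chrom, pos_bp) before LD pruning")

    X = G.dosages()
    window_bp = int(window_kb) * 1000
    keep = np.ones(G.n_snps, dtype=bool)
    changed = True
    while changed:
        changed = False
        for start in range(0, G.n_snps, step):
            if not keep[start]:
                continue
            in_window = [
                j
                for j in range(start, G.n_snps)
                if keep[j] and chroms[j] == chroms[start] and pos[j] - pos[start] <= window_bp
            ]
            for a_idx in range(len(in_window)):
                i = in_window[a_idx]
                if not keep[i]:
                    continue
                for j in in_window[a_idx + 1 :]:
                    if keep[j] and _pairwise_r2(X, i, j) > r2_max:
                        keep[j] = False  # later bp position loses
                        changed = True
    return G.take_snps(np.flatnonzero(keep))


def apply_qc(G: GenotypeMatrix, cfg: QcConfig) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full QC stack in the fixed order and report removals."""
    n_input = G.n_snps
    g1 = filter_missingness(G, cfg.max_missing_rate)
    g2 = filter_maf(g1, cfg.maf_min)
    g3 = filter_hwe(g2, cfg.hwe_p_min)
    g4 = ld_prune(g3, cfg.ld_window_kb, cfg.ld_step, cfg.ld_r2_max)
    report = QcReport(
        n_input=n_input,
        n_removed_missing=n_input - g1.n_snps,
        n_removed_maf=g1.n_snps - g2.n_snps,
        n_removed_hwe=g2.n_snps - g3.n_snps,
        n_removed_ld=g3.n_snps - g4.n_snps,
        surviving_ids=g4.snp_ids,
    )
    return g4, report
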