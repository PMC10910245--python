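"""Heritability-based feature ranking via ridge-regularized regression.

The model is the weighted linear regression y = Xm + ε with E(ε) = 0 and
cov(ε) = Δ_y², Δ_y diagonal, fitted by minimizing

    E²(m) = (y − Xm)ᵀ Δ_y⁻² (y − Xm) + C mᵀm .

Closed forms (W = Δ_y⁻²):

    m̄        = (XᵀWX + CI)⁻¹ XᵀWy
    cov(m̄)   = (XᵀWX + CI)⁻¹ XᵀWX (XᵀWX + CI)⁻¹
    E²_res    = yᵀWy − (Xm̄)ᵀW(Xm̄) − C m̄ᵀm̄
    E²(m)     = E²_res + (m − m̄)ᵀ (XᵀWX + CI) (m − m̄)

so the total weighted sum of squares decomposes exactly into residual,
explained, and penalty parts.  The per-feature share of the explained
term, h_j = m̄_j² · (x_jᵀ W x_j), is the heritability score used to rank
SNPs; on LD-pruned data the neglected cross terms are small.  When the
system is underdetermined (p ≥ n) the same solution is computed through
the n×n dual form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .types import GenotypeMatrix
from .youden import balanced_split


@dataclass
class DesignMatrix:
    """Design for the ridge fit: scaled dosages (and optional covariates)
    behind a leading all-ones intercept column, with per-sample noise
    scales ``delta`` (the diagonal of Δ_y)."""

    X: np.ndarray
    delta: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    has_intercept: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values; impute upstream")
        if self.delta.shape != (self.X.shape[0],):
            raise ValueError("delta length must match sample count")
        if (self.delta <= 0).any():
            raise ValueError("delta must be strictly positive")
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def weights(self) -> np.ndarray:
        """Diagonal of W = Δ_y⁻²."""
        return self.delta**-2


def build_design(
    G: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    delta: np.ndarray | None = None,
    standardize: bool = True,
) -> DesignMatrix:
    """Assemble the design: intercept column, then genotype dosages
    (mean-imputed, and centred/scaled to unit variance unless disabled;
    constant columns are left centred at zero), then covariates.

    ``delta`` defaults to all ones (homoscedastic noise).
    """
    X = G.dosages()
    names = ["_intercept"] + G.snp_ids
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd_safe
    cols = [np.ones((X.shape[0], 1)), X]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != X.shape[0]:
            covariates = covariates.T
        cols.append(covariates)
        names += [f"cov{k}" for k in range(covariates.shape[1])]
    full = np.hstack(cols)
    if delta is None:
        delta = np.ones(full.shape[0])
    return DesignMatrix(X=full, delta=delta, feature_names=names, has_intercept=True)


@dataclass
class RidgeFit:
    """Closed-form ridge solution and its exact error decomposition."""

    m_bar: np.ndarray
    C: float
    e_res2: float
    total_weighted_ss: float
    explained: float  # (Xm̄)ᵀ W (Xm̄)
    penalty: float  # C m̄ᵀm̄
    design: DesignMatrix
    y: np.ndarray

    @cached_property
    def cov_m(self) -> np.ndarray:
        """Sandwich covariance (XᵀWX+CI)⁻¹ XᵀWX (XᵀWX+CI)⁻¹."""
        X, w = self.design.X, self.design.weights
        gram = X.T @ (w[:, None] * X)
        A = gram + self.C * np.eye(gram.shape[0])
        Ainv = np.linalg.inv(A)
        return Ainv @ gram @ Ainv


def ridge_fit(D: DesignMatrix, y: np.ndarray, C: float) -> RidgeFit:
    """Fit the weighted ridge regression in closed form.

    Solves the p×p regularized normal equations when p ≤ n, otherwise
    the algebraically identical n×n dual system.  With C = 0 a singular
    system raises rather than silently pseudo-inverting.
    """
    y = np.asarray(y, dtype=float)
    n, p = D.X.shape
    if C < 0:
        raise ValueError("C must be non-negative")
    if C == 0 and p >= n:
        raise ValueError("C must be positive for an underdetermined system (p >= n)")
    w = D.weights
    ws = np.sqrt(w)
    Z = ws[:, None] * D.X  # W^{1/2} X
    zy = ws * y
    if p <= n:
        A = Z.T @ Z + C * np.eye(p)
        try:
            m_bar = np.linalg.solve(A, Z.T @ zy)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular normal equations; use a positive C") from exc
        if C == 0:
            # solve() succeeded but near-singularity can hide behind roundoff
            if np.linalg.cond(A) > 1e12:
                raise ValueError("ill-conditioned system with C = 0; use a positive C")
    else:
        K = Z @ Z.T + C * np.eye(n)
        m_bar = Z.T @ np.linalg.solve(K, zy)

    fitted = D.X @ m_bar
    total = float(y @ (w * y))
    explained = float(fitted @ (w * fitted))
    penalty = float(C * (m_bar @ m_bar))
    e_res2 = total - explained - penalty
    return RidgeFit(
        m_bar=m_bar,
        C=float(C),
        e_res2=e_res2,
        total_weighted_ss=total,
        explained=explained,
        penalty=penalty,
        design=D,
        y=y,
    )


def weighted_objective(D: DesignMatrix, y: np.ndarray, C: float, m: np.ndarray) -> float:
    """E²(m) = (y − Xm)ᵀW(y − Xm) + C mᵀm, for arbitrary m."""
    r = np.asarray(y, dtype=float) - D.X @ np.asarray(m, dtype=float)
    return float(r @ (D.weights * r) + C * (m @ m))


def error_decomposition_check(
    D: DesignMatrix, y: np.ndarray, fit: RidgeFit, m: np.ndarray
) -> float:
    """Absolute residual of the exact identity
    E²(m) = E²_res + (m−m̄)ᵀ(XᵀWX + CI)(m−m̄); ~0 for any m."""
    m = np.asarray(m, dtype=float)
    d = m - fit.m_bar
    Zd = np.sqrt(D.weights)[:, None] * D.X @ d
    quad = float(Zd @ Zd + fit.C * (d @ d))
    return abs(weighted_objective(D, y, fit.C, m) - fit.e_res2 - quad)


@dataclass(frozen=True)
class HeritabilityScores:
    """Per-feature components of the explained weighted sum of squares;
    the intercept column is excluded from ranking."""

    h: np.ndarray
    feature_names: tuple[str, ...]


def feature_heritability(
    D: DesignMatrix, fit: RidgeFit, include_cross_terms: bool = False
) -> HeritabilityScores:
    """Per-SNP heritability scores from the explained term (Xm̄)ᵀW(Xm̄).

    Default: h_j = m̄_j² · (x_jᵀWx_j), the j-th diagonal entry of
    diag(m̄)·XᵀWX·diag(m̄) — cross-covariance terms between features are
    dropped, which is appropriate after LD pruning.  With
    ``include_cross_terms`` the full row sum m̄_j·x_jᵀW(Xm̄) is used
    instead (these sum exactly to the explained term).
    """
    w = D.weights
    start = 1 if D.has_intercept else 0
    m = fit.m_bar
    if include_cross_terms:
        fitted = D.X @ m
        h = m * (D.X.T @ (w * fitted))
    else:
        col_ss = np.einsum("ij,ij->j", D.X, w[:, None] * D.X)
        h = m**2 * col_ss
    return HeritabilityScores(
        h=h[start:], feature_names=tuple(D.feature_names[start:])
    )


@dataclass(frozen=True)
class RankedFeatures:
    """Stable permutation of feature columns by decreasing score.

    ``order[k]`` is the index of the k-th best feature; ``sigma[j]`` is
    feature j's rank (0 = best).
    """

    order: np.ndarray
    sigma: np.ndarray
    scores: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.order)


def rank_features(h: HeritabilityScores | np.ndarray) -> RankedFeatures:
    """Stable sort of features by decreasing heritability score; ties
    retain the original column order."""
    scores = h.h if isinstance(h, HeritabilityScores) else np.asarray(h, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("heritability scores contain NaN")
    order = np.argsort(-scores, kind="stable")
    sigma = np.empty_like(order)
    sigma[order] = np.arange(len(order))
    return RankedFeatures(order=order, sigma=sigma, scores=scores)


def rank_by_folds(
    X_working: GenotypeMatrix,
    y_working: np.ndarray,
    n_folds: int,
    s_test: float,
    C: float,
    rng: np.random.Generator | int,
    covariates: np.ndarray | None = None,
) -> RankedFeatures:
    """Fold-averaged heritability ranking.

    Draws ``n_folds`` balanced train/test splits of the working set,
    fits the ridge on each train part, and averages the per-fold
    heritability scores c_{i,j} into c_j = Σ_i c_{i,j}/n_folds before
    ranking.  The held-out parts are reserved for scoring stages and are
    not consulted here.
    """
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    y_working = np.asarray(y_working, dtype=int)
    p = X_working.n_snps
    c_sum = np.zeros(p)
    for _ in range(n_folds):
        train_idx, _test_idx = balanced_split(y_working, s_test, rng)
        G_train = X_working.take_samples(train_idx)
        cov_train = covariates[train_idx] if covariates is not None else None
        D = build_design(G_train, covariates=cov_train)
        fit = ridge_fit(D, y_working[train_idx], C)
        scores = feature_heritability(D, fit)
        c_sum += scores.h[:p]  # genotype columns precede covariates
    return rank_features(c_sum / n_folds)
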