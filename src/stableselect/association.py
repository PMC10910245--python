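"""Downstream evaluation of selected SNP sets.

Covers per-SNP association inference (logistic-regression Wald tests and
2×2 contingency-table odds ratios with the normal log-OR approximation),
predictivity of a SNP set via a linear-kernel maximum-margin classifier
(fold-averaged F1 / AUC / precision / recall), significance-threshold
subsetting, and the histogram rule that extracts non-neutral weights
from an external polygenic-score β vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score

from .youden import _make_classifier, balanced_split


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    odds_ratio: float
    log_or: float
    se_log_or: float
    p_value: float
    method: str  # "logistic" | "contingency"
    converged: bool = True
    zero_cell_corrected: bool = False

    def __post_init__(self) -> None:
        if self.converged and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def logistic_assoc(
    g: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_id: str = "",
) -> AssociationResult:
    """Single-SNP logistic regression of status on dosage.

    Maximum-likelihood fit (IRLS); the Wald p-value and OR refer to the
    dosage coefficient.  Constant dosages raise; complete separation
    returns a flagged, non-converged result rather than a fake p-value.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.ptp(g) == 0:
        raise ValueError("constant dosage vector: association undefined")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    cols = [g]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(g):
            cov = cov.T
        cols.append(cov)
    X = sm.add_constant(np.column_stack(cols))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            converged = False
            res = None
    if res is None or not converged or not np.isfinite(res.bse[1]) or res.bse[1] > 1e3:
        return AssociationResult(
            snp_id=snp_id,
            odds_ratio=float("nan"),
            log_or=float("nan"),
            se_log_or=float("nan"),
            p_value=float("nan"),
            method="logistic",
            converged=False,
        )
    beta, se = float(res.params[1]), float(res.bse[1])
    return AssociationResult(
        snp_id=snp_id,
        odds_ratio=float(np.exp(beta)),
        log_or=beta,
        se_log_or=se,
        p_value=float(res.pvalues[1]),
        method="logistic",
    )


@dataclass(frozen=True)
class ContingencyTable:
    """Disease × exposure cross-classification.

    ``n_DE``: diseased & exposed; ``n_de``: healthy & unexposed;
    ``n_De``: diseased & unexposed; ``n_dE``: healthy & exposed.
    """

    n_DE: float
    n_de: float
    n_De: float
    n_dE: float

    def __post_init__(self) -> None:
        cells = (self.n_DE, self.n_de, self.n_De, self.n_dE)
        if any(c < 0 for c in cells):
            raise ValueError("contingency counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("empty contingency table")


def contingency_or_test(t: ContingencyTable, snp_id: str = "") -> AssociationResult:
    """Odds ratio with the normal approximation for the log OR.

    OR = n_DE·n_de / (n_De·n_dE); the sampled log OR is treated as
    normal with variance σ² = 1/n_DE + 1/n_de + 1/n_De + 1/n_dE, giving
    a two-sided p.  Any zero cell triggers the Haldane–Anscombe +0.5
    correction to all four cells (flagged on the result).
    """
    cells = np.array([t.n_DE, t.n_de, t.n_De, t.n_dE], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    n_DE, n_de, n_De, n_dE = cells
    log_or = float(np.log(n_DE * n_de / (n_De * n_dE)))
    se = float(np.sqrt((1.0 / cells).sum()))
    z = log_or / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(
        snp_id=snp_id,
        odds_ratio=float(np.exp(log_or)),
        log_or=log_or,
        se_log_or=se,
        p_value=p,
        method="contingency",
        zero_cell_corrected=corrected,
    )


@dataclass(frozen=True)
class PredictivityReport:
    """Fold-averaged classification quality of a SNP set."""

    f1: float
    auc: float
    precision: float
    recall: float
    description: str = ""


def evaluate_predictivity(
    X_selected: np.ndarray,
    y: np.ndarray,
    m_folds: int,
    t_test: float,
    rng: np.random.Generator | int,
    description: str = "",
) -> PredictivityReport:
    """Held-out predictivity of a feature set.

    Fits the linear-kernel maximum-margin classifier on the train part
    of each balanced split and averages F1, AUC (from the decision
    function), precision and recall over the held-out parts.
    """
    X_selected = np.asarray(X_selected, dtype=float)
    if X_selected.ndim == 1:
        X_selected = X_selected[:, np.newaxis]
    if X_selected.shape[1] == 0:
        raise ValueError("empty feature selection")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    f1s, aucs, precs, recs = [], [], [], []
    for _ in range(m_folds):
        train_idx, test_idx = balanced_split(y, t_test, rng)
        clf = _make_classifier()
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*converge.*")
            clf.fit(X_selected[train_idx], y[train_idx])
        pred = clf.predict(X_selected[test_idx])
        score = clf.decision_function(X_selected[test_idx])
        f1s.append(f1_score(y[test_idx], pred, zero_division=0))
        precs.append(precision_score(y[test_idx], pred, zero_division=0))
        recs.append(recall_score(y[test_idx], pred, zero_division=0))
        aucs.append(roc_auc_score(y[test_idx], score))
    return PredictivityReport(
        f1=float(np.mean(f1s)),
        auc=float(np.mean(aucs)),
        precision=float(np.mean(precs)),
        recall=float(np.mean(recs)),
        description=description,
    )


def subset_by_significance(
    assoc: list[AssociationResult], neg_log_p_min: float
) -> set[str]:
    """SNP ids with −log10(p) above the threshold (non-converged fits
    excluded)."""
    out = set()
    for a in assoc:
        if not a.converged or not np.isfinite(a.p_value) or a.p_value <= 0:
            if a.converged and a.p_value == 0.0:
                out.add(a.snp_id)  # -log10(0) = inf exceeds any threshold
            continue
        if -np.log10(a.p_value) > neg_log_p_min:
            out.add(a.snp_id)
    return out


@dataclass(frozen=True)
class PRSWeights:
    """External polygenic-score weights: one real β per SNP id."""

    snp_ids: tuple[str, ...]
    beta: np.ndarray

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if len(self.snp_ids) != len(beta):
            raise ValueError("ids and betas length mismatch")
        if not np.isfinite(beta).all():
            raise ValueError("betas must be finite")
        object.__setattr__(self, "beta", beta)


def select_by_beta_histogram(
    w: PRSWeights, n_bins: int = 50, bin_fraction_max: float = 2e-4
) -> set[str]:
    """Histogram tail rule for non-neutral polygenic-score weights.

    Most weights pile into a spike near β = 0 (effectively neutral
    SNPs).  An equal-width histogram with ``n_bins`` bins spans
    [min β, max β]; SNPs landing in any bin holding less than
    ``bin_fraction_max`` of all SNPs — the sparse tails outside the
    spike — are selected.  If all weights are equal the single occupied
    bin holds everything and the selection is empty.
    """
    if len(w.snp_ids) == 0:
        raise ValueError("empty weight vector")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    beta = w.beta
    lo, hi = float(beta.min()), float(beta.max())
    if lo == hi:
        return set()
    counts, edges = np.histogram(beta, bins=n_bins, range=(lo, hi))
    frac = counts / len(beta)
    sparse = frac < bin_fraction_max
    bin_of = np.clip(np.digitize(beta, edges) - 1, 0, n_bins - 1)
    return {sid for sid, b in zip(w.snp_ids, bin_of) if sparse[b]}


def select_by_beta_magnitude(w: PRSWeights, min_abs_beta: float = 2e-4) -> set[str]:
    """Alternative rule: keep SNPs with absolute weight above a floor."""
    return {sid for sid, b in zip(w.snp_ids, w.beta) if abs(b) > min_abs_beta}
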