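"""Outer replication loop: rank → nested subsets → Youden cutoff,
repeated N times over fresh splits, with per-SNP support counting.

A SNP's *support* is the number of replications whose cutoff feature
set contained it.  Features that survive many independent re-splits of
the working data are unlikely to be sampling artifacts: for a fraction
f of truly active SNPs and a single-replication false-identification
probability α and rejection probability β, the expected fraction of
all-N-supported SNPs that are true positives is

    f(1−β)ᴺ / ( f(1−β)ᴺ + (1−f)αᴺ )  → 1  as N → ∞  whenever 1−β > α,

which is the rationale for replication-based stable sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranking import rank_by_folds
from .types import GenotypeMatrix
from .youden import build_nested_subsets, score_subsets


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved knobs of one stability run.

    n_folds / s_test control the ranking splits, m_folds / t_test the
    scoring splits, n_steps the Youden-curve resolution, C the ridge
    penalty on standardized dosages, n_iterations the outer replication
    count N.
    """

    n_folds: int = 5
    s_test: float = 0.2
    m_folds: int = 5
    t_test: float = 0.2
    n_steps: int = 100
    C: float = 1.0
    n_iterations: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_folds, self.m_folds, self.n_steps, self.n_iterations) < 1:
            raise ValueError("fold, step and iteration counts must be >= 1")
        for name in ("s_test", "t_test"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.C < 0:
            raise ValueError("C must be non-negative")


def default_study_config(
    n_snps: int, n_iterations: int = 20, rng_seed: int = 0
) -> PipelineConfig:
    """Desk-scale configuration for synthetic-cohort studies.

    Each replication ranks on a single random half-sample
    (n_folds = 1, s_test = 0.5) so that replications decorrelate —
    support counting is informative only to the degree a fixed
    dataset's spurious champions are *not* re-ranked identically every
    time.  A 50-step curve keeps selections proportionally small (the
    cutoff prefix grows in increments of p/50), so a selected set means
    something; two scoring folds per replication suffice because only
    the location of the curve's first peak matters, not its level.  The
    ridge penalty is set to the marker count (the SNP-BLUP-style
    choice: with standardized dosages this puts the per-marker prior
    variance at 1/p of the phenotypic scale), which keeps
    per-replication coefficients from splining when p approaches n.
    """
    return PipelineConfig(
        n_folds=1,
        s_test=0.5,
        m_folds=2,
        t_test=0.25,
        n_steps=min(50, n_snps),
        C=float(n_snps),
        n_iterations=n_iterations,
        rng_seed=rng_seed,
    )


@dataclass
class SupportTable:
    """Per-SNP replication support counts plus the per-replication
    selected sets for audit."""

    snp_ids: list[str]
    support: np.ndarray
    n_iterations: int
    selected_sets: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        if ((self.support < 0) | (self.support > self.n_iterations)).any():
            raise ValueError("support counts must lie in [0, N]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "support": self.support,
                "n_iterations": self.n_iterations,
            }
        )


def replication_seeds(master_seed: int, n_iterations: int) -> list[np.random.SeedSequence]:
    """Counter-based derivation of one independent seed stream per
    replication; recorded in run manifests for audit."""
    return [np.random.SeedSequence([int(master_seed), rep]) for rep in range(n_iterations)]


def run_stability(
    X_working: GenotypeMatrix, y_working: np.ndarray, cfg: PipelineConfig
) -> SupportTable:
    """Run N outer replications and count per-SNP support.

    Each replication draws fresh ranking splits and fresh, independent
    scoring splits (two separate streams derived from the replication
    seed), ranks features by fold-averaged heritability, builds nested
    subsets, scores the Youden curve, and records the cutoff set.
    Deterministic for a fixed master seed.
    """
    y_working = np.asarray(y_working, dtype=int)
    p = X_working.n_snps
    support = np.zeros(p, dtype=int)
    selected_sets: list[tuple[int, ...]] = []
    dosages = None
    for rep, seed_seq in enumerate(replication_seeds(cfg.rng_seed, cfg.n_iterations)):
        try:
            rank_stream, score_stream = (np.random.default_rng(s) for s in seed_seq.spawn(2))
            ranking = rank_by_folds(
                X_working, y_working, cfg.n_folds, cfg.s_test, cfg.C, rank_stream
            )
            subsets = build_nested_subsets(ranking, min(cfg.n_steps, p))
            if dosages is None:
                dosages = X_working.dosages()
            curve = score_subsets(
                dosages, y_working, subsets, cfg.m_folds, cfg.t_test, score_stream
            )
        except Exception as exc:
            raise RuntimeError(f"replication {rep} failed: {exc}") from exc
        chosen = curve.selected_features
        selected_sets.append(chosen)
        support[list(chosen)] += 1
    return SupportTable(
        snp_ids=X_working.snp_ids,
        support=support,
        n_iterations=cfg.n_iterations,
        selected_sets=selected_sets,
    )


@dataclass(frozen=True)
class StableSet:
    snp_ids: tuple[str, ...]
    threshold: int


def stable_set(support: SupportTable, threshold: int) -> StableSet:
    """SNPs whose support reaches the threshold (e.g. 40 of 50)."""
    if not 0 <= threshold <= support.n_iterations:
        raise ValueError(
            f"threshold must be in [0, {support.n_iterations}], got {threshold}"
        )
    ids = tuple(
        sid for sid, s in zip(support.snp_ids, support.support) if s >= threshold
    )
    return StableSet(snp_ids=ids, threshold=threshold)


@dataclass(frozen=True)
class ReplicationErrorModel:
    """Two-type Bernoulli model of replication: a fraction f of active
    SNPs, per-replication false-identification probability alpha for
    inactive SNPs and rejection probability beta for active ones."""

    f: float
    alpha: float
    beta: float
    N: int

    def __post_init__(self) -> None:
        for name in ("f", "alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.N < 0:
            raise ValueError("N must be non-negative")


def expected_true_positive_fraction(model: ReplicationErrorModel) -> float:
    """Expected fraction of SNPs supported in all N replications that
    are truly active: f(1−β)ᴺ / (f(1−β)ᴺ + (1−f)αᴺ)."""
    num = model.f * (1.0 - model.beta) ** model.N
    den = num + (1.0 - model.f) * model.alpha**model.N
    if den == 0.0:
        raise ZeroDivisionError("degenerate model: no SNP can be fully supported")
    return num / den


def simulate_replication_process(
    model: ReplicationErrorModel, n_snps: int, rng_seed: int
) -> tuple[float, int]:
    """Monte-Carlo cross-check of the closed form.

    Draws n_snps SNPs (active with probability f), gives each an
    independent Bernoulli identification per replication (rate 1−β if
    active, α if not), and returns the observed true-positive fraction
    among fully supported SNPs with the supporting count.
    """
    rng = np.random.default_rng(rng_seed)
    active = rng.random(n_snps) < model.f
    rate = np.where(active, 1.0 - model.beta, model.alpha)
    identified_all = rng.binomial(model.N, rate) == model.N
    n_full = int(identified_all.sum())
    if n_full == 0:
        return float("nan"), 0
    return float((active & identified_all).sum() / n_full), n_full
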