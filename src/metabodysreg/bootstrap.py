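"""Resampling null for pathway scores.

For each (cohort, pathway) cell, null pathway scores are built by drawing
k gene scores with replacement from the cohort's full gene-score pool
(every gene surviving the expression filter), summing them and dividing
by sqrt(n) exactly as the observed score was built, where k is the number
of genes actually used for that pathway in that cohort.  The observed
score's one-sided upper-tail position in this null gives an empirical
p-value with the standard +1 correction (never exactly zero, ties counted
into the tail).  Non-significant scores are then masked to zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import PathwayScoreTable

DEFAULT_N_RESAMPLES = 100_000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class BootstrapResult:
    pathway_id: str
    cohort: str
    n_resamples: int
    boot_p: float
    significant: bool
    null_scores: np.ndarray | None = None


def _substream_seed(master_seed: int, cohort: str, pathway_id: str) -> np.random.SeedSequence:
    """Stable per-cell stream: adding a pathway never perturbs others' nulls."""
    digest = hashlib.sha256(f"{cohort}\t{pathway_id}".encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.SeedSequence([int(master_seed), key])


def null_distribution(pool, k: int, n_resamples: int, n_samples: int,
                      seed) -> np.ndarray:
    """Draw ``n_resamples`` null pathway scores for a size-k pathway.

    Each null score is the sum of k gene scores drawn uniformly with
    replacement from ``pool``, divided by sqrt(n_samples).
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty gene-score pool")
    if k < 1 or n_resamples < 1:
        raise ValueError("k and n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pool.size, size=(n_resamples, k))
    return pool[idx].sum(axis=1) / np.sqrt(n_samples)


def bootstrap_pvalue(observed: float, null_scores) -> float:
    """Upper-tail empirical p-value with the +1 correction."""
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        raise ValueError("empty null distribution")
    if not np.isfinite(observed):
        raise ValueError("observed score must be finite")
    return float((1 + np.count_nonzero(null_scores >= observed))
                 / (null_scores.size + 1))


def bootstrap_table(table: PathwayScoreTable,
                    n_resamples: int = DEFAULT_N_RESAMPLES,
                    seed: int = 0,
                    keep_null: bool = False) -> dict[tuple[str, str], BootstrapResult]:
    """Fill ``table.boot_p`` for every scored cell; returns per-cell results.

    The gene-score pool per cohort is taken from ``table.gene_scores``
    (populated by :func:`metabodysreg.scoring.score_all`).
    """
    if not table.gene_scores:
        raise ValueError("table carries no per-cohort gene scores")
    boot_p = pd.DataFrame(np.nan, index=table.cohorts, columns=table.pathways)
    boot_p.index.name = "cohort"
    results: dict[tuple[str, str], BootstrapResult] = {}
    for cohort in table.cohorts:
        pool = table.gene_scores[cohort].to_numpy(dtype=float)
        n = table.n_samples[cohort]
        for pid in table.pathways:
            observed = table.score.loc[cohort, pid]
            if pd.isna(observed):
                continue
            k = int(table.n_genes_used.loc[cohort, pid])
            null = null_distribution(pool, k, n_resamples, n,
                                     _substream_seed(seed, cohort, pid))
            p = bootstrap_pvalue(float(observed), null)
            boot_p.loc[cohort, pid] = p
            results[(cohort, pid)] = BootstrapResult(
                pid, cohort, n_resamples, p, False,
                null if keep_null else None,
            )
    table.boot_p = boot_p
    return results


def apply_mask(table: PathwayScoreTable, alpha: float = DEFAULT_ALPHA) -> PathwayScoreTable:
    """Zero non-significant scores (boot_p >= alpha); NA scores stay NA."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if table.boot_p is None:
        raise ValueError("boot_p not populated; run bootstrap_table first")
    score = table.score
    significant = table.boot_p < alpha  # NaN compares False
    masked = score.where(significant, 0.0)
    masked = masked.where(~score.isna(), np.nan)
    table.masked_score = masked
    return table


def run_bootstrap(table: PathwayScoreTable,
                  n_resamples: int = DEFAULT_N_RESAMPLES,
                  alpha: float = DEFAULT_ALPHA,
                  seed: int = 0) -> PathwayScoreTable:
    """Bootstrap every cell then mask; the standard entry point."""
    bootstrap_table(table, n_resamples=n_resamples, seed=seed)
    return apply_mask(table, alpha=alpha)
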