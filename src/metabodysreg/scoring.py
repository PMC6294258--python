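"""Gene and pathway dysregulation scores.

A gene's dysregulation magnitude is |log2FC x -log(adjusted p)|; a
pathway's score is the sum of its member genes' scores divided by the
square root of the cohort sample size, which puts cohorts of different
sizes on a comparable scale.  Scores are non-negative magnitudes: they
measure how strongly a pathway's transcription differs between tumor and
normal, not the direction of the difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import PathwayDB, read_table, write_table
from .deg import P_FLOOR

logger = logging.getLogger(__name__)


def gene_scores(deg: pd.DataFrame, log_base: float = 10.0) -> pd.Series:
    """Per-gene score |log_fc x -log(adj_p)| from a DEG table.

    The log base defaults to 10 (volcano-plot convention); adjusted
    p-values are floored at 1e-300 before the log.
    """
    adj = np.clip(deg["adj_p_value"].to_numpy(dtype=float), P_FLOOR, 1.0)
    if log_base == 10.0:
        neglog = -np.log10(adj)
    else:
        neglog = -np.log(adj) / np.log(log_base)
    scores = np.abs(deg["log_fc"].to_numpy(dtype=float) * neglog)
    return pd.Series(scores, index=deg.index, name="gene_score")


def pathway_score(scores: pd.Series, gene_set, n_samples: int,
                  min_genes: int = 2) -> tuple[float, int]:
    """Score one pathway: sum of member-gene scores / sqrt(n_samples).

    Pathway genes absent from ``scores`` are dropped (intersection rule).
    If fewer than ``min_genes`` members are scored the pathway gets NaN.
    Returns (score, n_genes_used).
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    present = scores.index.intersection(gene_set)
    n_used = len(present)
    if n_used < min_genes:
        logger.warning("pathway with %d scored gene(s) (< %d): score set to NA",
                       n_used, min_genes)
        return float("nan"), n_used
    return float(scores.loc[present].sum() / np.sqrt(n_samples)), n_used


@dataclass
class PathwayScoreTable:
    """Cohort x pathway dysregulation scores and their bootstrap status.

    ``score``/``n_genes_used`` are filled by :func:`score_all`; ``boot_p``
    and ``masked_score`` are populated by the bootstrap stage.
    ``n_samples`` records the per-cohort sample count used in Eq.-style
    sqrt(n) scaling, which the bootstrap null must reuse.
    """

    score: pd.DataFrame
    n_genes_used: pd.DataFrame
    n_samples: dict[str, int]
    boot_p: pd.DataFrame | None = None
    masked_score: pd.DataFrame | None = None
    gene_scores: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def cohorts(self) -> list[str]:
        return list(self.score.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.score.columns)

    def require_mask(self) -> pd.DataFrame:
        if self.masked_score is None:
            raise ValueError("masked scores not populated; run the bootstrap first")
        return self.masked_score

    # -- persistence --------------------------------------------------------

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        write_table(self.score, out_dir / "pathway_scores.tsv", index_label="cohort")
        write_table(self.n_genes_used, out_dir / "n_genes_used.tsv", index_label="cohort")
        ns = pd.DataFrame({"n_samples": pd.Series(self.n_samples)})
        ns.index.name = "cohort"
        write_table(ns, out_dir / "n_samples.tsv", index_label="cohort")
        if self.boot_p is not None:
            write_table(self.boot_p, out_dir / "boot_p.tsv", index_label="cohort")
        if self.masked_score is not None:
            write_table(self.masked_score, out_dir / "masked_scores.tsv", index_label="cohort")
        for cohort, gs in self.gene_scores.items():
            write_table(gs.to_frame(), out_dir / f"gene_scores_{cohort}.tsv",
                        index_label="gene_id")

    @classmethod
    def read(cls, out_dir: str | Path) -> "PathwayScoreTable":
        out_dir = Path(out_dir)
        score = read_table(out_dir / "pathway_scores.tsv").astype(float)
        n_used = read_table(out_dir / "n_genes_used.tsv").astype(int)
        ns = read_table(out_dir / "n_samples.tsv")["n_samples"].astype(int).to_dict()
        boot_p = mask = None
        if (out_dir / "boot_p.tsv").exists():
            boot_p = read_table(out_dir / "boot_p.tsv").astype(float)
        if (out_dir / "masked_scores.tsv").exists():
            mask = read_table(out_dir / "masked_scores.tsv").astype(float)
        gscores = {}
        for path in sorted(out_dir.glob("gene_scores_*.tsv")):
            cohort = path.stem.removeprefix("gene_scores_")
            gscores[cohort] = read_table(path)["gene_score"]
        return cls(score, n_used, ns, boot_p, mask, gscores)


def score_all(deg_by_cohort: Mapping[str, pd.DataFrame], db: PathwayDB,
              n_by_cohort: Mapping[str, int], min_genes: int = 2,
              log_base: float = 10.0) -> PathwayScoreTable:
    """Score every cohort x pathway cell; bootstrap fields stay unset."""
    missing = set(deg_by_cohort) - set(n_by_cohort)
    if missing:
        raise ValueError(f"cohort(s) missing from n_by_cohort: {sorted(missing)}")
    cohorts = list(deg_by_cohort)
    pathways = db.pathway_ids
    score = pd.DataFrame(np.nan, index=cohorts, columns=pathways)
    n_used = pd.DataFrame(0, index=cohorts, columns=pathways, dtype=int)
    gscores: dict[str, pd.Series] = {}
    for cohort, deg in deg_by_cohort.items():
        gs = gene_scores(deg, log_base=log_base)
        gscores[cohort] = gs
        n = int(n_by_cohort[cohort])
        for pid, members in db.items():
            s, k = pathway_score(gs, members, n, min_genes=min_genes)
            score.loc[cohort, pid] = s
            n_used.loc[cohort, pid] = k
    score.index.name = n_used.index.name = "cohort"
    return PathwayScoreTable(score, n_used, {c: int(n_by_cohort[c]) for c in cohorts},
                             gene_scores=gscores)


def min_max_scale(values) -> np.ndarray:
    """Scale to [0,1] via (m - min) / (max - min); NaN passes through.

    A constant vector maps to all zeros (with a warning) rather than
    erroring, so whole-matrix row scaling never aborts a run.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("min_max_scale needs >= 1 value")
    finite = arr[~np.isnan(arr)]
    if finite.size == 0:
        return arr.copy()
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        logger.warning("constant vector in min-max scaling; mapped to 0")
        out = np.where(np.isnan(arr), np.nan, 0.0)
        return out
    return (arr - lo) / (hi - lo)


def count_significant(table: PathwayScoreTable) -> tuple[pd.Series, float]:
    """Per-cohort count of bootstrap-significant pathways, plus the mean."""
    mask = table.require_mask()
    counts = (mask.fillna(0.0) > 0).sum(axis=1)
    counts.name = "n_significant"
    return counts, float(counts.mean())


def category_rollup(table: PathwayScoreTable,
                    cmap: Mapping[str, str]) -> tuple[pd.DataFrame, pd.Series]:
    """Category-level significance counts and the sharing histogram.

    Returns (category x cohort counts of significant pathways, histogram of
    pathways by the number of cohorts in which they are significant,
    binned 0..n_cohorts).
    """
    mask = table.require_mask()
    missing = [p for p in table.pathways if p not in cmap]
    if missing:
        raise ValueError(f"pathway(s) missing from category map: {missing}")
    sig = mask.fillna(0.0) > 0
    categories = pd.Series({p: cmap[p] for p in table.pathways}, name="category")
    rollup = sig.T.groupby(categories).sum().T  # cohorts x categories
    rollup = rollup.T  # categories x cohorts
    rollup.index.name = "category"
    n_cohorts = len(table.cohorts)
    per_pathway = sig.sum(axis=0)
    hist = per_pathway.value_counts().reindex(range(n_cohorts + 1), fill_value=0)
    hist.index.name = "n_cohorts_significant"
    hist.name = "n_pathways"
    return rollup, hist
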