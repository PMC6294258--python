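"""End-to-end orchestration: DEG -> scores -> bootstrap -> summaries.

`run_all` wires the stages together for every cohort in a sample sheet
(optionally splitting cohorts by subtype label) and writes every tabular
artifact under one output directory, deterministically for a fixed seed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import bootstrap, deg as deg_mod, direction, io, scoring

logger = logging.getLogger(__name__)


def deg_by_cohort(expr: pd.DataFrame, sheet: io.SampleSheet,
                  by_subtype: bool = False,
                  zero_fraction_threshold: float = 0.8
                  ) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Run differential expression per cohort (or per cohort.subtype).

    Subtype partitions compare one subtype's tumors against all of the
    cohort's normals; the sample size n is recomputed for every
    comparison actually run.
    """
    comparisons: dict[str, io.SampleSheet] = {}
    for cohort in sheet.cohorts:
        subtypes = sheet.subtypes(cohort) if by_subtype else []
        if subtypes:
            for st in subtypes:
                comparisons[f"{cohort}.{st}"] = sheet.subtype_partition(cohort, st)
        else:
            sub = io.SampleSheet(sheet.frame[sheet.frame["cohort"] == cohort].copy())
            comparisons[cohort] = sub

    degs: dict[str, pd.DataFrame] = {}
    n_samples: dict[str, int] = {}
    for label, sub in comparisons.items():
        cohort = sub.frame["cohort"].iloc[0]
        sub.check_comparable(cohort)
        cols = [s for s in sub.sample_ids if s in expr.columns]
        missing = set(sub.sample_ids) - set(cols)
        if missing:
            raise io.FormatError(
                f"sample(s) in sheet but not in expression matrix: {sorted(missing)}"
            )
        sub_expr = expr[cols]
        degs[label] = deg_mod.run_deg(sub_expr, sub,
                                      zero_fraction_threshold=zero_fraction_threshold)
        n_samples[label] = len(cols)
        logger.info("cohort %s: %d samples, %d genes tested",
                    label, len(cols), len(degs[label]))
    return degs, n_samples


def run_all(expr: pd.DataFrame, sheet: io.SampleSheet, db: io.PathwayDB,
            cmap: Mapping[str, str] | None = None,
            out_dir: str | Path | None = None,
            seed: int = 0,
            alpha: float = bootstrap.DEFAULT_ALPHA,
            gene_alpha: float = direction.DEFAULT_GENE_ALPHA,
            n_resamples: int = bootstrap.DEFAULT_N_RESAMPLES,
            min_genes: int = 2,
            log_base: float = 10.0,
            by_subtype: bool = False) -> scoring.PathwayScoreTable:
    """The full pipeline; returns the bootstrapped, masked score table."""
    degs, n_samples = deg_by_cohort(expr, sheet, by_subtype=by_subtype)
    table = scoring.score_all(degs, db, n_samples, min_genes=min_genes,
                              log_base=log_base)
    bootstrap.run_bootstrap(table, n_resamples=n_resamples, alpha=alpha, seed=seed)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label, d in degs.items():
            io.write_table(d, out_dir / f"deg_{label}.tsv", index_label="gene_id")
        table.write(out_dir)

        counts, mean_count = scoring.count_significant(table)
        summary = counts.to_frame()
        summary.loc["__mean__"] = mean_count
        io.write_table(summary, out_dir / "significant_counts.tsv", index_label="cohort")

        dir_frames = []
        for label, d in degs.items():
            dc = direction.direction_counts(d, db, gene_alpha=gene_alpha)
            dc.insert(0, "cohort", label)
            dir_frames.append(dc.reset_index())
        dir_all = pd.concat(dir_frames, ignore_index=True).set_index("pathway_id")
        io.write_table(dir_all, out_dir / "direction_counts.tsv", index_label="pathway_id")

        if len(table.cohorts) >= 2:
            uniq = direction.unique_pathways(table)
            rows = [{"cohort": c, "pathway_id": p}
                    for c, ps in uniq.items() for p in ps]
            uniq_df = pd.DataFrame(rows, columns=["cohort", "pathway_id"]).set_index("cohort")
            io.write_table(uniq_df, out_dir / "unique_pathways.tsv", index_label="cohort")

        if cmap is not None:
            rollup, hist = scoring.category_rollup(table, cmap)
            io.write_table(rollup, out_dir / "category_rollup.tsv", index_label="category")
            io.write_table(hist.to_frame(), out_dir / "pathway_sharing_histogram.tsv",
                           index_label="n_cohorts_significant")
    return table
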