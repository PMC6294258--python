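"""Master metabolic transcriptional regulator (MMTR) correlation analysis.

A candidate regulator of a pathway should co-express with the pathway's
genes more strongly than with the transcriptome at large.  For each
regulator we compute its Pearson correlation with every expressed gene
(on log2(x+1) values), compare the pathway-restricted correlations
against the genome-wide background via their empirical CDFs, and test
the shift with a two-sample Kolmogorov-Smirnov statistic.  Pathway genes
are removed from the background before the comparison so the two samples
do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .direction import hierarchical_order

logger = logging.getLogger(__name__)


@dataclass
class MMTRAssociation:
    """One regulator's correlation profile and its pathway shift test."""

    regulator: str
    background_r: pd.Series
    pathway_r: pd.Series
    ks_stat: float
    ks_p: float


def correlation_profile(expr: pd.DataFrame, regulator: str,
                        sample_subset=None, method: str = "pearson") -> pd.Series:
    """Correlation of one regulator with every other expressed gene.

    Computed on log2(x+1) values over ``sample_subset`` (default: all
    samples).  Genes with zero variance get NaN with a warning; the
    regulator is excluded from its own profile.
    """
    if regulator not in expr.index:
        raise KeyError(f"regulator {regulator!r} absent from expression matrix")
    cols = list(sample_subset) if sample_subset is not None else list(expr.columns)
    if len(cols) < 3:
        raise ValueError("need >= 3 samples for correlation")
    log = np.log2(expr[cols].to_numpy(dtype=float) + 1.0)
    genes = expr.index
    reg_vec = log[genes.get_loc(regulator)]
    if method == "spearman":
        log = stats.rankdata(log, axis=1)
        reg_vec = stats.rankdata(reg_vec)
    reg_c = reg_vec - reg_vec.mean()
    reg_ss = float(reg_c @ reg_c)
    mat_c = log - log.mean(axis=1, keepdims=True)
    mat_ss = (mat_c ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mat_c @ reg_c) / np.sqrt(mat_ss * reg_ss)
    if reg_ss == 0:
        r[:] = np.nan
    zero_var = mat_ss == 0
    if zero_var.any():
        logger.warning("%d constant gene(s) got NA correlation", int(zero_var.sum()))
        r[zero_var] = np.nan
    profile = pd.Series(r, index=genes, name=regulator)
    return profile.drop(regulator)


def ecdf_shift(background_r, pathway_r) -> tuple[float, float]:
    """Two-sample KS comparison of background vs pathway correlations.

    NaNs are dropped from both sides first.  Returns (ks_stat, ks_p) from
    the two-sided test.
    """
    bg = np.asarray(background_r, dtype=float)
    pw = np.asarray(pathway_r, dtype=float)
    bg = bg[~np.isnan(bg)]
    pw = pw[~np.isnan(pw)]
    if pw.size == 0:
        raise ValueError("no pathway correlations left after NA removal")
    if bg.size == 0:
        raise ValueError("no background correlations left after NA removal")
    res = stats.ks_2samp(bg, pw, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def associate(expr: pd.DataFrame, regulator: str, pathway_genes,
              sample_subset=None, method: str = "pearson") -> MMTRAssociation:
    """Full association for one regulator against one pathway."""
    profile = correlation_profile(expr, regulator, sample_subset, method=method)
    pathway_genes = [g for g in pathway_genes if g != regulator]
    pw_idx = profile.index.intersection(pathway_genes)
    pathway_r = profile.loc[pw_idx]
    background_r = profile.drop(pw_idx)
    ks_stat, ks_p = ecdf_shift(background_r.to_numpy(), pathway_r.to_numpy())
    return MMTRAssociation(regulator, background_r, pathway_r, ks_stat, ks_p)


def mmtr_report(expr: pd.DataFrame, regulators, pathway_genes,
                sample_subset=None, method: str = "pearson",
                ks_threshold: float = 0.05
                ) -> tuple[pd.DataFrame, dict[str, MMTRAssociation], pd.DataFrame]:
    """Regulator x pathway-gene correlation matrix plus per-regulator shifts.

    Returns (correlation matrix with both axes in hierarchical-clustering
    order, per-regulator associations, summary table flagging regulators
    whose KS p-value falls below ``ks_threshold``).
    """
    regulators = list(dict.fromkeys(regulators))
    present = [r for r in regulators if r in expr.index]
    absent = [r for r in regulators if r not in expr.index]
    if not present:
        raise ValueError(f"no regulator present in the expression matrix: {regulators}")
    if absent:
        logger.warning("regulator(s) absent from expression matrix: %s", absent)
    pw_present = [g for g in pathway_genes if g in expr.index]
    if not pw_present:
        raise ValueError("no pathway gene present in the expression matrix")

    assoc: dict[str, MMTRAssociation] = {}
    corr = pd.DataFrame(np.nan, index=pd.Index(pw_present, name="gene_id"),
                        columns=present)
    for reg in present:
        a = associate(expr, reg, pw_present, sample_subset, method=method)
        assoc[reg] = a
        corr.loc[a.pathway_r.index, reg] = a.pathway_r

    if corr.shape[0] >= 2:
        corr = corr.loc[hierarchical_order(corr, axis="rows").leaf_order]
    if corr.shape[1] >= 2:
        corr = corr[hierarchical_order(corr, axis="columns").leaf_order]

    summary = pd.DataFrame(
        {
            "n_background": [len(assoc[r].background_r.dropna()) for r in present],
            "n_pathway": [len(assoc[r].pathway_r.dropna()) for r in present],
            "ks_stat": [assoc[r].ks_stat for r in present],
            "ks_p": [assoc[r].ks_p for r in present],
        },
        index=pd.Index(present, name="regulator"),
    )
    summary["significant_shift"] = summary["ks_p"] < ks_threshold
    return corr, assoc, summary
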