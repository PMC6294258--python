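"""Tumor-vs-normal differential expression for one cohort.

Pipeline: drop genes with zeros in more than 80% of samples, move to
log2(x+1), match every sample's scale (median absolute deviation) to the
cohort geometric-mean scale, then test each gene with an empirical-Bayes
moderated t-statistic and control FDR by Benjamini-Hochberg.

The variance moderation follows the standard hierarchical model for
log-scale expression: gene-wise residual variances s_g^2 are shrunk
toward a common prior value s0^2 with prior degrees of freedom d0,
yielding posterior variances

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),      d = n - 2,

and t-statistics on d0 + d degrees of freedom.  (d0, s0^2) are estimated
by method of moments on log s_g^2, using the closed forms for the
log-scaled-chi-square distribution (digamma/trigamma identities).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import SampleSheet

logger = logging.getLogger(__name__)

#: adjusted p-values are floored here before any -log downstream
P_FLOOR = 1e-300

DEG_COLUMNS = ["log_fc", "t_stat", "p_value", "adj_p_value", "mean_expr"]


def filter_low_expression(matrix: pd.DataFrame,
                          zero_fraction_threshold: float = 0.8) -> pd.DataFrame:
    """Drop genes whose zero fraction strictly exceeds the threshold.

    A gene zero in exactly 80% of samples is kept; one zero in more than
    80% is removed.  Sample columns are untouched.
    """
    if not 0 < zero_fraction_threshold <= 1:
        raise ValueError("zero_fraction_threshold must be in (0, 1]")
    zero_frac = (matrix.to_numpy() == 0).mean(axis=1)
    keep = zero_frac <= zero_fraction_threshold
    if not keep.any():
        raise ValueError("expression filter removed every gene")
    return matrix.loc[keep]


def scale_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) transform, then match each sample's MAD to the cohort scale.

    Each column is rescaled about its median so its median absolute
    deviation equals the geometric mean of all columns' MADs.  Columns
    with zero MAD are left unscaled with a warning.
    """
    if matrix.shape[0] < 2:
        raise ValueError("scale normalization needs >= 2 genes")
    log = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    medians = np.median(log, axis=0)
    mads = np.median(np.abs(log - medians), axis=0)
    positive = mads > 0
    if not positive.all():
        bad = matrix.columns[~positive].tolist()
        logger.warning("column(s) with zero MAD left unscaled: %s", bad)
    if not positive.any():
        return pd.DataFrame(log, index=matrix.index, columns=matrix.columns)
    target = np.exp(np.mean(np.log(mads[positive])))
    factors = np.ones_like(mads)
    factors[positive] = target / mads[positive]
    scaled = medians + (log - medians) * factors
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for all x > 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / y < 1e-10):
            break
    return y


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from gene-wise variances.

    Works on z = log(s2).  Under the hierarchical model z is a shifted
    log-F variable with mean and variance expressible through digamma /
    trigamma functions; matching the empirical mean and variance of z
    gives closed-form estimates.  Returns (inf, exp(moment mean)) when the
    empirical spread of z is no larger than the sampling component, i.e.
    the variances look homogeneous.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive gene variances to estimate the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = float(2.0 * _trigamma_inverse(e_var))
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t_test(matrix: pd.DataFrame, labels: SampleSheet,
                     prior_df: float | None = None) -> pd.DataFrame:
    """Per-gene moderated t-test of tumor vs normal on a log-scale matrix.

    Parameters
    ----------
    matrix
        Genes x samples, already log2-scale (see :func:`scale_normalize`).
    labels
        Sample sheet assigning each column to tumor or normal.
    prior_df
        Override the estimated prior degrees of freedom d0 (0 recovers the
        ordinary pooled two-sample t-test; inf fixes all variances at s0^2).

    Returns a DEG table with columns log_fc, t_stat, p_value, adj_p_value
    and mean_expr, indexed by gene.
    """
    tumor_ids = [s for s in matrix.columns if labels.frame.loc[s, "condition"] == "tumor"]
    normal_ids = [s for s in matrix.columns if labels.frame.loc[s, "condition"] == "normal"]
    n_t, n_n = len(tumor_ids), len(normal_ids)
    if n_t < 2 or n_n < 2:
        raise ValueError(f"need >= 2 samples per condition (got {n_t} tumor, {n_n} normal)")
    df_resid = n_t + n_n - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    tumor = matrix[tumor_ids].to_numpy(dtype=float)
    normal = matrix[normal_ids].to_numpy(dtype=float)
    log_fc = tumor.mean(axis=1) - normal.mean(axis=1)
    ss = ((tumor - tumor.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((normal - normal.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2, df_resid) if d0 > 0 else (None, float("nan"))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n_t + 1.0 / n_n))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, log_fc / np.where(se > 0, se, 1.0),
                          np.where(log_fc == 0, 0.0, np.sign(log_fc) * np.inf))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=df_total) if np.isfinite(df_total) \
        else 2.0 * stats.norm.sf(np.abs(t_stat))
    p = np.clip(p, P_FLOOR, 1.0)
    adj = bh_adjust(p)

    return pd.DataFrame(
        {
            "log_fc": log_fc,
            "t_stat": t_stat,
            "p_value": p,
            "adj_p_value": adj,
            "mean_expr": matrix.to_numpy(dtype=float).mean(axis=1),
        },
        index=matrix.index.copy(),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("p-values contain NA")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_deg(matrix: pd.DataFrame, labels: SampleSheet,
            zero_fraction_threshold: float = 0.8,
            prior_df: float | None = None) -> pd.DataFrame:
    """Filter, normalize and test one cohort; the standard entry point."""
    filtered = filter_low_expression(matrix, zero_fraction_threshold)
    normalized = scale_normalize(filtered)
    return moderated_t_test(normalized, labels, prior_df=prior_df)
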