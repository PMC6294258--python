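"""Synthetic tumor/normal cohorts with planted pathway dysregulation.

The generator emulates RSEM-style expected counts: per-gene baseline means
drawn from a lognormal, negative-binomial sampling noise with a single
global dispersion, and a dropout mechanism that silences a fraction of
genes in most samples (exercising the low-expression filter).  Tumor
samples shift each perturbed gene's mean by a planted log2 fold change, so
every downstream stage can be checked against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PathwayDB, SampleSheet, validate_expression

# fixed spawn keys so each simulation stage has an independent,
# individually reproducible stream
_STREAM_TRUTH = 0
_STREAM_BASELINE = 1
_STREAM_COUNTS = 2
_STREAM_DROPOUT = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one simulated cohort.

    Defaults give a desk-scale study: 2,000 genes of which 50 pathways of
    20 genes each partition the first 1,000, 20 tumor and 20 normal
    samples, lognormal baseline means with median ~150 counts, moderate
    RNA-seq overdispersion, and 5% of genes subject to dropout.
    """

    n_genes: int = 2000
    n_tumor: int = 20
    n_normal: int = 20
    n_pathways: int = 50
    genes_per_pathway: int = 20
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.2
    dropout_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumor, self.n_normal,
               self.n_pathways, self.genes_per_pathway) < 1:
            raise ValueError("all size parameters must be positive")
        if self.n_pathways * self.genes_per_pathway > self.n_genes:
            raise ValueError("pathways require more genes than n_genes provides")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def pathway_ids(self) -> list[str]:
        width = len(str(self.n_pathways))
        return [f"PW{i:0{width}d}" for i in range(1, self.n_pathways + 1)]

    def pathway_db(self) -> PathwayDB:
        """Simulated pathways partition a prefix of the gene list."""
        genes = self.gene_ids
        g = self.genes_per_pathway
        sets = {pid: genes[i * g:(i + 1) * g]
                for i, pid in enumerate(self.pathway_ids)}
        return PathwayDB(sets, {pid: "simulated pathway" for pid in sets})


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a simulated cohort.

    ``true_log2fc`` maps every gene to its planted tumor-vs-normal log2
    fold change (0 for unperturbed genes); ``planted`` records, per
    planted pathway, the (effect_fraction, effect_log2fc) used.
    """

    true_log2fc: pd.Series
    planted: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def planted_pathways(self) -> list[str]:
        return list(self.planted)


def make_truth(config: SimulationConfig,
               planted: Sequence[tuple[int, float, float]] = ()) -> SyntheticTruth:
    """Assign planted log2 fold changes to pathway member genes.

    ``planted`` lists (pathway index, effect_fraction, effect_log2fc)
    triples; within each planted pathway, round(fraction * size) member
    genes are chosen uniformly without replacement and given the pathway's
    effect_log2fc.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_TRUTH]))
    db = config.pathway_db()
    pathway_ids = config.pathway_ids
    lfc = pd.Series(0.0, index=pd.Index(config.gene_ids, name="gene_id"))
    planted_map: dict[str, tuple[float, float]] = {}
    for idx, fraction, effect in planted:
        if not 0 <= idx < config.n_pathways:
            raise ValueError(f"planted pathway index {idx} out of range")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"effect_fraction {fraction} outside [0, 1]")
        pid = pathway_ids[idx]
        members = db[pid]
        k = int(round(fraction * len(members)))
        chosen = rng.choice(members, size=k, replace=False)
        for gene in chosen:
            if lfc[gene] != 0.0 and not np.isclose(lfc[gene], effect):
                raise ValueError(
                    f"gene {gene} assigned conflicting effects by overlapping pathways"
                )
            lfc[gene] = effect
        planted_map[pid] = (fraction, effect)
    return SyntheticTruth(lfc, planted_map)


def simulate_cohort(config: SimulationConfig,
                    truth: SyntheticTruth,
                    cohort: str = "SIM",
                    sample_prefix: str | None = None) -> tuple[pd.DataFrame, SampleSheet]:
    """Draw one tumor/normal cohort under the given truth.

    Normal samples are NegBin(mu_g, dispersion); tumor samples are
    NegBin(mu_g * 2**true_log2fc_g, dispersion) with mu_g ~
    LogNormal(baseline_log_mean, baseline_log_sd).  A dropout_fraction of
    genes is then silenced in a random sample subset (each sample zeroed
    with probability 0.85).  Bit-identical for identical seeds.
    """
    genes = config.gene_ids
    prefix = sample_prefix or cohort
    tumor_ids = [f"{prefix}-T{i:03d}" for i in range(1, config.n_tumor + 1)]
    normal_ids = [f"{prefix}-N{i:03d}" for i in range(1, config.n_normal + 1)]

    rng_base = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_BASELINE]))
    mu = rng_base.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                            size=config.n_genes)

    lfc = truth.true_log2fc.reindex(genes).fillna(0.0).to_numpy()
    mu_tumor = mu * np.exp2(lfc)

    # NB with mean m and dispersion a: var = m + a m^2, n = 1/a, p = n/(n+m)
    n_param = 1.0 / config.dispersion
    rng_counts = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_COUNTS]))

    def draw(means: np.ndarray, n_samples: int) -> np.ndarray:
        p = n_param / (n_param + means)
        return rng_counts.negative_binomial(
            n_param, p[:, None], size=(config.n_genes, n_samples)
        ).astype(float)

    normal = draw(mu, config.n_normal)
    tumor = draw(mu_tumor, config.n_tumor)
    values = np.concatenate([tumor, normal], axis=1)

    if config.dropout_fraction > 0:
        rng_drop = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_DROPOUT]))
        n_drop = int(round(config.dropout_fraction * config.n_genes))
        drop_genes = rng_drop.choice(config.n_genes, size=n_drop, replace=False)
        n_samples = values.shape[1]
        for g in drop_genes:
            mask = rng_drop.random(n_samples) < 0.85
            values[g, mask] = 0.0

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=tumor_ids + normal_ids)
    sheet_frame = pd.DataFrame(
        {
            "condition": ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
            "cohort": cohort,
        },
        index=pd.Index(tumor_ids + normal_ids, name="sample_id"),
    )
    return validate_expression(expr), SampleSheet(sheet_frame)


def simulate_replicate(config: SimulationConfig, truth: SyntheticTruth,
                       replicate_seed: int, cohort: str = "SIM") -> tuple[pd.DataFrame, SampleSheet]:
    """An independent cohort from the same truth (fresh sampling noise only)."""
    cfg = replace(config, seed=replicate_seed)
    return simulate_cohort(cfg, truth, cohort=cohort)


def simulate_regulator_cohort(n_genes: int = 2000,
                              n_samples: int = 60,
                              pathway_size: int = 15,
                              driver_strength: float = 1.0,
                              noise_sd: float = 0.5,
                              baseline_log2_mean: float = 7.0,
                              baseline_log2_sd: float = 1.0,
                              seed: int = 0) -> tuple[pd.DataFrame, str, list[str]]:
    """A cohort where one regulator gene linearly drives a pathway's genes.

    On the log2 scale the regulator follows a latent factor z ~ N(0,1);
    each pathway gene is baseline + driver_strength*z + N(0, noise_sd);
    all other genes are independent noise around their baselines.  Returns
    (expression matrix, regulator gene id, pathway gene ids); expression is
    2**log2 - 1 >= 0 so the standard log2(x+1) transform recovers the
    linear structure.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]

    z = rng.normal(size=n_samples)
    base = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    log2_expr = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    regulator = genes[0]
    pathway_genes = genes[1:1 + pathway_size]
    log2_expr[0] = base[0] + z  # regulator tracks the latent factor exactly
    for i in range(1, 1 + pathway_size):
        log2_expr[i] += driver_strength * z

    expr = pd.DataFrame(np.clip(np.exp2(log2_expr) - 1.0, 0.0, None),
                        index=pd.Index(genes, name="gene_id"), columns=samples)
    return validate_expression(expr), regulator, pathway_genes
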