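"""Negative-binomial count simulator for paired diploid/triploid designs.

The generative model draws, for gene ``g`` in sample ``s``,

    count[g, s] ~ NB(mean = L_s * p[g, s], size = theta)

where ``L_s`` is a log-normal library size and ``p[g, s]`` is the relative
expression share

    p[g, s] = c[chr(g), s]**gamma * e_g * m[g, s] / sum_g'(...)

built from the chromosome copy number ``c`` (2 per chromosome in diploids,
3 in triploids, overridden by planted aneuploidy events), a log-normal
per-gene baseline ``e_g`` shared by all samples, and gene-wise
multiplicative covariate effects ``m`` for the sample's site, cohort and
ploidy levels. Because shares are renormalized per sample, whole-genome
ploidy dosage cancels exactly — only chromosome-level deviations from the
ploidy baseline survive library-size normalization, which is the property
the downstream aneuploidy screen relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ploidyscreen.config import (
    BASELINE_COPIES,
    PLOIDIES,
    AneuploidyEvent,
    SimulationConfig,
)


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`.

    Attributes
    ----------
    counts
        Integer gene x sample count matrix.
    genemap
        Series mapping gene id -> chromosome id.
    samples
        Sample metadata indexed by sample id with columns
        ``ploidy``, ``site``, ``cohort``, ``dam``.
    truth
        Karyotype ground truth: samples x chromosomes copy numbers.
    """

    counts: pd.DataFrame
    genemap: pd.Series
    samples: pd.DataFrame
    truth: pd.DataFrame


def _allocate_genes(n_genes: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of gene counts per chromosome."""
    ideal = weights * n_genes
    counts = np.floor(ideal).astype(int)
    remainder = n_genes - counts.sum()
    if remainder > 0:
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _library_sizes(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, float(mean))
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def build_sample_table(config: SimulationConfig) -> pd.DataFrame:
    """Expand the design cells into one metadata row per individual."""
    rows = []
    for cell in config.design:
        for ploidy in PLOIDIES:
            for k in range(1, cell.n_per_ploidy + 1):
                sid = f"{cell.site}_{cell.cohort}_{cell.dam}_{ploidy}_{k:02d}"
                rows.append((sid, ploidy, cell.site, cell.cohort, cell.dam))
    table = pd.DataFrame(
        rows, columns=["sample_id", "ploidy", "site", "cohort", "dam"]
    ).set_index("sample_id")
    if table.index.has_duplicates:
        raise ValueError("design produces duplicate sample ids")
    return table


def build_truth(config: SimulationConfig, samples: pd.DataFrame) -> pd.DataFrame:
    """Karyotype matrix: ploidy baseline everywhere, events override."""
    chroms = config.chromosome_ids
    base = samples["ploidy"].map(BASELINE_COPIES).to_numpy()
    truth = pd.DataFrame(
        np.repeat(base[:, None], len(chroms), axis=1),
        index=samples.index,
        columns=chroms,
        dtype=int,
    )
    for ev in config.aneuploidy_events:
        if ev.sample not in truth.index:
            raise ValueError(f"aneuploidy_events: unknown sample id {ev.sample!r}")
        if ev.chromosome not in truth.columns:
            raise ValueError(f"aneuploidy_events: unknown chromosome {ev.chromosome!r}")
        truth.loc[ev.sample, ev.chromosome] = ev.copies
    return truth


def recover_events(truth: pd.DataFrame, samples: pd.DataFrame) -> list[AneuploidyEvent]:
    """Invert :func:`build_truth`: list every departure from the ploidy baseline."""
    base = samples.loc[truth.index, "ploidy"].map(BASELINE_COPIES).to_numpy()[:, None]
    rows, cols = np.nonzero(truth.to_numpy() != base)
    return [
        AneuploidyEvent(
            sample=truth.index[r], chromosome=truth.columns[c], copies=int(truth.iat[r, c])
        )
        for r, c in zip(rows, cols)
    ]


def expected_shares(
    config: SimulationConfig,
    baseline: np.ndarray,
    copy_matrix: np.ndarray,
    effects: np.ndarray,
) -> np.ndarray:
    """Per-sample relative expression shares (columns sum to 1)."""
    unnorm = (copy_matrix**config.dosage_exponent) * baseline[:, None] * effects
    return unnorm / unnorm.sum(axis=0, keepdims=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full dataset under ``config``; same seed, same bytes out.

    Returns counts, the gene->chromosome map, the sample table and the
    karyotype truth matrix. See the module docstring for the model.
    """
    rng = np.random.default_rng(config.seed)
    weights = np.asarray(config.chromosome_weights, dtype=float)

    genes_per_chrom = _allocate_genes(config.n_genes, weights)
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    chrom_of_gene = np.repeat(np.arange(config.n_chromosomes), genes_per_chrom)
    genemap = pd.Series(
        [config.chromosome_ids[c] for c in chrom_of_gene],
        index=pd.Index(gene_ids, name="gene_id"),
        name="chromosome_id",
    )

    samples = build_sample_table(config)
    truth = build_truth(config, samples)

    # per-gene baseline expression (natural-log normal)
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)
    )

    # gene-wise multiplicative covariate effects, shared within a level
    affected = rng.random(config.n_genes) < config.frac_affected_genes
    level_effect: dict[tuple[str, str], np.ndarray] = {}
    for column in ("site", "cohort", "ploidy"):
        for level in sorted(samples[column].unique()):
            eff = np.ones(config.n_genes)
            if config.covariate_effect_sd > 0:
                draw = rng.normal(0.0, config.covariate_effect_sd, size=config.n_genes)
                eff[affected] = np.exp(draw[affected])
            level_effect[(column, level)] = eff
    interaction = np.ones(config.n_genes)
    if config.interaction_site is not None and config.interaction_sd > 0:
        draw = rng.normal(0.0, config.interaction_sd, size=config.n_genes)
        interaction[affected] = np.exp(draw[affected])

    n_samples = len(samples)
    effects = np.ones((config.n_genes, n_samples))
    for j, (sid, row) in enumerate(samples.iterrows()):
        m = (
            level_effect[("site", row["site"])]
            * level_effect[("cohort", row["cohort"])]
            * level_effect[("ploidy", row["ploidy"])]
        )
        if row["ploidy"] == "3n" and row["site"] == config.interaction_site:
            m = m * interaction
        effects[:, j] = m

    copy_matrix = truth.to_numpy().T[chrom_of_gene, :].astype(float)  # genes x samples
    shares = expected_shares(config, baseline, copy_matrix, effects)

    lib_sizes = _library_sizes(rng, n_samples, config.lib_size_mean, config.lib_size_cv)
    mean = shares * lib_sizes[None, :]

    if math.isinf(config.dispersion):
        values = rng.poisson(mean)
    else:
        theta = config.dispersion
        values = rng.negative_binomial(theta, theta / (theta + mean))

    counts = pd.DataFrame(values.astype(np.int64), index=genemap.index, columns=samples.index)
    return SimulatedDataset(counts=counts, genemap=genemap, samples=samples, truth=truth)
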