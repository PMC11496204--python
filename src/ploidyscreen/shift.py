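"""PCA of the expression matrix and the variance-weighted shift distance.

The "transcriptomic shift" between a matched diploid/triploid pair is the
Euclidean distance between the two samples in principal-component space
after multiplying each component coordinate by the fraction of variance
that component explains:

    d(pair) = sqrt( sum_i ( w_i * (PC_i(3n) - PC_i(2n)) )^2 ),  w_i = var_frac_i

By default only PC1 and PC2 enter the distance. The weighting is pluggable
("none" reproduces the plain Euclidean distance, "sqrt-fraction" weights by
the square root of the variance fraction); the choice is recorded in the
output's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WEIGHTINGS = ("none", "fraction", "sqrt-fraction")


@dataclass
class PcaResult:
    """Sample scores and per-component variance fractions.

    ``scores`` is samples x components; ``loadings`` is genes x components
    (unit-norm columns); ``variance_fraction`` is nonincreasing and sums to
    at most 1.
    """

    scores: pd.DataFrame
    variance_fraction: np.ndarray
    loadings: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(logcpm: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """Gene-centered SVD of the expression matrix, samples as observations.

    Each gene (row) is centered across samples; scores are the projections
    of samples onto the right singular vectors. Components are oriented so
    the largest-magnitude loading entry is positive, making the sign
    deterministic.
    """
    n_genes, n_samples = logcpm.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_rank = min(n_samples - 1, n_genes)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must lie in [1, {max_rank}] for a {n_genes}x{n_samples} matrix"
        )
    centered = logcpm.to_numpy(dtype=float)
    centered = centered - centered.mean(axis=1, keepdims=True)
    if not centered.any():
        raise ValueError("expression matrix is constant; PCA undefined")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = float((s**2).sum())
    u = u[:, :n_components]
    s = s[:n_components]
    vt = vt[:n_components]
    # deterministic orientation: largest-|loading| entry positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            vt[i] = -vt[i]
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (s[:, None] * vt).T, index=logcpm.columns, columns=comp_names
    )
    loadings = pd.DataFrame(u, index=logcpm.index, columns=comp_names)
    return PcaResult(
        scores=scores,
        variance_fraction=(s**2) / total_var,
        loadings=loadings,
    )


def _weights(variance_fraction: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(variance_fraction)
    if weighting == "fraction":
        return variance_fraction
    if weighting == "sqrt-fraction":
        return np.sqrt(variance_fraction)
    raise ValueError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")


def transcriptomic_shift(
    pca_result: PcaResult,
    pairs: pd.DataFrame,
    n_components: int = 2,
    weighting: str = "fraction",
) -> pd.DataFrame:
    """Variance-weighted PC-space distance for every matched pair.

    Returns one row per pair with columns ``pair_id, diploid_id,
    triploid_id, site, cohort, dam, distance, components_used``; the
    weighting scheme is stored in ``DataFrame.attrs["weighting"]``.
    """
    if n_components > pca_result.n_components:
        raise ValueError(
            f"requested {n_components} components but PCA holds {pca_result.n_components}"
        )
    scores = pca_result.scores.iloc[:, :n_components]
    w = _weights(pca_result.variance_fraction[:n_components], weighting)
    missing = (set(pairs["diploid_id"]) | set(pairs["triploid_id"])) - set(scores.index)
    if missing:
        raise ValueError(f"sample(s) missing from PCA scores: {sorted(missing)[0]!r}")
    d2 = (
        (scores.loc[pairs["triploid_id"]].to_numpy() - scores.loc[pairs["diploid_id"]].to_numpy())
        * w[None, :]
    ) ** 2
    out = pairs.copy()
    out["distance"] = np.sqrt(d2.sum(axis=1))
    out["components_used"] = n_components
    out.attrs["weighting"] = weighting
    out.attrs["variance_fraction"] = list(map(float, pca_result.variance_fraction[:n_components]))
    return out


def shift_summary(shifts: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of pair distances by site x cohort."""
    def q1(x):
        return x.quantile(0.25)

    def q3(x):
        return x.quantile(0.75)

    summary = (
        shifts.groupby(["site", "cohort"], sort=True)["distance"]
        .agg(n="size", median="median", q1=q1, q3=q3)
        .reset_index()
    )
    summary["iqr"] = summary["q3"] - summary["q1"]
    return summary
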