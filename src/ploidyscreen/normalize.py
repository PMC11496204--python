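"""Library-size normalization (CPM), log transform and low-expression filter.

Counts-per-million removes library-size differences: every sample column is
rescaled to sum to 1e6. log2(CPM + pseudocount) is the working scale of the
aneuploidy screen and the PCA; pseudocount 1 keeps zero-CPM genes at 0.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

CPM_SCALE = 1_000_000.0


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.shape[0] < 1 or counts.shape[1] < 2:
        raise ValueError("count matrix needs at least 1 gene and 2 samples")
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``count * 1e6 / library size`` per sample.

    Raises if any sample has a zero library size, naming the sample.
    """
    _validate_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    return counts * (CPM_SCALE / lib)


def log_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount), elementwise."""
    if not pseudocount > 0:
        raise ValueError("pseudocount must be positive")
    return np.log2(cpm(counts) + pseudocount)


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 5.0, min_fraction: float = 0.8
) -> pd.DataFrame:
    """Drop lowly expressed genes before network/screen analyses.

    A gene is retained iff its CPM is >= ``min_cpm`` in at least
    ``ceil(min_fraction * n_samples)`` samples (default: at least 5 CPM in
    80% of all samples). Gene order is preserved.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    values = cpm(counts)
    needed = math.ceil(min_fraction * counts.shape[1])
    keep = (values >= min_cpm).sum(axis=1) >= needed
    if not keep.any():
        raise ValueError(
            "all genes removed by the low-expression filter; "
            "review min_cpm/min_fraction thresholds"
        )
    return counts.loc[keep]
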