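"""Covariate-matched diploid/triploid sample pairing.

Within every (site, cohort, dam) cell, diploids and triploids are paired
one-to-one up to ``min(n_2n, n_3n)`` pairs. The ordered strategy pairs by
lexicographic sample id and is fully deterministic; the random strategy
permutes ids within each cell under a seed, for sensitivity analyses of the
arbitrary within-cell assignment. Unmatched samples are reported, never
silently dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["pair_id", "diploid_id", "triploid_id", "site", "cohort", "dam"]


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the metadata contract: unique ids, ploidy in {2n, 3n}."""
    required = {"ploidy", "site", "cohort", "dam"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing required column(s): {sorted(missing)}")
    if samples.index.has_duplicates:
        dup = samples.index[samples.index.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    bad = set(samples["ploidy"].unique()) - {"2n", "3n"}
    if bad:
        raise ValueError(f"ploidy values outside {{'2n', '3n'}}: {sorted(bad)}")
    return samples


def match_pairs(
    samples: pd.DataFrame,
    strategy: str = "ordered",
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Build the matched 2n/3n pair set.

    Parameters
    ----------
    samples
        Metadata indexed by sample id with columns ploidy/site/cohort/dam.
    strategy
        ``"ordered"`` (lexicographic, deterministic) or ``"random"``
        (seeded within-cell permutation).
    seed
        Required when ``strategy="random"``.

    Returns
    -------
    pairs, unmatched
        ``pairs`` has columns ``pair_id, diploid_id, triploid_id, site,
        cohort, dam``; ``unmatched`` lists the ids left over in cells with
        unequal ploidy counts.
    """
    validate_sample_table(samples)
    if len(samples) == 0:
        raise ValueError("sample table is empty")
    if strategy not in ("ordered", "random"):
        raise ValueError(f"unknown strategy {strategy!r}; use 'ordered' or 'random'")
    if strategy == "random" and seed is None:
        raise ValueError("random strategy requires a seed")
    rng = np.random.default_rng(seed) if strategy == "random" else None

    rows = []
    unmatched: list[str] = []
    for (site, cohort, dam), cell in samples.groupby(["site", "cohort", "dam"], sort=True):
        diploids = sorted(cell.index[cell["ploidy"] == "2n"])
        triploids = sorted(cell.index[cell["ploidy"] == "3n"])
        if not diploids or not triploids:
            logger.warning(
                "cell site=%s cohort=%s dam=%s has no %s samples; skipped",
                site, cohort, dam, "2n" if not diploids else "3n",
            )
            unmatched.extend(diploids + triploids)
            continue
        if rng is not None:
            diploids = list(rng.permutation(diploids))
            triploids = list(rng.permutation(triploids))
        n = min(len(diploids), len(triploids))
        unmatched.extend(diploids[n:] + triploids[n:])
        for d, t in zip(diploids[:n], triploids[:n]):
            rows.append((f"{d}__vs__{t}", d, t, site, cohort, dam))

    if unmatched:
        logger.warning("%d sample(s) left unmatched: %s", len(unmatched), unmatched)
    return pd.DataFrame(rows, columns=PAIR_COLUMNS), unmatched
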