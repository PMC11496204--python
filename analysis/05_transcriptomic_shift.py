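#!/usr/bin/env python
"""PCA of the log-CPM matrix and the variance-weighted shift distance for
every matched pair, summarized by site and cohort."""

from pathlib import Path

from ploidyscreen import io as psio
from ploidyscreen.normalize import log_cpm
from ploidyscreen.shift import pca, shift_summary, transcriptomic_shift

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    counts = psio.read_counts(DATA / "filtered_counts.tsv")
    pairs = psio.read_pairs(DATA / "pairs.tsv")
    values = log_cpm(counts)

    result = pca(values, n_components=2)
    shifts = transcriptomic_shift(result, pairs, weighting="fraction")
    psio.write_pairs(shifts, ROOT / "shift.tsv")
    summary = shift_summary(shifts)
    psio.write_pairs(summary, ROOT / "shift_summary.tsv")

    pc1, pc2 = result.variance_fraction[:2]
    print(f"PC1 explains {pc1:.1%}, PC2 {pc2:.1%} of variance")
    by_site = shifts.groupby("site")["distance"].median()
    for site, value in by_site.items():
        print(f"median pair shift at {site}: {value:.3f}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
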