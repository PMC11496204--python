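#!/usr/bin/env python
"""Apply the low-expression filter (>= 5 CPM in >= 80% of samples) and
write the filtered counts and the log2(CPM + 1) matrix used by both the
aneuploidy screen and the shift metric."""

from pathlib import Path

from ploidyscreen import io as psio
from ploidyscreen.normalize import filter_low_expression, log_cpm

DATA = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    counts = psio.read_counts(DATA / "counts.tsv")
    kept = filter_low_expression(counts)
    psio.write_counts(kept, DATA / "filtered_counts.tsv")
    psio.write_matrix(log_cpm(kept), DATA / "logcpm.tsv")
    print(
        f"filter retained {kept.shape[0]} of {counts.shape[0]} genes "
        f"({kept.shape[0] / counts.shape[0]:.0%}); log-CPM written"
    )


if __name__ == "__main__":
    main()
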