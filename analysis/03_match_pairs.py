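#!/usr/bin/env python
"""Match diploid and triploid individuals one-to-one within every
site x cohort x dam cell (96 pairs under the full design)."""

from pathlib import Path

from ploidyscreen import io as psio
from ploidyscreen.pairing import match_pairs

DATA = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    samples = psio.read_samples(DATA / "samples.csv")
    pairs, unmatched = match_pairs(samples)
    psio.write_pairs(pairs, DATA / "pairs.tsv")
    print(f"{len(pairs)} matched 2n/3n pairs across "
          f"{pairs[['site', 'cohort', 'dam']].drop_duplicates().shape[0]} cells; "
          f"{len(unmatched)} samples unmatched")


if __name__ == "__main__":
    main()
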