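#!/usr/bin/env python
"""Calibrate the screen by simulation: sensitivity to planted losses and
gains and the false-positive rate under the euploid null, at default
thresholds (robust z >= 3, effect floor log2(1.15))."""

from pathlib import Path

from ploidyscreen import io as psio
from ploidyscreen.screen import Scenario, power_analysis

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20210708


def main() -> None:
    scenarios = [
        Scenario("euploid_null", copies=None),
        Scenario("copy_1_of_3", copies=1),
        Scenario("copy_2_of_3", copies=2),
        Scenario("copy_4_of_3", copies=4),
    ]
    table = power_analysis(scenarios, n_reps=200, seed=SEED)
    ROOT.mkdir(parents=True, exist_ok=True)
    psio.write_pairs(table, ROOT / "power_analysis.tsv")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
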