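#!/usr/bin/env python
"""Simulate the full outplant study: 2 sites x 2 cohorts x 3 dams, eight
individuals per cross per ploidy (192 samples), 5000 genes on 10
chromosomes, with two planted aneuploidy events in triploids (a chr3
monosomy and a chr7 trisomy-equivalent gain) and a stronger triploid
response at the low-salinity-like LUMCON site.

Writes counts, gene map, sample metadata and the karyotype truth to
results/data/.
"""

from pathlib import Path

import ploidyscreen as ps
from ploidyscreen import io as psio
from ploidyscreen.config import AneuploidyEvent, SimulationConfig

SEED = 20210708  # sampling date of the field study this design emulates
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    config = SimulationConfig(
        interaction_site="LUMCON",
        interaction_sd=0.5,
        aneuploidy_events=[
            AneuploidyEvent("LUMCON_LSU_dam2_3n_03", "chr3", 2),
            AneuploidyEvent("GrandIsle_AU_dam1_3n_05", "chr7", 4),
        ],
        seed=SEED,
    )
    data = ps.simulate_dataset(config)
    OUT.mkdir(parents=True, exist_ok=True)
    psio.write_counts(data.counts, OUT / "counts.tsv")
    psio.write_genemap(data.genemap, OUT / "genemap.tsv")
    psio.write_samples(data.samples, OUT / "samples.csv")
    psio.write_truth(data.truth, OUT / "truth.tsv")
    config.to_yaml(OUT / "simulation_config.yaml")
    n_events = len(config.aneuploidy_events)
    print(
        f"simulated {data.counts.shape[0]} genes x {data.counts.shape[1]} samples "
        f"with {n_events} planted aneuploidy events -> {OUT}"
    )


if __name__ == "__main__":
    main()
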