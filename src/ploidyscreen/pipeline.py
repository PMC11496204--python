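"""End-to-end pipeline: simulate (optional) -> filter -> normalize -> pairs
-> aneuploidy screen -> shift metric, with a machine-readable run manifest.

The manifest records every parameter (including applied defaults), the
seed, package versions and SHA-256 checksums of all inputs and outputs, so
a run is fully reconstructible and a rerun under the same manifest is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import ploidyscreen
from ploidyscreen import io as psio
from ploidyscreen.config import SimulationConfig
from ploidyscreen.normalize import filter_low_expression, log_cpm
from ploidyscreen.pairing import match_pairs
from ploidyscreen.screen import (
    DEFAULT_EFFECT_FLOOR,
    DEFAULT_MIN_GENES,
    DEFAULT_Z_THRESHOLD,
    pair_summary,
    screen_all_pairs,
)
from ploidyscreen.shift import pca, shift_summary, transcriptomic_shift

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one end-to-end run.

    Either ``simulate`` is set (synthetic inputs are generated under the
    global seed) or the three input paths are given.
    """

    outdir: str | Path = "results"
    seed: int = 0
    simulate: SimulationConfig | None = None
    counts_path: str | Path | None = None
    genemap_path: str | Path | None = None
    samples_path: str | Path | None = None
    apply_filter: bool = True
    min_cpm: float = 5.0
    min_fraction: float = 0.8
    pseudocount: float = 1.0
    pair_strategy: str = "ordered"
    min_genes: int = DEFAULT_MIN_GENES
    z_threshold: float = DEFAULT_Z_THRESHOLD
    effect_floor_log2: float = DEFAULT_EFFECT_FLOOR
    n_components: int = 2
    weighting: str = "fraction"

    def __post_init__(self) -> None:
        if self.simulate is None and not (
            self.counts_path and self.genemap_path and self.samples_path
        ):
            raise ValueError(
                "either a simulation config or counts/genemap/samples paths are required"
            )
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        for key in ("counts_path", "genemap_path", "samples_path"):
            if d[key] is not None:
                d[key] = str(d[key])
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the manifest dict.

    A stage failure raises with the stage name; outputs written before the
    failure are listed as partial in the exception's ``__notes__``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    outputs: dict[str, Path] = {}
    current_stage = "setup"

    def emit(name: str, writer, obj) -> Path:
        path = outdir / name
        writer(obj, path)
        outputs[name] = path
        return path

    try:
        if config.simulate is not None:
            current_stage = "simulate"
            sim_config = dataclasses.replace(config.simulate, seed=config.seed)
            data = ploidyscreen.simulate_dataset(sim_config)
            counts, genemap, samples = data.counts, data.genemap, data.samples
            emit("counts.tsv", psio.write_counts, counts)
            emit("genemap.tsv", psio.write_genemap, genemap)
            emit("samples.csv", psio.write_samples, samples)
            emit("truth.tsv", psio.write_truth, data.truth)
            stages.append("simulate")
        else:
            current_stage = "read_inputs"
            counts = psio.read_counts(config.counts_path)
            genemap = psio.read_genemap(config.genemap_path)
            samples = psio.read_samples(config.samples_path)
            stages.append("read_inputs")

        current_stage = "filter"
        if config.apply_filter:
            counts = filter_low_expression(
                counts, min_cpm=config.min_cpm, min_fraction=config.min_fraction
            )
        emit("filtered_counts.tsv", psio.write_counts, counts)
        stages.append("filter")

        current_stage = "normalize"
        logcpm = log_cpm(counts, pseudocount=config.pseudocount)
        emit("logcpm.tsv", psio.write_matrix, logcpm)
        stages.append("normalize")

        current_stage = "pairs"
        pairs, unmatched = match_pairs(
            samples, strategy=config.pair_strategy, seed=config.seed
        )
        emit("pairs.tsv", psio.write_pairs, pairs)
        (outdir / "unmatched.txt").write_text("\n".join(unmatched) + "\n" if unmatched else "")
        outputs["unmatched.txt"] = outdir / "unmatched.txt"
        stages.append("pairs")

        current_stage = "aneuploidy"
        results = screen_all_pairs(
            psio.align_to_genemap(logcpm, genemap),
            genemap,
            pairs,
            min_genes=config.min_genes,
            z_threshold=config.z_threshold,
            effect_floor_log2=config.effect_floor_log2,
        )
        emit("aneuploidy.tsv", psio.write_pairs, results)
        emit("aneuploidy_pair_summary.tsv", psio.write_pairs, pair_summary(results))
        stages.append("aneuploidy")

        current_stage = "shift"
        pca_result = pca(logcpm, n_components=config.n_components)
        shifts = transcriptomic_shift(
            pca_result, pairs, n_components=config.n_components, weighting=config.weighting
        )
        emit("shift.tsv", psio.write_pairs, shifts)
        emit("shift_summary.tsv", psio.write_pairs, shift_summary(shifts))
        stages.append("shift")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {current_stage!r}; "
            f"partial outputs: {sorted(outputs)}"
        ) from exc

    current_stage = "manifest"
    checksums = {name: _sha256(path) for name, path in sorted(outputs.items())}
    inputs = {}
    for key in ("counts_path", "genemap_path", "samples_path"):
        value = getattr(config, key)
        if value is not None:
            inputs[key] = {"path": str(value), "sha256": _sha256(Path(value))}
    manifest = {
        "tool": "ploidyscreen",
        "version": ploidyscreen.__version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": stages,
        "inputs": inputs,
        "outputs": checksums,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d stages, outputs in %s", len(stages), outdir)
    return manifest
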