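"""Simulation configuration for the paired diploid/triploid count generator.

The defaults emulate the field design the pipeline was built for: 10
chromosomes, two outplant sites crossed with two hatchery cohorts and three
maternal dam lines, and eight individuals per cross per ploidy at each site
(192 samples in total).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

PLOIDIES = ("2n", "3n")
#: baseline chromosome copy number per ploidy level
BASELINE_COPIES = {"2n": 2, "3n": 3}


@dataclass(frozen=True)
class DesignCell:
    """One site x cohort x dam cross with a replicate count per ploidy."""

    site: str
    cohort: str
    dam: str
    n_per_ploidy: int = 8


@dataclass(frozen=True)
class AneuploidyEvent:
    """A planted whole-chromosome copy-number deviation.

    ``sample`` selects the affected individual by sample id; ``copies`` is
    the absolute copy number of ``chromosome`` in that individual
    (e.g. 2 for a monosomic triploid chromosome, 4 for a trisomic one).
    """

    sample: str
    chromosome: str
    copies: int

    def __post_init__(self) -> None:
        if not (isinstance(self.copies, (int, np.integer)) and 1 <= self.copies <= 4):
            raise ValueError(
                f"aneuploidy_events: copies must be an integer in 1..4, got {self.copies!r}"
            )


def study_design(
    sites: Sequence[str] = ("GrandIsle", "LUMCON"),
    cohorts: Sequence[str] = ("AU", "LSU"),
    dams: Sequence[str] = ("dam1", "dam2", "dam3"),
    n_per_ploidy: int = 8,
) -> list[DesignCell]:
    """Full-factorial site x cohort x dam design, one cell per cross/site."""
    return [
        DesignCell(site=s, cohort=c, dam=d, n_per_ploidy=n_per_ploidy)
        for s in sites
        for c in cohorts
        for d in dams
    ]


@dataclass
class SimulationConfig:
    """Parameters of the negative-binomial count simulator.

    Attributes
    ----------
    n_genes
        Total number of genes across all chromosomes.
    n_chromosomes
        Number of chromosomes (default 10, the oyster karyotype).
    chromosome_weights
        Fraction of genes carried by each chromosome; must sum to 1.
        ``None`` means equal weights.
    design
        List of :class:`DesignCell`; both ploidies are generated per cell.
    baseline_log_mean, baseline_log_sd
        Natural-log mean and sd of per-gene relative expression
        (log-normal across genes).
    dispersion
        Negative-binomial size parameter theta (variance = mu + mu^2/theta).
        ``inf`` gives exact Poisson sampling.
    lib_size_mean, lib_size_cv
        Mean and coefficient of variation of log-normally distributed
        library sizes (total counts per sample).
    covariate_effect_sd
        Log-scale sd of gene-wise multiplicative site/cohort/ploidy effects.
    frac_affected_genes
        Fraction of genes receiving covariate effects.
    dosage_exponent
        Expression responds to copy number as ``c ** dosage_exponent``;
        1.0 is fully proportional dosage, 0.0 full dosage compensation.
    interaction_site
        Optional site at which triploids receive an extra gene-wise
        expression effect of log-sd ``interaction_sd`` (models a
        site-dependent ploidy response).
    aneuploidy_events
        Planted whole-chromosome copy-number deviations.
    seed
        Mandatory seed; identical configs give byte-identical output.
    """

    n_genes: int = 5000
    n_chromosomes: int = 10
    chromosome_weights: Sequence[float] | None = None
    design: Sequence[DesignCell] = field(default_factory=study_design)
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.5
    dispersion: float = 10.0
    lib_size_mean: float = 1_000_000
    lib_size_cv: float = 0.3
    covariate_effect_sd: float = 0.2
    frac_affected_genes: float = 0.3
    dosage_exponent: float = 1.0
    interaction_site: str | None = None
    interaction_sd: float = 0.0
    aneuploidy_events: Sequence[AneuploidyEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")
        if self.chromosome_weights is None:
            self.chromosome_weights = [1.0 / self.n_chromosomes] * self.n_chromosomes
        w = np.asarray(self.chromosome_weights, dtype=float)
        if w.shape != (self.n_chromosomes,):
            raise ValueError(
                f"chromosome_weights must have length n_chromosomes={self.n_chromosomes}"
            )
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("chromosome_weights must be a simplex vector summing to 1")
        if not self.design:
            raise ValueError("design must contain at least one cell")
        if any(cell.n_per_ploidy <= 0 for cell in self.design):
            raise ValueError("design: n_per_ploidy must be positive in every cell")
        if not (self.dispersion > 0):  # rejects 0, negatives and NaN; inf allowed
            raise ValueError("dispersion must be positive (inf = Poisson limit)")
        if self.lib_size_mean <= 0:
            raise ValueError("lib_size_mean must be positive")
        if self.lib_size_cv < 0:
            raise ValueError("lib_size_cv must be nonnegative")
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd must be nonnegative")
        if self.covariate_effect_sd < 0:
            raise ValueError("covariate_effect_sd must be nonnegative")
        if not 0.0 <= self.frac_affected_genes <= 1.0:
            raise ValueError("frac_affected_genes must lie in [0, 1]")
        if self.interaction_sd < 0:
            raise ValueError("interaction_sd must be nonnegative")
        events = []
        for ev in self.aneuploidy_events:
            if not isinstance(ev, AneuploidyEvent):
                ev = AneuploidyEvent(*ev)
            events.append(ev)
        self.aneuploidy_events = events

    @property
    def chromosome_ids(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosome_weights"] = list(map(float, self.chromosome_weights))
        d["dispersion"] = float(self.dispersion) if math.isfinite(self.dispersion) else "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if isinstance(d.get("dispersion"), str):
            d["dispersion"] = float(d["dispersion"])
        if "design" in d and d["design"] is not None:
            d["design"] = [
                cell if isinstance(cell, DesignCell) else DesignCell(**cell)
                for cell in d["design"]
            ]
        if "aneuploidy_events" in d and d["aneuploidy_events"] is not None:
            d["aneuploidy_events"] = [
                ev if isinstance(ev, AneuploidyEvent) else AneuploidyEvent(**ev)
                for ev in d["aneuploidy_events"]
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
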