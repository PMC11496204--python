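"""Per-chromosome expression-dosage screen for aneuploidy in matched pairs.

For each matched diploid/triploid pair and each chromosome the screen
computes

* the OLS slope (with intercept) of triploid log2-CPM on diploid log2-CPM
  over that chromosome's genes — the classic per-chromosome scatter-plot
  summary, reported for fidelity; and
* the median over the chromosome's genes of the per-gene log2-CPM
  difference (triploid minus diploid), the ``median_log_ratio``.

Because CPM renormalizes each library, a whole-genome ploidy difference
cancels and every chromosome's expected log-ratio is the same; only a
chromosome whose copy number departs from the ploidy baseline shifts its
median log-ratio away from the other chromosomes. The screen therefore
centers each pair's ten medians on their own cross-chromosome median
(the within-pair baseline), scales by 1.4826 x MAD, and flags chromosomes
whose robust z exceeds a threshold AND whose deviation exceeds a minimum
effect floor. Note that a uniform dosage shift on one chromosome moves the
*intercept* of the log-log regression, not its slope, so the flags are
based on the ratio statistic; the slope is still the right summary for a
per-chromosome overview table.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ploidyscreen.config import AneuploidyEvent, SimulationConfig, DesignCell
from ploidyscreen.normalize import filter_low_expression, log_cpm
from ploidyscreen.pairing import match_pairs
from ploidyscreen.simulate import simulate_dataset

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 20
DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_EFFECT_FLOOR = math.log2(1.15)

RESULT_COLUMNS = [
    "pair_id",
    "chromosome_id",
    "n_genes",
    "slope",
    "intercept",
    "slope_se",
    "median_log_ratio",
    "robust_z",
    "flagged",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    n_genes: int
    reason: str | None = None  # set when the fit is undefined

    @property
    def defined(self) -> bool:
        return self.reason is None


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS of y on x with intercept; returns slope, intercept, slope SE."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    sxx = float(dx @ dx)
    slope = float(dx @ (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    if n > 2:
        se = math.sqrt(float(resid @ resid) / (n - 2) / sxx)
    else:
        se = 0.0 if np.allclose(resid, 0) else float("nan")
    return slope, intercept, se


def chromosome_regression(
    logcpm: pd.DataFrame,
    genemap: pd.Series,
    pair: tuple[str, str],
    chromosome_id: str,
    min_genes: int = DEFAULT_MIN_GENES,
) -> RegressionResult:
    """OLS fit of triploid on diploid log2-CPM over one chromosome's genes.

    ``pair`` is ``(diploid_id, triploid_id)``. Returns an undefined record
    (NaN statistics plus a reason) when fewer than ``min_genes`` genes map
    to the chromosome or the diploid values are constant.
    """
    diploid_id, triploid_id = pair
    genes = logcpm.index.intersection(genemap.index[genemap == chromosome_id])
    x = logcpm.loc[genes, diploid_id].to_numpy(dtype=float)
    y = logcpm.loc[genes, triploid_id].to_numpy(dtype=float)
    n = len(genes)
    if n < min_genes:
        return RegressionResult(np.nan, np.nan, np.nan, n, reason=f"fewer than {min_genes} genes")
    if np.ptp(x) == 0:
        return RegressionResult(np.nan, np.nan, np.nan, n, reason="diploid values constant")
    slope, intercept, se = _ols(x, y)
    return RegressionResult(slope, intercept, se, n)


def dosage_statistics(
    logcpm: pd.DataFrame,
    genemap: pd.Series,
    pair: tuple[str, str],
    min_genes: int = DEFAULT_MIN_GENES,
) -> pd.Series:
    """Per-chromosome median of (triploid - diploid) log2-CPM for one pair.

    Chromosomes with fewer than ``min_genes`` mapped genes get NaN.
    """
    diploid_id, triploid_id = pair
    shared = logcpm.index.intersection(genemap.index)
    ratio = (
        logcpm.loc[shared, triploid_id] - logcpm.loc[shared, diploid_id]
    )
    chrom = genemap.loc[shared]
    grouped = ratio.groupby(chrom, sort=True)
    medians = grouped.median()
    counts = grouped.size()
    medians[counts < min_genes] = np.nan
    medians.name = "median_log_ratio"
    medians.index.name = "chromosome_id"
    return medians


def call_aneuploidy(
    medians: pd.Series,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    effect_floor_log2: float = DEFAULT_EFFECT_FLOOR,
) -> pd.DataFrame:
    """Flag chromosomes whose median log-ratio is a robust outlier.

    The baseline is the median of the per-chromosome medians; the scale is
    1.4826 x MAD. A chromosome is flagged when |robust_z| >= ``z_threshold``
    and its absolute deviation from baseline is >= ``effect_floor_log2``
    (default log2(1.15), a 15% dosage change). If the MAD collapses to zero
    the z-score is degenerate and flags fall back to the effect floor alone.
    """
    defined = medians.dropna()
    if len(defined) < 5:
        raise ValueError(
            f"need >= 5 chromosomes with defined statistics, got {len(defined)}"
        )
    baseline = float(defined.median())
    deviation = medians - baseline
    mad = float(np.nanmedian(np.abs(defined - baseline)))
    scale = 1.4826 * mad
    if scale == 0.0:
        if (deviation.abs() > 0).any():
            warnings.warn(
                "MAD scale is zero with nonzero deviations; "
                "flagging on the effect floor alone",
                RuntimeWarning,
                stacklevel=2,
            )
        robust_z = deviation.map(
            lambda d: 0.0 if d == 0 else math.copysign(math.inf, d)
        ).astype(float)
        flagged = deviation.abs() >= effect_floor_log2
    else:
        robust_z = deviation / scale
        flagged = (robust_z.abs() >= z_threshold) & (deviation.abs() >= effect_floor_log2)
    flagged &= medians.notna()
    out = pd.DataFrame(
        {"median_log_ratio": medians, "robust_z": robust_z, "flagged": flagged}
    )
    out.attrs["baseline"] = baseline
    out.attrs["scale"] = scale
    return out


def screen_all_pairs(
    logcpm: pd.DataFrame,
    genemap: pd.Series,
    pairs: pd.DataFrame,
    min_genes: int = DEFAULT_MIN_GENES,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    effect_floor_log2: float = DEFAULT_EFFECT_FLOOR,
) -> pd.DataFrame:
    """Run the screen for every pair: one row per pair x chromosome.

    Undefined records (too few genes, constant diploid values) are kept as
    explicit rows with NaN statistics, never dropped.
    """
    unmapped = logcpm.index.difference(genemap.index)
    if len(unmapped):
        logger.info(
            "%d gene(s) absent from the chromosome map; excluded from the screen",
            len(unmapped),
        )
    rows = []
    for rec in pairs.itertuples(index=False):
        pair = (rec.diploid_id, rec.triploid_id)
        medians = dosage_statistics(logcpm, genemap, pair, min_genes=min_genes)
        calls = call_aneuploidy(
            medians, z_threshold=z_threshold, effect_floor_log2=effect_floor_log2
        )
        for chromosome_id in medians.index:
            reg = chromosome_regression(
                logcpm, genemap, pair, chromosome_id, min_genes=min_genes
            )
            rows.append(
                (
                    rec.pair_id,
                    chromosome_id,
                    reg.n_genes,
                    reg.slope,
                    reg.intercept,
                    reg.slope_se,
                    calls.loc[chromosome_id, "median_log_ratio"],
                    calls.loc[chromosome_id, "robust_z"],
                    bool(calls.loc[chromosome_id, "flagged"]),
                )
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def pair_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-pair flag count; a pair is 'euploid' iff no chromosome is flagged."""
    grouped = results.groupby("pair_id", sort=False)["flagged"].sum().rename("n_flagged")
    out = grouped.to_frame()
    out["euploid"] = out["n_flagged"] == 0
    return out.reset_index()


# ---------------------------------------------------------------------------
# calibration by simulation


@dataclass(frozen=True)
class Scenario:
    """One power-analysis cell: a planted copy number (or euploid null).

    ``copies=None`` simulates the euploid null (all triploid chromosomes at
    copy 3). ``affected_fraction`` is the fraction of per-copy expression
    carried by the event chromosome.
    """

    name: str
    copies: int | None = None
    affected_fraction: float = 0.1
    n_genes: int = 5000
    n_chromosomes: int = 10
    dispersion: float = 100.0
    lib_size_mean: float = 1_000_000
    event_chromosome: str = "chr1"


def _scenario_config(scn: Scenario, seed: int) -> SimulationConfig:
    f = scn.affected_fraction
    rest = (1.0 - f) / (scn.n_chromosomes - 1)
    weights = [f] + [rest] * (scn.n_chromosomes - 1)
    chroms = [f"chr{i + 1}" for i in range(scn.n_chromosomes)]
    k = chroms.index(scn.event_chromosome)
    # rotate so the event chromosome carries fraction f
    weights = [weights[(i - k) % scn.n_chromosomes] for i in range(scn.n_chromosomes)]
    events = []
    if scn.copies is not None:
        events = [AneuploidyEvent("cell_a_a_3n_01", scn.event_chromosome, scn.copies)]
    return SimulationConfig(
        n_genes=scn.n_genes,
        n_chromosomes=scn.n_chromosomes,
        chromosome_weights=weights,
        design=[DesignCell(site="cell", cohort="a", dam="a", n_per_ploidy=1)],
        dispersion=scn.dispersion,
        lib_size_mean=scn.lib_size_mean,
        lib_size_cv=0.1,
        covariate_effect_sd=0.0,
        frac_affected_genes=0.0,
        aneuploidy_events=events,
        seed=seed,
    )


def power_analysis(
    scenarios: list[Scenario],
    n_reps: int = 200,
    seed: int = 0,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    effect_floor_log2: float = DEFAULT_EFFECT_FLOOR,
    min_genes: int = DEFAULT_MIN_GENES,
) -> pd.DataFrame:
    """Estimate sensitivity and false-positive rate by simulation.

    For each scenario, ``n_reps`` independent single-pair datasets are
    simulated and screened. Sensitivity is the fraction of planted events
    flagged; the false-positive rate is the fraction of euploid chromosomes
    flagged. Binomial standard errors accompany both.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    ss = np.random.SeedSequence(seed)
    for scn in scenarios:
        child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_reps)]
        hits = 0
        n_events = 0
        false_pos = 0
        n_null_chroms = 0
        for rep_seed in child_seeds:
            config = _scenario_config(scn, rep_seed)
            data = simulate_dataset(config)
            filtered = filter_low_expression(data.counts)
            values = log_cpm(filtered)
            pairs, _ = match_pairs(data.samples)
            pair = (pairs.iloc[0]["diploid_id"], pairs.iloc[0]["triploid_id"])
            medians = dosage_statistics(values, data.genemap, pair, min_genes=min_genes)
            calls = call_aneuploidy(
                medians, z_threshold=z_threshold, effect_floor_log2=effect_floor_log2
            )
            for chromosome_id, flagged in calls["flagged"].items():
                planted = scn.copies is not None and chromosome_id == scn.event_chromosome
                if planted:
                    n_events += 1
                    hits += int(flagged)
                else:
                    n_null_chroms += 1
                    false_pos += int(flagged)
        sensitivity = hits / n_events if n_events else np.nan
        fpr = false_pos / n_null_chroms if n_null_chroms else np.nan
        rows.append(
            {
                "scenario": scn.name,
                "copies": scn.copies,
                "n_reps": n_reps,
                "sensitivity": sensitivity,
                "sensitivity_se": (
                    math.sqrt(sensitivity * (1 - sensitivity) / n_events)
                    if n_events
                    else np.nan
                ),
                "false_positive_rate": fpr,
                "fpr_se": (
                    math.sqrt(fpr * (1 - fpr) / n_null_chroms) if n_null_chroms else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
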