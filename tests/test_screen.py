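"""Aneuploidy screen: OLS fidelity, dosage statistics, robust flagging."""

import math

import numpy as np
import pandas as pd
import pytest

import ploidyscreen as ps
from ploidyscreen.config import DesignCell, SimulationConfig
from ploidyscreen.normalize import filter_low_expression, log_cpm
from ploidyscreen.screen import (
    Scenario,
    call_aneuploidy,
    chromosome_regression,
    dosage_statistics,
    pair_summary,
    power_analysis,
    screen_all_pairs,
)


def brute_force_ols(x, y, span=10.0, tol=1e-8):
    """Independent least-squares oracle: iteratively refined grid search
    minimizing the residual sum of squares. The line is parametrized as
    y = a + b*(x - mean(x)) so the two grid axes decouple and the search
    cannot stall in the slope/intercept valley."""
    xc = x - x.mean()
    b, a = 0.0, float(np.mean(y))
    width = span
    while width > tol:
        bs = np.linspace(b - width, b + width, 41)
        as_ = np.linspace(a - width, a + width, 41)
        sse = (
            (y[None, None, :] - as_[None, :, None] - bs[:, None, None] * xc) ** 2
        ).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        b, a = bs[i], as_[j]
        width /= 4.0
    return b, a - b * x.mean()


def frame(x, y, chrom="chr1"):
    genes = [f"g{i}" for i in range(len(x))]
    logcpm = pd.DataFrame({"dip": x, "tri": y}, index=genes)
    genemap = pd.Series(chrom, index=pd.Index(genes, name="gene_id"))
    return logcpm, genemap


class TestRegression:
    def test_identity_line(self):
        x = np.linspace(0, 10, 30)
        logcpm, genemap = frame(x, x)
        res = chromosome_regression(logcpm, genemap, ("dip", "tri"), "chr1")
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_constant_log_ratio_shifts_intercept_not_slope(self):
        """A uniform dosage change moves the intercept; the slope stays 1.
        This is why the screen flags on the ratio statistic, not the slope."""
        x = np.linspace(2, 12, 40)
        delta = math.log2(2 / 3)
        logcpm, genemap = frame(x, x + delta)
        res = chromosome_regression(logcpm, genemap, ("dip", "tri"), "chr1")
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(delta)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(8, 2, size=50)
            y = 0.5 + 0.9 * x + rng.normal(0, 0.5, size=50)
            logcpm, genemap = frame(x, y)
            res = chromosome_regression(logcpm, genemap, ("dip", "tri"), "chr1")
            slope, intercept = brute_force_ols(x, y)
            assert res.slope == pytest.approx(slope, abs=1e-5)
            assert res.intercept == pytest.approx(intercept, abs=1e-5)

    def test_slope_se_matches_statsmodels_convention(self, rng):
        import scipy.stats

        x = rng.normal(5, 1, 60)
        y = 1 + 2 * x + rng.normal(0, 0.3, 60)
        logcpm, genemap = frame(x, y)
        res = chromosome_regression(logcpm, genemap, ("dip", "tri"), "chr1")
        ref = scipy.stats.linregress(x, y)
        assert res.slope_se == pytest.approx(ref.stderr, rel=1e-10)

    def test_too_few_genes_undefined(self):
        logcpm, genemap = frame(np.arange(5.0), np.arange(5.0))
        res = chromosome_regression(logcpm, genemap, ("dip", "tri"), "chr1")
        assert not res.defined and "fewer than" in res.reason
        assert math.isnan(res.slope)

    def test_constant_diploid_undefined(self):
        logcpm, genemap = frame(np.full(30, 4.0), np.arange(30.0))
        res = chromosome_regression(logcpm, genemap, ("dip", "tri"), "chr1")
        assert not res.defined and "constant" in res.reason


class TestDosageStatistics:
    def test_self_pair_is_zero(self, small_dataset):
        values = log_cpm(filter_low_expression(small_dataset.counts))
        sid = values.columns[0]
        doubled = values.copy()
        doubled["twin"] = values[sid]
        genemap = small_dataset.genemap
        medians = dosage_statistics(doubled, genemap, (sid, "twin"), min_genes=5)
        assert (medians == 0).all()

    def test_invariant_to_library_rescaling(self, small_dataset):
        counts = filter_low_expression(small_dataset.counts)
        sid_d, sid_t = counts.columns[:2]
        rescaled = counts.copy()
        rescaled[sid_t] = counts[sid_t] * 7  # CPM cancels the scale exactly
        a = dosage_statistics(log_cpm(counts), small_dataset.genemap, (sid_d, sid_t))
        b = dosage_statistics(log_cpm(rescaled), small_dataset.genemap, (sid_d, sid_t))
        pd.testing.assert_series_equal(a, b)

    def test_chromosome_below_min_genes_is_nan(self):
        x = np.arange(30.0)
        logcpm, genemap = frame(x, x)
        genemap.iloc[:3] = "tiny_chr"
        medians = dosage_statistics(logcpm, genemap, ("dip", "tri"), min_genes=20)
        assert math.isnan(medians["tiny_chr"])
        assert not math.isnan(medians["chr1"])


class TestCalls:
    def ten_medians(self, values):
        return pd.Series(values, index=[f"chr{i+1}" for i in range(len(values))])

    def test_all_equal_no_flags(self):
        calls = call_aneuploidy(self.ten_medians([0.3] * 10))
        assert (calls["robust_z"] == 0).all()
        assert not calls["flagged"].any()

    def test_location_invariance(self):
        base = self.ten_medians([0.0, 0.01, -0.02, 0.03, 0.0, -0.01, 0.02, 0.0, -0.6, 0.01])
        shifted = base + 1.7  # e.g. triploid logCPM offset by a constant
        a, b = call_aneuploidy(base), call_aneuploidy(shifted)
        pd.testing.assert_series_equal(a["robust_z"], b["robust_z"])
        pd.testing.assert_series_equal(a["flagged"], b["flagged"])

    def test_outlier_flagged_with_sign(self):
        calls = call_aneuploidy(
            self.ten_medians([0.0, 0.01, -0.02, 0.03, 0.0, -0.01, 0.02, 0.0, 0.415, 0.01])
        )
        assert calls.loc["chr9", "flagged"]
        assert calls.loc["chr9", "robust_z"] > 3  # gain: positive z
        assert calls["flagged"].sum() == 1

    def test_symmetric_under_chromosome_swap(self):
        values = [0.0, 0.01, -0.02, 0.03, 0.0, -0.01, 0.02, 0.0, -0.585, 0.01]
        a = call_aneuploidy(self.ten_medians(values))
        swapped = values.copy()
        swapped[1], swapped[8] = swapped[8], swapped[1]
        b = call_aneuploidy(self.ten_medians(swapped))
        assert a.loc["chr9", "flagged"] and b.loc["chr2", "flagged"]
        assert a["flagged"].sum() == b["flagged"].sum() == 1

    def test_small_effect_below_floor_not_flagged(self):
        # a robust-z outlier whose deviation is under log2(1.15) stays unflagged
        calls = call_aneuploidy(
            self.ten_medians([0.0, 0.001, -0.001, 0.0, 0.001, -0.001, 0.0, 0.001, 0.1, 0.0])
        )
        assert abs(calls.loc["chr9", "robust_z"]) > 3
        assert not calls.loc["chr9", "flagged"]

    def test_zero_scale_falls_back_to_floor(self):
        with pytest.warns(RuntimeWarning, match="MAD"):
            calls = call_aneuploidy(self.ten_medians([0.2] * 9 + [-0.5]))
        assert calls.loc["chr10", "flagged"]
        assert not calls["flagged"].iloc[:9].any()

    def test_needs_five_defined_chromosomes(self):
        medians = self.ten_medians([0.1, 0.2, 0.3, 0.4] + [np.nan] * 6)
        with pytest.raises(ValueError, match=">= 5"):
            call_aneuploidy(medians)


class TestScreenAllPairs:
    def test_cardinality_and_self_pairs(self, small_dataset):
        values = log_cpm(filter_low_expression(small_dataset.counts))
        ids = list(values.columns[:3])
        pairs = pd.DataFrame(
            {
                "pair_id": [f"self_{s}" for s in ids],
                "diploid_id": ids,
                "triploid_id": ids,
                "site": "siteA",
                "cohort": "cohX",
                "dam": "dam1",
            }
        )
        results = screen_all_pairs(values, small_dataset.genemap, pairs)
        assert len(results) == 3 * 10
        assert np.allclose(results["slope"], 1.0)
        assert not results["flagged"].any()
        summary = pair_summary(results)
        assert summary["euploid"].all()

    def test_planted_monosomy_flagged_on_event_chromosome_only(self):
        config = SimulationConfig(
            n_genes=5000,
            design=[DesignCell("s", "c", "d", 1)],
            dispersion=float("inf"),
            lib_size_mean=1_000_000,
            lib_size_cv=0.0,
            covariate_effect_sd=0.0,
            frac_affected_genes=0.0,
            aneuploidy_events=[("s_c_d_3n_01", "chr4", 2)],
            seed=21,
        )
        data = ps.simulate_dataset(config)
        values = log_cpm(filter_low_expression(data.counts))
        pairs, _ = ps.match_pairs(data.samples)
        results = screen_all_pairs(values, data.genemap, pairs)
        flagged = results.loc[results["flagged"], "chromosome_id"].tolist()
        assert flagged == ["chr4"]
        z = results.set_index("chromosome_id").loc["chr4", "robust_z"]
        assert z < -3  # loss: negative sign


class TestPowerAnalysis:
    def test_monotone_sensitivity_and_sign(self):
        scenarios = [
            Scenario("null", copies=None),
            Scenario("loss", copies=2),
            Scenario("gain", copies=4),
        ]
        tab = power_analysis(scenarios, n_reps=8, seed=3).set_index("scenario")
        assert math.isnan(tab.loc["null", "sensitivity"])
        assert tab.loc["null", "false_positive_rate"] <= 0.05
        assert tab.loc["loss", "sensitivity"] >= 0.9
        assert tab.loc["gain", "sensitivity"] >= 0.9

    def test_rejects_zero_reps(self):
        with pytest.raises(ValueError, match="n_reps"):
            power_analysis([Scenario("null")], n_reps=0, seed=0)
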