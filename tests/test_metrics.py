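"""Accreditation metrics: analytical range, CV, LLOD, trueness, recommendations."""

import math

import numpy as np
import pytest

from chipvalid import (
    ConfusionCounts,
    SimConfig,
    VariantSpec,
    analytical_range,
    binomial_cv,
    llod,
    precision_cv,
    presumed_negative_concordance,
    recommend,
    reference_grid,
    simulate_pileup,
    trueness,
)
from chipvalid.consensus import call_variants

from conftest import make_call


def ols_oracle(x, y):
    """Textbook OLS + Pearson formulas, independent of scipy.linregress."""
    x, y = np.asarray(x), np.asarray(y)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    syy = ((y - ym) ** 2).sum()
    slope = sxy / sxx
    return slope, ym - slope * xm, sxy / math.sqrt(sxx * syy)


class TestAnalyticalRange:
    def test_identity_pairs(self):
        pairs = [(0.01, 0.01), (0.05, 0.05), (0.2, 0.2)]
        fit = analytical_range(pairs)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.fold_bias == pytest.approx(1.0)

    def test_constant_fold_bias(self):
        pairs = [(x, 0.89 * x) for x in (0.005, 0.02, 0.1, 0.4)]
        fit = analytical_range(pairs)
        assert fit.fold_bias == pytest.approx(0.89)
        assert fit.r == pytest.approx(1.0)
        assert fit.limits[0] == pytest.approx(0.89)

    def test_reference_grid_fit_matches_independent_recomputation(self):
        # eligible dilution-grid pairs: expected >= 0.004, detected, the two
        # bias-affected loci excluded; spreadsheet-style recomputation oracle
        grid = reference_grid().dropna(subset=["observed_vaf"])
        grid = grid[grid["expected_vaf"] >= 0.004]
        pairs = list(zip(grid["expected_vaf"], grid["observed_vaf"]))
        loci = list(grid["locus_id"])
        exclusions = ("ASXL1:c.1934dup", "FLT3:c.2503G>T")
        fit = analytical_range(pairs, exclusions=exclusions, loci=loci)

        keep = ~grid["locus_id"].isin(exclusions)
        x = grid.loc[keep, "expected_vaf"].to_numpy()
        y = grid.loc[keep, "observed_vaf"].to_numpy()
        slope, intercept, r = ols_oracle(x, y)
        ratios = y / x
        assert fit.n == keep.sum()
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r == pytest.approx(r)
        assert fit.r2 == pytest.approx(r**2)
        assert fit.fold_bias == pytest.approx(ratios.mean())
        assert fit.limits[1] - fit.limits[0] == pytest.approx(
            2 * 1.96 * ratios.std(ddof=1)
        )
        # the grid shows high linearity and a modest sub-unity mean bias
        assert fit.r > 0.99
        assert 0.7 < fit.fold_bias < 1.1

    def test_nd_entries_dropped_not_imputed(self):
        pairs = [(0.01, 0.01), (0.05, 0.05), (0.2, 0.2), (0.001, float("nan"))]
        assert analytical_range(pairs).n == 3

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            analytical_range([(0.1, 0.1), (0.2, 0.2)])


class TestPrecision:
    def test_constant_replicates_zero_cv(self):
        table = precision_cv({"v": [0.05, 0.05, 0.05]})
        assert table.iloc[0]["cv"] == pytest.approx(0.0, abs=1e-12)

    def test_sample_sd_over_mean(self):
        table = precision_cv({"v": [0.04, 0.05, 0.06]})
        assert table.iloc[0]["cv"] == pytest.approx(0.01 / 0.05)

    def test_zero_mean_flagged_undefined(self):
        table = precision_cv({"v": [0.0, 0.0]})
        assert table.iloc[0]["cv_undefined"]
        assert math.isnan(table.iloc[0]["cv"])

    def test_single_measurement_rejected(self):
        with pytest.raises(ValueError):
            precision_cv({"v": [0.05]})

    def test_sampling_noise_cv_matches_binomial_closed_form(self):
        # pure molecule-sampling noise: CV(vaf-hat) ~ sqrt((1-f)/(f m))
        f, m, reps = 0.05, 2000, 300
        spec = VariantSpec(locus_id="G:v", true_vaf=f)
        vafs = []
        for r in range(reps):
            cfg = SimConfig(
                pre_consensus_error=0.0,
                post_consensus_error=0.0,
                reads_per_family_mean=1.0,
                seed=5000 + r,
            )
            pile = simulate_pileup([spec], cfg, n_families=m)
            calls = call_variants(pile)
            vafs.append(calls[0].vaf if calls else 0.0)
        cv = precision_cv({"v": vafs}).iloc[0]["cv"]
        expected = binomial_cv(f, m)
        assert abs(cv - expected) < 3 * expected / math.sqrt(2 * (reps - 1))

    def test_cv_decreases_with_expected_vaf(self):
        assert binomial_cv(0.004, 3000) > binomial_cv(0.02, 3000) > binomial_cv(0.1, 3000)


class TestLlod:
    def test_validated_grid(self):
        result = llod({0.004: 1.00, 0.0031: 0.56})
        assert result.llod_vaf == 0.004

    def test_all_rates_pass_gives_smallest_vaf(self):
        result = llod({0.05: 1.0, 0.01: 1.0, 0.004: 1.0})
        assert result.llod_vaf == 0.004

    def test_contiguity_required(self):
        result = llod({0.01: 1.0, 0.005: 0.90, 0.004: 1.0})
        assert result.llod_vaf == 0.01

    def test_nothing_meets_criterion(self):
        result = llod({0.01: 0.5, 0.004: 0.2})
        assert result.llod_vaf is None
        assert result.diagnostic is not None

    def test_monotone_in_criterion(self):
        rates = {0.01: 1.0, 0.005: 0.96, 0.004: 0.9}
        llods = [llod(rates, criterion=c).llod_vaf for c in (0.9, 0.95, 0.99)]
        assert llods == [0.004, 0.005, 0.01]


class TestTrueness:
    def test_perfect_validation(self):
        table = trueness(ConfusionCounts(tp=59, fp=0, fn=0, tn=29))
        assert (table["percent"] == 100.0).all()
        assert table["passed"].all()

    def test_half_sensitivity(self):
        table = trueness(ConfusionCounts(tp=1, fp=0, fn=1, tn=0))
        sens = table.set_index("metric").loc["sensitivity", "percent"]
        assert sens == 50.0

    def test_arithmetic_cross_check(self):
        table = trueness(ConfusionCounts(tp=97, fp=1, fn=3, tn=99)).set_index("metric")
        assert table.loc["sensitivity", "percent"] == pytest.approx(97.0)
        assert table.loc["specificity", "percent"] == pytest.approx(99.0)
        assert table.loc["accuracy", "percent"] == pytest.approx(98.0)
        assert table.loc["accuracy", "passed"]

    def test_scale_invariance(self):
        a = trueness(ConfusionCounts(12, 3, 4, 20))["percent"]
        b = trueness(ConfusionCounts(36, 9, 12, 60))["percent"]
        assert np.allclose(a, b)

    def test_zero_denominator_undefined_without_flag(self):
        table = trueness(ConfusionCounts(tp=0, fp=0, fn=0, tn=5)).set_index("metric")
        assert math.isnan(table.loc["sensitivity", "percent"])
        assert table.loc["sensitivity", "passed"] is None


class TestPresumedNegative:
    def _calls(self, n, locus_prefix, vaf=0.01):
        return [make_call(locus_id=f"{locus_prefix}:{i}", vaf=vaf) for i in range(n)]

    def test_printed_category_partition(self):
        # 193 detected: 108 off-panel, 85 on-panel below the reference LLOD
        off = self._calls(108, "OFF")
        below = self._calls(85, "ON", vaf=0.01)
        panel = [c.locus_id for c in below]
        llod_map = {locus: 0.05 for locus in panel}
        acc = presumed_negative_concordance(off + below, panel, llod_map)
        assert (acc.total, acc.off_panel, acc.below_reference_llod) == (193, 108, 85)
        assert acc.remaining == 0
        assert acc.concordance_pct == 100.0

    def test_empty_detected_set_vacuously_concordant(self):
        acc = presumed_negative_concordance([], ["A"], {"A": 0.05})
        assert acc.remaining == 0
        assert acc.concordance_pct == 100.0

    def test_on_panel_above_llod_breaks_concordance(self):
        call = make_call(locus_id="ON:0", vaf=0.2)
        acc = presumed_negative_concordance([call], ["ON:0"], {"ON:0": 0.05})
        assert acc.remaining == 1
        assert acc.concordance_pct < 100.0

    def test_unknown_coverage_unclassifiable(self):
        call = make_call(locus_id="ON:0", vaf=0.2)
        acc = presumed_negative_concordance([call], ["ON:0"], {})
        assert acc.unclassifiable == 1
        assert acc.concordance_pct is None


class TestRecommend:
    @pytest.mark.parametrize(
        "band,depth,ng,uao,cost",
        [
            (">=0.02", "1,000-2,000x", ">=50", 1, 0.8),
            ("0.01-0.02", "2,000-3,000x", "200-400", 3, 1.0),
            ("0.004-0.01", "3,000-4,000x", "400", 3, 1.1),
        ],
    )
    def test_band_lookup(self, band, depth, ng, uao, cost):
        rec = recommend(band)
        assert rec["depth"] == depth
        assert rec["input_ng"] == ng
        assert rec["uao_min"] == uao
        assert rec["relative_cost"] == cost

    def test_below_validated_llod_rejected(self):
        with pytest.raises(ValueError):
            recommend("0.001-0.004")
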