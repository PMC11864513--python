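"""Simulator: dilution arithmetic, molecule budgets, pileup generation, cohort."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from chipvalid import (
    ArtifactSpec,
    CohortSpec,
    DilutionSeries,
    SimConfig,
    VariantSpec,
    expected_vaf,
    molecules_from_input,
    simulate_cohort,
    simulate_pileup,
    simulate_reference_panel,
)
from chipvalid.consensus import call_variants


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "stock,conc,expected",
        [
            (0.0500, 0.25, 0.0125),
            (0.0500, 1.0, 0.0500),
            (0.0500, 0.015625, 0.0008),
            (0.40, 0.0625, 0.0250),
            (0.40, 0.015625, 0.0063),
            (0.35, 0.03125, 0.0109),
            (0.10, 0.0625, 0.0063),
        ],
    )
    def test_dilution_worksheet_values(self, stock, conc, expected):
        assert expected_vaf(stock, conc) == expected

    @pytest.mark.parametrize("stock,conc", [(-0.1, 0.5), (1.1, 0.5), (0.5, 0.0), (0.5, 1.5)])
    def test_domain_errors(self, stock, conc):
        with pytest.raises(ValueError):
            expected_vaf(stock, conc)

    @given(
        stock=st.floats(0.001, 1.0),
        c1=st.floats(0.01, 1.0),
        c2=st.floats(0.01, 1.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_concentration(self, stock, c1, c2):
        lo, hi = sorted((c1, c2))
        assert expected_vaf(stock, lo, rounding=10) <= expected_vaf(stock, hi, rounding=10)

    def test_exactly_multiplicative_at_full_precision(self):
        assert expected_vaf(0.123, 0.5, rounding=10) == pytest.approx(0.0615, abs=1e-12)


class TestMoleculeBudget:
    def test_100ng_is_30300_haploid_copies(self):
        # 3.3 pg/haploid genome => 303 copies/ng; x 0.001 VAF ~ 30 alleles ~ 15 diploid cells
        assert molecules_from_input(100, 1.0) == 30300

    def test_zero_input(self):
        assert molecules_from_input(0, 1.0) == 0

    def test_linear_in_both_arguments(self):
        assert molecules_from_input(400, 0.5) == 60600

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            molecules_from_input(-1, 1.0)


class TestSimulatePileup:
    def test_no_truth_no_error_gives_zero_alt(self, error_free_config):
        pile = simulate_pileup([], error_free_config, n_families=500)
        assert all(f.allele == "ref" for f in pile.families)

    def test_depth_conservation_and_uao_bound(self):
        spec = VariantSpec(locus_id="G:v", true_vaf=0.1)
        pile = simulate_pileup([spec], SimConfig(seed=3), n_families=800)
        assert pile.depth == sum(f.read_count for f in pile.families)
        calls = call_variants(pile)
        assert all(c.uao <= c.depth for c in calls)

    def test_same_seed_identical_pileup(self):
        spec = VariantSpec(locus_id="G:v", true_vaf=0.05)
        cfg = SimConfig(seed=11)
        a = simulate_pileup([spec], cfg, n_families=300)
        b = simulate_pileup([spec], cfg, n_families=300)
        assert a == b

    def test_zero_families_gives_empty_pileup(self, error_free_config):
        pile = simulate_pileup([], error_free_config, n_families=0, locus_id="L")
        assert pile.families == ()

    def test_alt_fraction_binomially_consistent(self, error_free_config):
        # with all error rates zero the alt-family fraction converges to
        # true_vaf * locus_bias (3 Monte-Carlo SE at 10,000 families)
        f, bias, m = 0.10, 0.8, 10_000
        spec = VariantSpec(locus_id="G:v", true_vaf=f, locus_bias=bias)
        pile = simulate_pileup([spec], error_free_config, n_families=m)
        n_alt = sum(1 for fam in pile.families if fam.allele == "alt")
        p = f * bias
        assert abs(n_alt / m - p) < 3 * math.sqrt(p * (1 - p) / m)

    def test_uao_threshold_detection_matches_binomial_closed_form(self, error_free_config):
        # fraction of pileups with UAO >= 3 at f=0.02, 500 families
        f, m, u, reps = 0.02, 500, 3, 1500
        hits = 0
        for r in range(reps):
            cfg = SimConfig(
                pre_consensus_error=0.0,
                post_consensus_error=0.0,
                reads_per_family_mean=1.0,
                seed=1000 + r,
            )
            pile = simulate_pileup(
                [VariantSpec(locus_id="G:v", true_vaf=f)], cfg, n_families=m
            )
            hits += sum(1 for fam in pile.families if fam.allele == "alt") >= u
        p = float(scipy.stats.binom.sf(u - 1, m, f))  # 0.9974
        assert abs(hits / reps - p) < 3 * math.sqrt(p * (1 - p) / reps)

    def test_strand_balance_of_genuine_families(self):
        # duplex-balanced capture: strand split of true-allele families is near 50:50
        spec = VariantSpec(locus_id="G:v", true_vaf=0.2)
        pile = simulate_pileup([spec], SimConfig(seed=5), n_families=1000)
        alt = [f for f in pile.families if f.allele == "alt"]
        n_plus = sum(1 for f in alt if f.strand == "+")
        assert abs(n_plus - len(alt) / 2) <= 1


class TestReferencePanel:
    def test_single_replicate_identity_concentration(self, error_free_config):
        stock = (VariantSpec(locus_id="G:v", true_vaf=0.05),)
        series = DilutionSeries(stock=stock, concentrations=(1.0,))
        panel = simulate_reference_panel(series, error_free_config, n_replicates=1)
        pile = panel[0].panels[1.0][0]
        assert pile.truth[0].true_vaf == 0.05

    def test_replicates_unique_and_deterministic(self, error_free_config):
        stock = (VariantSpec(locus_id="G:v", true_vaf=0.05),)
        series = DilutionSeries(stock=stock, concentrations=(1.0, 0.25))
        a = simulate_reference_panel(series, error_free_config, n_replicates=3)
        b = simulate_reference_panel(series, error_free_config, n_replicates=3)
        assert [r.replicate_id for r in a] == [0, 1, 2]
        assert a == b
        # replicates differ from each other (independent draws)
        assert a[0].panels[0.25][0] != a[1].panels[0.25][0]

    def test_concentration_scales_truth(self, error_free_config):
        stock = (VariantSpec(locus_id="G:v", true_vaf=0.4),)
        series = DilutionSeries(stock=stock, concentrations=(1.0, 0.0625))
        panel = simulate_reference_panel(series, error_free_config, n_replicates=1)
        assert panel[0].panels[0.0625][0].truth[0].true_vaf == pytest.approx(0.025)

    def test_decreasing_concentrations_enforced(self):
        with pytest.raises(ValueError):
            DilutionSeries(stock=(), concentrations=(0.25, 1.0))


def _count_chip_clones(subject):
    return sum(1 for p in subject.pileups if "chip" in p.locus_id)


class TestCohort:
    def test_empty_cohort(self, error_free_config):
        assert simulate_cohort(CohortSpec(n_subjects=0), error_free_config) == []

    def test_mean_chip_clone_count_matches_configured_mean(self):
        # slope 0: every subject has Poisson(1.4) clones at >= 0.02 VAF
        spec = CohortSpec(
            n_subjects=3000,
            chip_rate_intercept=1.4,
            chip_rate_slope=0.0,
            subclonal_count_mean=0.0,
        )
        cfg = SimConfig(target_read_depth=40.0, seed=2)
        cohort = simulate_cohort(spec, cfg)
        counts = [_count_chip_clones(s) for s in cohort]
        se = math.sqrt(1.4 / len(counts))
        assert abs(np.mean(counts) - 1.4) < 3 * se

    def test_age_slope_recovered_by_regression(self):
        spec = CohortSpec(
            n_subjects=2500,
            chip_rate_intercept=-0.9,
            chip_rate_slope=0.04,
            subclonal_count_mean=0.0,
        )
        cfg = SimConfig(target_read_depth=40.0, seed=3)
        cohort = simulate_cohort(spec, cfg)
        ages = [s.age for s in cohort]
        counts = [_count_chip_clones(s) for s in cohort]
        fit = scipy.stats.linregress(ages, counts)
        assert abs(fit.slope - 0.04) < 2 * fit.stderr

    def test_artifact_locus_prevalence(self):
        art = ArtifactSpec(locus_id="ART:1", prevalence=0.5, vaf=0.01)
        spec = CohortSpec(
            n_subjects=400,
            chip_rate_intercept=0.0,
            chip_rate_slope=0.0,
            subclonal_count_mean=0.0,
            artifact_loci=(art,),
        )
        cfg = SimConfig(target_read_depth=400.0, seed=4)
        cohort = simulate_cohort(spec, cfg)
        carriers = sum(
            1 for s in cohort if any(p.locus_id == "ART:1" for p in s.pileups)
        )
        frac = carriers / len(cohort)
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / len(cohort))
        # well above the 10% cohort-prevalence exclusion threshold
        assert frac > 0.10
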