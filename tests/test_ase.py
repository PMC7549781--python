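"""Exact ASE tests, null calibration, cis statistic, group comparisons."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ddase import (
    SaturationError,
    SimConfig,
    ValidationError,
    amh_igf3_ratio,
    binomial_ase_test,
    calibrate_null,
    cis_contribution,
    exact_binomial_pvalue,
    fit_trend,
    fractional_abundance,
    rate_ratio_test,
    simulate_dna_control,
    simulate_droplet_run,
    simulate_het_ase_run,
    tally_significance,
    test_sample_ase,
    welch_test,
)
from ddase.ase import DIRECTION_E, DIRECTION_L, DIRECTION_NS
from ddase.quant import DropletRun


def enumeration_pvalue(k, n, p0):
    """Independent minlike oracle: direct enumeration of the binomial pmf."""
    pmf = [math.comb(n, i) * p0 ** i * (1 - p0) ** (n - i) for i in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] * (1 + 1e-7)))


class TestExactKernel:
    @given(st.integers(0, 30), st.integers(0, 30),
           st.sampled_from([0.3, 0.5, 0.504, 0.7]))
    def test_matches_enumeration_oracle(self, k1, k2, p0):
        n = k1 + k2
        if n == 0:
            return
        assert exact_binomial_pvalue(k1, n, p0) == \
            pytest.approx(enumeration_pvalue(k1, n, p0), abs=1e-12)

    @given(st.integers(0, 40), st.integers(1, 40))
    def test_agrees_with_scipy_binomtest(self, k, extra):
        n = k + extra
        assert exact_binomial_pvalue(k, n, 0.5) == \
            pytest.approx(stats.binomtest(k, n, 0.5).pvalue, abs=1e-12)

    @given(st.integers(0, 50), st.integers(0, 50))
    def test_symmetry_at_half(self, k1, k2):
        n = k1 + k2
        if n == 0:
            return
        assert exact_binomial_pvalue(k1, n, 0.5) == \
            pytest.approx(exact_binomial_pvalue(n - k1, n, 0.5), abs=1e-12)

    def test_exact_fraction_oracle_at_half(self):
        """At p0 = 1/2 the minlike p-value is a dyadic rational; check exactly."""
        for (k, n, expect) in [(8, 9, Fraction(20, 512)),
                               (5, 10, Fraction(1, 1))]:
            assert exact_binomial_pvalue(k, n, 0.5) == pytest.approx(float(expect))


class TestRateRatio:
    def test_symmetric_null(self):
        res = rate_ratio_test(7, 7, 100.0, 100.0, 1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.rate_ratio == pytest.approx(1.0)

    def test_equal_exposures_reduce_to_binomial(self):
        for k1, k2 in [(8, 1), (0, 5), (13, 8), (42, 25)]:
            assert rate_ratio_test(k1, k2, 50.0, 50.0).p_value == \
                pytest.approx(binomial_ase_test(k1, k2), abs=1e-14)

    def test_unequal_exposures(self):
        # doubling exposure 1 halves its rate: p0 shifts to 1/3
        res = rate_ratio_test(5, 5, 200.0, 100.0, 1.0)
        assert res.p_value == pytest.approx(enumeration_pvalue(5, 10, 1 / 3),
                                            abs=1e-12)
        assert res.rate_ratio == pytest.approx(0.5)

    def test_double_zero_flagged(self):
        res = rate_ratio_test(0, 0, 10.0, 10.0)
        assert res.undefined and res.p_value == 1.0

    def test_ci_contains_truth_direction(self):
        res = rate_ratio_test(100, 50, 1000.0, 1000.0)
        assert res.ci95[0] < 2.0 < res.ci95[1]


class TestFractionalAbundance:
    def test_worked_and_edge_values(self):
        assert fractional_abundance(1.0, 1.0) == 0.5
        assert fractional_abundance(60.3, 53.5) == pytest.approx(0.5299, abs=1e-4)
        assert fractional_abundance(1.0, 0.0) == 1.0
        assert math.isnan(fractional_abundance(0.0, 0.0))


class TestCisContribution:
    def test_no_allelic_difference(self):
        assert cis_contribution(50.0, 50.0, 110.0, 90.0).cis_percent == 0.0

    def test_volume_constant_cancels(self):
        a = cis_contribution(60.3, 53.5, 106.35, 91.06).cis_percent
        c = 3.7  # any rescaling of the copies/ng conversion
        b = cis_contribution(60.3 * c, 53.5 * c, 106.35 * c, 91.06 * c).cis_percent
        assert a == pytest.approx(b)

    def test_equal_homozygotes_rejected(self):
        with pytest.raises(ValidationError):
            cis_contribution(60.0, 55.0, 100.0, 100.0)

    def test_anti_directional_cis_is_negative(self):
        assert cis_contribution(45.0, 55.0, 110.0, 90.0).cis_percent < 0


class TestNullCalibration:
    def test_probe_skew_recovered(self, rng):
        cfg = SimConfig(seed=0, n_droplets=20_000, n_replicates=40)
        exon2 = simulate_dna_control(cfg, 0.504 / 0.496, assay="vgll3_exon2",
                                     rng=rng)
        exon3 = simulate_dna_control(cfg, 0.494 / 0.506, assay="vgll3_exon3",
                                     rng=rng)
        nulls = calibrate_null(exon2 + exon3, no_dna_control=["vgll3_5utr"])
        assert nulls["vgll3_exon2"] == pytest.approx(0.504, abs=0.005)
        assert nulls["vgll3_exon3"] == pytest.approx(0.494, abs=0.005)
        assert nulls["vgll3_5utr"] == 0.5  # declared, not measured

    def test_no_controls_is_an_error(self):
        with pytest.raises(ValidationError):
            calibrate_null([])

    def test_calibration_closure(self, rng):
        """ASE test on the control wells themselves is null-behaved."""
        cfg = SimConfig(seed=0, n_droplets=15_000, n_replicates=40)
        controls = simulate_dna_control(cfg, 0.504 / 0.496, rng=rng)
        null = calibrate_null(controls)["vgll3_exon2"]
        ns = sum(test_sample_ase(r, null).direction == DIRECTION_NS
                 for r in controls)
        assert ns / len(controls) >= 0.85


class TestSampleAse:
    def test_balanced_counts_are_ns(self):
        run = DropletRun("w", "s", 15_000, {1: 1500, 2: 1500},
                         {1: "a_L", 2: "a_E"}, 50.0)
        res = test_sample_ase(run, 0.5)
        assert res.direction == DIRECTION_NS
        assert res.fa_l == pytest.approx(0.5)

    def test_power_at_sixty_percent(self, rng):
        cfg = SimConfig(seed=0, n_droplets=15_000)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            run = simulate_het_ase_run(cfg, 100.0, 0.60, rng=rng)
            res = test_sample_ase(run, 0.5)
            hits += res.direction == DIRECTION_L and res.p_value < 0.05
        assert hits / n_sim > 0.95


class TestTally:
    def test_worked_percentages(self):
        r31 = [DIRECTION_L] * 31 + [DIRECTION_E] * 1 + [DIRECTION_NS] * 15
        t = tally_significance(r31)
        assert (t.n_l_higher, t.n_total, t.pct_l_higher) == (31, 47, 66)
        t = tally_significance([DIRECTION_L] * 21 + [DIRECTION_NS] * 14)
        assert (t.pct_l_higher, t.n_total) == (60, 35)

    def test_all_ns_and_order_invariance(self):
        t = tally_significance([DIRECTION_NS] * 5)
        assert (t.n_l_higher, t.n_e_higher, t.n_ns) == (0, 0, 5)
        mixed = [DIRECTION_L, DIRECTION_NS, DIRECTION_E, DIRECTION_L]
        assert tally_significance(mixed) == tally_significance(mixed[::-1])


class TestAmhIgf3:
    def make(self, k_amh, k_igf3, n=15_000):
        return DropletRun("w", "s", n, {1: k_amh, 2: k_igf3},
                          {1: "amh", 2: "igf3"}, 2.0)

    def test_equal_counts(self):
        res = amh_igf3_ratio(self.make(800, 800))
        assert res.rate_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_amh_boundary(self):
        res = amh_igf3_ratio(self.make(0, 500))
        assert res.rate_ratio == 0.0
        assert 0.0 < res.ci95[1] < math.inf

    def test_saturated_refused(self):
        with pytest.raises(SaturationError):
            amh_igf3_ratio(self.make(14_800, 500))

    def test_ci_coverage(self, rng):
        cfg = SimConfig(seed=0, n_droplets=14_000, input_ng=2.0)
        lam_a = 1000.0 * cfg.lambda_per_copy
        lam_i = 400.0 * cfg.lambda_per_copy
        truth = (1 - math.exp(-lam_a)) / (1 - math.exp(-lam_i))
        covered = 0
        n_sim = 300
        for _ in range(n_sim):
            run = simulate_droplet_run(
                cfg, [("amh", 1000.0, 1), ("igf3", 400.0, 2)], rng=rng)
            res = amh_igf3_ratio(run)
            covered += res.ci95[0] <= truth <= res.ci95[1]
        assert 0.92 <= covered / n_sim <= 0.99


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.difference == 0.0 and res.p_value == 1.0

    def test_matches_scipy_reference(self, rng):
        for _ in range(20):
            a = rng.normal(10, 3, size=rng.integers(5, 30))
            b = rng.normal(12, 5, size=rng.integers(5, 30))
            mine = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert mine.df == pytest.approx(ref.df, abs=1e-10)
            lo, hi = ref.confidence_interval(0.95)
            assert mine.ci95 == pytest.approx((lo, hi), abs=1e-10)

    def test_group_scale_difference(self, rng):
        a = rng.normal(107, 20, size=65)
        b = rng.normal(37, 15, size=14)
        res = welch_test(a, b)
        assert res.difference == pytest.approx(70, abs=15)
        assert res.p_value < 1e-4


class TestTrendFit:
    def make_frame(self, rng, slope=-0.3, geno_effect=15.0, n=120):
        import pandas as pd
        days = rng.choice([180, 210, 240, 270, 300], size=n)
        geno = rng.choice(["EE", "LL"], size=n)
        y = 100 + slope * (days - 240) + geno_effect * (geno == "LL") \
            + rng.normal(0, 8, size=n)
        return pd.DataFrame({"copies_per_ng": y, "genotype": geno,
                             "days_post_hatch": days})

    def test_slope_recovery(self, rng):
        fit = fit_trend(self.make_frame(rng))
        assert fit.day_slope < 0
        assert abs(fit.day_slope - (-0.3)) < 2 * fit.day_slope_se

    def test_constant_response(self, rng):
        frame = self.make_frame(rng)
        frame["copies_per_ng"] = 50.0
        fit = fit_trend(frame)
        assert fit.day_slope == pytest.approx(0.0, abs=1e-10)

    def test_row_order_invariance(self, rng):
        frame = self.make_frame(rng)
        a = fit_trend(frame)
        b = fit_trend(frame.sample(frac=1.0, random_state=1))
        assert a.day_slope == pytest.approx(b.day_slope)

    def test_rank_deficiency_named(self, rng):
        frame = self.make_frame(rng)
        frame["genotype"] = "EE"
        with pytest.raises(ValidationError, match="genotype"):
            fit_trend(frame)
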