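"""Respiration arithmetic, response ratios, DOM PC1, regression and rank tests."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from domphoto.core_io import SampleRecord
from domphoto.response_analysis import (
    co2_production,
    dom_pc1,
    factorial_anova,
    fdr_adjust,
    group_rank_test,
    lake_co2_response,
    response_ratio,
    standardized_coef,
)


def rec(lake="L", trt="dark", d0=5.0, d7=None, d28=None, blank=False, temp=20.0):
    co2 = {0: d0}
    if d7 is not None:
        co2[7] = d7
    if d28 is not None:
        co2[28] = d28
    return SampleRecord(lake, trt, temp, 1, doc_mgC_L=0.0 if blank else 7.0,
                        don_mg_L=0.5, co2_umol=co2, is_blank=blank)


class TestCO2Production:
    def test_blank_corrected_rise(self):
        sample = rec(d0=5, d28=25)
        blank = rec(lake="b", d0=3, d28=5, blank=True)
        assert co2_production(sample, blank, 28) == pytest.approx(18.0)

    def test_sample_equal_to_blank_gives_zero(self):
        sample = rec(d0=5, d28=9)
        blank = rec(lake="b", d0=2, d28=6, blank=True)
        assert co2_production(sample, blank, 28) == pytest.approx(0.0)

    def test_no_blank_returns_uncorrected_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            value = co2_production(rec(d0=5, d28=25), None, 28)
        assert value == pytest.approx(20.0)
        assert any("uncorrected" in m for m in caplog.messages)

    def test_negative_production_retained_and_flagged(self, caplog):
        sample = rec(d0=5, d28=6)
        blank = rec(lake="b", d0=2, d28=6, blank=True)
        with caplog.at_level(logging.WARNING):
            value = co2_production(sample, blank, 28)
        assert value == pytest.approx(-3.0)
        assert any("negative" in m for m in caplog.messages)

    def test_missing_day_errors(self):
        with pytest.raises(ValueError):
            co2_production(rec(d0=5), rec(lake="b", d0=2, d28=6, blank=True), 28)


class TestResponseRatio:
    def test_identity_and_ln2(self):
        assert response_ratio(3.0, 3.0) == 0.0
        assert response_ratio(2.0, 1.0) == pytest.approx(math.log(2), abs=1e-9)

    def test_low_end_anchor(self):
        assert response_ratio(0.565, 1.0) == pytest.approx(-0.571, abs=5e-4)

    def test_antisymmetry(self):
        assert response_ratio(4.2, 1.7) == pytest.approx(-response_ratio(1.7, 4.2))

    def test_plain_ratio_form(self):
        assert response_ratio(3.0, 2.0, log=False) == pytest.approx(1.5)

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ValueError):
            response_ratio(0.0, 2.0)


class TestDomPC1:
    def test_perfectly_correlated_variables(self):
        doc = np.array([5.0, 8.0, 11.0, 14.0])
        don = 0.1 * doc + 0.05
        scores, explained = dom_pc1(doc, don)
        assert explained == pytest.approx(1.0)
        z = (doc - doc.mean()) / doc.std(ddof=1)
        np.testing.assert_allclose(scores, z * math.sqrt(2), atol=1e-9)

    def test_uncorrelated_variables_split_variance(self):
        doc = np.array([1.0, -1.0, 1.0, -1.0])
        don = np.array([1.0, 1.0, -1.0, -1.0])  # exactly orthogonal
        _, explained = dom_pc1(doc, don)
        assert explained == pytest.approx(0.5)

    def test_closed_form_for_intermediate_correlation(self):
        # construct DON with exact sample correlation r against DOC
        r = 0.8
        n = 12
        rng = np.random.default_rng(5)
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        e -= e.mean()
        x -= x.mean()
        e -= (e @ x) / (x @ x) * x  # orthogonalise
        zx = x / np.sqrt(x @ x)
        ze = e / np.sqrt(e @ e)
        don = r * zx + math.sqrt(1 - r * r) * ze
        _, explained = dom_pc1(x, don)
        assert explained == pytest.approx((1 + r) / 2, abs=1e-12)

    def test_affine_invariance_and_orientation(self):
        rng = np.random.default_rng(11)
        doc = rng.uniform(5, 17, 10)
        don = 0.07 * doc + rng.normal(0, 0.05, 10)
        s1, e1 = dom_pc1(doc, don)
        s2, e2 = dom_pc1(doc * 1000 + 3, don * 12 - 7)
        np.testing.assert_allclose(s1, s2, atol=1e-9)
        assert e1 == pytest.approx(e2)
        assert np.corrcoef(s1, doc)[0, 1] > 0  # DOC loading oriented positive

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            dom_pc1([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestStandardizedCoef:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        up = standardized_coef(x, 2 * x + 1)
        down = standardized_coef(x, -x)
        assert up.coef == pytest.approx(1.0)
        assert up.r2 == pytest.approx(1.0)
        assert down.coef == pytest.approx(-1.0)

    def test_equals_pearson_r_in_both_directions(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        from scipy.stats import pearsonr

        r, p = pearsonr(x, y)
        fwd = standardized_coef(x, y)
        rev = standardized_coef(y, x)
        assert fwd.coef == pytest.approx(r, abs=1e-12)
        assert fwd.p_value == pytest.approx(p, abs=1e-12)
        assert abs(rev.coef) == pytest.approx(abs(r), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardized_coef([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _anova_table(rng, sxl_effect=0.0, treatment_effect=0.0, n_lakes=4):
    rows = []
    for lake in range(n_lakes):
        lake_eff = rng.normal(0, 1)
        for trt in ("light", "dark"):
            for temp in (10.0, 20.0):
                for rep in range(3):
                    y = lake_eff + rng.normal(0, 1)
                    if trt == "light":
                        y += treatment_effect + sxl_effect * lake
                    rows.append(dict(lake_id=f"L{lake}", treatment=trt,
                                     temperature_C=temp, replicate=rep,
                                     co2_production=y))
    return pd.DataFrame(rows)


class TestFactorialAnova:
    def test_strong_treatment_effect_detected(self, rng):
        table = _anova_table(rng, treatment_effect=3.0)
        aov = factorial_anova(table)
        assert aov.loc["treatment", "PR(>F)"] < 1e-6
        assert {"treatment:temperature", "treatment:lake"} <= set(aov.index)

    def test_strong_interaction_detected(self, rng):
        table = _anova_table(rng, sxl_effect=2.0)
        aov = factorial_anova(table)
        assert aov.loc["treatment:lake", "PR(>F)"] < 1e-4

    def test_two_factor_subset(self, rng):
        table = _anova_table(rng)
        aov = factorial_anova(table, factors=("treatment", "lake"))
        assert "treatment:lake" in aov.index
        assert "treatment:temperature" not in aov.index

    def test_single_level_factor_rejected(self, rng):
        table = _anova_table(rng)
        table["treatment"] = "dark"
        with pytest.raises(ValueError, match="single level"):
            factorial_anova(table)

    def test_constant_response_flagged(self, rng, caplog):
        table = _anova_table(rng)
        table["co2_production"] = 1.0
        with caplog.at_level(logging.WARNING):
            aov = factorial_anova(table)
        assert any("zero variance" in m for m in caplog.messages)
        # effect sums of squares collapse to numerical zero
        assert aov["sum_sq"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestRankTest:
    def test_identical_groups_maximal_p(self):
        w, p = group_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_three_vs_three(self):
        w, p = group_rank_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert w == pytest.approx(6.0)       # ranks 1+2+3
        assert p == pytest.approx(0.1)       # minimal exact two-sided p for 3 vs 3

    def test_power_monotone_in_shift(self, rng):
        rejections = []
        for shift in (0.0, 1.0, 2.0):
            hits = 0
            for _ in range(200):
                a = rng.normal(0, 1, 8)
                b = rng.normal(shift, 1, 8)
                hits += group_rank_test(a, b)[1] < 0.05
            rejections.append(hits)
        assert rejections[0] < rejections[1] < rejections[2]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_rank_test([1.0], [2.0, 3.0])


def test_fdr_adjustment_is_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    q = fdr_adjust(p)
    assert np.all(q >= p)
    assert np.all(q <= 1.0)
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)


class TestLakeResponse:
    def test_recovers_generated_response_ratios(self, small_study):
        table, summaries = lake_co2_response(small_study.records)
        assert len(table) == small_study.cfg.n_lakes * 2 * 2 * 3
        rr = {s.lake_id: s.co2_rr for s in summaries}
        for lake, true_rr in small_study.truth.rr_co2.items():
            assert rr[lake] == pytest.approx(true_rr, abs=0.15)

    def test_anova_on_generated_study_finds_lake_effect(self, small_study):
        table, _ = lake_co2_response(small_study.records)
        aov = factorial_anova(table)
        assert aov.loc["lake", "PR(>F)"] < 1e-6
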