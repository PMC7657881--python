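"""Criterion/sensitivity cell algebra, percent transforms, contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from vocalsdt.coding import TERMS
from vocalsdt.sdt import (
    CELLS,
    cell_combination,
    cell_draws,
    contrast,
    mean_of_transform_percent,
    sensitivity_to_percent,
    summarize_draws,
    summary_table,
    z_to_percent,
)
from vocalsdt.study import REPORTED_CONDITION_Z, betas_from_condition_z

from conftest import make_fake_fit


def _idx(term):
    return TERMS.index(term)


class TestCellCombination:
    def test_reference_cell_is_intercept_only(self):
        w = cell_combination("cospeech", "original", "criterion")
        expected = np.zeros(8)
        expected[_idx("intercept")] = 1
        assert np.array_equal(w, expected)

    def test_reference_sensitivity_is_familiarity_only(self):
        w = cell_combination("cospeech", "original", "sensitivity")
        expected = np.zeros(8)
        expected[_idx("familiarity")] = 1
        assert np.array_equal(w, expected)

    def test_colaughter_sped_sensitivity_sums_all_familiarity_terms(self):
        w = cell_combination("colaughter", "sped-up", "sensitivity")
        expected = np.zeros(8)
        for t in (
            "familiarity",
            "familiarity:talk",
            "familiarity:speed",
            "familiarity:talk:speed",
        ):
            expected[_idx(t)] = 1
        assert np.array_equal(w, expected)

    def test_colaughter_sped_criterion(self):
        w = cell_combination("colaughter", "sped-up", "criterion")
        expected = np.zeros(8)
        for t in ("intercept", "talk", "speed", "talk:speed"):
            expected[_idx(t)] = 1
        assert np.array_equal(w, expected)

    def test_unknown_cell_or_quantity_rejected(self):
        with pytest.raises(ValueError):
            cell_combination("humming", "original", "criterion")
        with pytest.raises(ValueError):
            cell_combination("cospeech", "original", "bias")


class TestPercentTransforms:
    @pytest.mark.parametrize(
        "z, pct", [(-0.22, 41), (-0.01, 50), (-0.03, 49), (0.16, 56), (0.0, 50)]
    )
    def test_criterion_percent_pairs(self, z, pct):
        assert round(z_to_percent(z)) == pct

    @pytest.mark.parametrize(
        "c, d, pct",
        [(-0.22, 0.33, 13), (-0.01, 0.22, 9), (-0.03, 0.70, 26), (0.16, 0.69, 24)],
    )
    def test_sensitivity_percent_pairs(self, c, d, pct):
        assert round(sensitivity_to_percent(c, d)) == pct

    def test_sensitivity_zero_iff_d_zero(self):
        assert sensitivity_to_percent(0.37, 0.0) == 0.0
        assert sensitivity_to_percent(0.37, 0.01) != 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(z=st.floats(-5, 5), dz=st.floats(0.001, 2))
    def test_z_to_percent_strictly_increasing(self, z, dz):
        assert z_to_percent(z + dz) > z_to_percent(z)


class TestSummarizeDraws:
    def test_symmetric_draws_give_half_credibility(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20000)
        s = summarize_draws(x)
        assert s.credibility == pytest.approx(50.0, abs=2.0)

    def test_all_positive_draws_full_credibility(self):
        s = summarize_draws(np.abs(np.random.default_rng(1).normal(size=500)) + 0.01)
        assert s.credibility == 100.0

    def test_quantiles_match_closed_form_normal(self):
        rng = np.random.default_rng(2)
        mu, sigma = 0.4, 0.15
        s = summarize_draws(rng.normal(mu, sigma, size=200000))
        assert s.mean == pytest.approx(mu, abs=3 * sigma / np.sqrt(200000))
        assert s.ci_low == pytest.approx(norm.ppf(0.025, mu, sigma), abs=0.005)
        assert s.ci_high == pytest.approx(norm.ppf(0.975, mu, sigma), abs=0.005)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_draws(np.ones(10))


@pytest.fixture(scope="module")
def table1_fit():
    """Fit whose draws sit exactly at the reported posterior means."""
    beta = betas_from_condition_z()
    draws = np.tile(beta, (200, 1))
    return make_fake_fit(draws, level=4)


class TestCellDrawsAndContrasts:
    def test_cell_draws_reproduce_reported_condition_values(self, table1_fit):
        for (mode, speed), (c, d) in REPORTED_CONDITION_Z.items():
            crit = cell_draws(table1_fit, mode, speed, "criterion")
            sens = cell_draws(table1_fit, mode, speed, "sensitivity")
            assert crit.mean() == pytest.approx(c, abs=1e-12)
            assert sens.mean() == pytest.approx(d, abs=1e-12)

    def test_sensitivity_mode_contrast(self, table1_fit):
        s = contrast(
            table1_fit,
            {
                ("colaughter", "original", "sensitivity"): 1.0,
                ("cospeech", "original", "sensitivity"): -1.0,
            },
        )
        assert s.mean == pytest.approx(0.37, abs=1e-12)

    def test_colaughter_speed_criterion_contrast(self, table1_fit):
        s = contrast(
            table1_fit,
            {
                ("colaughter", "sped-up", "criterion"): 1.0,
                ("colaughter", "original", "criterion"): -1.0,
            },
        )
        assert s.mean == pytest.approx(0.19, abs=1e-12)

    def test_constant_draws_have_zero_width_interval(self, table1_fit):
        s = contrast(table1_fit, {("cospeech", "original", "criterion"): 1.0})
        assert s.ci_low == s.ci_high
        assert s.mean == pytest.approx(s.ci_low, abs=1e-12)

    def test_zero_weight_contrast_rejected(self, table1_fit):
        with pytest.raises(ValueError, match="zero"):
            contrast(table1_fit, {("cospeech", "original", "criterion"): 0.0})


class TestSummaryTable:
    def test_structure_and_percent_consistency(self, small_fit):
        table = summary_table(small_fit)
        assert len(table) == 4
        assert set(table["condition"]) == {f"{m} ({s})" for m, s in CELLS}
        for _, row in table.iterrows():
            assert row["criterion_pct"] == pytest.approx(
                z_to_percent(row["criterion_z"]), abs=1e-9
            )
            assert row["criterion_ci_low"] <= row["criterion_z"] <= row["criterion_ci_high"]

    def test_transform_of_mean_close_to_mean_of_transform(self, small_fit):
        """For |z| < 1 the two percent conventions agree within ~1 point."""
        table = summary_table(small_fit).set_index("condition")
        for mode, speed in CELLS:
            pct_c, pct_d = mean_of_transform_percent(small_fit, mode, speed)
            row = table.loc[f"{mode} ({speed})"]
            if abs(row["criterion_z"]) < 1 and abs(row["sensitivity_z"]) < 1:
                assert abs(row["criterion_pct"] - pct_c) < 1.0
                assert abs(row["sensitivity_pct"] - pct_d) < 1.5
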