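import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metphos.differential import (estimate_moderation_params,
                                  loose_fold_changes, make_call,
                                  moderated_ttest, ttest_differential)
from metphos.simulate import SimConfig, make_design


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t (independent of the
    implementation path, which works row-wise on matrices)."""
    n1, n2 = len(a), len(b)
    s2 = (((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1))
          / (n1 + n2 - 2))
    t = (np.mean(a) - np.mean(b)) / np.sqrt(s2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def _two_line_setup(treated_rows, control_rows):
    """Matrix + design for one cell line, 24-h comparison."""
    design = make_design(SimConfig(n_cell_lines=1, n_replicates=3))
    line = design["cell_line"].iloc[0]
    mat = pd.DataFrame(index=[f"f{i}" for i in range(len(treated_rows))],
                       columns=list(design["run_id"]), dtype=float)
    for i, (t_vals, c_vals) in enumerate(zip(treated_rows, control_rows)):
        for j, v in enumerate(t_vals):
            mat.iloc[i, mat.columns.get_loc(f"{line}.met_24h.r{j + 1}")] = v
        for j, v in enumerate(c_vals):
            mat.iloc[i, mat.columns.get_loc(
                f"{line}.control_24h.r{j + 1}")] = v
    return mat, design, line


class TestTTest:
    def test_identical_groups_give_t0_p1_call0(self):
        mat, design, line = _two_line_setup([[10, 10, 10]], [[10, 10, 10]])
        res = ttest_differential(mat, design, line, "met24_vs_ctrl24")
        row = res.iloc[0]
        assert row["t_stat"] == 0 and row["p_value"] == 1
        assert row["call"] == 0

    def test_matches_textbook_formula(self):
        a, b = [8.0, 9.0, 10.0], [11.0, 12.0, 13.0]
        mat, design, line = _two_line_setup([a], [b])
        res = ttest_differential(mat, design, line, "met24_vs_ctrl24")
        t_exp, p_exp = pooled_t_oracle(np.array(a), np.array(b))
        assert res.iloc[0]["t_stat"] == pytest.approx(t_exp, abs=1e-10)
        assert res.iloc[0]["p_value"] == pytest.approx(p_exp, abs=1e-10)
        assert res.iloc[0]["log2fc"] == pytest.approx(-3.0)

    def test_single_valid_value_gives_missing_call(self):
        mat, design, line = _two_line_setup(
            [[8.0, np.nan, np.nan]], [[11.0, 12.0, 13.0]])
        res = ttest_differential(mat, design, line, "met24_vs_ctrl24")
        assert np.isnan(res.iloc[0]["call"])
        assert np.isnan(res.iloc[0]["p_value"])

    def test_swapping_groups_negates_fc_and_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(10, 1, 3), rng.normal(12, 1, 3)
        mat1, design, line = _two_line_setup([a], [b])
        mat2, _, _ = _two_line_setup([b], [a])
        r1 = ttest_differential(mat1, design, line, "met24_vs_ctrl24")
        r2 = ttest_differential(mat2, design, line, "met24_vs_ctrl24")
        assert r1.iloc[0]["log2fc"] == pytest.approx(-r2.iloc[0]["log2fc"])
        assert r1.iloc[0]["t_stat"] == pytest.approx(-r2.iloc[0]["t_stat"])
        assert r1.iloc[0]["p_value"] == pytest.approx(r2.iloc[0]["p_value"])

    def test_unknown_cell_line_or_comparison_raises(self):
        mat, design, line = _two_line_setup([[1, 2, 3]], [[1, 2, 3]])
        with pytest.raises(ValueError):
            ttest_differential(mat, design, "nope", "met24_vs_ctrl24")
        with pytest.raises(ValueError):
            ttest_differential(mat, design, line, "met48")

    def test_bh_q_values_monotone_in_p_rank(self):
        rng = np.random.default_rng(7)
        treated = [rng.normal(10, 1, 3) for _ in range(40)]
        control = [rng.normal(10 + rng.choice([0, 1]), 1, 3)
                   for _ in range(40)]
        mat, design, line = _two_line_setup(treated, control)
        res = ttest_differential(mat, design, line, "met24_vs_ctrl24")
        srt = res.sort_values("p_value")
        assert (np.diff(srt["q_value"]) >= -1e-12).all()
        assert srt["q_value"].iloc[-1] >= srt["p_value"].iloc[-1] - 1e-12


class TestMakeCall:
    @pytest.mark.parametrize("p,lfc,expected", [
        (0.005, 0.70, 1), (0.02, 2.0, 0), (0.001, -1.0, -1),
        (0.005, 0.30, 0),  # fold change below 1.5
    ])
    def test_threshold_combinations(self, p, lfc, expected):
        assert make_call(p, lfc) == expected


class TestModeratedT:
    def _sim(self, n_features=60, shift=0.0, seed=3):
        rng = np.random.default_rng(seed)
        treated = [rng.normal(10 + shift, 1, 3) for _ in range(n_features)]
        control = [rng.normal(10, 1, 3) for _ in range(n_features)]
        return _two_line_setup(treated, control)

    def test_d0_zero_equals_ordinary_t(self):
        mat, design, line = self._sim()
        plain = ttest_differential(mat, design, line, "met24_vs_ctrl24")
        mod = moderated_ttest(mat, design, line, "met24_vs_ctrl24",
                              prior=(0.0, 1.0))
        np.testing.assert_allclose(mod["t_stat"], plain["t_stat"],
                                   rtol=1e-10)

    def test_d0_infinite_uses_prior_variance_everywhere(self):
        mat, design, line = self._sim()
        s0sq = 2.5
        mod = moderated_ttest(mat, design, line, "met24_vs_ctrl24",
                              prior=(np.inf, s0sq))
        expected = mod["log2fc"] / np.sqrt(s0sq * (2 / 3))
        np.testing.assert_allclose(mod["t_stat"], expected, rtol=1e-10)

    def test_shrinkage_formula_against_direct_computation(self):
        """Moderated t and p recomputed from the documented formulas."""
        mat, design, line = self._sim()
        d0, s0sq = 4.0, 0.8
        mod = moderated_ttest(mat, design, line, "met24_vs_ctrl24",
                              prior=(d0, s0sq))
        treated = mat[[c for c in mat.columns if "met_24h" in c]].to_numpy()
        control = mat[[c for c in mat.columns
                       if "control_24h" in c]].to_numpy()
        s2 = ((2 * treated.var(axis=1, ddof=1)
               + 2 * control.var(axis=1, ddof=1)) / 4)
        s2_mod = (d0 * s0sq + 4 * s2) / (d0 + 4)
        t_exp = ((treated.mean(axis=1) - control.mean(axis=1))
                 / np.sqrt(s2_mod * (2 / 3)))
        p_exp = 2 * stats.t.sf(np.abs(t_exp), 4 + d0)
        np.testing.assert_allclose(mod["t_stat"], t_exp, atol=1e-8)
        np.testing.assert_allclose(mod["p_value"], p_exp, atol=1e-8)

    def test_moment_estimates_recover_f_distributed_variances(self):
        """Sample variances drawn from the assumed scaled-F model give
        back the generating prior df and variance."""
        rng = np.random.default_rng(12)
        d, d0_true, s0_true = 4.0, 6.0, 1.5
        n = 20000
        sg2 = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = sg2 * rng.chisquare(d, size=n) / d
        d0, s0sq = estimate_moderation_params(s2, np.full(n, d))
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0sq == pytest.approx(s0_true, rel=0.1)

    def test_null_type_i_rate_calibrated(self):
        mat, design, line = self._sim(n_features=500, seed=21)
        mod = moderated_ttest(mat, design, line, "met24_vs_ctrl24")
        rate = (mod["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07


class TestLooseFoldChanges:
    def test_single_value_per_triplicate_suffices(self):
        mat, design, line = _two_line_setup(
            [[np.nan, 8.0, np.nan]], [[9.0, 9.0, 9.0]])
        fc = loose_fold_changes(mat, design)
        assert fc.loc["f0", line] == pytest.approx(-1.0)

    def test_fully_missing_condition_gives_missing(self):
        mat, design, line = _two_line_setup(
            [[np.nan] * 3], [[9.0, 9.0, 9.0]])
        fc = loose_fold_changes(mat, design)
        assert np.isnan(fc.loc["f0", line])

    def test_complete_triplicates_match_ttest_log2fc(self):
        rng = np.random.default_rng(5)
        treated = [rng.normal(10, 1, 3) for _ in range(10)]
        control = [rng.normal(11, 1, 3) for _ in range(10)]
        mat, design, line = _two_line_setup(treated, control)
        fc = loose_fold_changes(mat, design)
        res = ttest_differential(mat, design, line, "met24_vs_ctrl24")
        np.testing.assert_allclose(fc[line].to_numpy(),
                                   res["log2fc"].to_numpy(), atol=1e-12)
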