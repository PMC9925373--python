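import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metphos.enrichment import (fisher_enrichment, icelogo_positional,
                                motif_extract, one_d_enrichment,
                                pairwise_set_shift, set_shift_test)
from metphos.simulate import simulate_windows


def fisher_exact_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins
    and summing probabilities <= that of the observed table."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_prob(x):
        return (math.comb(row1, x) * math.comb(row2, col1 - x)
                / math.comb(n, col1))

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = table_prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


class TestFisher:
    def test_matches_hypergeometric_enumeration(self):
        """Perfectly separated 5/0/0/5 table and assorted others."""
        bg = {f"x{i}" for i in range(10)}
        fg = {f"x{i}" for i in range(5)}
        annotations = {"term": {f"x{i}" for i in range(5)}}
        res = fisher_enrichment(fg, bg, annotations)
        assert res["p_value"].iloc[0] == pytest.approx(
            fisher_exact_oracle(5, 0, 0, 5), abs=1e-12)

    @pytest.mark.parametrize("a,b,c,d", [(3, 7, 2, 8), (1, 9, 5, 5),
                                         (6, 2, 1, 9)])
    def test_arbitrary_tables_match_oracle(self, a, b, c, d):
        fg = {f"f{i}" for i in range(a + b)}
        bg = fg | {f"g{i}" for i in range(c + d)}
        term = ({f"f{i}" for i in range(a)}
                | {f"g{i}" for i in range(c)})
        res = fisher_enrichment(fg, bg, {"t": term})
        assert res["p_value"].iloc[0] == pytest.approx(
            fisher_exact_oracle(a, b, c, d), rel=1e-10)

    def test_null_subsets_give_roughly_uniform_p(self):
        rng = np.random.default_rng(0)
        bg = {f"x{i}" for i in range(200)}
        annotations = {"t": {f"x{i}" for i in range(40)}}
        ps = []
        for _ in range(50):
            fg = set(rng.choice(sorted(bg), size=50, replace=False))
            ps.append(fisher_enrichment(fg, bg,
                                        annotations)["p_value"].iloc[0])
        assert np.mean(ps) > 0.3  # no systematic enrichment under null

    def test_by_protein_collapses_sites(self):
        """Ten sites on one protein count once in protein mode."""
        fg = {f"P1_S{i}" for i in range(10)} | {"P2_S1"}
        bg = fg | {"P3_S1", "P4_S1"}
        site2prot = {s: s.split("_")[0] for s in bg}
        annotations = {"t": {f"P1_S{i}" for i in range(10)}}
        by_site = fisher_enrichment(fg, bg, annotations, "by_site")
        by_prot = fisher_enrichment(fg, bg, annotations, "by_protein",
                                    feature_to_protein=site2prot)
        assert by_site["n_fg"].iloc[0] == 10
        assert by_prot["n_fg"].iloc[0] == 1

    def test_zero_overlap_term_reported_with_p1(self):
        res = fisher_enrichment({"a"}, {"a", "b"}, {"t": {"b"}})
        assert res["p_value"].iloc[0] == 1.0

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment(set(), {"a"}, {})


class TestOneD:
    def test_top_ranked_members_match_mwu_oracle(self):
        values = pd.Series(np.arange(20, dtype=float),
                           index=[f"f{i}" for i in range(20)])
        members = {f"f{i}" for i in range(15, 20)}  # the top 5 values
        res = one_d_enrichment(values, {"t": members}, min_members=5)
        assert res["score"].iloc[0] > 0
        _, p_oracle = stats.mannwhitneyu(values[15:], values[:15],
                                         alternative="two-sided")
        assert res["p_value"].iloc[0] == pytest.approx(p_oracle,
                                                       abs=1e-10)

    def test_interleaved_members_score_near_zero(self):
        values = pd.Series(np.arange(40, dtype=float),
                           index=[f"f{i}" for i in range(40)])
        members = {f"f{i}" for i in range(0, 40, 2)}
        res = one_d_enrichment(values, {"t": members})
        assert abs(res["score"].iloc[0]) <= 0.05

    def test_score_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        values = pd.Series(rng.normal(size=30),
                           index=[f"f{i}" for i in range(30)])
        members = {f"f{i}" for i in range(8)}
        r1 = one_d_enrichment(values, {"t": members})
        r2 = one_d_enrichment(np.exp(values * 3), {"t": members})
        assert r1["score"].iloc[0] == pytest.approx(r2["score"].iloc[0])
        assert r1["p_value"].iloc[0] == pytest.approx(r2["p_value"].iloc[0])

    def test_small_terms_excluded(self):
        values = pd.Series(np.arange(10, dtype=float),
                           index=[f"f{i}" for i in range(10)])
        res = one_d_enrichment(values, {"small": {"f0", "f1", "f2", "f3"}},
                               min_members=5)
        assert len(res) == 0


class TestSetShift:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(20):
            values = pd.Series(rng.normal(size=100),
                               index=[f"f{i}" for i in range(100)])
            members = {f"f{i}" for i in range(30)}
            p, _ = set_shift_test(values, members)
            ps.append(p)
        assert np.mean(ps) > 0.3

    def test_shifted_members_detected(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(1, 1, 50),
                               rng.normal(0, 1, 500)])
        values = pd.Series(vals, index=[f"f{i}" for i in range(550)])
        members = {f"f{i}" for i in range(50)}
        p, med = set_shift_test(values, members)
        assert p < 0.001 and med > 0.5

    def test_degenerate_groups_raise(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0],
                           index=["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            set_shift_test(values, {"a"})

    def test_pairwise_segments_with_bh(self):
        rng = np.random.default_rng(4)
        values = pd.Series(rng.normal(size=90),
                           index=[f"f{i}" for i in range(90)])
        values[:30] += 2.0
        groups = {"G1": {f"f{i}" for i in range(30)},
                  "G3": {f"f{i}" for i in range(30, 60)},
                  "G5": {f"f{i}" for i in range(60, 90)}}
        res = pairwise_set_shift(values, groups)
        assert len(res) == 3
        assert "q_value" in res.columns
        g1g3 = res[(res["group_a"] == "G1") & (res["group_b"] == "G3")]
        assert g1g3["q_value"].iloc[0] < 0.01


class TestIceLogo:
    def test_identical_sets_flag_nothing(self):
        windows = simulate_windows(50, "S", seed=5)
        res = icelogo_positional(windows, windows, 0.05)
        assert (res["flag"] == 0).all()

    def test_planted_residue_detected_and_matches_binomial_oracle(self):
        fg = simulate_windows(100, "S", planted={-3: "R"},
                              planted_frac=0.8, seed=6)
        bg = simulate_windows(1000, "S", seed=7)
        res = icelogo_positional(fg, bg, 0.05)
        cell = res[(res["position"] == -3) & (res["residue"] == "R")]
        assert cell["flag"].iloc[0] == 1
        # p agrees with a direct two-proportion test on the same counts
        k = round(cell["freq_fg"].iloc[0] * 100)
        p_bg = cell["freq_bg"].iloc[0]
        z = (k / 100 - p_bg) / np.sqrt(p_bg * (1 - p_bg) / 100)
        assert cell["p_value"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(abs(z)), rel=1e-6)

    def test_padding_excluded_from_denominator(self):
        fg = ["_" * 7 + "S" + "A" * 7] * 10
        bg = ["_" * 7 + "S" + "A" * 7] * 10
        res = icelogo_positional(fg, bg, 0.05)
        # at fully padded positions nothing is counted at all
        assert (res["position"] >= 0).all()

    def test_mixed_window_lengths_rejected(self):
        with pytest.raises(ValueError):
            icelogo_positional(["SHORT"], ["A" * 15])


class TestMotifExtract:
    def test_planted_proline_motif_extracted(self):
        fg = simulate_windows(40, "S", planted={1: "P"},
                              planted_frac=0.75, seed=1)
        bg = simulate_windows(1000, "S", seed=2)
        motifs = motif_extract(fg, bg, min_occurrence=20, p_threshold=1e-6)
        assert len(motifs) == 1
        assert motifs[0].pattern == ".......SP......"
        assert motifs[0].n_fg >= 20
        # stepwise p agrees with a direct binomial tail computation
        pos, aa, p = motifs[0].fixed[0]
        k = sum(1 for w in fg if w[7 + pos] == aa)
        p_bg = sum(1 for w in bg if w[7 + pos] == aa) / len(bg)
        oracle = sum(math.comb(len(fg), x) * p_bg ** x
                     * (1 - p_bg) ** (len(fg) - x)
                     for x in range(k, len(fg) + 1))
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_min_occurrence_gate(self):
        """A pattern carried by only 19 foreground windows is withheld."""
        filler = [w for w in simulate_windows(40, "S", seed=4)
                  if w[8] != "P"][:30]
        fg = simulate_windows(19, "S", planted={1: "P"}, seed=3) + filler
        bg = simulate_windows(1000, "S", seed=5)
        motifs = motif_extract(fg, bg, min_occurrence=20, p_threshold=1e-6)
        assert all("P" not in m.pattern[8:9] for m in motifs)

    def test_no_signal_gives_empty_result(self):
        fg = simulate_windows(40, "S", seed=8)
        bg = simulate_windows(1000, "S", seed=9)
        assert motif_extract(fg, bg) == []

    def test_empty_foreground_gives_empty_result(self):
        assert motif_extract([], simulate_windows(10, "S", seed=1)) == []

    def test_removing_first_motif_yields_remaining_motifs(self):
        """Greedy extraction is consistent: dropping the first motif's
        supporting windows and re-running reproduces the rest."""
        fg = (simulate_windows(40, "S", planted={1: "P"}, seed=10)
              + simulate_windows(40, "S", planted={-3: "R"}, seed=11))
        bg = simulate_windows(2000, "S", seed=12)
        motifs = motif_extract(fg, bg, min_occurrence=20, p_threshold=1e-4)
        assert len(motifs) >= 2
        first = motifs[0]
        remaining_fg = [w for w in fg if not first.matches(w)]
        rerun = motif_extract(remaining_fg, bg, min_occurrence=20,
                              p_threshold=1e-4)
        assert [m.pattern for m in rerun] == \
            [m.pattern for m in motifs[1:]]
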