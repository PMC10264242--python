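import numpy as np
import pandas as pd
import pytest

import ribostat as rs
from ribostat.apa import PasUsageTester
from ribostat.io import DataError


def make_pas(site_counts, samples, ranks=None):
    """site_counts: {(tx, site): [counts per sample]}"""
    idx = pd.MultiIndex.from_tuples(
        list(site_counts), names=["transcript_id", "site_id"]
    )
    counts = pd.DataFrame(
        [site_counts[k] for k in site_counts], index=idx, columns=samples
    ).astype(float)
    if ranks is None:
        rank_s = (
            pd.Series(idx.get_level_values(1), index=idx)
            .groupby(level=0, sort=False)
            .rank(method="first")
            .astype(int)
        )
    else:
        rank_s = pd.Series(ranks, index=idx)
    return rs.PasCountTable(counts, rank_s, rank_source="manual")


def binary_design(labels, name="condition", samples=None):
    samples = samples or [f"s{i}" for i in range(len(labels))]
    return rs.DesignMatrix(
        pd.DataFrame(
            {name: np.asarray(labels, dtype=float)}, index=samples
        )
    )


class TestOverall:
    def test_identical_proportions_give_null_deviance(self):
        pas = make_pas(
            {("t", "pA1"): [30, 60], ("t", "pA2"): [70, 140]}, ["s0", "s1"]
        )
        res = rs.fit_overall(pas, binary_design([0, 1]), normalize=False)
        assert res["deviance"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert res["p"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_df_formula_three_sites(self):
        pas = make_pas(
            {
                ("t", "pA1"): [30, 40, 20, 30],
                ("t", "pA2"): [30, 25, 35, 30],
                ("t", "pA3"): [40, 35, 45, 40],
            },
            [f"s{i}" for i in range(4)],
        )
        res = rs.fit_overall(pas, binary_design([0, 0, 1, 1]), normalize=False)
        assert res["df"].iloc[0] == 2  # (3-1) x 1 covariate

    def test_deviance_equals_g_statistic(self, two_site_pas):
        pas, design = two_site_pas
        res = rs.fit_overall(pas, design, normalize=False)
        o = np.array([[80.0, 20.0], [20.0, 80.0]])
        e = np.outer(o.sum(1), o.sum(0)) / o.sum()
        g = 2 * (o * np.log(o / e)).sum()
        assert res["deviance"].iloc[0] == pytest.approx(g, abs=1e-6)

    def test_single_site_and_degenerate_untestable(self):
        pas = make_pas(
            {
                ("t1", "pA1"): [10, 10],
                ("t2", "pA1"): [50, 60],
                ("t2", "pA2"): [0, 0],
            },
            ["s0", "s1"],
        )
        tester = PasUsageTester(mode="overall", normalize=False).fit(
            pas, binary_design([0, 1])
        )
        assert set(tester.untestable_) == {"t1", "t2"}


class TestVsReference:
    def test_two_site_matches_pairwise_magnitude(self, two_site_pas):
        pas, design = two_site_pas
        ref = rs.fit_vs_reference(pas, design, normalize=False)
        pw = rs.fit_pairwise(pas, design, normalize=False)
        assert abs(ref["beta"].iloc[0]) == pytest.approx(
            abs(pw["beta"].iloc[0]), abs=1e-8
        )
        assert ref["p"].iloc[0] == pytest.approx(pw["p"].iloc[0], abs=1e-8)

    def test_proximal_rule_overrides_alphabetical(self):
        # pA2 is proximal (rank 1) despite sorting after pA1
        pas = make_pas(
            {("t", "pA2"): [80, 20], ("t", "pA1"): [20, 80]},
            ["s0", "s1"],
            ranks=[1, 2],
        )
        res = rs.fit_vs_reference(
            pas, binary_design([0, 1]), reference_rule="proximal", normalize=False
        )
        assert res["reference"].iloc[0] == "pA2"
        res_alpha = rs.fit_vs_reference(pas, binary_design([0, 1]), normalize=False)
        assert res_alpha["reference"].iloc[0] == "pA1"

    def test_user_reference_and_missing_reference_error(self):
        pas = make_pas(
            {("t", "pA1"): [10, 20], ("t", "pA2"): [20, 10]}, ["s0", "s1"]
        )
        res = rs.fit_vs_reference(
            pas, binary_design([0, 1]), reference_rule={"t": "pA2"}, normalize=False
        )
        assert res["reference"].iloc[0] == "pA2"
        with pytest.raises(DataError, match="absent"):
            rs.fit_vs_reference(
                pas, binary_design([0, 1]), reference_rule={"t": "pA9"},
                normalize=False,
            )

    def test_constant_covariate_flagged_degenerate(self):
        pas = make_pas(
            {("t", "pA1"): [10, 20], ("t", "pA2"): [20, 10]}, ["s0", "s1"]
        )
        design = rs.DesignMatrix(
            pd.DataFrame({"condition": [0.0, 1.0]}, index=["s0", "s1"])
        )
        # a covariate of all zeros is collinear with the intercept and is
        # rejected at design construction
        with pytest.raises(DataError, match="collinear"):
            rs.DesignMatrix(
                pd.DataFrame({"z": [0.0, 0.0]}, index=["s0", "s1"])
            )
        res = rs.fit_vs_reference(pas, design, normalize=False)
        assert np.isfinite(res["beta"]).all()


class TestPairwise:
    def test_three_sites_give_three_pairs(self):
        pas = make_pas(
            {
                ("t", "pA1"): [30, 40],
                ("t", "pA2"): [30, 25],
                ("t", "pA3"): [40, 35],
            },
            ["s0", "s1"],
        )
        pw = rs.fit_pairwise(pas, binary_design([0, 1]), normalize=False)
        assert len(pw) == 3

    def test_derived_odds_ratio_example(self, two_site_pas):
        pas, design = two_site_pas
        pw = rs.fit_pairwise(pas, design, normalize=False)
        assert pw["beta"].iloc[0] == pytest.approx(np.log(1 / 16), abs=1e-6)

    def test_identical_proportions_give_zero_beta(self):
        pas = make_pas(
            {("t", "pA1"): [40, 80], ("t", "pA2"): [60, 120]}, ["s0", "s1"]
        )
        pw = rs.fit_pairwise(pas, binary_design([0, 1]), normalize=False)
        assert pw["beta"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_zero_total_sample_dropped_and_flagged(self):
        pas = make_pas(
            {
                ("t", "pA1"): [40, 0, 30, 20],
                ("t", "pA2"): [60, 0, 35, 40],
            },
            [f"s{i}" for i in range(4)],
        )
        pw = rs.fit_pairwise(pas, binary_design([0, 0, 1, 1]), normalize=False)
        assert pw["n_dropped_samples"].iloc[0] == 1


class TestMultinomialBinomialEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_s2_coefficients_agree(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(10, 200, (2, 6)).astype(float)
        pas = make_pas(
            {("t", "pA1"): counts[0], ("t", "pA2"): counts[1]},
            [f"s{i}" for i in range(6)],
        )
        design = binary_design([0, 0, 0, 1, 1, 1])
        ref = rs.fit_vs_reference(pas, design, normalize=False)
        pw = rs.fit_pairwise(pas, design, normalize=False)
        # vs_reference models log(pA2/pA1); pairwise models log(prox/dist) =
        # log(pA1/pA2): coefficients agree up to sign
        assert ref["beta"].iloc[0] == pytest.approx(-pw["beta"].iloc[0], abs=1e-8)
        assert ref["se"].iloc[0] == pytest.approx(pw["se"].iloc[0], abs=1e-8)


class TestLogApar:
    def test_distal_shift_is_negative(self, two_site_pas):
        pas, design = two_site_pas
        pw = rs.fit_pairwise(pas, design, normalize=False)
        apar = rs.compute_logapar(pw, pas)
        assert apar["logAPAR"].iloc[0] == pytest.approx(np.log(1 / 16), abs=1e-6)

    def test_no_change_gives_zero(self):
        pas = make_pas(
            {("t", "pA1"): [50, 100], ("t", "pA2"): [50, 100]}, ["s0", "s1"]
        )
        pw = rs.fit_pairwise(pas, binary_design([0, 1]), normalize=False)
        apar = rs.compute_logapar(pw, pas)
        assert apar["logAPAR"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_label_swap_flips_sign_and_keeps_p(self, two_site_pas):
        pas, _ = two_site_pas
        d12 = binary_design([0, 1], samples=["c1", "c2"])
        d21 = binary_design([1, 0], samples=["c1", "c2"])
        a = rs.compute_logapar(rs.fit_pairwise(pas, d12, normalize=False), pas)
        b = rs.compute_logapar(rs.fit_pairwise(pas, d21, normalize=False), pas)
        assert a["logAPAR"].iloc[0] == pytest.approx(-b["logAPAR"].iloc[0], abs=1e-8)
        assert a["p"].iloc[0] == pytest.approx(b["p"].iloc[0], abs=1e-10)

    def test_extreme_pair_selection_and_log2(self):
        pas = make_pas(
            {
                ("t", "pA1"): [80, 20],
                ("t", "pA2"): [10, 10],
                ("t", "pA3"): [20, 80],
            },
            ["s0", "s1"],
        )
        pw = rs.fit_pairwise(pas, binary_design([0, 1]), normalize=False)
        apar = rs.compute_logapar(pw, pas, pairs="extreme")
        assert len(apar) == 1
        assert apar["proximal_site"].iloc[0] == "pA1"
        assert apar["distal_site"].iloc[0] == "pA3"
        apar2 = rs.compute_logapar(pw, pas, pairs="extreme", log2=True)
        assert apar2["logAPAR"].iloc[0] == pytest.approx(
            apar["logAPAR"].iloc[0] / np.log(2), abs=1e-9
        )
        adj = rs.compute_logapar(pw, pas, pairs="adjacent")
        assert len(adj) == 2


def test_recovery_on_simulated_shift(small_apa):
    """Planted proximal log-odds shift delta = 1 recovered by logAPAR."""
    pas, truth, design = (
        small_apa["pas"], small_apa["truth"], small_apa["design"],
    )
    pw = rs.fit_pairwise(pas, design)
    apar = rs.compute_logapar(pw, pas).set_index("transcript_id")
    shifted = truth.index[truth["is_shifted"]]
    est = apar.loc[apar.index.intersection(shifted), "logAPAR"]
    assert len(est) >= 5
    assert est.mean() == pytest.approx(1.0, abs=0.15)
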