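"""Association tests: agreement with R, power, letters, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from homeoplex import synthgen as sg
from homeoplex.assoc import (association_report, compact_letters,
                             pairwise_tests, tukey_hsd)

# Fixture values computed once with R 4.3 (wilcox.test exact/correct,
# t.test var.equal TRUE/FALSE, TukeyHSD(aov)) and frozen here.
X_SMALL = [12.1, 14.3, 11.8, 13.5, 15.0, 12.7, 13.9, 14.8]
Y_SMALL = [15.2, 16.1, 14.9, 17.3, 15.8, 16.5, 14.4]
R_SMALL = {"wilcoxon": (3.0, 0.002175602176),
           "student_t": (-3.864511673, 0.001953072695),
           "welch_t": (-3.918236545, 0.001772466185)}

A_LARGE = [8.747, 10.367, 8.329, 13.191, 10.659, 8.359, 10.975, 11.477,
           11.152, 9.389, 13.024, 10.78, 8.758, 5.571, 12.25, 9.91, 9.968,
           11.888, 11.642, 11.188, 11.838, 11.564, 10.149, 6.021, 11.24,
           9.888, 9.688, 7.058, 9.044, 10.836, 12.717, 9.794, 10.775,
           9.892, 7.246, 9.17, 9.211, 9.881, 12.2, 11.526]
B_LARGE = [10.671, 10.493, 12.394, 12.113, 9.622, 9.585, 11.729, 12.537,
           10.775, 12.762, 11.796, 9.776, 11.682, 8.741, 13.866, 14.961,
           10.266, 8.912, 12.139, 10.73, 15.803, 10.922, 12.379, 11.056,
           9.513, 11.378, 7.39, 13.931, 11.307, 15.345, 11.951, 9.58,
           12.221, 9.132, 8.493]
R_LARGE_WILCOX = (500.5, 0.03456893009)

TUKEY_V = [10.1, 11.2, 9.8, 10.6, 10.9, 10.3,
           12.4, 13.1, 12.8, 11.9, 12.6, 13.4,
           10.4, 10.8, 11.1, 9.9, 10.2, 10.7]
TUKEY_G = ["g1"] * 6 + ["g2"] * 6 + ["g3"] * 6
R_TUKEY_P = {("g1", "g2"): 3.702880386e-06, ("g1", "g3"): 0.9925745432,
             ("g2", "g3"): 4.447404720e-06}


class TestPairwise:
    def test_matches_r_reference_small_sample(self):
        res = {r.test: (r.statistic, r.p_value)
               for r in pairwise_tests(X_SMALL + Y_SMALL,
                                       ["a"] * 8 + ["b"] * 7)}
        for test, (stat, p) in R_SMALL.items():
            assert res[test][0] == pytest.approx(stat, abs=1e-6)
            assert res[test][1] == pytest.approx(p, abs=1e-6)

    def test_matches_r_reference_normal_approximation(self):
        res = pairwise_tests(A_LARGE + B_LARGE,
                             ["a"] * 40 + ["b"] * 35)
        w = next(r for r in res if r.test == "wilcoxon")
        assert w.statistic == pytest.approx(R_LARGE_WILCOX[0])
        assert w.p_value == pytest.approx(R_LARGE_WILCOX[1], abs=1e-6)

    def test_identical_samples_give_p_one(self):
        vals = [5.0] * 4 + [5.0] * 4
        res = pairwise_tests(vals, ["a"] * 4 + ["b"] * 4)
        assert all(r.p_value == 1.0 and "degenerate" in r.flags
                   for r in res)

    def test_planted_deficit_power(self):
        """-0.8 SD effect, n = 15 vs 150: Wilcoxon power > 0.8 at 0.05."""
        rng = np.random.default_rng(0)
        reps = 1000
        x = rng.normal(0.0, 1.0, (reps, 150))
        y = rng.normal(-0.8, 1.0, (reps, 15))
        p_w = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", axis=1).pvalue
        p_t = stats.ttest_ind(x, y, axis=1).pvalue
        detected = (p_w <= 0.05) | (p_t <= 0.05)
        assert detected.mean() > 0.8

    def test_phenotype_effect_detected_through_generator(self):
        """A planted 10% yield deficit on 20+20 cultivars is detected."""
        model = sg.PhenoModel(effects={"sv": {"grain_yield_dt_ha": -9.5}})
        hits = 0
        for seed in range(200):
            table = sg.simulate_phenotypes(["sv", "intact"], model,
                                           n_per_group=20, seed=seed)
            res = pairwise_tests(table["grain_yield_dt_ha"], table["group"])
            w = next(r for r in res if r.test == "wilcoxon")
            hits += w.p_value <= 0.05
        assert hits / 200 > 0.8


class TestTukey:
    def test_pairwise_p_matches_r(self):
        labels = sorted(set(TUKEY_G))
        samples = [np.array(TUKEY_V)[np.array(TUKEY_G) == g]
                   for g in labels]
        res = stats.tukey_hsd(*samples)
        for (i, gi) in enumerate(labels):
            for (j, gj) in enumerate(labels):
                if i < j:
                    assert res.pvalue[i, j] == pytest.approx(
                        R_TUKEY_P[(gi, gj)], abs=1e-6)

    def test_letters_separate_only_significant_groups(self):
        r = tukey_hsd(TUKEY_V, TUKEY_G)
        assert r.letters["g1"] == r.letters["g3"]
        assert r.letters["g2"] != r.letters["g1"]

    def test_distinct_letters_for_huge_separation(self):
        rng = np.random.default_rng(1)
        v = list(rng.normal(0, 1, 10)) + list(rng.normal(10, 1, 10))
        r = tukey_hsd(v, ["a"] * 10 + ["b"] * 10)
        assert r.letters["a"] != r.letters["b"]

    def test_null_groups_share_a_letter(self):
        """k groups from one distribution share a letter in >= 95% of
        replicates."""
        rng = np.random.default_rng(2)
        share = 0
        reps = 200
        for _ in range(reps):
            v = rng.normal(0, 1, 30)
            r = tukey_hsd(v, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
            common = set(r.letters["a"]) & set(r.letters["b"]) & \
                set(r.letters["c"])
            share += bool(common)
        assert share / reps >= 0.95

    def test_compact_letters_consistency(self):
        letters = compact_letters(["a", "b", "c"], {("a", "b")})
        assert set(letters["a"]) & set(letters["b"]) == set()
        assert set(letters["c"]) & (set(letters["a"]) |
                                    set(letters["b"])) != set()


class TestReport:
    def test_twenty_traits_one_grouping(self):
        table = sg.simulate_phenotypes(["g1", "g2", "g3"], sg.PhenoModel(),
                                       n_per_group=10, seed=4)
        report = association_report(table, ["group"])
        assert set(report.trait.unique()) == set(sg.PhenoModel().trait_names)
        assert len(report) == 20  # one Tukey row per trait

    def test_single_group_warns_and_skips(self):
        table = sg.simulate_phenotypes(["only"], sg.PhenoModel(),
                                       n_per_group=8, seed=1)
        with pytest.warns(UserWarning):
            report = association_report(table, ["group"])
        assert report.empty

    def test_planted_effects_are_the_significant_rows(self):
        """The planted trait contrasts dominate the significant calls
        across simulated panels."""
        model = sg.PhenoModel(effects={"sv": {"grain_yield_dt_ha": -9.5,
                                              "biomass_t_ha": -2.0}})
        good = 0
        for seed in range(25):
            table = sg.simulate_phenotypes(["sv", "intact"], model,
                                           n_per_group=20, seed=100 + seed)
            report = association_report(table, ["group"])
            wil = report[report.test == "wilcoxon"]
            sig = set(wil[wil.significant].trait)
            planted = {"grain_yield_dt_ha", "biomass_t_ha"}
            if planted <= sig and len(sig - planted) <= 2:
                good += 1
        assert good / 25 >= 0.9

    def test_report_deterministic(self):
        table = sg.simulate_phenotypes(["a", "b"], sg.PhenoModel(),
                                       n_per_group=12, seed=9)
        r1 = association_report(table, ["group"])
        r2 = association_report(table, ["group"])
        pd.testing.assert_frame_equal(r1, r2)

    def test_bh_option_adds_adjusted_column(self):
        table = sg.simulate_phenotypes(["a", "b"], sg.PhenoModel(),
                                       n_per_group=12, seed=9)
        report = association_report(table, ["group"], bh_correct=True)
        assert "p_bh" in report.columns
        assert (report.p_bh >= report.p_value - 1e-12).all()
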