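"""Agreement statistics against the shipped evaluation counts and
against independent implementations (scipy / statsmodels / sklearn)."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

import ppewatch as pw
from ppewatch import tables
from ppewatch.stats import ConfusionMatrix2x2, Strata2x2

# (item, split, a, b, c, d, accuracy %, kappa, mcnemar, p < 0.001?)
REFERENCE_ROWS = [
    ("mask", "training", 2620, 148, 74, 2832, 96.09, 0.922, 24.67, True),
    ("mask", "live", 476, 70, 118, 1120, 89.46, 0.758, 12.26, True),
    ("gloves", "training", 5577, 264, 468, 4527, 93.24, 0.864, 56.85, True),
    ("gloves", "live", 1161, 168, 186, 1765, 89.21, 0.777, 0.92, False),
    ("gown", "training", 3725, 51, 136, 3117, 97.34, 0.946, 38.64, True),
    ("gown", "live", 376, 29, 239, 1561, 87.85, 0.663, 164.55, True),
]


@pytest.mark.parametrize("item,split,a,b,c,d,acc,kap,mc,sig", REFERENCE_ROWS)
def test_reference_confusion_rows(item, split, a, b, c, d, acc, kap, mc, sig):
    cm = ConfusionMatrix2x2(a, b, c, d)
    assert pw.accuracy(cm) * 100 == pytest.approx(acc, abs=0.005)
    assert pw.cohen_kappa(cm) == pytest.approx(kap, abs=0.001)
    res = pw.mcnemar(cm)
    assert res.statistic == pytest.approx(mc, abs=0.01)
    assert (res.pvalue < 0.001) == sig


def test_gloves_live_pvalue_value():
    res = pw.mcnemar(ConfusionMatrix2x2(1161, 168, 186, 1765))
    assert res.pvalue == pytest.approx(0.337, abs=0.002)
    assert pw.format_pvalue(res.pvalue) == "0.339"


@pytest.mark.parametrize(
    "correct,incorrect,acc",
    [(6097, 1027, 85.58), (6254, 870, 87.79), (1624, 679, 70.52), (1884, 419, 81.81)],
)
def test_overall_accuracies(correct, incorrect, acc):
    # frame correctness as agreement: correct frames on the diagonal
    cm = ConfusionMatrix2x2(correct, incorrect, 0, 0)
    assert pw.accuracy(cm) * 100 == pytest.approx(acc, abs=0.005)


class TestKappa:
    def test_perfect_diagonal_is_one(self):
        assert pw.cohen_kappa(ConfusionMatrix2x2(5, 0, 0, 7)) == pytest.approx(1.0)

    def test_degenerate_marginals_undefined(self):
        assert math.isnan(pw.cohen_kappa(ConfusionMatrix2x2(9, 0, 0, 0)))

    def test_invariant_under_simultaneous_swap(self):
        cm = ConfusionMatrix2x2(30, 5, 9, 40)
        swapped = ConfusionMatrix2x2(40, 9, 5, 30)
        assert pw.cohen_kappa(cm) == pytest.approx(pw.cohen_kappa(swapped))
        assert pw.accuracy(cm) == pytest.approx(pw.accuracy(swapped))

    def test_range_and_sklearn_agreement(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, 4)
            cm = ConfusionMatrix2x2(a, b, c, d)
            k = pw.cohen_kappa(cm)
            assert -1.0 <= k <= 1.0
            truth = [1] * (a + b) + [0] * (c + d)
            pred = [1] * a + [0] * b + [1] * c + [0] * d
            assert k == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-12)


class TestMcNemar:
    def test_equal_discordant_cells_give_zero(self):
        res = pw.mcnemar(ConfusionMatrix2x2(10, 7, 7, 10))
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_no_discordant_pairs_flagged_degenerate(self):
        res = pw.mcnemar(ConfusionMatrix2x2(10, 0, 0, 10))
        assert res.degenerate
        assert (res.statistic, res.pvalue) == (0.0, 1.0)

    def test_matches_statsmodels_without_correction(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b, c, d = rng.integers(1, 60, 4)
            ours = pw.mcnemar(ConfusionMatrix2x2(a, b, c, d))
            ref = sm_mcnemar([[a, b], [c, d]], exact=False, correction=False)
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.pvalue == pytest.approx(ref.pvalue)

    def test_continuity_correction_available(self):
        res = pw.mcnemar(ConfusionMatrix2x2(10, 8, 2, 10), correction=True)
        assert res.statistic == pytest.approx((abs(8 - 2) - 1) ** 2 / 10)


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "strata,expected",
        [
            (Strata2x2(3638, 2459, 557, 470), 10.71),   # clothing
            (Strata2x2(2934, 3163, 282, 745), 151.51),  # scenery
            (Strata2x2(4211, 1886, 613, 414), 35.35),   # sex
        ],
    )
    def test_reference_strata_within_print_rounding(self, strata, expected):
        assert pw.pearson_chi2(strata).statistic == pytest.approx(expected, abs=0.05)

    def test_height_row_documented_discrepancy(self):
        """The published height chi-square (46.51) does not recompute from
        its published counts; the mismatch is preserved, not corrected."""
        recomputed = pw.pearson_chi2(Strata2x2(3925, 2121, 550, 472)).statistic
        printed = tables.load_strata_counts().set_index("confounder").loc["height", "printed_chi2"]
        assert recomputed == pytest.approx(46.40, abs=0.05)
        assert abs(recomputed - printed) > 0.05
        # the height column totals also disagree with the other confounders
        df = tables.load_strata_counts().set_index("confounder")
        height_n = df.loc["height", ["correct_a", "correct_b", "incorrect_a", "incorrect_b"]].sum()
        clothing_n = df.loc["clothing", ["correct_a", "correct_b", "incorrect_a", "incorrect_b"]].sum()
        assert height_n == 6046 + 1022
        assert clothing_n == 6097 + 1027

    def test_proportional_table_independence(self):
        assert pw.pearson_chi2(Strata2x2(20, 10, 40, 20)).statistic == pytest.approx(0.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pw.pearson_chi2(Strata2x2(0, 0, 5, 5))

    def test_matches_scipy_contingency(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a, b, c, d = rng.integers(1, 80, 4)
            ours = pw.pearson_chi2(Strata2x2(a, b, c, d))
            ref_stat, ref_p, dof, _ = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert dof == 1
            assert ours.statistic == pytest.approx(ref_stat)
            assert ours.pvalue == pytest.approx(ref_p)


class TestIntervalAndSampleSize:
    def test_reference_margin(self):
        assert pw.wald_ci_margin(0.8558, 7124) == pytest.approx(0.0082, abs=5e-5)

    def test_margin_edge_cases(self):
        assert pw.wald_ci_margin(0.0, 50) == 0.0
        assert pw.wald_ci_margin(0.5, 100) == pytest.approx(0.098, abs=5e-4)

    @pytest.mark.parametrize(
        "p,half,expected", [(0.8, 0.05, 246), (0.5, 0.05, 385)]
    )
    def test_required_sample_size_examples(self, p, half, expected):
        assert pw.required_sample_size(p, half) == expected

    def test_sample_size_floor_of_one(self):
        assert pw.required_sample_size(0.5, 1e6) == 1

    def test_sample_size_monotone_and_maximised_at_half(self):
        sizes = [pw.required_sample_size(0.8, h) for h in (0.01, 0.02, 0.05, 0.1)]
        assert sizes == sorted(sizes, reverse=True)
        for p in (0.1, 0.3, 0.45, 0.6, 0.9):
            assert pw.required_sample_size(p, 0.05) <= pw.required_sample_size(0.5, 0.05)

    def test_wilson_margin_close_to_wald_at_large_n(self):
        assert pw.wilson_ci_margin(0.8558, 7124) == pytest.approx(
            pw.wald_ci_margin(0.8558, 7124), rel=0.01
        )


class TestChi2Survival:
    def test_reference_points(self):
        assert pw.chi2_survival(0.0) == pytest.approx(1.0)
        assert pw.chi2_survival(3.841) == pytest.approx(0.050, abs=5e-4)
        assert pw.chi2_survival(0.92) == pytest.approx(0.337, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pw.chi2_survival(-1.0)

    def test_matches_numeric_integration(self):
        # brute-force oracle: integrate the chi2(1) density upward from x
        def density(t):
            return math.exp(-t / 2.0) / math.sqrt(2.0 * math.pi * t)

        for x in (0.5, 1.0, 3.841, 10.0, 25.0):
            ref, _ = integrate.quad(density, x, np.inf)
            assert pw.chi2_survival(x) == pytest.approx(ref, abs=1e-9)


class TestInputValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix2x2(-1, 0, 0, 0)
        with pytest.raises(ValueError):
            Strata2x2(1, 2, -3, 4)

    def test_empty_table_rejected(self):
        cm = ConfusionMatrix2x2(0, 0, 0, 0)
        for fn in (pw.accuracy, pw.cohen_kappa, pw.mcnemar):
            with pytest.raises(ValueError):
                fn(cm)

    def test_pvalue_formatting(self):
        assert pw.format_pvalue(0.0005) == "<0.001"
        assert pw.format_pvalue(0.3387) == "0.339"
        assert pw.format_pvalue(0.011) == "0.011"


class TestShippedTables:
    def test_confusion_summary_reproduces_reference_metrics(self):
        summary = tables.summarize_confusions().set_index(["item", "split"])
        for item, split, *_rest in REFERENCE_ROWS:
            acc, kap, mc, sig = _rest[4], _rest[5], _rest[6], _rest[7]
            row = summary.loc[(item, split)]
            assert row["accuracy"] * 100 == pytest.approx(acc, abs=0.005)
            assert row["kappa"] == pytest.approx(kap, abs=0.001)
            assert row["mcnemar"] == pytest.approx(mc, abs=0.01)
            assert (row["pvalue_str"] == "<0.001") == sig

    def test_overall_summary(self):
        summary = tables.summarize_overall().set_index(["split", "definition"])
        assert summary.loc[("training", "no_misclassified_regions"), "accuracy"] * 100 == pytest.approx(85.58, abs=0.005)
        assert summary.loc[("training", "no_misclassified_regions"), "n"] == 7124
        # relaxing the correctness definition never lowers the correct count
        assert (
            summary.loc[("training", "no_misclassified_mask_or_gown"), "correct"]
            >= summary.loc[("training", "no_misclassified_regions"), "correct"]
        )

    def test_strata_summary_flags_printed_values(self):
        summary = tables.summarize_strata().set_index("confounder")
        assert summary.loc["clothing", "chi2"] == pytest.approx(10.71, abs=0.05)
        assert summary.loc["scenery", "chi2"] == pytest.approx(151.51, abs=0.05)
        assert summary.loc["clothing", "pvalue_str"] == "0.001"
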