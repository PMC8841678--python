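"""Multi-reader agreement statistics against formula and library oracles."""

import numpy as np
import pandas as pd
import pytest

import cac
from cac.example_data import (
    EXAMPLE_CAC_MEAN_MM,
    EXAMPLE_CAC_SD_MM,
    TESTING_CAC_PCC,
    TESTING_MANUAL_PCC,
    reconstruct_readings,
)


def table_from(values, readers=None):
    arr = np.asarray(values)
    readers = readers or [f"r{i}" for i in range(arr.shape[1])]
    return cac.RatingsTable(pd.DataFrame(arr, columns=readers))


class TestCV:
    def test_hand_computed_example(self):
        """Values 1..5: sample SD 1.5811, CV 0.5270."""
        assert cac.cv_per_row([1, 2, 3, 4, 5]) == pytest.approx(0.5270, abs=1e-4)

    def test_identical_values_zero(self):
        assert cac.cv_per_row([7.0, 7.0, 7.0]) == 0.0

    def test_published_worked_example(self):
        """Five contouring measurements summarized as 98.1 +/- 0.3 mm have
        CV 0.3% (printed value of the worked example)."""
        readings = reconstruct_readings(EXAMPLE_CAC_MEAN_MM, EXAMPLE_CAC_SD_MM)
        cv = cac.cv_per_row(readings)
        assert round(100 * cv, 1) == 0.3

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cac.cv_per_row([1.0, -1.0])


class TestGoodAgreement:
    def test_identical_table_full_agreement(self):
        t = table_from(np.full((4, 5), 30.0) + np.arange(4)[:, None])
        assert cac.good_agreement_fraction(t) == 1.0

    def test_threshold_is_strict(self):
        rows = []
        for target_cv in (0.19, 0.21):
            base = reconstruct_readings(10.0, target_cv * 10.0, n=5)
            rows.append(base)
        t = table_from(np.array(rows))
        assert cac.good_agreement_fraction(t, threshold=0.20) == 0.5

    def test_simulated_noise_matches_monte_carlo_expectation(self):
        """Reader noise sigma/mu = 0.15 over 500 lesions: the fraction of
        CV < 0.2 matches an independent Monte-Carlo estimate within 3%."""
        rng = np.random.default_rng(77)
        values = 30.0 * (1 + rng.normal(0, 0.15, size=(500, 5)))
        frac = cac.good_agreement_fraction(table_from(values))
        mc = np.random.default_rng(778)
        sims = 30.0 * (1 + mc.normal(0, 0.15, size=(20000, 5)))
        expect = np.mean(sims.std(axis=1, ddof=1) / sims.mean(axis=1) < 0.2)
        assert abs(frac - expect) < 0.03


class TestPearson:
    def test_published_manual_matrix_summary(self):
        """The five-reader manual matrix reproduces the printed
        correlation-with-others row and 0.73 +/- 0.07 summary."""
        s = cac.summarize_correlation_matrix(TESTING_MANUAL_PCC)
        assert list(s["per_reader_mean"].round(2)) == [0.62, 0.73, 0.78, 0.74, 0.77]
        assert round(s["grand_mean"], 2) == 0.73
        assert round(s["sd"], 2) == 0.07

    def test_published_cac_matrix_summary(self):
        s = cac.summarize_correlation_matrix(TESTING_CAC_PCC)
        assert list(s["per_reader_mean"].round(2)) == [0.81, 0.81, 0.84, 0.84, 0.87]
        assert round(s["grand_mean"], 2) == 0.84
        assert round(s["sd"], 2) == 0.03

    def test_identical_readers_give_unit_matrix(self):
        rng = np.random.default_rng(5)
        col = rng.uniform(10, 50, 20)
        t = table_from(np.column_stack([col, col]))
        out = cac.pearson_matrix(t)
        np.testing.assert_allclose(out["matrix"].to_numpy(), 1.0)

    def test_matrix_matches_direct_formula(self):
        """Each entry equals the covariance formula computed by hand."""
        rng = np.random.default_rng(6)
        data = rng.uniform(5, 50, size=(20, 5))
        out = cac.pearson_matrix(table_from(data))["matrix"].to_numpy()
        for i in range(5):
            for j in range(5):
                x, y = data[:, i], data[:, j]
                xc, yc = x - x.mean(), y - y.mean()
                expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
                assert out[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(out, out.T)
        assert np.all(np.abs(out) <= 1.0 + 1e-12)

    def test_constant_reader_named_in_error(self):
        data = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="r1"):
            cac.pearson_matrix(table_from(data))


class TestICC:
    def test_identical_readers_give_one(self):
        col = np.arange(10.0) + 5
        t = table_from(np.column_stack([col] * 4))
        assert cac.icc_two_way_mixed(t)["icc"] == pytest.approx(1.0)

    def test_variance_components_model(self):
        """Rows with variance 4 plus unit reader noise: consistency ICC
        converges to 4 / (4 + 1) = 0.8."""
        rng = np.random.default_rng(21)
        rows = rng.normal(30, 2.0, size=(10000, 1))
        data = rows + rng.normal(0, 1.0, size=(10000, 5))
        out = cac.icc_two_way_mixed(table_from(data))
        assert out["icc"] == pytest.approx(0.8, abs=0.02)
        assert out["band"] == "excellent"

    def test_small_table_matches_hand_anova(self):
        """6x3 table: ICC(3,1) recomputed from hand-built mean squares."""
        data = np.array(
            [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]],
            dtype=float,
        )
        n, k = data.shape
        grand = data.mean()
        ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
        ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((data - grand) ** 2).sum() - ss_rows - ss_cols
        ms_rows = ss_rows / (n - 1)
        ms_err = ss_err / ((n - 1) * (k - 1))
        expected = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        out = cac.icc_two_way_mixed(table_from(data))
        assert out["icc"] == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_oracle(self):
        """ICC3 and ICC2 single measures agree with pingouin on a random
        complete table."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        data = rng.uniform(10, 60, size=(12, 4))
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(12), 4),
                "rater": np.tile(np.arange(4), 12),
                "score": data.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        ).set_index("Type")
        t = table_from(data)
        # ICC(C,1) is the two-way consistency form, ICC(A,1) absolute agreement
        assert cac.icc_two_way_mixed(t, "icc3")["icc"] == pytest.approx(
            ref.loc["ICC(C,1)", "ICC"], abs=1e-9
        )
        assert cac.icc_two_way_mixed(t, "icc2")["icc"] == pytest.approx(
            ref.loc["ICC(A,1)", "ICC"], abs=1e-9
        )

    def test_additive_shifts_do_not_change_consistency_icc(self):
        rng = np.random.default_rng(31)
        data = rng.uniform(10, 40, size=(30, 4))
        base = cac.icc_two_way_mixed(table_from(data))["icc"]
        shifted = data + np.array([0.0, 5.0, -3.0, 11.0])
        assert cac.icc_two_way_mixed(table_from(shifted))["icc"] == pytest.approx(
            base, abs=1e-9
        )
        assert cac.icc_two_way_mixed(table_from(data + 100.0))["icc"] == pytest.approx(
            base, abs=1e-9
        )

    def test_degenerate_table(self):
        t = table_from(np.full((5, 3), 2.0))
        assert cac.icc_two_way_mixed(t)["degenerate"]
        with pytest.raises(ValueError):
            cac.icc_two_way_mixed(t, on_degenerate="raise")


class TestFleissKappa:
    def test_perfect_agreement_mixed_categories(self):
        table = np.array([["CR"] * 5, ["PD"] * 5, ["SD"] * 5, ["PR"] * 5])
        out = cac.fleiss_kappa(table)
        assert out["kappa"] == pytest.approx(1.0)
        assert out["percent_agreement"] == 1.0

    def test_random_ratings_near_zero(self):
        """Uniformly random category calls over 10000 evaluations give
        kappa within 0.02 of the chance level."""
        rng = np.random.default_rng(13)
        table = rng.choice(list(cac.CATEGORIES), size=(10000, 5))
        out = cac.fleiss_kappa(table)
        assert abs(out["kappa"]) < 0.02

    def test_worked_table_matches_hand_formula_and_statsmodels(self):
        rng = np.random.default_rng(14)
        table = rng.choice(["CR", "PR", "SD", "PD"], size=(10, 5), p=[0.1, 0.3, 0.4, 0.2])
        out = cac.fleiss_kappa(table)
        # hand formula
        counts = np.zeros((10, 4))
        for j, cat in enumerate(("CR", "PR", "SD", "PD")):
            counts[:, j] = (table == cat).sum(axis=1)
        p_i = ((counts**2).sum(axis=1) - 5) / (5 * 4)
        p_bar = p_i.mean()
        p_j = counts.sum(axis=0) / 50
        p_e = (p_j**2).sum()
        assert out["kappa"] == pytest.approx((p_bar - p_e) / (1 - p_e), abs=1e-12)
        assert out["percent_agreement"] == pytest.approx(p_bar, abs=1e-12)
        statsmodels_ir = pytest.importorskip("statsmodels.stats.inter_rater")
        assert out["kappa"] == pytest.approx(
            statsmodels_ir.fleiss_kappa(counts), abs=1e-12
        )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(15)
        table = rng.choice(["CR", "PR", "SD", "PD"], size=(50, 5))
        swapped = np.where(table == "CR", "PD", np.where(table == "PD", "CR", table))
        k1 = cac.fleiss_kappa(table)["kappa"]
        k2 = cac.fleiss_kappa(swapped)["kappa"]
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_single_category_degenerate(self):
        out = cac.fleiss_kappa(np.full((6, 5), "SD"))
        assert out["degenerate"]
        assert np.isnan(out["kappa"])

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            cac.fleiss_kappa(np.full((3, 5), "XX"))


class TestVoteAgreement:
    def test_unanimous_table(self):
        table = np.array([["PR"] * 5, ["SD"] * 5])
        assert cac.vote_agreement(table, 0.8) == 1.0
        assert cac.vote_agreement(table, 1.0) == 1.0

    def test_four_of_five_counts_at_80_but_not_100(self):
        table = np.array([["PR", "PR", "PR", "PR", "SD"]])
        assert cac.vote_agreement(table, 0.8) == 1.0
        assert cac.vote_agreement(table, 1.0) == 0.0

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(16)
        table = rng.choice(["CR", "PR", "SD", "PD"], size=(200, 5))
        for quorum, need in [(0.8, 4), (1.0, 5)]:
            brute = np.mean(
                [
                    max(np.unique(row, return_counts=True)[1]) >= need
                    for row in table
                ]
            )
            assert cac.vote_agreement(table, quorum) == pytest.approx(brute)


class TestRatingsTable:
    def test_incomplete_rows_excluded(self):
        df = pd.DataFrame(
            {"r0": [1.0, 2.0, np.nan], "r1": [1.5, 2.5, 3.0], "r2": [1.2, 2.2, 3.3]}
        )
        t = cac.RatingsTable(df)
        assert len(t.complete()) == 2

    def test_from_long_format(self):
        long = pd.DataFrame(
            {
                "lesion_id": ["a", "a", "b", "b"],
                "reader_id": ["r0", "r1", "r0", "r1"],
                "value": [10.0, 11.0, 20.0, 21.0],
            }
        )
        t = cac.RatingsTable.from_long(long)
        assert t.values.loc["b", "r1"] == 21.0

    def test_single_reader_rejected(self):
        with pytest.raises(ValueError):
            cac.RatingsTable(pd.DataFrame({"r0": [1.0, 2.0]}))
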