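"""Mechano-RISQ ratio and its inferential wrapper."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mechanonps.risq_scoring import (
    baseline_error_rate,
    bh_adjust,
    ch_power_simulation,
    crawford_howell,
    group_compare,
    mechano_risq,
    perturbation_fisher,
    risq_table,
)


class TestBaseline:
    def test_definition(self):
        pred = ["older"] * 10 + ["younger"] * 90
        lab = ["younger"] * 100
        assert baseline_error_rate(pred, lab) == pytest.approx(0.10)

    def test_zero_misclassification_rejected(self):
        with pytest.raises(ValueError, match="larger reference"):
            baseline_error_rate(["younger"] * 50, ["younger"] * 50)

    def test_only_younger_cells_count(self):
        pred = ["older", "older", "younger", "older"]
        lab = ["younger", "younger", "younger", "older"]
        assert baseline_error_rate(pred, lab) == pytest.approx(2 / 3)

    def test_idempotent(self):
        pred = ["older"] * 3 + ["younger"] * 7
        lab = ["younger"] * 10
        assert baseline_error_rate(pred, lab) == \
            baseline_error_rate(pred, lab)


class TestRisq:
    def test_identity_at_baseline_rate(self):
        preds = ["older"] * 10 + ["younger"] * 90
        assert mechano_risq(preds, 0.10) == 1.0

    def test_threefold_elevation(self):
        preds = ["older"] * 30 + ["younger"] * 70
        assert mechano_risq(preds, 0.10) == pytest.approx(3.0)

    def test_zero_older_fraction(self):
        assert mechano_risq(["younger"] * 5, 0.10) == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mechano_risq([], 0.10)

    def test_linearity_in_older_fraction(self):
        b = 0.08
        one = mechano_risq(["older"] * 4 + ["younger"] * 96, b)
        three = mechano_risq(["older"] * 12 + ["younger"] * 88, b)
        assert three == pytest.approx(3 * one)


class TestCrawfordHowell:
    def test_case_at_mean_gives_t_zero(self):
        t, df, p = crawford_howell(3.0, [1, 2, 3, 4, 5])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_hand_computed_example(self):
        t, df, p = crawford_howell(6.0, [1, 2, 3, 4, 5])
        assert t == pytest.approx(1.7321, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.1583, abs=1e-3)

    def test_constant_normative_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            crawford_howell(1.0, [2.0, 2.0, 2.0])

    def test_tiny_normative_rejected(self):
        with pytest.raises(ValueError):
            crawford_howell(1.0, [2.0])

    def test_null_p_values_uniform(self):
        """Under the null the CH p-value is exactly U(0,1)."""
        rng = np.random.default_rng(17)
        n_sim, n_norm = 10_000, 10
        norm = rng.normal(size=(n_sim, n_norm))
        case = rng.normal(size=n_sim)
        ps = np.empty(n_sim)
        mean = norm.mean(axis=1)
        s = norm.std(axis=1, ddof=1)
        t = (case - mean) / (s * np.sqrt((n_norm + 1) / n_norm))
        ps = 2 * stats.t.sf(np.abs(t), n_norm - 1)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        # and the library call agrees with the vectorised oracle on one draw
        t0, _, p0 = crawford_howell(case[0], norm[0])
        assert p0 == pytest.approx(ps[0], rel=1e-12)

    @pytest.mark.parametrize("n_norm", [5, 10, 18])
    def test_type_one_error_calibrated(self, n_norm):
        power = ch_power_simulation(n_norm, cohens_d=0.0, iterations=10_000,
                                    seed=n_norm)
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(power - 0.05) < 2.576 * se  # binomial 99% CI

    def test_one_sided_alternative(self):
        _, _, p_two = crawford_howell(6.0, [1, 2, 3, 4, 5])
        _, _, p_gt = crawford_howell(6.0, [1, 2, 3, 4, 5],
                                     alternative="greater")
        assert p_gt == pytest.approx(p_two / 2)


class TestPower:
    def test_monotone_in_effect_size(self):
        powers = [ch_power_simulation(10, d, iterations=4000, seed=1)
                  for d in (0.0, 1.0, 2.0, 3.0)]
        assert all(a <= b + 0.02 for a, b in zip(powers, powers[1:]))

    def test_monotone_in_normative_size(self):
        powers = [ch_power_simulation(n, 2.0, iterations=4000, seed=2)
                  for n in (3, 6, 12, 24)]
        assert all(a <= b + 0.02 for a, b in zip(powers, powers[1:]))

    def test_few_iterations_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            ch_power_simulation(5, iterations=50, seed=1)


class TestBH:
    def test_hand_computed_triple(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_never_below_raw_and_order_preserved(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.random(40)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestGroupCompare:
    def test_identical_groups_large_p(self):
        p = group_compare([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p > 0.99

    def test_fully_separated_exact_p(self):
        # 2 / C(10,5) * ... : exact two-sided p = 2/252
        p = group_compare([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        assert group_compare(a, b) == pytest.approx(
            group_compare(np.exp(a), np.exp(b)))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])


class TestFisher:
    def test_balanced_table_p_one(self):
        assert perturbation_fisher([[10, 10], [10, 10]]) == 1.0

    def test_diagonal_table_hypergeometric_oracle(self):
        # P = 2 * C(10,10)C(10,0)/C(20,10) = 2/184756
        assert perturbation_fisher([[10, 0], [0, 10]]) == pytest.approx(
            2 / 184756, rel=1e-9)

    def test_row_swap_symmetry(self):
        assert perturbation_fisher([[8, 3], [2, 9]]) == pytest.approx(
            perturbation_fisher([[2, 9], [8, 3]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            perturbation_fisher([[1, -1], [2, 3]])


def test_risq_table_end_to_end():
    rng = np.random.default_rng(11)
    rows = []
    for donor, frac in [("HR1", 0.4), ("HR2", 0.35), ("AR9", 0.1)]:
        n = 100
        cls = np.where(rng.random(n) < frac, "older", "younger")
        rows.append(pd.DataFrame({"donor_id": donor, "class": cls}))
    preds = pd.concat(rows, ignore_index=True)
    meta = pd.DataFrame({"donor_id": ["HR1", "HR2", "AR9"],
                         "age": [30.0, 32.0, 29.0],
                         "risk_group": ["HR", "HR", "AR"]})
    normative = [0.8, 1.1, 0.9, 1.2, 1.0]
    table = risq_table(preds, meta, baseline=0.10, normative_risq=normative)
    assert set(table["sample_id"]) == {"HR1", "HR2", "AR9"}
    assert (table["p_adj"] >= table["p"] - 1e-15).all()
    hr1 = table.set_index("sample_id").loc["HR1"]
    assert hr1["risq"] == pytest.approx(hr1["p_older"] / 0.10)
    assert hr1["risq"] > table.set_index("sample_id").loc["AR9"]["risq"]
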