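"""Nested replicate statistics, comparative-Ct fold changes and EM
morphometry arithmetic.

The two-sample t oracle value below was computed by hand from the classic
pooled-variance formula on replicate means {1,2,3} vs {4,5,6}:
sp2 = 1, se = sqrt(2/3), t = (2-5)/se = -3.674, df = 4.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcvpipe.stats import ddct_fold_change, morphometry_derive, superplot_compare


def nested_frame(groups):
    rows = []
    for group, reps in groups.items():
        for rep, values in reps.items():
            rows += [
                {"group": group, "replicate": rep, "value": v} for v in values
            ]
    return pd.DataFrame(rows)


class TestSuperplotCompare:
    def test_identical_groups_give_t0_p1(self):
        data = nested_frame({
            "a": {1: [1.0, 2.0], 2: [3.0], 3: [2.0]},
            "b": {4: [1.0, 2.0], 5: [3.0], 6: [2.0]},
        })
        res = superplot_compare(data, "a", "b")
        assert res.t == 0.0
        assert res.p == 1.0

    def test_matches_hand_computed_two_sample_t(self):
        data = nested_frame({
            "a": {1: [1.0], 2: [2.0], 3: [3.0]},
            "b": {4: [4.0], 5: [5.0], 6: [6.0]},
        })
        res = superplot_compare(data, "a", "b")
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.grand_means == {"a": 2.0, "b": 5.0}

    def test_statistics_run_on_replicate_means_not_units(self):
        # unbalanced units must not change the result if replicate means agree
        a = nested_frame({
            "a": {1: [1.0], 2: [2.0], 3: [3.0]},
            "b": {4: [4.0], 5: [5.0], 6: [6.0]},
        })
        b = nested_frame({
            "a": {1: [0.5, 1.5], 2: [2.0] * 7, 3: [3.0]},
            "b": {4: [4.0], 5: [0.0, 10.0], 6: [6.0] * 3},
        })
        ra, rb = superplot_compare(a, "a", "b"), superplot_compare(b, "a", "b")
        assert rb.t == pytest.approx(ra.t)
        assert rb.p == pytest.approx(ra.p)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_unit_order(self, seed):
        rng = np.random.default_rng(seed)
        data = nested_frame({
            "a": {i: list(rng.normal(0, 1, 5)) for i in range(3)},
            "b": {i + 10: list(rng.normal(0.5, 1, 5)) for i in range(3)},
        })
        shuffled = data.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        r1, r2 = superplot_compare(data, "a", "b"), superplot_compare(shuffled, "a", "b")
        assert r2.t == pytest.approx(r1.t)

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(99)
        n_sims, hits = 400, 0
        for _ in range(n_sims):
            data = nested_frame({
                "a": {i: list(rng.normal(0, 1, 8)) for i in range(3)},
                "b": {i + 10: list(rng.normal(0, 1, 8)) for i in range(3)},
            })
            hits += superplot_compare(data, "a", "b").p < 0.05
        assert hits / n_sims == pytest.approx(0.05, abs=0.03)

    def test_single_replicate_group_rejected(self):
        data = nested_frame({"a": {1: [1.0]}, "b": {2: [2.0], 3: [3.0]}})
        with pytest.raises(ValueError):
            superplot_compare(data, "a", "b")


def ct_table(rows):
    return pd.DataFrame(rows, columns=["pair", "condition", "gene", "ct"])


class TestDdctFoldChange:
    def test_textbook_example_halves_expression(self):
        table = ct_table([
            (1, "ctrl", "Bdnf", 20.0), (1, "ctrl", "Gapdh", 15.0),
            (1, "ko", "Bdnf", 21.0), (1, "ko", "Gapdh", 15.0),
        ])
        res = ddct_fold_change(table, "Bdnf", "ctrl")
        assert res.per_pair["ddct"].iloc[0] == pytest.approx(1.0)
        assert res.per_pair["fold_change"].iloc[0] == pytest.approx(0.5)

    def test_reference_gene_against_itself_is_unity(self):
        table = ct_table([
            (p, cond, "Gapdh", ct)
            for p, cond, ct in [(1, "ctrl", 15.0), (1, "ko", 15.4),
                                (2, "ctrl", 14.8), (2, "ko", 15.1)]
        ])
        res = ddct_fold_change(table, "Gapdh", "ctrl")
        assert np.allclose(res.per_pair["fold_change"], 1.0)

    def test_identical_conditions_flagged_zero_variance(self):
        table = ct_table([
            (p, cond, g, ct)
            for p in (1, 2, 3)
            for cond in ("ctrl", "ko")
            for g, ct in (("Bdnf", 20.0), ("Gapdh", 15.0))
        ])
        res = ddct_fold_change(table, "Bdnf", "ctrl")
        assert np.allclose(res.per_pair["fold_change"], 1.0)
        assert res.t is None and res.p is None

    def test_incomplete_pair_dropped_with_warning(self):
        table = ct_table([
            (1, "ctrl", "Bdnf", 20.0), (1, "ctrl", "Gapdh", 15.0),
            (1, "ko", "Bdnf", 21.0), (1, "ko", "Gapdh", 15.0),
            (2, "ctrl", "Bdnf", 20.0), (2, "ko", "Bdnf", 21.0),  # no Gapdh
        ])
        with pytest.warns(UserWarning, match="dropped"):
            res = ddct_fold_change(table, "Bdnf", "ctrl")
        assert len(res.per_pair) == 1

    def test_monte_carlo_recovery_of_true_fold_change(self):
        rng = np.random.default_rng(17)
        true_fc = 0.7
        geo_means = []
        for _ in range(10):
            rows = []
            for p in range(8):
                dct_ctrl = rng.normal(5.0, 0.2)
                dct_ko = dct_ctrl - np.log2(true_fc) + rng.normal(0, 0.2)
                rows += [
                    (p, "ctrl", "Vgf", 15.0 + dct_ctrl), (p, "ctrl", "Gapdh", 15.0),
                    (p, "ko", "Vgf", 15.0 + dct_ko), (p, "ko", "Gapdh", 15.0),
                ]
            geo_means.append(ddct_fold_change(ct_table(rows), "Vgf", "ctrl").geometric_mean_fc)
        assert np.mean(geo_means) == pytest.approx(true_fc, abs=0.05)


class TestMorphometry:
    def test_printed_diameters_give_25pct_volume_decrease(self):
        out = morphometry_derive(d_control=71.52, d_test=65.01)
        assert round(out["volume_change_pct"]) == 25

    def test_printed_prevalences_give_30pct_relative_decrease(self):
        out = morphometry_derive(p_control=17.0, p_test=12.0)
        assert out["relative_change_pct"] == pytest.approx(29.41, abs=0.01)
        assert round(out["relative_change_pct"], -1) == 30

    def test_equal_diameters_no_volume_change(self):
        assert morphometry_derive(d_control=70.0, d_test=70.0)["volume_change_pct"] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(d=st.floats(min_value=1.0, max_value=200.0))
    def test_volume_change_strictly_decreasing_in_test_diameter(self, d):
        v1 = morphometry_derive(d_control=100.0, d_test=d)["volume_change_pct"]
        v2 = morphometry_derive(d_control=100.0, d_test=d + 1.0)["volume_change_pct"]
        assert v2 < v1

    def test_binned_fractions_use_half_open_bins(self):
        out = morphometry_derive(
            diameters=[40.0, 45.0, 49.9, 50.0, 65.0],
            bin_edges=[40, 50, 60, 70],
        )
        assert out["binned_fractions"][0] == pytest.approx(3 / 5)
        assert out["binned_fractions"][1] == pytest.approx(1 / 5)
        assert out["binned_fractions"][2] == pytest.approx(1 / 5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            morphometry_derive(d_control=0.0, d_test=50.0)
        with pytest.raises(ValueError):
            morphometry_derive()
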