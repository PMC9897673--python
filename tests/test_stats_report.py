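"""Proportion tables, normalization, CMH/Bonferroni, small-table statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import acinotrack as at
from acinotrack.stats_report import summarize_conditions
from conftest import simulate_null_calls


def _calls_frame(labels, experiment="e1", condition="c", well="w", interval=0):
    return pd.DataFrame(
        {
            "experiment": experiment,
            "condition": condition,
            "well": well,
            "interval": interval,
            "label": labels,
        }
    )


class TestProportions:
    def test_pure_well_fraction_one(self):
        table = at.proportions(_calls_frame(["round"] * 20))
        assert table.loc[0, "frac_round"] == 1.0
        assert table.loc[0, "n"] == 20

    def test_fractions_sum_to_one(self, rng):
        labels = rng.choice(["round", "spread", "tunnel"], 200)
        table = at.proportions(_calls_frame(list(labels)))
        total = table[["frac_round", "frac_spread", "frac_tunnel"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            at.proportions(_calls_frame(["round", "weird"]))

    def test_border_flagged_composites_excluded(self):
        calls = _calls_frame(["round"] * 5 + ["tunnel"] * 5)
        calls["touches_border"] = [False] * 5 + [True] * 5
        table = at.proportions(calls)
        assert table.loc[0, "n"] == 5
        assert table.loc[0, "frac_round"] == 1.0

    def test_multinomial_mixture_recovered(self):
        # 500 draws from (0.5, 0.3, 0.2): fractions within +-0.05 (~2 sd)
        rng = np.random.default_rng(1)
        labels = rng.choice(
            ["round", "spread", "tunnel"], size=500, p=[0.5, 0.3, 0.2]
        )
        table = at.proportions(_calls_frame(list(labels)))
        assert table.loc[0, "frac_round"] == pytest.approx(0.5, abs=0.05)
        assert table.loc[0, "frac_spread"] == pytest.approx(0.3, abs=0.05)
        assert table.loc[0, "frac_tunnel"] == pytest.approx(0.2, abs=0.05)


class TestNormalizeAndZscore:
    def test_control_wells_normalize_to_mean_one(self, rng):
        table = simulate_null_calls(rng, {"ctrl": (0.5, 0.3, 0.2)})
        long = at.normalize_and_zscore(table, "ctrl")
        means = long.groupby(["experiment", "interval", "class"])["normalized"].mean()
        assert np.allclose(means, 1.0, atol=1e-9)

    def test_zscores_standardized_within_groups(self, rng):
        table = simulate_null_calls(
            rng, {"ctrl": (0.5, 0.3, 0.2), "trt": (0.3, 0.3, 0.4)}
        )
        long = at.normalize_and_zscore(table, "ctrl")
        for _, g in long.groupby(["experiment", "class"]):
            z = g["z"].dropna()
            assert abs(z.mean()) < 1e-9
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_group_flagged_missing_not_infinite(self):
        table = at.proportions(
            pd.concat(
                [
                    _calls_frame(["round"] * 10, well="w1"),
                    _calls_frame(["round"] * 10, well="w2"),
                ]
            )
        )
        long = at.normalize_and_zscore(table, "c")
        assert long["z"].isna().all()  # sd = 0 everywhere
        assert not np.isinf(long["z"].fillna(0)).any()

    def test_missing_control_named_in_error(self, rng):
        table = simulate_null_calls(rng, {"trt": (0.5, 0.3, 0.2)})
        with pytest.raises(ValueError, match="ctrl"):
            at.normalize_and_zscore(table, "ctrl")

    def test_control_summary_z_near_zero_under_null(self, rng):
        table = simulate_null_calls(
            rng, {"ctrl": (0.5, 0.3, 0.2), "trt": (0.5, 0.3, 0.2)}
        )
        summary = summarize_conditions(at.normalize_and_zscore(table, "ctrl"))
        ctrl_z = summary[summary.condition == "ctrl"]["z"]
        assert abs(ctrl_z.mean()) < 0.5


class TestCMH:
    def test_single_stratum_equals_scaled_pearson(self):
        # CMH on one stratum is ((N-1)/N) * Pearson chi-square, exactly
        table = [[8, 2], [3, 6]]
        stat, p = at.cmh_test([table])
        chi2, _, _ = at.chi_square_2x2(table)
        assert stat == pytest.approx(chi2 * 18 / 19, rel=1e-12)
        assert stat == pytest.approx(4.009, abs=5e-4)
        assert p == pytest.approx(0.0452, abs=5e-4)

    def test_no_association_gives_unit_p(self):
        stat, p = at.cmh_test([[[10, 10], [10, 10]]])
        assert stat == 0.0
        assert p == 1.0

    def test_duplicated_strata_match_direct_formula(self):
        t = np.array([[8, 2], [3, 6]], dtype=float)
        stat2, _ = at.cmh_test([t, t])
        a, (r1, r2), (c1, c2), n = t[0, 0], t.sum(1), t.sum(0), t.sum()
        num = 2 * (a - r1 * c1 / n)
        var = 2 * r1 * r2 * c1 * c2 / (n**2 * (n - 1))
        assert stat2 == pytest.approx(num**2 / var, rel=1e-12)

    def test_matches_statsmodels_stratified_table(self, rng):
        from statsmodels.stats.contingency_tables import StratifiedTable

        tables = [
            rng.integers(1, 30, size=(2, 2)).astype(float) for _ in range(4)
        ]
        stat, p = at.cmh_test(tables)
        sm = StratifiedTable(np.stack(tables, axis=-1))
        res = sm.test_null_odds(correction=False)
        assert stat == pytest.approx(float(res.statistic), rel=1e-10)
        assert p == pytest.approx(float(res.pvalue), rel=1e-10)

    def test_degenerate_strata_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            stat, p = at.cmh_test([[[0, 0], [5, 5]], [[8, 2], [3, 6]]])
        ref, _ = at.cmh_test([[[8, 2], [3, 6]]])
        assert stat == ref

    def test_all_degenerate_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                at.cmh_test([[[0, 0], [5, 5]]])

    def test_type_one_error_controlled_on_null_studies(self):
        rng = np.random.default_rng(2024)
        mixtures = {"ctrl": (0.5, 0.3, 0.2), "trt": (0.5, 0.3, 0.2)}
        rejections = 0
        total = 0
        for _ in range(200):
            table = simulate_null_calls(rng, mixtures)
            res = at.cmh_by_class(table, "ctrl")
            rejections += int((res["p_adj"] < 0.05).sum())
            total += len(res)
        assert rejections / total <= 0.05

    def test_power_to_detect_tunnel_shift(self):
        # a 0.3 tunnel-fraction shift over 3 experiments x 3 wells x 100 acini
        rng = np.random.default_rng(7)
        mixtures = {"ctrl": (0.6, 0.3, 0.1), "trt": (0.3, 0.3, 0.4)}
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            table = simulate_null_calls(rng, mixtures)
            res = at.cmh_by_class(table, "ctrl")
            row = res[(res["class"] == "tunnel")]
            hits += int((row["p_adj"] < 0.05).all())
        assert hits / n_sim >= 0.90


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected", [(0.01, 5, 0.05), (0.5, 3, 1.0), (0.2, 1, 0.2)]
    )
    def test_examples(self, p, m, expected):
        assert at.bonferroni([p], m)[0] == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            at.bonferroni([1.5], 2)

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(ValueError):
            at.bonferroni([0.1, 0.2, 0.3], 2)

    @settings(deadline=None, max_examples=50)
    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=10),
        extra=st.integers(0, 5),
    )
    def test_adjusted_p_capped_and_ordered(self, p, extra):
        m = len(p) + extra
        adj = at.bonferroni(p, m)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= np.asarray(p) - 1e-12)


class TestChiSquare2x2:
    def test_metastasis_incidence_tables_reproduce_printed_p(self):
        chi2, p, _ = at.chi_square_2x2([[8, 2], [3, 6]])
        assert chi2 == pytest.approx(4.232, abs=5e-4)
        assert p == pytest.approx(0.0397, abs=5e-4)
        chi2, p, _ = at.chi_square_2x2([[7, 0], [5, 4]])
        assert p == pytest.approx(0.0417, abs=5e-4)

    def test_balanced_table_no_association(self):
        chi2, p, fisher_p = at.chi_square_2x2([[5, 5], [5, 5]])
        assert chi2 == 0.0
        assert p == 1.0
        assert fisher_p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            at.chi_square_2x2([[0, 0], [5, 5]])

    def test_contingency_dataclass_validates(self):
        with pytest.raises(ValueError):
            at.ContingencyTable2x2(-1, 2, 3, 4)
        t = at.ContingencyTable2x2(8, 2, 3, 6)
        chi2, p, _ = at.chi_square_2x2(t)
        assert p == pytest.approx(0.0397, abs=5e-4)

    def test_fisher_and_chi2_rank_evidence_consistently(self, rng):
        # on random null tables both tests should order evidence the same way
        ps_chi, ps_fisher = [], []
        for _ in range(500):
            t = rng.integers(1, 25, size=(2, 2))
            _, p, fp = at.chi_square_2x2(t)
            ps_chi.append(p)
            ps_fisher.append(fp)
        rho = sps.spearmanr(ps_chi, ps_fisher).statistic
        assert rho > 0.9


class TestHistoscore:
    @pytest.mark.parametrize(
        "weak, mod, strong, expected",
        [(100, 0, 0, 100), (0, 0, 100, 300), (20, 30, 10, 110), (0, 0, 0, 0)],
    )
    def test_examples(self, weak, mod, strong, expected):
        assert at.weighted_histoscore(weak, mod, strong) == expected

    def test_percentages_over_100_rejected(self):
        with pytest.raises(ValueError):
            at.weighted_histoscore(60, 30, 20)

    def test_negative_percentage_rejected(self):
        with pytest.raises(ValueError):
            at.weighted_histoscore(-1, 0, 0)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100))
    def test_score_bounded_0_300(self, a, b, c):
        total = a + b + c
        if total > 100:
            a, b, c = (100 * v / total for v in (a, b, c))
        score = at.weighted_histoscore(a, b, c)
        assert 0.0 <= score <= 300.0 + 1e-9


class TestPearson:
    def test_perfect_linear_correlation(self):
        x = np.arange(10.0)
        r, _ = at.pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = at.pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            at.pearson_r([1, 1, 1], [1, 2, 3])

    def test_p_matches_permutation_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r, p = at.pearson_r(x, y)
        perm_r = np.empty(10_000)
        for i in range(10_000):
            perm_r[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        perm_p = np.mean(np.abs(perm_r) >= abs(r) - 1e-12)
        assert p == pytest.approx(perm_p, abs=0.02)


class TestAreaTTest:
    def _areas(self, ctrl, trt):
        rows = []
        for i, v in enumerate(ctrl):
            rows.append(("ctrl", 0, v))
        for i, v in enumerate(trt):
            rows.append(("trt", 0, v))
        return pd.DataFrame(rows, columns=["condition", "interval", "mean_area_um2"])

    def test_identical_groups_unit_p(self):
        areas = self._areas([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = at.area_t_test(areas, "ctrl")
        assert res.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_symmetric_under_label_swap(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        p1 = at.area_t_test(self._areas(a, b), "ctrl").loc[0, "p"]
        p2 = at.area_t_test(self._areas(b, a), "ctrl").loc[0, "p"]
        assert p1 == pytest.approx(p2)

    def test_small_group_flagged_missing(self):
        res = at.area_t_test(self._areas([1.0], [1.0, 2.0, 3.0]), "ctrl")
        assert np.isnan(res.loc[0, "p"])

    def test_p_matches_permutation_oracle(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.8, 1, 10)
        res = at.area_t_test(self._areas(x, y), "ctrl")
        pooled = np.concatenate([x, y])
        t_obs = abs(sps.ttest_ind(y, x).statistic)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            count += abs(sps.ttest_ind(perm[:10], perm[10:]).statistic) >= t_obs - 1e-12
        assert res.loc[0, "p"] == pytest.approx(count / n_perm, abs=0.01)


class TestHeatmaps:
    def test_csv_round_trip_and_control_centering(self, rng, tmp_path):
        table = simulate_null_calls(
            rng, {"ctrl": (0.5, 0.3, 0.2), "trt": (0.5, 0.3, 0.2)}
        )
        long = at.normalize_and_zscore(table, "ctrl")
        summary = summarize_conditions(long)
        pvals = at.cmh_by_class(table, "ctrl")
        paths = at.export_heatmaps(summary, pvals, tmp_path / "hm")
        for cls, cls_paths in paths.items():
            z = pd.read_csv(cls_paths["z_csv"], index_col=0)
            expected = summary[summary["class"] == cls].pivot(
                index="condition", columns="interval", values="z"
            )
            assert np.allclose(
                z.to_numpy(dtype=float), expected.to_numpy(dtype=float),
                equal_nan=True,
            )
            assert cls_paths["p_png"].exists()

    def test_single_cell_matrices(self, tmp_path):
        summary = pd.DataFrame(
            {"condition": ["trt"], "class": ["round"], "interval": [0],
             "z": [0.5], "n_experiments": [3]}
        )
        pvals = pd.DataFrame(
            {"condition": ["trt"], "class": ["round"], "interval": [0],
             "cmh_stat": [1.0], "p": [0.3], "p_adj": [0.9]}
        )
        paths = at.export_heatmaps(summary, pvals, tmp_path, classes=("round",))
        z = pd.read_csv(paths["round"]["z_csv"], index_col=0)
        assert z.shape == (1, 1)
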