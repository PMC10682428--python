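import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from mirnorm import (
    BestMiRNormRanker,
    Combination,
    CombinationScore,
    default_weight_grid,
    enumerate_combinations,
    planted_spec,
    rank_combinations,
    run_bestmirnorm,
    score_combination,
    simulate_cq_dataset,
    two_sample_ks_statistic,
    weight_grid_scan,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracle: naive Python loops over subsets, targets
# and samples; shares no code with the implementation under test.


def brute_ks(x, y):
    pts = sorted(list(x) + list(y))
    best = 0.0
    for t in pts:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def brute_sd(values):
    m = sum(values) / len(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def brute_score(cq, members, targets, groups, control, case):
    ks_list, dev_list, sd_list = [], [], []
    for target in targets:
        per_group = {control: [], case: []}
        for s in cq.index:
            ref = sum(cq.loc[s, m] for m in members) / len(members)
            t_val = cq.loc[s, target]
            if any(math.isnan(cq.loc[s, m]) for m in members) or math.isnan(t_val):
                continue
            per_group[groups.loc[s]].append(t_val - ref)
        if len(per_group[control]) < 3 or len(per_group[case]) < 3:
            continue
        anchor = sum(per_group[control]) / len(per_group[control])
        vals = {g: [-(d - anchor) for d in per_group[g]] for g in per_group}
        ks_list.append(brute_ks(vals[control], vals[case]))
        dev_list.append(
            (
                abs(sum(vals[control]) / len(vals[control]))
                + abs(sum(vals[case]) / len(vals[case]))
            )
            / 2
        )
        sd_list.append((brute_sd(vals[control]) + brute_sd(vals[case])) / 2)
    if not ks_list:
        return None
    n = len(ks_list)
    return (sum(ks_list) / n, sum(dev_list) / n, sum(sd_list) / n)


def brute_rank(metric_rows, weights):
    """Rank combinations by weighted tie-averaged points, naive O(n^2)."""
    n_c = len(metric_rows)
    totals = [0.0] * n_c
    for m in range(3):
        vals = [row[m] for row in metric_rows]
        for i, v in enumerate(vals):
            smaller = sum(1 for u in vals if u < v)
            equal = sum(1 for u in vals if u == v)
            # average 0-based ascending rank over the tied block
            avg_rank = smaller + (equal - 1) / 2
            totals[i] += weights[m] * (n_c - 1 - avg_rank)
    return totals


# ---------------------------------------------------------------------------


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(1, 1), (3, 7), (4, 15), (7, 127)])
    def test_counts(self, n, expected):
        combos = enumerate_combinations([f"m{i}" for i in range(n)])
        assert len(combos) == expected

    def test_codes_bijective_bitmask(self):
        combos = enumerate_combinations(["A", "B", "C"])
        assert [c.code for c in combos] == list(range(1, 8))
        by_code = {c.code: c.members for c in combos}
        assert by_code[5] == ("A", "C")
        assert by_code[7] == ("A", "B", "C")
        # exhaustive bitmask cross-check
        for code, members in by_code.items():
            assert code == sum(2 ** "ABC".index(m) for m in members)

    def test_singleton_panel(self):
        combos = enumerate_combinations(["only"])
        assert len(combos) == 1 and combos[0].code == 1

    def test_empty_and_oversized(self):
        with pytest.raises(ValueError):
            enumerate_combinations([])
        with pytest.raises(ValueError, match="allow_large"):
            enumerate_combinations([f"m{i}" for i in range(12)])


class TestKSStatistic:
    @given(
        x=st.lists(st.floats(-5, 5), min_size=2, max_size=15),
        y=st.lists(st.floats(-5, 5), min_size=2, max_size=15),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_scipy(self, x, y):
        ours = two_sample_ks_statistic(np.array(x), np.array(y))
        assert ours == pytest.approx(ks_2samp(x, y).statistic, abs=1e-12)

    def test_disjoint_supports(self):
        assert two_sample_ks_statistic(np.array([0.0, 0.0]), np.array([-1.0, -3.0])) == 1.0


class TestScoreCombination:
    def test_singleton_self_target_all_zero(self, toy_cq, toy_groups):
        score = score_combination(
            toy_cq, ("A",), toy_groups, "HC", "AD", targets=["A"],
            min_group_size=2,
        )
        assert (score.ks_metric, score.dev_metric, score.sd_metric) == (0, 0, 0)

    def test_hand_computed_toy(self, toy_cq, toy_groups):
        """Combination {B}, targets {A,B}: target A gives D=1, dev 1,
        sd (0 + sqrt(2))/2; target B all zeros; metrics are target means."""
        score = score_combination(
            toy_cq, ("B",), toy_groups, "HC", "AD", targets=["A", "B"],
            min_group_size=2,
        )
        assert score.ks_metric == pytest.approx(0.5)
        assert score.dev_metric == pytest.approx(0.5)
        assert score.sd_metric == pytest.approx((0 + math.sqrt(2) / 2) / 2)
        assert score.n_targets == 2

    def test_identical_groups_ks_zero(self):
        cq = pd.DataFrame(
            {"A": [20.0, 21, 22, 20, 21, 22], "B": [18.0] * 6},
            index=list("abcdef"),
        )
        groups = pd.Series(["HC"] * 3 + ["AD"] * 3, index=cq.index)
        score = score_combination(cq, ("B",), groups, "HC", "AD")
        assert score.ks_metric == pytest.approx(0.0)

    def test_unknown_group_label_errors(self, toy_cq, toy_groups):
        with pytest.raises(ValueError, match="label"):
            score_combination(toy_cq, ("B",), toy_groups, "HC", "XX")

    def test_unevaluable_is_explicit(self, toy_cq, toy_groups):
        # only 2 samples per group -> every target dropped
        with pytest.warns(UserWarning):
            score = score_combination(toy_cq, ("B",), toy_groups, "HC", "AD",
                                      targets=["A"])
        assert not score.evaluable
        assert "unevaluable" in score.status


def make_scores(metric_rows):
    return [
        CombinationScore(
            Combination(members=(f"c{i}",), code=i + 1), ks, dev, sd, 1, 5, 5
        )
        for i, (ks, dev, sd) in enumerate(metric_rows)
    ]


class TestRankCombinations:
    def test_two_combination_example(self):
        table = rank_combinations(
            make_scores([(0.1, 0.1, 0.1), (0.2, 0.2, 0.2)]), (1, 1, 1)
        )
        first = table.iloc[0]
        assert first["code"] == 1
        assert (first["ks_points"], first["dev_points"], first["sd_points"]) == (1, 1, 1)
        assert first["total"] == 3
        assert table.iloc[1]["total"] == 0

    def test_strict_ordering_bottom_gets_zero_everywhere(self):
        rows = [(0.01 * i, 0.02 * i, 0.03 * i) for i in range(1, 16)]
        table = rank_combinations(make_scores(rows), (1, 1, 1))
        worst = table[table["final_rank"] == 15].iloc[0]
        assert (worst["ks_points"], worst["dev_points"], worst["sd_points"]) == (0, 0, 0)
        best = table[table["final_rank"] == 1].iloc[0]
        assert best["ks_points"] == 14

    def test_tie_averaging(self):
        rows = [(0.1, 1, 1), (0.1, 2, 2), (0.3, 3, 3)]
        table = rank_combinations(make_scores(rows), (1, 1, 1)).set_index("code")
        assert table.loc[1, "ks_points"] == pytest.approx(1.5)
        assert table.loc[2, "ks_points"] == pytest.approx(1.5)
        assert table.loc[3, "ks_points"] == 0

    def test_points_conservation(self):
        rng = np.random.default_rng(3)
        rows = [tuple(np.round(rng.random(3), 1)) for _ in range(20)]
        table = rank_combinations(make_scores(rows), (1, 1, 1))
        for col in ("ks_points", "dev_points", "sd_points"):
            assert table[col].sum() == pytest.approx(20 * 19 / 2)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(4)
        rows = [tuple(rng.random(3)) for _ in range(12)]
        t1 = rank_combinations(make_scores(rows), (1, 1, 1))
        t2 = rank_combinations(make_scores(rows), (2, 2, 2))
        assert t1["code"].tolist() == t2["code"].tolist()

    def test_matches_brute_force_totals(self):
        rng = np.random.default_rng(5)
        rows = [tuple(np.round(rng.random(3), 1)) for _ in range(10)]
        weights = (2.0, 1.0, 3.0)
        table = rank_combinations(make_scores(rows), weights).set_index("code")
        brute = brute_rank(rows, weights)
        for i, total in enumerate(brute):
            assert table.loc[i + 1, "total"] == pytest.approx(total)

    def test_all_equal_metric_warns_and_averages(self):
        with pytest.warns(UserWarning, match="degenerate"):
            table = rank_combinations(make_scores([(0.1, 1, 1), (0.1, 2, 2)]), (1, 0, 0))
        assert (table["ks_points"] == 0.5).all()

    def test_monotonicity_worsening_all_metrics_never_improves_rank(self):
        rng = np.random.default_rng(6)
        rows = [tuple(rng.random(3)) for _ in range(8)]
        table = rank_combinations(make_scores(rows), (1, 1, 1)).set_index("code")
        worsened = [tuple(np.array(r) + (0.5 if i == 2 else 0)) for i, r in enumerate(rows)]
        table2 = rank_combinations(make_scores(worsened), (1, 1, 1)).set_index("code")
        assert table2.loc[3, "final_rank"] >= table.loc[3, "final_rank"]


class TestOracleEquivalence:
    def test_full_pipeline_matches_brute_force(self):
        """For n=4 candidates and 20 samples, naive loops reproduce every
        combination score to 1e-12 and the identical final ranking."""
        rng = np.random.default_rng(42)
        n = 20
        idx = [f"S{i}" for i in range(n)]
        cands = ["w", "x", "y", "z"]
        cq = pd.DataFrame(
            {c: 24 + rng.normal(0, 0.5, n) for c in cands}, index=idx
        )
        cq.loc[idx[10:], "x"] += 1.0  # planted case shift on one candidate
        cq.iloc[3, 2] = np.nan  # and one missing value
        groups = pd.Series(["HC"] * 10 + ["AD"] * 10, index=idx)
        meta = pd.DataFrame({"group": groups})

        result = run_bestmirnorm(cq, meta=meta, candidates=cands)
        for score in result.scores:
            expected = brute_score(cq, score.combination.members, cands,
                                   groups, "HC", "AD")
            assert expected is not None
            assert score.ks_metric == pytest.approx(expected[0], abs=1e-12)
            assert score.dev_metric == pytest.approx(expected[1], abs=1e-12)
            assert score.sd_metric == pytest.approx(expected[2], abs=1e-12)

        # the naive O(n^2) ranking applied to the same metric values must
        # reproduce totals and the identical final ordering (ties included)
        metric_rows = [
            (s.ks_metric, s.dev_metric, s.sd_metric) for s in result.scores
        ]
        brute_totals = brute_rank(metric_rows, (1.0, 1.0, 1.0))
        table = result.rank_table.set_index("code")
        for code, total in zip((s.combination.code for s in result.scores),
                               brute_totals):
            assert table.loc[code, "total"] == pytest.approx(total, abs=1e-9)
        # identical final ordering under the same tie-breakers
        order = sorted(
            range(len(brute_totals)),
            key=lambda i: (
                -brute_totals[i],
                metric_rows[i][0],
                metric_rows[i][2],
                result.scores[i].combination.code,
            ),
        )
        expected_codes = [result.scores[i].combination.code for i in order]
        assert result.rank_table["code"].tolist() == expected_codes


class TestRunBestMiRNorm:
    def test_seven_candidates_gives_127_rows(self, small_dataset):
        result = run_bestmirnorm(small_dataset)
        assert len(result.rank_table) == 127
        assert len(result.code_table) == 127

    def test_planted_stable_set_recovered(self):
        ds = simulate_cq_dataset(planted_spec(seed=0))
        result = run_bestmirnorm(ds)
        assert result.best_combination == tuple(f"stable-{i}" for i in range(1, 6))

    def test_uniform_weight_scaling_identical_order(self, small_dataset):
        t1 = run_bestmirnorm(small_dataset, weights=(1, 1, 1)).rank_table
        t2 = run_bestmirnorm(small_dataset, weights=(2, 2, 2)).rank_table
        assert t1["code"].tolist() == t2["code"].tolist()

    def test_top_k_membership_matrix(self, small_dataset):
        result = run_bestmirnorm(small_dataset)
        mat = result.top_k_membership(10)
        assert mat.shape == (7, 10)
        top_members = set(result.best_combination)
        assert all(mat.loc[c, 1] == (c in top_members) for c in mat.index)

    def test_exclude_samples(self, small_dataset):
        excluded = small_dataset.sample_ids[:2]
        result = run_bestmirnorm(small_dataset, exclude_samples=excluded)
        assert result.scores[0].n_control + result.scores[0].n_case == 38

    def test_ranker_estimator_api(self, small_dataset):
        cands = list(small_dataset.panel.candidate_normalizers)
        est = BestMiRNormRanker(candidates=cands)
        est.fit(small_dataset.cq, small_dataset.meta["group"])
        assert est.n_combinations_ == 127
        assert set(est.best_combination_) <= set(cands)
        reference = est.transform(small_dataset.cq)
        assert list(reference.columns) == list(est.best_combination_)
        # get_params/set_params round trip (sklearn contract)
        params = est.get_params()
        assert params["control_label"] == "HC"
        est.set_params(weights=(2, 1, 1))
        assert est.get_params()["weights"] == (2, 1, 1)


class TestWeightGrid:
    def test_default_grid_is_25(self):
        grid = default_weight_grid()
        assert len(grid) == 25
        assert (2, 2, 2) not in grid and (3, 3, 3) not in grid
        assert (1, 1, 1) in grid

    def test_unit_grid_matches_plain_run(self, small_dataset):
        table, summary = weight_grid_scan(small_dataset, grid=[(1, 1, 1)], top_k=5)
        plain = run_bestmirnorm(small_dataset).rank_table.head(5)["code"].tolist()
        assert table.iloc[0]["top_codes"] == plain

    def test_stability_summary_counts(self, small_dataset):
        table, summary = weight_grid_scan(small_dataset, top_k=5)
        assert len(table) == 25
        assert summary.max() <= 25
        # every weighting contributes exactly top_k appearances
        assert summary.sum() == 25 * 5

    def test_empty_grid_errors(self, small_dataset):
        with pytest.raises(ValueError, match="empty"):
            weight_grid_scan(small_dataset, grid=[])
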