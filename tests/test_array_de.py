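"""Noise-floor filtering, differential expression, and sample clustering."""

import numpy as np
import pandas as pd
import pytest

from stressmyelin.array_de import (
    EmptyMatrixError,
    ExpressionMatrix,
    CategorySummary,
    cluster_samples,
    cut_clusters,
    cv_mean_profile,
    detect_noise_floor,
    differential_expression,
    filter_and_floor,
    signed_fold_change,
    summarize_categories,
)
from stressmyelin.synthetic import gen_expression


def _matrix(linear: np.ndarray, n_hc: int, n_csd: int, ids=None) -> ExpressionMatrix:
    samples = [f"HC_{i}" for i in range(n_hc)] + [f"CSD_{i}" for i in range(n_csd)]
    ids = ids or [f"f{i}" for i in range(len(linear))]
    return ExpressionMatrix(
        values=pd.DataFrame(np.log2(linear), index=ids, columns=samples),
        groups=pd.Series(["HC"] * n_hc + ["CSD"] * n_csd, index=samples),
    )


class TestCvMeanProfile:
    def test_constant_fragment_has_zero_cv(self):
        m = _matrix(np.array([[4.0, 4.0, 4.0, 4.0]]), 2, 2)
        assert cv_mean_profile(m)["cv"].iloc[0] == 0.0

    def test_hand_computed_mean_and_cv(self):
        # linear values [2, 8, 2, 8]: mean 5, sd sqrt(12), cv = sqrt(12)/5
        m = _matrix(np.array([[2.0, 8.0, 2.0, 8.0]]), 2, 2)
        prof = cv_mean_profile(m)
        assert prof["mean"].iloc[0] == pytest.approx(5.0)
        assert prof["cv"].iloc[0] == pytest.approx(np.sqrt(12.0) / 5.0)

    def test_cv_invariant_to_global_scaling(self, rng):
        lin = rng.lognormal(5, 1, (30, 6))
        a = cv_mean_profile(_matrix(lin, 3, 3))
        b = cv_mean_profile(_matrix(lin * 7.5, 3, 3))
        assert a["cv"].to_numpy() == pytest.approx(b["cv"].to_numpy())
        assert b["mean"].to_numpy() == pytest.approx(7.5 * a["mean"].to_numpy())


class TestDetectNoiseFloor:
    def test_recovers_generator_changepoint(self):
        m, truth = gen_expression(seed=11)
        prof = cv_mean_profile(m)
        res = detect_noise_floor(prof)
        step = (np.log2(prof["mean"].max()) - np.log2(prof["mean"].min())) / 39
        assert abs(np.log2(res.floor / truth["noise_floor"])) <= step
        assert res.n_discarded + res.n_kept == len(prof)
        assert res.floor in set(prof["mean"])

    def test_globally_flat_profile_floor_is_lowest_mean(self, rng):
        means = np.exp(rng.uniform(np.log(10), np.log(10000), 400))
        profile = pd.DataFrame({"mean": means, "cv": 0.1 + rng.normal(0, 1e-4, 400)})
        res = detect_noise_floor(profile)
        assert res.floor == means.min()

    def test_row_order_invariance(self):
        m, _ = gen_expression(seed=3)
        prof = cv_mean_profile(m)
        shuffled = prof.sample(frac=1.0, random_state=0)
        assert detect_noise_floor(prof).floor == detect_noise_floor(shuffled).floor

    def test_too_few_points_rejected(self):
        profile = pd.DataFrame({"mean": np.arange(1, 20.0), "cv": np.full(19, 0.1)})
        with pytest.raises(ValueError):
            detect_noise_floor(profile)


class TestFilterAndFloor:
    def test_fragment_below_floor_removed_and_survivors_floored(self):
        lin = np.array([[10.0, 20.0, 30.0, 40.0], [1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 1.0, 50.0]])
        out = filter_and_floor(_matrix(lin, 2, 2), floor=5.0)
        assert out.fragment_ids == ["f0", "f2"]
        # sub-floor entries replaced by exactly the floor (log2 is the stored scale)
        assert out.values.loc["f2"].tolist()[:3] == [np.log2(5.0)] * 3
        assert out.linear().loc["f2"].to_numpy() == pytest.approx([5.0, 5.0, 5.0, 50.0])

    def test_survivor_count_matches_row_wise_oracle(self, rng):
        lin = rng.lognormal(3, 2, (200, 8))
        floor = float(np.median(lin))
        out = filter_and_floor(_matrix(lin, 4, 4), floor)
        expected = sum(1 for row in lin if (row > floor).any())
        assert len(out.fragment_ids) == expected

    def test_idempotent(self, rng):
        lin = rng.lognormal(3, 2, (100, 6))
        once = filter_and_floor(_matrix(lin, 3, 3), 20.0)
        twice = filter_and_floor(once, 20.0)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_discarded_raises(self):
        with pytest.raises(EmptyMatrixError):
            filter_and_floor(_matrix(np.full((3, 4), 2.0), 2, 2), floor=10.0)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "log2fc,expected", [(1.0, 2.0), (0.0, 1.0), (-np.log2(1.75), -1.75)]
    )
    def test_convention(self, log2fc, expected):
        assert signed_fold_change(log2fc) == pytest.approx(expected)

    def test_round_trip_identity(self, rng):
        fc = rng.uniform(1.0, 8.0, 50) * rng.choice([-1.0, 1.0], 50)
        log2fc = np.where(fc >= 1, np.log2(np.abs(fc)), -np.log2(np.abs(fc)))
        assert signed_fold_change(log2fc) == pytest.approx(fc)


class TestDifferentialExpression:
    def test_identical_group_means_are_ns(self):
        lin = np.array([[8.0, 10.0, 8.0, 10.0]] * 2)
        table = differential_expression(_matrix(lin, 2, 2))
        assert (table["direction"] == "ns").all()

    def test_q_values_invariant_to_row_order(self):
        m, _ = gen_expression(n_fragments=300, n_myelin=30, seed=5)
        t1 = differential_expression(m)
        perm = m.values.sample(frac=1.0, random_state=1)
        t2 = differential_expression(ExpressionMatrix(values=perm, groups=m.groups))
        pd.testing.assert_series_equal(t1["q"].sort_index(), t2["q"].sort_index())

    def test_recovers_planted_effects(self):
        m, truth = gen_expression(effect_range=(-1.6, -1.6), seed=2)
        prof = cv_mean_profile(m)
        floor = detect_noise_floor(prof).floor
        ann = pd.Series({g: v["category"] for g, v in truth["genes"].items()})
        table = differential_expression(filter_and_floor(m, floor), annotation=ann)
        true_pos = {g for g, v in truth["genes"].items() if v["category"] == "myelin"}
        called = set(table.index[table["direction"] != "ns"])
        assert len(called & true_pos) / len(true_pos) >= 0.8
        assert len(called - true_pos) / max(1, len(called)) <= 0.10
        # down-regulation direction matches the planted sign
        assert (table.loc[sorted(called & true_pos), "direction"] == "down").all()

    def test_one_group_missing_rejected(self):
        samples = ["HC_0", "HC_1", "HC_2", "HC_3"]
        m = ExpressionMatrix(
            values=pd.DataFrame(np.ones((3, 4)), index=list("abc"), columns=samples),
            groups=pd.Series(["HC"] * 4, index=samples),
        )
        with pytest.raises(ValueError):
            differential_expression(m)


class TestSummarizeCategories:
    def test_printed_myelin_share(self):
        # 74 myelin-related of 108 down-regulated -> 69%
        assert CategorySummary.from_counts(34, 108, 74).pct_down_in_category == 69

    def test_no_down_regulated_pct_absent(self):
        assert CategorySummary.from_counts(5, 0, 0).pct_down_in_category is None

    def test_all_down_in_category_is_100(self):
        assert CategorySummary.from_counts(0, 12, 12).pct_down_in_category == 100

    def test_counts_from_de_table(self):
        table = pd.DataFrame(
            {
                "direction": ["down", "down", "down", "up", "ns"],
                "category": ["myelin", "myelin", "other", "myelin", "myelin"],
            }
        )
        s = summarize_categories(table)
        assert (s.n_up, s.n_down, s.n_down_in_category) == (1, 3, 2)
        assert s.pct_down_in_category == 67  # 66.67 rounds half-up to 67


class TestClusterSamples:
    def test_identical_samples_merge_first_at_zero_distance(self, rng):
        base = rng.normal(8, 1, 20)
        values = pd.DataFrame(
            {
                "HC_1": base,
                "HC_2": base,
                "CSD_1": base + rng.normal(0, 2, 20),
                "CSD_2": base + rng.normal(0, 2, 20),
            }
        )
        m = ExpressionMatrix(
            values=values,
            groups=pd.Series(
                {"HC_1": "HC", "HC_2": "HC", "CSD_1": "CSD", "CSD_2": "CSD"}
            ),
        )
        z = cluster_samples(m).linkage
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_linkage_matches_hand_computation(self):
        # A and B perfectly correlated (d=0), C and D likewise; ties break by
        # lowest index, and the final average-linkage merge height equals the
        # common cross-pair correlation distance d(A,C)
        values = pd.DataFrame(
            {
                "A": [1.0, 2.0, 3.0, 4.0],
                "B": [2.0, 4.0, 6.0, 8.0],
                "C": [4.0, 3.0, 2.0, 0.5],
                "D": [8.0, 6.0, 4.0, 1.0],
            }
        )
        groups = pd.Series({"A": "HC", "B": "HC", "C": "CSD", "D": "CSD"})
        m = ExpressionMatrix(values=values, groups=groups)
        arr = values.to_numpy().T
        d_ac = 1 - np.corrcoef(arr[0], arr[2])[0, 1]
        z = cluster_samples(m).linkage
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(z[1, 0]), int(z[1, 1])} == {2, 3}
        assert z[2, 2] == pytest.approx(d_ac)

    def test_strong_effects_separate_groups(self):
        m, truth = gen_expression(seed=8)
        table = differential_expression(m)
        sig = table.index[table["direction"] != "ns"]
        result = cluster_samples(m, genes=sig)
        labels = cut_clusters(result, 2)
        by_group = {
            g: {labels[s] for s in m.samples_of(g)} for g in ("HC", "CSD")
        }
        assert len(by_group["HC"]) == 1
        assert len(by_group["CSD"]) == 1
        assert by_group["HC"] != by_group["CSD"]

    def test_constant_sample_rejected(self):
        values = pd.DataFrame(
            {"A": [1.0, 1.0, 1.0], "B": [1, 2.0, 3.0], "C": [2, 1, 3.0], "D": [1, 3, 2.0]}
        )
        groups = pd.Series({"A": "HC", "B": "HC", "C": "CSD", "D": "CSD"})
        with pytest.raises(ValueError, match="constant"):
            cluster_samples(ExpressionMatrix(values=values, groups=groups))
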