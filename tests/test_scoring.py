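import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage

from _oracles import complete_linkage_bruteforce
from isoscreen import scoring, synthetic
from isoscreen.scoring import (
    InhibitionProfile,
    aggregate,
    build_profile,
    call_hits,
    cluster_profiles,
    efficacy_filter,
    i_score,
    score_screen,
    selectivity_class,
)


class TestIScore:
    @pytest.mark.parametrize(
        "signal, dmso, expected",
        [
            (1000, [900, 1000, 1100], 0.0),
            (0, [900, 1000, 1100], 100.0),
            (400, [1000, 1000], 60.0),
            (1200, [1000], -20.0),
        ],
    )
    def test_examples(self, signal, dmso, expected):
        assert i_score(signal, dmso) == pytest.approx(expected)

    def test_even_length_median_is_mean_of_central_two(self):
        assert i_score(500, [800, 1200]) == pytest.approx(50.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            i_score(100, [])
        with pytest.raises(ValueError):
            i_score(100, [0, 0, 0])
        with pytest.raises(ValueError):
            i_score(100, [-10, -5])

    @given(
        a=st.floats(0, 5, allow_nan=False),
        med=st.floats(1e-3, 1e6, allow_nan=False),
    )
    def test_affine_in_signal(self, a, med):
        # i_score(a * median) = (1 - a) * 100, for any positive median
        assert i_score(a * med, [med]) == pytest.approx((1.0 - a) * 100.0, abs=1e-6)

    @given(
        signal=st.floats(0, 2000, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_plate_rescaling_invariance(self, signal, scale):
        dmso = [900.0, 1000.0, 1100.0]
        before = i_score(signal, dmso)
        after = i_score(signal * scale, [d * scale for d in dmso])
        assert after == pytest.approx(before, abs=1e-8)

    def test_strictly_decreasing_in_signal(self):
        dmso = [1000.0]
        scores = [i_score(s, dmso) for s in np.linspace(0, 2000, 50)]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestAggregate:
    def make_scored(self, values, dose=1.0):
        return pd.DataFrame(
            {
                "plate_id": [f"p{i}" for i in range(len(values))],
                "well": ["A1"] * len(values),
                "cell_line": ["L"] * len(values),
                "compound": ["C"] * len(values),
                "dose_um": [dose] * len(values),
                "replicate": list(range(1, len(values) + 1)),
                "i_score": values,
            }
        )

    def test_triplicate_mean_and_sd(self):
        out = aggregate(self.make_scored([58.0, 60.0, 62.0]))
        assert out.loc[0, "i_score"] == pytest.approx(60.0)
        assert out.loc[0, "sd"] == pytest.approx(2.0)
        assert out.loc[0, "n_replicates"] == 3

    def test_single_replicate_sd_zero(self):
        out = aggregate(self.make_scored([60.0]))
        assert out.loc[0, "i_score"] == pytest.approx(60.0)
        assert out.loc[0, "sd"] == 0.0

    def test_order_of_averaging_matches_under_zero_noise(self, noiseless_config, three_line_truths):
        ds = synthetic.generate_single_dose_screen(noiseless_config, three_line_truths, [0.5])
        scored = score_screen(ds)
        per_well_then_mean = aggregate(scored)
        # signal-space average first, then a single i-score per group
        ctrl_med = ds.controls().groupby("plate_id")["luminescence"].median()
        treated = ds.treated()
        merged = treated.assign(norm=treated["luminescence"] / treated["plate_id"].map(ctrl_med))
        mean_signal = merged.groupby(["compound", "cell_line", "dose_um"])["norm"].mean()
        for (c, l, d), m in mean_signal.items():
            row = per_well_then_mean.query("compound == @c and cell_line == @l and dose_um == @d")
            assert row["i_score"].iloc[0] == pytest.approx((1 - m) * 100, abs=1e-9)


class TestHitCalling:
    panel = ["R158G", "WT", "NULL"]

    def profile(self, rows):
        mat = pd.DataFrame(rows, columns=self.panel)
        mat.index = [f"C{i}" for i in range(len(rows))]
        return InhibitionProfile(mat)

    @pytest.mark.parametrize(
        "row, efficacious",
        [([55, 10, 10], True), ([50, 50, 50], False), ([40, 45, 30], False)],
    )
    def test_efficacy_strict_threshold(self, row, efficacious):
        assert efficacy_filter(self.profile([row])).iloc[0] == efficacious

    @pytest.mark.parametrize(
        "row, expected",
        [
            ({"R158G": 60, "WT": 20, "NULL": 30}, "R158G_selective"),
            ({"R158G": 60, "WT": 60, "NULL": 60}, "pan_active"),
            ({"R158G": 60, "WT": 55, "NULL": 20}, "other_selective_pattern"),
            ({"R158G": 60, "WT": 50, "NULL": 20}, "other_selective_pattern"),
            ({"R158G": 20, "WT": 70, "NULL": 30}, "WT_selective"),
            ({"R158G": 10, "WT": 20, "NULL": 30}, "inactive"),
        ],
    )
    def test_selectivity_classes(self, row, expected):
        assert selectivity_class(row) == expected

    def test_classes_partition_hits(self):
        prof = self.profile([[60, 20, 20], [60, 60, 60], [60, 55, 20], [10, 10, 10]])
        calls = call_hits(prof)
        assert [c.selectivity_class for c in calls] == [
            "R158G_selective",
            "pan_active",
            "other_selective_pattern",
            "inactive",
        ]
        assert [c.efficacious for c in calls] == [True, True, True, False]


class TestClustering:
    def profile_from(self, rows, ids):
        mat = pd.DataFrame(rows, index=ids, columns=["x", "y"])
        return InhibitionProfile(mat)

    def test_identical_rows_merge_first_at_zero(self):
        res = cluster_profiles(self.profile_from([[1, 1], [5, 5], [1, 1]], ["a", "b", "c"]))
        left, right, h = res.merges[0]
        assert h == 0.0
        assert set(left + right) == {"a", "c"}

    def test_hand_computed_three_rows(self):
        # rows (0,0), (0,3), (10,10): first merge height 3 between the close
        # pair, then complete linkage max(sqrt(200), sqrt(149)) = sqrt(200)
        res = cluster_profiles(self.profile_from([[0, 0], [0, 3], [10, 10]], ["a", "b", "c"]))
        assert res.heights == pytest.approx([3.0, np.sqrt(200.0)])
        assert set(res.merges[0][0] + res.merges[0][1]) == {"a", "b"}

    def test_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(4)
        rows = rng.uniform(0, 100, size=(7, 2))
        ids = [f"c{i}" for i in range(7)]
        base = cluster_profiles(self.profile_from(rows, ids))
        perm = rng.permutation(7)
        permuted = cluster_profiles(self.profile_from(rows[perm], [ids[i] for i in perm]))
        assert sorted(base.heights) == pytest.approx(sorted(permuted.heights))

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_heights_match_bruteforce_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        X = rng.uniform(0, 100, size=(n, 3))
        mat = pd.DataFrame(X, index=[f"c{i}" for i in range(n)], columns=list("xyz"))
        res = cluster_profiles(InhibitionProfile(mat))
        assert res.heights == pytest.approx(complete_linkage_bruteforce(X))

    def test_heights_match_scipy_linkage(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 100, size=(12, 3))
        mat = pd.DataFrame(X, index=[f"c{i:02d}" for i in range(12)], columns=list("xyz"))
        res = cluster_profiles(InhibitionProfile(mat))
        Z = linkage(X, method="complete", metric="euclidean")
        assert sorted(res.heights) == pytest.approx(sorted(Z[:, 2].tolist()))

    def test_leaf_order_deterministic_and_complete(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 100, size=(6, 2))
        mat = pd.DataFrame(X, index=[f"c{i}" for i in range(6)], columns=list("xy"))
        a = cluster_profiles(InhibitionProfile(mat))
        b = cluster_profiles(InhibitionProfile(mat.copy()))
        assert a.leaf_order == b.leaf_order
        assert sorted(a.leaf_order) == sorted(mat.index)

    def test_nan_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]], index=["a", "b"], columns=["x", "y"])
        with pytest.raises(ValueError):
            InhibitionProfile(mat)

    def test_needs_two_compounds(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["x", "y"])
        with pytest.raises(ValueError):
            cluster_profiles(InhibitionProfile(mat))
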