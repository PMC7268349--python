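"""Element-level aggregation: Stouffer combination, control null, windows, FDR."""

import numpy as np
import pandas as pd
import pytest

from sortscreen import (
    NullModel,
    annotated_elements,
    bh_fdr,
    build_null_model,
    combine_replicates,
    element_significance,
    sliding_window_elements,
    stouffer_combine,
)
from sortscreen.elements import _enumerate_windows


class TestStoufferCombine:
    def test_examples(self):
        assert stouffer_combine([2, 2, 2, 2]) == pytest.approx(4.0)
        assert stouffer_combine([1.7]) == pytest.approx(1.7)
        assert stouffer_combine([1, -1]) == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stouffer_combine([])


class TestNullModel:
    def test_standard_normal_controls_give_unit_sd(self, rng):
        """Stouffer of k iid N(0,1) draws is N(0,1), so the null SD is ~1."""
        control_z = rng.standard_normal(500)
        null = build_null_model(control_z, [4], n_draws=10000, seed=5)
        assert null.sd(4) == pytest.approx(1.0, abs=0.05)

    def test_scaled_controls_scale_the_null(self, rng):
        control_z = 2.0 * rng.standard_normal(500)
        null = build_null_model(control_z, [5], n_draws=10000, seed=5)
        assert null.sd(5) == pytest.approx(2.0, abs=0.1)

    def test_identical_controls_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            build_null_model(np.full(20, 0.7), [4], seed=1)

    def test_pool_exhaustion_degenerate(self, rng):
        z = rng.standard_normal(8)
        with pytest.raises(ValueError, match="zero variance"):
            build_null_model(z, [8], resample_factor=1, n_draws=100, seed=1)

    def test_k_beyond_pool_rejected(self, rng):
        z = rng.standard_normal(5)
        with pytest.raises(ValueError, match="more negative control"):
            build_null_model(z, [51], resample_factor=10, seed=1)

    def test_missing_k_reported(self):
        null = NullModel(None, {5: 1.0})
        with pytest.raises(KeyError, match="7 guides"):
            null.sd(7)


class TestElementSignificance:
    def test_upper_tail(self):
        res = element_significance([1.0, 1.0, 1.0, 1.0], NullModel(None, {4: 1.0}))
        assert res["significance_z"] == pytest.approx(2.0)
        assert res["p_up"] == pytest.approx(0.02275, abs=1e-4)
        assert res["p_either"] == pytest.approx(2 * res["p_up"], rel=1e-12)

    def test_null_element_is_symmetric(self):
        res = element_significance([1.0, -1.0], NullModel(None, {2: 1.0}))
        assert res["p_up"] == pytest.approx(0.5)
        assert res["p_down"] == pytest.approx(0.5)
        assert res["p_either"] == pytest.approx(1.0)

    def test_lower_tail_with_scaled_null(self):
        # stouffer = -3 over null SD 1.5 -> significance -2
        z = [-3.0 / np.sqrt(3)] * 3
        res = element_significance(z, NullModel(None, {3: 1.5}))
        assert res["significance_z"] == pytest.approx(-2.0)
        assert res["p_down"] == pytest.approx(0.02275, abs=1e-4)


def _guide_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "guide_id",
            "experiment_id",
            "z_score",
            "is_negative_control",
            "element_label",
            "chrom",
            "pos",
        ],
    )


UNIT_NULL = NullModel(None, {k: 1.0 for k in range(1, 20)})


class TestAnnotatedElements:
    def test_arithmetic_and_grouping(self):
        rows = [(f"g{i}", "r1", 1.0, False, "E1", None, None) for i in range(5)]
        rows += [(f"c{i}", "r1", 0.0, True, None, None, None) for i in range(3)]
        out = annotated_elements(_guide_frame(rows), null_model=UNIT_NULL)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["effect_z"] == pytest.approx(1.0)
        assert row["stouffer_z"] == pytest.approx(np.sqrt(5))
        assert row["n_guides"] == 5

    def test_one_result_per_experiment(self):
        rows = [
            (f"g{i}", exp, 0.5, False, "E1", None, None)
            for exp in ("r1", "r2")
            for i in range(5)
        ]
        out = annotated_elements(_guide_frame(rows), null_model=UNIT_NULL)
        assert sorted(out["experiment_id"]) == ["r1", "r2"]

    def test_small_elements_filtered(self):
        rows = [(f"g{i}", "r1", 1.0, False, "E1", None, None) for i in range(4)]
        rows += [(f"h{i}", "r1", 1.0, False, "E2", None, None) for i in range(5)]
        out = annotated_elements(_guide_frame(rows), null_model=UNIT_NULL, min_guides=5)
        assert out["element_id"].tolist() == ["E2"]

    def test_fdr_at_least_p(self, mean_guide_results):
        out = annotated_elements(mean_guide_results, seed=3)
        for tail in ("up", "down", "either"):
            assert (out[f"fdr_{tail}"] >= out[f"p_{tail}"] - 1e-12).all()

    def test_guide_order_invariance(self, mean_guide_results):
        """Shuffling the guide table changes no element-level statistic."""
        shuffled = mean_guide_results.sample(frac=1.0, random_state=99).reset_index(
            drop=True
        )
        a = annotated_elements(mean_guide_results, seed=3)
        b = annotated_elements(shuffled, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestSlidingWindows:
    def test_single_full_window(self):
        rows = [
            (f"g{i}", "r1", 0.5, False, None, "chr1", 100 * (i + 1)) for i in range(5)
        ]
        out = sliding_window_elements(_guide_frame(rows), null_model=UNIT_NULL)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 100
        assert out.iloc[0]["end"] == 500

    def test_distant_guides_never_cowindowed(self):
        rows = [
            ("g1", "r1", 0.5, False, None, "chr1", 100),
            ("g2", "r1", 0.5, False, None, "chr1", 10_000),
        ]
        out = sliding_window_elements(
            _guide_frame(rows), min_guides=2, null_model=UNIT_NULL
        )
        assert out.empty

    def test_two_distinct_guide_sets(self):
        rows = [
            (f"g{i}", "r1", 0.5, False, None, "chr1", 100 * i) for i in range(6)
        ]
        out = sliding_window_elements(_guide_frame(rows), null_model=UNIT_NULL)
        assert len(out) == 2
        assert {(r["start"], r["end"]) for _, r in out.iterrows()} == {
            (0, 400),
            (100, 500),
        }

    def test_positions_required(self):
        rows = [(f"g{i}", "r1", 0.5, False, "E1", None, None) for i in range(5)]
        df = _guide_frame(rows).drop(columns=["chrom", "pos"])
        with pytest.raises(ValueError, match="annotated-element"):
            sliding_window_elements(df)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_enumeration(self, trial):
        """Window guide sets equal a naive O(n^2) scan over guide anchors."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 50))
        pos = np.sort(rng.integers(0, 3000, size=n)).astype(np.int64)
        ids = np.array([f"g{i}" for i in range(n)])
        window, min_guides = 500, 3

        fast = {
            frozenset(ids[m]) for m in _enumerate_windows(pos, ids, window, min_guides)
        }
        brute = set()
        for anchor in pos:
            members = frozenset(
                ids[j]
                for j in range(n)
                if anchor <= pos[j] < anchor + window
            )
            if len(members) >= min_guides:
                brute.add(members)
        assert fast == brute


class TestBhFdr:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5], atol=1e-12
        )

    def test_single_and_ties(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(37)
        # textbook step-up: sort, scale by m/rank, enforce monotonicity
        order = np.argsort(p)
        m = p.size
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)


class TestCombineReplicates:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["element_id", "experiment_id", "effect_z", "fdr_either"]
        )

    def test_consistent_up_call(self):
        df = self._frame([("E1", "r1", 0.3, 0.005), ("E1", "r2", 0.2, 0.005)])
        out = combine_replicates(df)
        assert out["element_id"].tolist() == ["E1"]
        assert out.iloc[0]["direction"] == "up"

    def test_one_failing_replicate_blocks_call(self):
        df = self._frame([("E1", "r1", 0.3, 0.005), ("E1", "r2", 0.2, 0.5)])
        with pytest.warns(UserWarning):
            assert combine_replicates(df).empty

    def test_sign_conflict_blocks_call(self):
        df = self._frame([("E1", "r1", 0.3, 0.005), ("E1", "r2", -0.2, 0.005)])
        with pytest.warns(UserWarning):
            assert combine_replicates(df).empty

    def test_disjoint_elements_warn_empty(self):
        df = self._frame([("E1", "r1", 0.3, 0.005), ("E2", "r2", 0.2, 0.005)])
        with pytest.warns(UserWarning):
            assert combine_replicates(df).empty
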