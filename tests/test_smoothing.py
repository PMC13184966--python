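import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_swis
from swismooth import (
    CellTable,
    SmoothingParams,
    assign_window,
    enumerate_windows,
    fovs_smooth,
    local_knn_estimates,
    scale_scores,
    swis_smooth,
)
from swismooth.errors import EmptyInputError, InvalidBoundsError, PreconditionError
from tests_util import make_table


class TestScaleScores:
    def test_endpoints_and_midpoint(self):
        np.testing.assert_allclose(scale_scores([0, 5, 10]), [-1, 0, 1])

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(scale_scores([7, 7, 7]), [0, 0, 0])

    def test_empty_is_error(self):
        with pytest.raises(EmptyInputError):
            scale_scores([])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=100, unique=True))
    def test_rank_order_preserved_and_range_hit(self, values):
        out = scale_scores(values)
        assert out.min() == -1 and out.max() == 1
        # order-preserving: sorting by input sorts the output (weakly, since
        # the affine map may merge values separated by less than one ulp)
        assert np.all(np.diff(out[np.argsort(values)]) >= 0)


class TestEnumerateWindows:
    def test_manual_enumeration_of_loop_rule(self):
        params = SmoothingParams(width=1000, height=1000, stride=500, padding=100, n_min=1, k=1)
        origins = enumerate_windows((0, 2000, 0, 1000), params)
        assert sorted({o[0] for o in origins}) == [0, 500, 1000]
        assert sorted({o[1] for o in origins}) == [0]

    def test_window_larger_than_tissue_clamps_to_single_origin(self):
        params = SmoothingParams(width=1000, height=1000, stride=500, padding=100, n_min=1, k=1)
        origins = enumerate_windows((0, 900, 0, 900), params)
        assert origins == [(0.0, 0.0)]

    def test_inverted_bounds_rejected(self):
        with pytest.raises(InvalidBoundsError):
            enumerate_windows((10, 0, 0, 10), SmoothingParams())

    def test_union_of_cores_covers_interior(self, rng):
        """Probe points deeper than the padding from the hull must fall in >=1 core."""
        for _ in range(10):
            xmax = float(rng.uniform(500, 3000))
            ymax = float(rng.uniform(500, 3000))
            width = float(rng.uniform(200, 1500))
            height = float(rng.uniform(200, 1500))
            padding = float(rng.uniform(0, 80))
            stride = float(rng.uniform(50, min(width, height) - 2 * padding))
            params = SmoothingParams(
                width=width, height=height, stride=stride, padding=padding, n_min=1, k=1
            )
            origins = enumerate_windows((0, xmax, 0, ymax), params)
            gx = np.linspace(padding + 1e-6, xmax - padding - 1e-6, 25)
            gy = np.linspace(padding + 1e-6, ymax - padding - 1e-6, 25)
            for px in gx:
                for py in gy:
                    assert any(
                        x0 + padding <= px < x0 + width - padding
                        and y0 + padding <= py < y0 + height - padding
                        for x0, y0 in origins
                    ), (px, py, params)


class TestAssignWindow:
    PARAMS = SmoothingParams(width=10, height=10, stride=5, padding=2, n_min=1, k=1)

    def _table(self, coords):
        return make_table(np.asarray(coords, float), np.zeros(len(coords)))

    def test_cell_at_origin_is_member(self):
        win = assign_window(self._table([(0.0, 0.0)]), (0.0, 0.0), self.PARAMS)
        assert list(win.member_idx) == [0]

    def test_cell_in_padding_band_is_member_not_core(self):
        win = assign_window(self._table([(1.0, 5.0)]), (0.0, 0.0), self.PARAMS)
        assert list(win.member_idx) == [0] and list(win.core_idx) == []

    def test_matches_per_cell_predicates_on_random_instance(self, rng):
        coords = rng.uniform(-5, 15, size=(200, 2))
        table = self._table(coords)
        win = assign_window(table, (0.0, 0.0), self.PARAMS)
        member = [
            i for i, (x, y) in enumerate(coords) if 0 <= x < 10 and 0 <= y < 10
        ]
        core = [
            i for i, (x, y) in enumerate(coords) if 2 <= x < 8 and 2 <= y < 8
        ]
        assert list(win.member_idx) == member
        assert list(win.core_idx) == core


class TestLocalKnnEstimates:
    def test_constant_scores_give_constant_estimates(self, rng):
        xy = rng.uniform(0, 10, size=(30, 2))
        scores = np.full(30, 0.42)
        idx, vals, _ = local_knn_estimates(xy, scores, np.arange(30), np.arange(30), k=5)
        np.testing.assert_allclose(vals, 0.42)

    def test_hand_knn_on_collinear_points(self):
        xy = np.column_stack([np.arange(6.0), np.zeros(6)])
        scores = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        idx, vals, _ = local_knn_estimates(xy, scores, np.array([2]), np.arange(6), k=2)
        assert list(idx) == [2]
        assert vals[0] == pytest.approx((0.0 + 1.0) / 2)  # neighbours at x=1 and x=3

    def test_matches_all_pairs_oracle(self, rng):
        xy = rng.uniform(0, 100, size=(300, 2))
        scores = rng.uniform(-1, 1, 300)
        core = np.sort(rng.choice(300, 80, replace=False))
        idx, vals, _ = local_knn_estimates(xy, scores, core, np.arange(300), k=5)
        for ci, v in zip(idx, vals):
            d = np.hypot(xy[:, 0] - xy[ci, 0], xy[:, 1] - xy[ci, 1])
            d[ci] = np.inf
            expect = scores[np.argsort(d, kind="stable")[:5]].mean()
            assert v == expect

    def test_under_k_uses_all_available_and_counts(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        scores = np.array([0.0, 1.0, 0.5])
        idx, vals, under = local_knn_estimates(xy, scores, np.arange(3), np.arange(3), k=10)
        assert under == 3
        assert vals[0] == pytest.approx((1.0 + 0.5) / 2)

    def test_singleton_pool_yields_no_estimate(self):
        xy = np.array([[0.0, 0.0]])
        idx, vals, _ = local_knn_estimates(xy, np.array([0.3]), np.array([0]), np.array([0]), k=1)
        assert len(idx) == 0


class TestSwisSmooth:
    def test_paper_default_parameters_accepted(self):
        p = SmoothingParams()
        assert (p.width, p.height, p.stride, p.padding, p.n_min, p.k) == (1000, 1000, 500, 100, 50, 5)

    def test_constant_field_fixed_point(self, rng):
        table = make_table(rng.uniform(0, 300, size=(400, 2)), np.full(400, 0.37))
        res = swis_smooth(table, SmoothingParams(width=100, height=100, stride=50, padding=10, n_min=5, k=3))
        np.testing.assert_allclose(res.df["score_smoothed"], 0.37)

    def test_missing_scaled_scores_rejected(self, rng):
        df = pd.DataFrame(
            {"cell_id": ["a", "b"], "x": [0.0, 1.0], "y": [0.0, 1.0], "score_raw": [0.0, 1.0]}
        )
        with pytest.raises(PreconditionError, match="score_scaled"):
            swis_smooth(CellTable(df), SmoothingParams())

    def test_matches_brute_force_on_random_instance(self, rng):
        xy = np.column_stack([rng.uniform(0, 800, 1000), rng.uniform(0, 600, 1000)])
        scores = rng.uniform(-1, 1, 1000)
        params = dict(width=250, height=200, stride=120, padding=25, n_min=8, k=5)
        res = swis_smooth(make_table(xy, scores), SmoothingParams(**params))
        exp_s, exp_n, exp_cov = brute_force_swis(xy, scores, **params)
        np.testing.assert_array_equal(res.df["score_smoothed"].to_numpy(), exp_s)
        np.testing.assert_array_equal(res.df["n_estimates"].to_numpy(), exp_n)
        np.testing.assert_array_equal(res.df["covered"].to_numpy(), exp_cov)

    def test_range_preservation_for_covered_cells(self, rng):
        xy = rng.uniform(0, 500, size=(800, 2))
        scores = rng.uniform(-1, 1, 800)
        res = swis_smooth(
            make_table(xy, scores),
            SmoothingParams(width=150, height=150, stride=75, padding=15, n_min=5, k=4),
        )
        cov = res.df["covered"]
        assert res.df.loc[cov, "score_smoothed"].between(scores.min(), scores.max()).all()

    def test_permutation_equivariance(self, rng):
        xy = rng.uniform(0, 400, size=(300, 2))
        scores = rng.uniform(-1, 1, 300)
        params = SmoothingParams(width=150, height=150, stride=80, padding=20, n_min=5, k=3)
        base = swis_smooth(make_table(xy, scores), params)
        perm = rng.permutation(300)
        permuted = swis_smooth(make_table(xy[perm], scores[perm], ids=perm), params)
        merged = permuted.df.set_index("cell_id").loc[base.df["cell_id"]]
        np.testing.assert_array_equal(
            merged["score_smoothed"].to_numpy(), base.df["score_smoothed"].to_numpy()
        )

    def test_estimate_count_bounded_by_window_overlap(self, rng):
        """With width = 2 x stride, any point lies in <= 4 window cores."""
        xy = np.column_stack([rng.uniform(0, 3500, 4000), rng.uniform(0, 2500, 4000)])
        scores = rng.uniform(-1, 1, 4000)
        res = swis_smooth(make_table(xy, scores), SmoothingParams(n_min=1))
        assert res.df["n_estimates"].max() <= 4

    def test_exclude_policy_drops_uncovered(self, rng):
        xy = rng.uniform(0, 200, size=(200, 2))
        scores = rng.uniform(-1, 1, 200)
        params = SmoothingParams(
            width=100, height=100, stride=50, padding=20, n_min=3, k=3, uncovered_policy="exclude"
        )
        res = swis_smooth(make_table(xy, scores), params)
        assert res.df["covered"].all()
        assert len(res.df) == res.n_covered <= 200


class TestFovsSmooth:
    def test_missing_fov_column_rejected(self, small_table):
        with pytest.raises(PreconditionError, match="fov_id"):
            fovs_smooth(small_table, k=3)

    def test_single_fov_constant_scores(self, rng):
        table = make_table(rng.uniform(0, 50, size=(60, 2)), np.full(60, 0.8))
        table = table.with_columns(fov_id="F0")
        res = fovs_smooth(table, k=50)
        np.testing.assert_allclose(res.df["score_smoothed"], 0.8)
        assert (res.df["n_estimates"] == 1).all()

    def test_cosmx_default_k(self):
        from swismooth.smoothing import COSMX_FOV_K

        assert COSMX_FOV_K == 50

    def test_equals_per_fov_swis_with_single_window(self, rng):
        """FoVS reduces to SWiS run per FOV with padding 0 and one all-covering window."""
        n = 450
        xy = np.column_stack([rng.uniform(0, 900, n), rng.uniform(0, 300, n)])
        scores = rng.uniform(-1, 1, n)
        fov = np.minimum((xy[:, 0] // 300).astype(int), 2)
        table = make_table(xy, scores).with_columns(fov_id=[f"F{f}" for f in fov])
        res = fovs_smooth(table, k=7, n_min=1)
        for f in range(3):
            mask = fov == f
            sub = make_table(xy[mask], scores[mask], ids=np.flatnonzero(mask))
            xmin, xmax, ymin, ymax = sub.bounds()
            params = SmoothingParams(
                width=(xmax - xmin) * 2 + 1,
                height=(ymax - ymin) * 2 + 1,
                stride=(xmax - xmin) * 2 + 1,
                padding=0,
                n_min=1,
                k=7,
            )
            sub_res = swis_smooth(sub, params)
            np.testing.assert_array_equal(
                res.df.loc[mask, "score_smoothed"].to_numpy(),
                sub_res.df["score_smoothed"].to_numpy(),
            )

    def test_small_fov_skipped_under_nmin(self, rng):
        xy = np.vstack([rng.uniform(0, 50, size=(40, 2)), [[100.0, 100.0]]])
        scores = np.concatenate([rng.uniform(-1, 1, 40), [0.9]])
        table = make_table(xy, scores).with_columns(fov_id=["A"] * 40 + ["B"])
        res = fovs_smooth(table, k=5, n_min=5)
        assert res.n_windows_skipped == 1
        assert res.df.loc[40, "score_smoothed"] == 0.9  # fallback to scaled score
        assert not res.df.loc[40, "covered"]
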