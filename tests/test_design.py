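import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pellethglm as ph
from pellethglm.design import PlacementError, VEGETATION_CLASSES

from conftest import lattice_units


class TestLocalGrid:
    def test_900m_square_gives_4_by_10(self):
        plots = ph.generate_local_grid(0.0, 0.0, 450.0, 300.0, 100.0)
        assert len(plots) == 40
        xs = sorted({p.x for p in plots})
        ys = sorted({p.y for p in plots})
        assert len(xs) == 4 and len(ys) == 10
        assert np.allclose(np.diff(xs), 300.0)
        assert np.allclose(np.diff(ys), 100.0)

    def test_zero_extent_gives_single_center_plot(self):
        plots = ph.generate_local_grid(10.0, -5.0, 0.0)
        assert len(plots) == 1
        assert plots[0].x == 10.0 and plots[0].y == -5.0

    @pytest.mark.parametrize("bad", [{"transect_spacing": 0.0},
                                     {"plot_spacing": -10.0},
                                     {"half_extent": -1.0}])
    def test_invalid_arguments_raise(self, bad):
        kwargs = {"half_extent": 100.0}
        kwargs.update(bad)
        with pytest.raises(ValueError):
            ph.generate_local_grid(0.0, 0.0, **kwargs)

    @given(half_extent=st.floats(0.0, 3000.0),
           ts=st.floats(50.0, 800.0), ps=st.floats(25.0, 400.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_count_matches_lattice_enumeration(self, half_extent, ts, ps):
        plots = ph.generate_local_grid(0.0, 0.0, half_extent, ts, ps)
        side = 2.0 * half_extent
        # brute-force enumeration of lattice points inside the extent
        n_t = len([k for k in range(10_000) if k * ts <= side + 1e-9])
        n_p = len([k for k in range(10_000) if k * ps <= side + 1e-9])
        assert len(plots) == n_t * n_p == (int(side / ts) + 1) * (int(side / ps) + 1)


class TestRegionalSquares:
    def test_default_layout_580_plots(self):
        plots = ph.generate_regional_squares(seed=0)
        assert len(plots) == 29 * 20
        # corners not double-counted: every square has exactly 20 distinct plots
        df = pd.DataFrame([(p.plot_id.rsplit("-", 2)[1], p.x, p.y) for p in plots],
                          columns=["sq", "x", "y"])
        assert (df.groupby("sq").size() == 20).all()
        assert not df.duplicated(["x", "y"]).any()

    def test_single_square_traces_perimeter(self):
        plots = ph.generate_regional_squares(n_squares=1, seed=1)
        assert len(plots) == 20
        xy = np.array([(p.x, p.y) for p in plots])
        # all plots on the square boundary: max coordinate offset == side/2
        c = xy.mean(axis=0)
        assert np.allclose(np.abs(xy - c).max(axis=1), 500.0)

    def test_min_separation_enforced(self):
        plots = ph.generate_regional_squares(n_squares=8, seed=2)
        df = pd.DataFrame([(p.plot_id.rsplit("-", 2)[1], p.x, p.y) for p in plots],
                          columns=["sq", "x", "y"])
        for a in df["sq"].unique():
            for b in df["sq"].unique():
                if a >= b:
                    continue
                pa = df.loc[df.sq == a, ["x", "y"]].to_numpy()
                pb = df.loc[df.sq == b, ["x", "y"]].to_numpy()
                d = np.sqrt(((pa[:, None] - pb[None]) ** 2).sum(-1)).min()
                assert d >= 1400.0 - 1e-9

    def test_infeasible_packing_raises(self):
        with pytest.raises(PlacementError):
            ph.generate_regional_squares(n_squares=200, region_radius=2000.0,
                                         min_separation=1400.0, seed=0,
                                         max_attempts=2000)

    def test_reproducible_from_seed(self):
        a = ph.generate_regional_squares(n_squares=4, seed=7)
        b = ph.generate_regional_squares(n_squares=4, seed=7)
        assert [(p.x, p.y) for p in a] == [(p.x, p.y) for p in b]


class TestAdjacency:
    def test_threshold_is_inclusive(self):
        units = pd.DataFrame({
            "plot_id": ["a", "b", "c", "d"],
            "x": [0.0, 100.0, 450.0, 801.0],
            "y": 0.0, "year": 2010,
        })
        adj = ph.build_adjacency(units)
        m = adj.matrix.toarray()
        assert m[0, 1] == 1          # 100 m apart
        assert m[1, 2] == 1          # exactly 350 m: inclusive rule
        assert m[2, 3] == 0          # 351 m
        assert m[0, 2] == 0          # 450 m
        assert np.all(np.diag(m) == 0)

    def test_year_blocking(self):
        units = pd.DataFrame({
            "plot_id": ["a", "a", "b", "b"],
            "x": [0.0, 0.0, 100.0, 100.0],
            "y": 0.0,
            "year": [2010, 2011, 2010, 2011],
        })
        adj = ph.build_adjacency(units)
        m = adj.matrix.toarray()
        assert m[0, 2] == 1 and m[1, 3] == 1      # same-year neighbors
        assert m[0, 1] == 0 and m[0, 3] == 0      # cross-year never
        pooled = ph.build_adjacency(units.assign(plot_id=["a", "c", "b", "d"]),
                                    block_by_year=False)
        assert pooled.matrix.toarray()[0, 1] == 1  # cross-year allowed when pooled

    def test_duplicate_units_raise(self):
        units = pd.DataFrame({"plot_id": ["a", "a"], "x": [0.0, 10.0],
                              "y": 0.0, "year": 2010})
        with pytest.raises(ValueError, match="duplicate"):
            ph.build_adjacency(units)

    def test_random_designs_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            units = pd.DataFrame({
                "plot_id": [f"p{i}" for i in range(n)],
                "x": rng.uniform(0, 2000, n), "y": rng.uniform(0, 2000, n),
                "year": rng.integers(2010, 2013, n),
            })
            adj = ph.build_adjacency(units)
            m = adj.matrix
            assert (m != m.T).nnz == 0
            assert np.all(m.diagonal() == 0)
            assert set(np.unique(m.toarray())) <= {0.0, 1.0}


class TestSqrtDistance:
    @pytest.mark.parametrize("d,expected", [(100.0, 1.0), (400.0, 2.0), (0.0, 0.0)])
    def test_examples(self, d, expected):
        assert ph.sqrt_distance_covariate(d) == pytest.approx(expected)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            ph.sqrt_distance_covariate(-1.0)

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=20))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_monotone(self, ds):
        ds = sorted(ds)
        vals = [ph.sqrt_distance_covariate(d) for d in ds]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestVIF:
    def test_orthogonal_columns_all_one(self):
        # centered then orthonormalized columns: mutually orthogonal and
        # orthogonal to the intercept, so every auxiliary R^2 is exactly 0
        A = np.random.default_rng(0).normal(size=(30, 4))
        A = A - A.mean(axis=0)
        X = np.linalg.qr(A)[0]
        out = ph.compute_vif(X)
        assert np.allclose(out["vif"], 1.0, atol=1e-8)
        assert not out["flagged"].any()

    def test_correlation_08_closed_form(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        b /= b.std()
        y = 0.8 * a + 0.6 * b  # sample correlation with a exactly 0.8
        out = ph.compute_vif(np.column_stack([a, y]))
        assert np.allclose(out["vif"], 1.0 / (1.0 - 0.64), atol=1e-8)
        assert not out["flagged"].any()

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        out = ph.compute_vif(np.column_stack([x, x, rng.normal(size=50)]))
        assert np.isinf(out["vif"].iloc[0]) and np.isinf(out["vif"].iloc[1])
        assert out["flagged"].iloc[0] and out["flagged"].iloc[1]

    def test_agrees_with_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        for p in (3, 6, 10):
            base = rng.normal(size=(80, p))
            base[:, 0] += 0.7 * base[:, 1]  # induce collinearity
            mine = ph.compute_vif(base)["vif"].to_numpy()
            oracle = []
            for j in range(p):
                others = sm.add_constant(np.delete(base, j, axis=1))
                r2 = sm.OLS(base[:, j], others).fit().rsquared
                oracle.append(1.0 / (1.0 - r2))
            assert np.allclose(mine, oracle, rtol=1e-10, atol=1e-10)

    def test_shape_preconditions(self):
        with pytest.raises(ValueError):
            ph.compute_vif(np.ones((10, 1)))
        with pytest.raises(ValueError):
            ph.compute_vif(np.ones((3, 5)))


class TestClassMerge:
    MAPPING = {"bog": "mire", "fen": "mire", "pine": "forest", "cut1": "clear_cut"}

    def test_identity_of_mapping(self):
        assert ph.apply_class_merge("bog", self.MAPPING) == "mire"
        assert ph.apply_class_merge("pine", self.MAPPING) == "forest"

    def test_unmapped_code_raises(self):
        with pytest.raises(KeyError, match="unmapped"):
            ph.apply_class_merge("lake", self.MAPPING)

    def test_sixth_label_is_configuration_error(self):
        bad = dict(self.MAPPING, water="lake_class")
        with pytest.raises(ValueError, match="outside the merged domain"):
            ph.apply_class_merge("bog", bad)

    def test_output_domain_closed(self):
        assert set(self.MAPPING.values()) <= set(VEGETATION_CLASSES)
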