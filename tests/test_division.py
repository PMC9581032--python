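import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dyncubeprod as dcp
from dyncubeprod.core import ContractError, Cube, FeasibilityGrid

from conftest import random_params


class TestCubeBounds:
    def test_root_cube_is_whole_space(self, toy_maxima):
        box = dcp.cube_bounds(toy_maxima, 0, 1, 1, 1)
        assert box.gr == (0.0, 3.0)
        assert box.pr == (0.0, 3.0)
        assert box.sf == (0.0, 26.0)  # SF axis spans twice TMSF

    def test_level_one_first_cube(self, toy_maxima):
        box = dcp.cube_bounds(toy_maxima, 1, 1, 1, 1)
        assert box.gr == (0.0, 1.5)
        assert box.pr == (0.0, 1.5)
        assert box.sf == (0.0, 13.0)

    def test_sf_upper_boundary(self, toy_maxima):
        assert dcp.cube_bounds(toy_maxima, 1, 1, 1, 2).sf[1] == 26.0

    def test_index_out_of_range(self, toy_maxima):
        with pytest.raises(ContractError):
            dcp.cube_bounds(toy_maxima, 1, 3, 1, 1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tm=st.tuples(
            st.floats(0.1, 50), st.floats(0.1, 50), st.floats(0.1, 50)
        ),
        n=st.integers(0, 4),
        data=st.data(),
    )
    def test_partition_property(self, tm, n, data):
        """Cubes at a level tile [0,TMGR]x[0,TMPR]x[0,2*TMSF]: adjacent
        cubes share faces and the extreme cubes hit the axis ends."""
        maxima = dcp.TheoreticalMaxima(*tm)
        P = 2 ** n
        i = data.draw(st.integers(1, P))
        j = data.draw(st.integers(1, P))
        k = data.draw(st.integers(1, P))
        box = dcp.cube_bounds(maxima, n, i, j, k)
        for (lo, hi), axis_max, idx in (
            (box.gr, maxima.tmgr, i),
            (box.pr, maxima.tmpr, j),
            (box.sf, 2 * maxima.tmsf, k),
        ):
            assert lo == pytest.approx((idx - 1) * axis_max / P)
            assert hi == pytest.approx(idx * axis_max / P)
            assert 0 <= lo <= hi <= axis_max * (1 + 1e-12)
        if i > 1:  # shared face with the left neighbour
            left = dcp.cube_bounds(maxima, n, i - 1, j, k)
            assert left.gr[1] == box.gr[0]

    def test_cube_count_identity(self):
        for n in range(4):
            assert (2 ** n) ** 3 == 8 ** n


class TestRefineMask:
    def test_children_inherit_parent_flag(self):
        parent = FeasibilityGrid(
            2,
            np.ones((2, 2, 2), dtype=bool),
            np.zeros((2, 2, 2), dtype=bool),
        )
        parent.c[0, 1, 0] = True
        child = dcp.refine_mask(parent)
        assert child.P == 4
        for di in range(2):
            for dj in range(2):
                for dk in range(2):
                    assert child.d[0 + di, 2 + dj, 0 + dk]
        assert child.d.sum() == 8  # only the feasible parent's 8 children

    def test_infeasible_parent_masks_all_children(self):
        parent = FeasibilityGrid(
            2, np.ones((2, 2, 2), dtype=bool), np.zeros((2, 2, 2), dtype=bool)
        )
        child = dcp.refine_mask(parent)
        assert not child.d.any()

    def test_root_feasible_explores_all_eight(self):
        root = FeasibilityGrid.root()
        root.c[0, 0, 0] = True
        child = dcp.refine_mask(root)
        assert child.d.shape == (2, 2, 2) and child.d.all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 27 - 1))
    def test_mask_equals_kron_of_parent(self, bits):
        c = np.array([(bits >> b) & 1 for b in range(27)], dtype=bool).reshape(3, 3, 3)
        # refine_mask is defined for power-of-two grids; the 8-to-1 child
        # relation itself is shape-generic
        parent = FeasibilityGrid(3, np.ones_like(c), c)
        child = dcp.refine_mask(parent)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert child.d[i, j, k] == c[i // 2, j // 2, k // 2]


class TestExamineCube:
    def test_root_cube_candidate_rejected(self, toy, toy_maxima, toy_params):
        cube = Cube(0, 1, 1, 1, dcp.cube_bounds(toy_maxima, 0, 1, 1, 1))
        c, strat = dcp.examine_cube(toy, cube, toy_params)
        assert c == 1
        assert strat.K == {"R2", "R4", "R5"}
        assert (strat.GR, strat.PR) == (3.0, 0.0)
        assert not strat.accepted

    def test_empty_sf_half_is_infeasible(self, toy, toy_maxima, toy_params):
        cube = Cube(1, 1, 1, 2, dcp.cube_bounds(toy_maxima, 1, 1, 1, 2))
        c, strat = dcp.examine_cube(toy, cube, toy_params)
        assert (c, strat) == (0, None)

    def test_box_outside_polytope(self, toy, toy_params):
        box = dcp.BoxConstraint((4.0, 5.0), (0.0, 3.0), (0.0, 26.0))
        c, strat = dcp.examine_cube(toy, Cube(0, 1, 1, 1, box), toy_params)
        assert (c, strat) == (0, None)


class TestRunDynCubeProd:
    def test_toy_finds_r3(self, toy, toy_params):
        res = dcp.run_dyncubeprod(toy, None, toy_params)
        assert res.success
        assert res.strategy.K == {"R3"}
        assert res.strategy.GR == pytest.approx(1.0)
        assert res.strategy.PR == pytest.approx(2.0)
        assert res.strategy.found_at[0] == 2  # found at P=2

    def test_accepted_strategy_revalidates(self, toy, toy_params):
        res = dcp.run_dyncubeprod(toy, None, toy_params)
        gr, pr = dcp.validate_deletion(toy, res.strategy.K)
        assert gr == pytest.approx(res.strategy.GR)
        assert pr == pytest.approx(res.strategy.PR)
        assert gr >= toy_params.min_growth and pr >= toy_params.min_target

    def test_nmax_zero_fails_with_one_examined_cube(self, toy, toy_params):
        import dataclasses

        params = dataclasses.replace(toy_params, n_max=0)
        res = dcp.run_dyncubeprod(toy, None, params)
        assert not res.success and res.strategy is None
        assert res.level_stats[0]["examined"] == 1
        assert res.level_stats[0]["rejected"] == 1

    def test_determinism(self, toy, toy_params):
        a = dcp.run_dyncubeprod(toy, None, toy_params)
        b = dcp.run_dyncubeprod(toy, None, toy_params)
        assert a.strategy.K == b.strategy.K
        assert a.strategy.found_at == b.strategy.found_at
        assert [r.as_dict() for r in a.trace] == [r.as_dict() for r in b.trace]

    def test_algorithmic_root_mode_equivalent_on_toy(self, toy, toy_params):
        import dataclasses

        implicit = dataclasses.replace(toy_params, examine_root=False)
        res = dcp.run_dyncubeprod(toy, None, implicit)
        assert res.success and res.strategy.K == {"R3"}

    def test_infeasible_base_model(self, toy, toy_params):
        bad = toy.with_bounds({"R2": (0.0, 0.0), "R3": (0.0, 0.0)})
        with pytest.raises(dcp.ModelInfeasibleError):
            dcp.run_dyncubeprod(bad, None, toy_params)

    def test_trace_is_json_serializable(self, toy, toy_params):
        import json

        res = dcp.run_dyncubeprod(toy, None, toy_params)
        json.dumps(res.trace_dict())


class TestLemmaPruning:
    """Skipped cubes would have been infeasible if solved directly."""

    def _check(self, model, params, n_max):
        import dataclasses

        params = dataclasses.replace(params, n_max=n_max)
        res = dcp.run_dyncubeprod(model, None, params, early_stop=False)
        model2, maxima = model, res.maxima
        skipped = [r for r in res.trace if r.status == "skipped"]
        for rec in skipped:
            n = int(math.log2(rec.P))
            box = dcp.cube_bounds(maxima, n, rec.i, rec.j, rec.k)
            direct = dcp.min_total_flux(model2, box)
            assert direct.status == "infeasible", (rec, box)
        return len(skipped)

    def test_toy_skips_are_sound(self, toy, toy_params):
        n_skipped = self._check(toy, toy_params, n_max=2)
        assert n_skipped > 0  # the empty SF half does get pruned

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_network_skips_are_sound(self, seed):
        m = dcp.generate_random_network(5, 10, seed=seed)
        self._check(m, random_params(m), n_max=2)


class TestStaticVariants:
    def test_cubeprod_toy_p2_grid(self, toy, toy_params):
        res = dcp.run_cubeprod(toy, None, toy_params, P=2)
        grid = res.grids[2]
        # the three empty SF-half cubes are infeasible; the boundary cube
        # (gr [0,1.5], pr [1.5,3], sf [13,26]) holds the unique max-SF point
        # and is accepted with K={R3}
        assert int((~grid.c).sum()) == 3
        assert not grid.c[0, 0, 1] and not grid.c[1, 0, 1] and not grid.c[1, 1, 1]
        assert [s.K for s in res.accepted_all] == [frozenset({"R3"})]

    def test_cubeprod_toy_p1_rejected_but_feasible(self, toy, toy_params):
        res = dcp.run_cubeprod(toy, None, toy_params, P=1)
        assert res.grids[1].c[0, 0, 0]
        assert res.accepted_all == [] and not res.success

    @pytest.mark.parametrize("P", [1, 2, 4])
    def test_parity_with_dyncubeprod(self, toy, toy_params, P):
        import dataclasses

        static = dcp.run_cubeprod(toy, None, toy_params, P=P)
        dyn = dcp.run_dyncubeprod(
            toy, None, dataclasses.replace(toy_params, n_max=int(math.log2(P)))
        )
        assert bool(static.accepted_all) == dyn.success

    def test_gridprod_cell_flux_and_candidate(self, toy, toy_params):
        """The 2-D cell gr [0.75,1.5] x pr [1.5,2.25] (P=4) proposes {R5},
        which fails validation."""
        res = dcp.run_gridprod(toy, None, toy_params, P=4)
        flux = dcp.min_total_flux(
            toy, dcp.BoxConstraint((0.75, 1.5), (1.5, 2.25), (0.0, math.inf))
        )
        assert flux.x == pytest.approx([3, 1.5, 1.5, 1.5, 0, 1.5, 1.5], abs=1e-7)
        K = dcp.extract_candidate(flux, dcp.default_protected(toy))
        assert K == {"R5"}
        assert dcp.validate_deletion(toy, K) == pytest.approx((3.0, 0.0))

    def test_gridprod_point_cell_rejected(self, toy, toy_params):
        flux = dcp.min_total_flux(
            toy, dcp.BoxConstraint((1.0, 1.0), (2.0, 2.0), (0.0, math.inf))
        )
        assert flux.x == pytest.approx([3, 2, 1, 2, 0, 1, 2], abs=1e-7)
        K = dcp.extract_candidate(flux, dcp.default_protected(toy))
        gr, pr = dcp.validate_deletion(toy, K)
        assert (gr, pr) == pytest.approx((3.0, 0.0))  # not growth-coupled

    @pytest.mark.parametrize("P", [1, 2, 4, 8])
    def test_gridprod_never_succeeds_on_toy(self, toy, toy_params, P):
        res = dcp.run_gridprod(toy, None, toy_params, P=P)
        assert res.accepted_all == []


class TestEconomy:
    def test_dyncubeprod_solves_no_more_first_lps_than_cubeprod(self, toy, toy_params):
        import dataclasses

        n = 2
        dyn = dcp.run_dyncubeprod(
            toy, None, dataclasses.replace(toy_params, n_max=n), early_stop=False
        )
        static_total = sum(
            dcp.run_cubeprod(toy, None, toy_params, P=2 ** m).first_lp_count
            for m in range(n + 1)
        )
        assert dyn.first_lp_count <= static_total
        # the toy has infeasible cubes at P=2, so strictly fewer
        assert dyn.first_lp_count < static_total
        assert static_total == sum(8 ** m for m in range(n + 1))
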