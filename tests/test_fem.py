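import dataclasses
import math

import numpy as np
import pytest

from amphistoma import fem


class TestMesh:
    def test_node_and_triangle_counts(self):
        mesh = fem.build_mesh(100.0, 200.0, 4, 4)
        assert mesh.n_nodes == 25
        assert mesh.triangles.shape == (32, 3)

    def test_triangles_tile_domain(self):
        mesh = fem.build_mesh(101.0, 301.0, 8, 8)
        p = mesh.nodes[mesh.triangles]
        cross = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                 - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
        total = 0.5 * np.abs(cross).sum()
        exact = (101.0 / 2 * 1e-6) * (301.0 * 1e-6)
        assert total == pytest.approx(exact, rel=1e-12)

    def test_refinement_halves_edges(self):
        def max_edge(mesh):
            p = mesh.nodes[mesh.triangles]
            e = np.concatenate([p[:, 1] - p[:, 0], p[:, 2] - p[:, 1],
                                p[:, 0] - p[:, 2]])
            return np.linalg.norm(e, axis=1).max()

        a = max_edge(fem.build_mesh(100.0, 200.0, 8, 8))
        b = max_edge(fem.build_mesh(100.0, 200.0, 16, 16))
        assert b == pytest.approx(a / 2, rel=1e-12)

    def test_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            fem.build_mesh(100.0, 200.0, 2, 8)


class TestEffectiveDiffusivity:
    def test_reference_value(self):
        assert fem.effective_diffusivity(1.6e-5, 0.2, 1.57) == pytest.approx(
            2.038e-6, rel=1e-3)

    def test_identity_and_monotonicity(self):
        assert fem.effective_diffusivity(1.6e-5, 1.0 - 1e-12, 1.0) == pytest.approx(1.6e-5)
        assert (fem.effective_diffusivity(1.6e-5, 0.3, 1.5)
                > fem.effective_diffusivity(1.6e-5, 0.2, 1.5))
        assert (fem.effective_diffusivity(1.6e-5, 0.2, 2.0)
                < fem.effective_diffusivity(1.6e-5, 0.2, 1.5))


class TestDemand:
    def test_compensation_point_gives_minus_rd(self):
        p = fem.LeafModelParams()
        a = fem.demand(p.Gamma_star, 50.0, p)
        assert a == pytest.approx(-p.Rd_vol, abs=1e-15)

    def test_darkness_gives_minus_rd(self):
        p = dataclasses.replace(fem.LeafModelParams(), I0=0.0)
        y = np.linspace(0, p.T_leaf, 7)
        np.testing.assert_allclose(fem.demand(0.0163, y, p), -p.Rd_vol, atol=1e-15)

    def test_rubisco_asymptote_at_saturating_light(self):
        # Rubisco-limited ceiling requires J/4 > Vcmax
        p = dataclasses.replace(fem.LeafModelParams(), Jmax_vol=4.0, I0=1e5)
        a = fem.demand(50.0, 0.0, p)
        assert a == pytest.approx(p.Vcmax_vol - p.Rd_vol, rel=1e-2)

    def test_light_attenuates_with_depth(self):
        p = fem.LeafModelParams()
        shallow = fem.demand(0.0163, 0.0, p)
        deep = fem.demand(0.0163, p.T_leaf, p)
        assert shallow > deep


class TestSolveLeaf:
    def test_no_reaction_constant_field(self):
        p = dataclasses.replace(fem.LeafModelParams(),
                                Vcmax_vol=0.0, Jmax_vol=0.0, Rd_vol=0.0)
        sol = fem.solve_leaf(p, nx=16, ny=16)
        np.testing.assert_allclose(sol.c_field, p.c_pore, atol=1e-12)
        assert sol.A_total == pytest.approx(0.0, abs=1e-12)

    def test_linear_reaction_matches_cosh_solution(self):
        # Dirichlet on the whole top and bottom: the field is 1-D in depth
        # with c(y) = c0 cosh(m (y - T/2)) / cosh(m T/2), m = sqrt(k/D)
        T = 300e-6
        D = 2e-6
        k = 50.0
        c0 = 0.0163
        mesh = fem.build_mesh(200.0, 300.0, 64, 64)
        nx = 64
        dirichlet = np.concatenate([np.arange(nx + 1),
                                    np.arange(nx + 1) + 64 * (nx + 1)])
        c, _, _, _, _ = fem.solve_reaction_diffusion(
            mesh, D, lambda c, nodes: k * c, dirichlet, c0, tol=1e-10)
        m = math.sqrt(k / D)
        y = mesh.nodes[:, 1]
        exact = c0 * np.cosh(m * (y - T / 2)) / math.cosh(m * T / 2)
        assert np.max(np.abs(c - exact)) / c0 < 0.005

    def test_mass_balance_at_convergence(self):
        sol = fem.solve_leaf(fem.LeafModelParams())
        assert abs(sol.A_total - sol.flux_in) / abs(sol.flux_in) < 1e-3

    def test_concentration_bounded_by_pore_value(self):
        p = fem.LeafModelParams()
        sol = fem.solve_leaf(p, nx=32, ny=32)
        assert sol.c_field.min() >= 0.0
        assert sol.c_field.max() <= p.c_pore + 1e-12

    def test_assimilation_monotone_in_light_and_co2(self):
        base = fem.LeafModelParams()
        a = [fem.solve_leaf(dataclasses.replace(base, I0=i0), 32, 32).A_total
             for i0 in (50.0, 300.0, 1000.0)]
        assert a[0] < a[1] < a[2]
        b = [fem.solve_leaf(dataclasses.replace(base, c_pore=c), 32, 32).A_total
             for c in (0.008, 0.0163, 0.03)]
        assert b[0] < b[1] < b[2]

    def test_pore_under_resolved_suggests_nx(self):
        p = dataclasses.replace(fem.LeafModelParams(), U=338.0)
        with pytest.raises(ValueError, match="nx"):
            fem.solve_leaf(p, nx=16, ny=16)


class TestCoordinationAdvantage:
    def test_identical_geometries_zero(self):
        # same-arrangement solves are identical, so the log ratio vanishes
        p = fem.LeafModelParams()
        a = fem.solve_leaf(p, 32, 32).A_total
        b = fem.solve_leaf(dataclasses.replace(p), 32, 32).A_total
        assert math.log(b / a) == 0.0

    def test_contiguous_stomata_limit_vanishes(self):
        # pores nearly fill the epidermis: arrangement cannot matter much
        p = dataclasses.replace(fem.LeafModelParams(), U=34.0, pore_halfwidth=10.0)
        assert abs(fem.coordination_advantage(p, nx=32, ny=32)) < 1e-4

    def test_thin_sparse_leaf_benefits_most(self):
        thin = fem.coordination_advantage(
            dataclasses.replace(fem.LeafModelParams(), T_leaf=101.0, U=338.0))
        thick = fem.coordination_advantage(
            dataclasses.replace(fem.LeafModelParams(), T_leaf=501.0, U=101.0))
        assert thin > 10 * abs(thick)
        assert thin > 0

    def test_mesh_convergence_on_thin_sparse_cell(self):
        # checked where the advantage signal is far above solver tolerance
        p = dataclasses.replace(fem.LeafModelParams(), T_leaf=101.0, U=338.0)
        a64 = fem.coordination_advantage(p, nx=64, ny=64)
        a128 = fem.coordination_advantage(p, nx=128, ny=128)
        assert abs(a128 - a64) / abs(a64) < 0.05


def test_load_params_from_yaml(tmp_path):
    cfg = tmp_path / "leaf.yaml"
    cfg.write_text(
        "params:\n  T_leaf: 301.0\n  I0: 500.0\n"
        "grid:\n  phi_pal: [0.1, 0.3]\n")
    params, grid = fem.load_params(cfg)
    assert params.T_leaf == 301.0 and params.I0 == 500.0
    assert params.U == fem.LeafModelParams().U  # untouched default
    assert grid == {"phi_pal": [0.1, 0.3]}


class TestParameterSweep:
    def test_grid_cardinality(self):
        grid = {"T_leaf": [151.0, 301.0], "U": [50.0, 100.0],
                "phi_pal": [0.1, 0.3], "I0": [100.0, 1000.0]}
        table = fem.parameter_sweep(grid, nx=16, ny=16)
        assert len(table) == 16
        assert (table["error"] == "").all()

    def test_failed_cells_isolated(self):
        grid = {"T_leaf": [201.0], "U": [338.0, 101.0], "phi_pal": [0.2],
                "I0": [1000.0]}
        table = fem.parameter_sweep(grid, nx=16, ny=16)
        bad = table[table["U"] == 338.0]
        good = table[table["U"] == 101.0]
        assert bad["error"].iloc[0] != "" and np.isnan(bad["advantage"].iloc[0])
        assert good["error"].iloc[0] == "" and np.isfinite(good["advantage"].iloc[0])
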