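import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import kstest

from amphistoma import coordination as co
from amphistoma import spatial, synthetic
from amphistoma.synthetic import GridSimConfig, PairSimConfig


def _brute_mean_nn(xy):
    """O(n²) oracle for the mean nearest-neighbour distance."""
    n = len(xy)
    total = 0.0
    for i in range(n):
        best = np.inf
        for j in range(n):
            if i != j:
                best = min(best, np.hypot(*(xy[i] - xy[j])))
        total += best
    return total / n


class TestRandomSurface:
    def test_deterministic_under_seed(self):
        a = synthetic.random_surface(500, seed=3)
        b = synthetic.random_surface(500, seed=3)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_empty_and_negative(self):
        assert synthetic.random_surface(0, seed=1).n == 0
        with pytest.raises(ValueError):
            synthetic.random_surface(-1)

    def test_coordinates_uniform(self):
        # KS test of x-coordinates vs uniform should rarely reject at 1 %
        rejections = 0
        for seed in range(40):
            rec = synthetic.random_surface(500, window=(1.0, 1.0), seed=seed)
            if kstest(rec.xy[:, 0], "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= 3


class TestTriangularGrid:
    def test_exact_count_and_determinism(self):
        cfg = GridSimConfig(n_target=40, seed=7)
        a = synthetic.triangular_grid_surface(cfg)
        b = synthetic.triangular_grid_surface(cfg)
        assert a.n == 40
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_interior_nn_distance_equals_lattice_constant(self):
        rec = synthetic.triangular_grid_surface(GridSimConfig(n_target=60, seed=2))
        d = pdist(rec.xy)
        a = d.min()
        # points farther than a from every window edge have all six
        # neighbours present, so their NN distance is exactly a
        w, h = rec.window
        interior = ((rec.xy[:, 0] > a) & (rec.xy[:, 0] < w - a)
                    & (rec.xy[:, 1] > a) & (rec.xy[:, 1] < h - a))
        assert interior.sum() > 5
        from scipy.spatial import cKDTree
        nn = cKDTree(rec.xy).query(rec.xy, k=2)[0][:, 1]
        np.testing.assert_allclose(nn[interior], a, atol=1e-9)

    def test_nni_near_lattice_maximum(self):
        # the triangular lattice maximizes NNI at 2/sqrt(2/sqrt(3)) ~ 2.149
        rec = synthetic.triangular_grid_surface(
            GridSimConfig(n_target=200, window=(1.0, 1.0), seed=5))
        oracle = _brute_mean_nn(rec.xy) / spatial.expected_nn_distance(1.0, 200)
        assert oracle == pytest.approx(2.1491, rel=0.05)
        assert spatial.nni(rec).nni == pytest.approx(oracle, rel=1e-12)

    def test_budget_exhaustion_reports_rate(self):
        with pytest.raises(RuntimeError, match="acceptance rate"):
            synthetic.conditioned_lattice_sample(50, size=5, seed=0,
                                                 max_rejections=2)


class TestIdealGridSpacing:
    def test_matches_reported_density(self):
        assert synthetic.ideal_grid_spacing(10.107) == pytest.approx(338.0, abs=0.1)

    def test_roundtrip_identity(self):
        u = synthetic.ideal_grid_spacing(137.2)
        assert synthetic.ideal_grid_density(u) == pytest.approx(137.2, rel=1e-9)

    def test_quadrupling_density_halves_spacing(self):
        assert synthetic.ideal_grid_spacing(40.0) == pytest.approx(
            synthetic.ideal_grid_spacing(10.0) / 2, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            synthetic.ideal_grid_spacing(0.0)


class TestHardcore:
    def test_min_distance_respected(self):
        rec = synthetic.hardcore_surface(80, r_min=0.03, seed=4)
        assert rec.n == 80
        assert pdist(rec.xy).min() >= 0.03

    def test_zero_inhibition_matches_uniform(self):
        rec = synthetic.hardcore_surface(400, r_min=0.0, seed=9)
        assert kstest(rec.xy[:, 0] / rec.window[0], "uniform").pvalue > 0.01

    def test_infeasible_packing_raises(self):
        with pytest.raises(RuntimeError, match="infeasible"):
            synthetic.hardcore_surface(200, window=(0.1, 0.1), r_min=0.05,
                                       seed=1, max_attempts=2000)

    def test_moderate_inhibition_intermediate_dispersion(self):
        # overdispersed relative to random but far from the ideal lattice
        dis = []
        for seed in range(15):
            rec = synthetic.hardcore_surface(60, r_min=0.032, seed=seed)
            res = spatial.dispersion_analysis(rec, n_sim=199, seed=seed + 100)
            dis.append(res.dispersion_index)
        med = np.median(dis)
        assert 0.05 < med < 0.95


class TestSimulatePair:
    def test_aligned_identical_coordinates(self):
        pair = synthetic.simulate_pair(PairSimConfig(30, 30, mode="aligned", seed=1))
        np.testing.assert_array_equal(pair.abaxial.xy, pair.adaxial.xy)

    def test_independent_mean_nsd_correlation_near_zero(self):
        rs = [co.nsd_correlation(
            synthetic.simulate_pair(PairSimConfig(60, 60, mode="independent", seed=s)),
            resolution=32)
            for s in range(30)]
        assert abs(np.mean(rs)) < 0.05

    def test_offset_coordinated_negative_correlation(self):
        rs = [co.nsd_correlation(
            synthetic.simulate_pair(
                PairSimConfig(120, 120, mode="offset_coordinated", seed=s)),
            resolution=64)
            for s in range(10)]
        assert all(r < 0 for r in rs)


class TestAttachLengths:
    def test_zero_noise_exactly_affine(self, random50):
        from amphistoma.zones import voronoi_zones

        rec = synthetic.attach_lengths(random50, alpha=18.0, beta=400.0,
                                       sigma=0.0, seed=0)
        areas = voronoi_zones(rec).areas
        np.testing.assert_allclose(rec.lengths, 18.0 + 400.0 * areas, rtol=1e-12)

    def test_zero_slope_uncorrelated(self):
        from amphistoma.zones import voronoi_zones

        rec = synthetic.random_surface(200, seed=21)
        rec = synthetic.attach_lengths(rec, alpha=25.0, beta=0.0, sigma=3.0, seed=22)
        r = np.corrcoef(rec.lengths, voronoi_zones(rec).areas)[0, 1]
        assert abs(r) < 0.2

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            synthetic.attach_lengths(synthetic.random_surface(0, seed=1),
                                     18.0, 400.0, 2.0)


def test_generators_emit_valid_records():
    # every generator output passes SurfaceRecord invariant checks on
    # construction; spot-check bounds too
    for rec in (synthetic.random_surface(25, seed=1),
                synthetic.hardcore_surface(25, r_min=0.02, seed=1),
                synthetic.triangular_grid_surface(GridSimConfig(25, seed=1))):
        w, h = rec.window
        assert rec.xy[:, 0].min() >= 0 and rec.xy[:, 0].max() <= w
        assert rec.xy[:, 1].min() >= 0 and rec.xy[:, 1].max() <= h
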