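import numpy as np
import pytest
from scipy.stats import kstest

from enf3d import (BoxWindow, MarkovZParams, conditional_density,
                   estimate_hardcore, fit_markov, hardcore_ok,
                   log_pseudolikelihood, neighbor_count_si, neighbor_counts,
                   normalizing_constant_ci, pair_neighbor_count, simulate_z)


def quad_ci(i, coords, params, nodes=100_000):
    """Riemann-sum oracle for the normalising constant c_i."""
    zz = (np.arange(nodes) + 0.5) * params.zmax / nodes
    others = np.delete(np.arange(len(coords)), i)
    dxy = np.linalg.norm(coords[others, :2] - coords[i, :2], axis=1)
    zo = coords[others, 2]
    s = ((dxy[None, :] <= params.w)
         & (np.abs(zz[:, None] - zo[None, :]) <= params.t)).sum(axis=1)
    feas = np.all(dxy[None, :] ** 2 + (zz[:, None] - zo[None, :]) ** 2
                  > params.h**2, axis=1)
    return float(np.sum(params.gamma**s * feas) * params.zmax / nodes)


class TestNeighbourCounts:
    def test_hand_enumeration(self):
        pts = np.array([[0, 0, 0], [1, 0, 2], [0, 3, 10.0]])
        s = neighbor_counts(pts, w=2, t=3)
        assert s.tolist() == [1, 1, 0]
        assert pair_neighbor_count(pts, 2, 3) == 1
        assert neighbor_count_si(0, pts, 2, 3) == 1

    def test_single_point(self):
        assert neighbor_counts(np.array([[1, 1, 1.0]]), 5, 5).tolist() == [0]

    def test_sum_matches_pair_oracle(self, rng):
        pts = rng.uniform(0, 50, size=(100, 3))
        w, t = 6.0, 3.0
        s = neighbor_counts(pts, w, t)
        brute = sum(
            1 for i in range(100) for j in range(i + 1, 100)
            if np.hypot(*(pts[i, :2] - pts[j, :2])) <= w
            and abs(pts[i, 2] - pts[j, 2]) <= t
        )
        assert s.sum() == 2 * brute
        assert s.sum() % 2 == 0


class TestHardcore:
    def test_simple_pattern_ok_at_zero(self, clustered_ends):
        assert hardcore_ok(clustered_ends, 0.0)

    def test_boundary_distance_is_violation(self):
        pts = np.array([[0, 0, 0], [2, 0, 0.0]])
        assert not hardcore_ok(pts, 2.0)  # strict inequality required
        assert hardcore_ok(pts, 1.999)

    def test_matches_exhaustive_check(self, rng):
        pts = rng.uniform(0, 30, size=(200, 3))
        for h in (0.5, 1.0, 2.0):
            brute = all(
                np.linalg.norm(pts[i] - pts[j]) > h
                for i in range(200) for j in range(i + 1, 200)
            )
            assert hardcore_ok(pts, h) == brute

    def test_estimator_formula(self):
        pts = np.array([[0, 0, 0], [0, 0, 4.0]])
        assert estimate_hardcore(pts) == pytest.approx(2.0)
        pts4 = np.array([[0, 0, 0], [0, 0, 2.0], [50, 0, 0], [0, 50, 0.0]])
        assert estimate_hardcore(pts4) == pytest.approx(1.5)

    def test_estimate_below_dmin(self, clustered_ends):
        from enf3d import min_interpoint_distance
        assert estimate_hardcore(clustered_ends) < min_interpoint_distance(clustered_ends)


class TestNormalisingConstant:
    def test_no_other_points_gives_zmax(self):
        p = MarkovZParams(2.0, 1.0, 2.0, 2.0, 10.0)
        assert normalizing_constant_ci(0, np.array([[0, 0, 3.0]]), p) == pytest.approx(10.0)

    def test_hand_piecewise_integration(self):
        # neighbour on [3,7], hardcore excludes (4,6): c = 3 + 2*2 + 3 = 10
        p = MarkovZParams(gamma=2.0, h=1.0, w=2.0, t=2.0, zmax=10.0)
        coords = np.array([[0, 0, 0.5], [0, 0, 5.0]])
        assert normalizing_constant_ci(0, coords, p) == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadrature_oracle(self, seed):
        """Agreement with a midpoint Riemann sum, within the oracle's own
        discretization error (the integrand jumps at ≤ 2n breakpoints, so a
        100k-node sum carries O(n Δz) error of its own)."""
        rng = np.random.default_rng(seed)
        coords = np.column_stack([rng.uniform(0, 25, (15, 2)), rng.uniform(0, 40, 15)])
        p = MarkovZParams(gamma=2.7, h=3.0, w=8.0, t=4.0, zmax=40.0)
        for i in range(0, 15, 3):
            exact = normalizing_constant_ci(i, coords, p)
            assert exact == pytest.approx(quad_ci(i, coords, p), rel=1e-4)


class TestConditionalDensity:
    def test_uniform_when_no_interaction(self):
        p = MarkovZParams(gamma=1.0, h=0.0, w=5.0, t=2.0, zmax=80.0)
        coords = np.array([[0, 0, 10.0], [1, 1, 50.0]])
        for z in (0.0, 17.3, 80.0):
            assert conditional_density(z, 0, coords, p) == pytest.approx(1 / 80.0)

    def test_zero_inside_hardcore(self):
        p = MarkovZParams(gamma=2.0, h=3.0, w=5.0, t=2.0, zmax=50.0)
        coords = np.array([[0, 0, 10.0], [0, 0, 20.0]])
        assert conditional_density(19.0, 0, coords, p) == 0.0

    def test_integrates_to_one(self, rng):
        p = MarkovZParams(gamma=3.0, h=2.0, w=8.0, t=3.0, zmax=60.0)
        coords = np.column_stack([rng.uniform(0, 20, (10, 2)), rng.uniform(0, 60, 10)])
        zz = (np.arange(200_000) + 0.5) * p.zmax / 200_000
        f = np.array([conditional_density(z, 3, coords, p) for z in zz[::200]])
        # trapezoid on the closed-form values, modest grid
        integral = f.mean() * p.zmax
        assert integral == pytest.approx(1.0, abs=2e-3)


class TestPseudoLikelihood:
    def test_single_interior_point_uniform(self):
        w = BoxWindow.from_extents(320, 432, 100)
        p = MarkovZParams(1.0, 0.0, 5.0, 2.0, 100.0)
        pl = log_pseudolikelihood(np.array([[50, 50, 30.0]]), p, window=w)
        assert pl == pytest.approx(-np.log(100))

    def test_no_interaction_uniform_product(self, rng):
        w = BoxWindow.from_extents(320, 432, 100)
        pts = rng.uniform((0, 0, 0), (320, 432, 100), size=(40, 3))
        p = MarkovZParams(1.0, 0.0, 5.0, 2.0, 100.0)
        assert log_pseudolikelihood(pts, p, window=w) == pytest.approx(-40 * np.log(100))

    def test_hardcore_violation_gives_minus_inf(self):
        w = BoxWindow.from_extents(100, 100, 100)
        pts = np.array([[10, 10, 10.0], [10, 10, 11.0]])
        p = MarkovZParams(2.0, 1.5, 5.0, 2.0, 100.0)
        assert log_pseudolikelihood(pts, p, window=w) == -np.inf

    def test_matches_quadrature_oracle(self, rng):
        w = BoxWindow.from_extents(60, 60, 50)
        coords = np.column_stack([rng.uniform(0, 60, (20, 2)), rng.uniform(0, 50, 20)])
        p = MarkovZParams(gamma=2.0, h=0.8, w=7.0, t=3.0, zmax=50.0)
        if not hardcore_ok(coords, p.h):
            pytest.skip("rare: random configuration violates test hardcore")
        s = neighbor_counts(coords, p.w, p.t)
        oracle = sum(
            s[i] * np.log(p.gamma) - np.log(quad_ci(i, coords, p))
            for i in range(20)
        )
        assert log_pseudolikelihood(coords, p, window=w) == pytest.approx(oracle, rel=1e-6)


class TestFit:
    def test_grid_argmax_property(self, clustered_ends, biopsy_window):
        fr = fit_markov(clustered_ends, [6, 10], [2, 4], window=biopsy_window)
        assert fr.log_pl == pytest.approx(np.max(fr.grid["log_pl"]))
        assert len(fr.grid) == 4
        assert fr.params.h == pytest.approx(estimate_hardcore(clustered_ends))

    def test_optimizer_unimodal_convergence(self, clustered_ends, biopsy_window):
        """The profile pseudo-likelihood is unimodal in log γ: optimising on
        overlapping brackets lands on the same estimate."""
        from enf3d.markov import _interior_profiles, _optimize_gamma
        h = estimate_hardcore(clustered_ends)
        eroded = biopsy_window.erode(10, 4)
        stats = _interior_profiles(clustered_ends, biopsy_window, h, 10.0, 4.0, eroded)
        g1, _ = _optimize_gamma(stats, (-5.0, 2.0))
        g2, _ = _optimize_gamma(stats, (-2.0, 5.0))
        assert np.log(g1) == pytest.approx(np.log(g2), abs=1e-4)

    def test_interaction_recovery(self):
        """Patterns simulated at γ=3 with the true cell on the grid recover
        the interaction strength and usually the right cell."""
        from enf3d import healthy_like_group, simulate_planar
        w3 = BoxWindow.from_extents(320, 432, 100)
        g = healthy_like_group()
        truth = MarkovZParams(gamma=3.0, h=1.5, w=10.0, t=4.0, zmax=100.0)
        gammas, cells = [], []
        rng = np.random.default_rng(606)
        for rep in range(8):
            from enf3d import generate_base_points
            bases = generate_base_points(w3, 2.0e-4, 10.0, rng)
            sim = simulate_planar(bases, g.planar, w3, rng)
            z = simulate_z(sim.ends, truth, n_sweeps=500, burn_in=1500, seed=rng)
            fr = fit_markov(np.column_stack([sim.ends, z]),
                            [6.0, 10.0, 14.0], [2.0, 4.0, 6.0], window=w3)
            gammas.append(fr.params.gamma)
            cells.append((fr.params.w, fr.params.t))
        med = np.median(gammas)
        assert 1.5 < med < 6.0
        assert cells.count((10.0, 4.0)) >= 4  # modal cell is the truth

    def test_empty_grid_rejected(self, clustered_ends, biopsy_window):
        with pytest.raises(ValueError):
            fit_markov(clustered_ends, [], [2], window=biopsy_window)


class TestSimulateZ:
    def test_uniform_when_no_interaction(self):
        planar = np.random.default_rng(5).uniform(0, 100, size=(40, 2))
        p = MarkovZParams(gamma=1.0, h=0.0, w=8.0, t=3.0, zmax=100.0)
        zs = np.concatenate([
            simulate_z(planar, p, n_sweeps=5, burn_in=30, seed=s)
            for s in range(20)
        ])
        assert kstest(zs, "uniform", args=(0, 100)).pvalue > 0.001

    def test_reproducible_under_seed(self):
        planar = np.random.default_rng(6).uniform(0, 50, size=(15, 2))
        p = MarkovZParams(gamma=2.0, h=1.0, w=8.0, t=3.0, zmax=60.0)
        a = simulate_z(planar, p, n_sweeps=50, burn_in=50, seed=42)
        b = simulate_z(planar, p, n_sweeps=50, burn_in=50, seed=42)
        assert np.array_equal(a, b)

    def test_hardcore_maintained(self):
        planar = np.random.default_rng(7).uniform(0, 40, size=(30, 2))
        p = MarkovZParams(gamma=2.0, h=2.0, w=8.0, t=3.0, zmax=80.0)
        z = simulate_z(planar, p, n_sweeps=200, burn_in=200, seed=8)
        assert hardcore_ok(np.column_stack([planar, z]), p.h)

    def test_attraction_raises_pair_count(self):
        planar = np.random.default_rng(9).uniform(0, 60, size=(40, 2))
        base = MarkovZParams(gamma=1.0, h=0.0, w=10.0, t=4.0, zmax=100.0)
        attr = MarkovZParams(gamma=5.0, h=0.0, w=10.0, t=4.0, zmax=100.0)
        _, h1 = simulate_z(planar, base, n_sweeps=300, burn_in=300, seed=10,
                           record_pair_counts=True)
        _, h5 = simulate_z(planar, attr, n_sweeps=300, burn_in=300, seed=10,
                           record_pair_counts=True)
        assert h5.mean() > h1.mean()

    def test_infeasible_window_raises(self):
        # 30 coincident planar points in a 10 μm window with h=5: impossible
        planar = np.zeros((30, 2))
        p = MarkovZParams(gamma=1.0, h=5.0, w=8.0, t=3.0, zmax=10.0)
        with pytest.raises(RuntimeError, match="too shallow"):
            simulate_z(planar, p, n_sweeps=1, burn_in=1, seed=11)


def test_minus_sampling_reduces_bias():
    """On replicated γ=2 patterns, erosion-based fitting is no further from
    the truth on average than fitting with every point."""
    from enf3d.markov import _interior_profiles, _optimize_gamma
    w3 = BoxWindow.from_extents(160, 160, 60)
    truth = MarkovZParams(gamma=2.0, h=1.0, w=10.0, t=4.0, zmax=60.0)
    rng = np.random.default_rng(71)
    with_erosion, without = [], []
    eroded = w3.erode(10, 4)
    for rep in range(12):
        planar = rng.uniform(0, 160, size=(80, 2))
        z = simulate_z(planar, truth, n_sweeps=400, burn_in=800, seed=rng)
        coords = np.column_stack([planar, z])
        for target, win in ((with_erosion, eroded), (without, w3)):
            stats = _interior_profiles(coords, w3, truth.h, truth.w, truth.t, win)
            target.append(_optimize_gamma(stats)[0])
    bias_minus = abs(np.mean(with_erosion) - truth.gamma)
    bias_full = abs(np.mean(without) - truth.gamma)
    assert bias_minus <= bias_full + 0.05
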