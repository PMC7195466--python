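"""Guiding path geometry, string method, umbrella windows, replica exchange."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import loadpath as lp
from loadpath.potentials import MimeticLandscapeSpec
from loadpath.reus import ExchangeLog, StringResult


class TestGuidingPath:
    def test_default_circle_geometry(self):
        path = lp.init_guiding_path(n=48, radius=2.0)
        assert path.n_points == 48
        spacing = path.segment_lengths()
        # uniform chord spacing of the 48-gon, closing edge included
        assert spacing.size == 48
        assert np.allclose(spacing, 2 * 2.0 * math.sin(math.pi / 48))
        assert path.neighbor_indices(0) == (47, 1)
        assert path.neighbor_indices(47) == (46, 0)
        # pins: interface at angle pi, active site at angle 0
        assert np.allclose(path.points[0], [-2.0, 0.0], atol=1e-12)
        assert np.allclose(path.points[24], [2.0, 0.0], atol=1e-12)

    def test_four_point_square(self):
        path = lp.init_guiding_path(n=4, radius=1.0, active_index=2, interface_index=0)
        angles = np.arctan2(path.points[:, 1], path.points[:, 0])
        angles = np.sort(np.mod(angles + 1e-9, 2 * np.pi) - 1e-9)
        assert np.allclose(angles, [0.0, np.pi / 2, np.pi, 3 * np.pi / 2], atol=1e-8)

    def test_fixed_points_survive_repeated_reparameterization(self):
        path = lp.init_guiding_path(n=48, radius=2.0)
        p0, p24 = path.points[0].copy(), path.points[24].copy()
        for _ in range(100):
            path = path.reparameterize()
        assert np.array_equal(path.points[0], p0)
        assert np.array_equal(path.points[24], p24)

    def test_reparameterization_equalizes_and_is_idempotent(self):
        rng = np.random.default_rng(0)
        path = lp.init_guiding_path(n=48, radius=2.0)
        perturbed = lp.GuidingPath(
            points=path.points + rng.normal(0, 0.05, path.points.shape),
            cyclic=True,
            fixed_indices=path.fixed_indices,
        )
        once = perturbed.reparameterize()
        lengths = once.segment_lengths()
        # within each pinned segment the spacing is uniform to 1e-8 relative
        for seg in (lengths[:24], lengths[24:]):
            assert (seg.max() - seg.min()) / seg.mean() < 1e-8
        twice = once.reparameterize()
        assert np.allclose(once.points, twice.points, atol=1e-9)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            lp.init_guiding_path(n=3)
        with pytest.raises(ValueError):
            lp.init_guiding_path(n=8, active_index=0, interface_index=0)
        with pytest.raises(ValueError):
            lp.init_guiding_path(n=8, active_index=9)


class TestWindows:
    def test_one_window_per_point(self):
        path = lp.init_guiding_path(n=48, radius=2.0)
        windows = lp.build_windows(path, k=0.48)
        assert len(windows) == 48
        assert windows[47].neighbors == (46, 0)

    def test_bias_convention(self):
        path = lp.init_guiding_path(n=48, radius=2.0)
        w = lp.build_windows(path, k=0.48)[0]
        assert w.energy(w.center) == 0.0
        displaced = w.center + np.array([1.0, 0.0])
        assert w.energy(displaced) == pytest.approx(0.48)

    def test_nonpositive_k(self):
        path = lp.init_guiding_path(n=8, active_index=4)
        with pytest.raises(ValueError):
            lp.build_windows(path, k=0.0)


class TestExchange:
    def _two_windows(self, c1, c2, k1=1.0, k2=1.0):
        return [
            lp.UmbrellaWindow(index=0, center=np.array(c1), k=k1, neighbors=(1, 1)),
            lp.UmbrellaWindow(index=1, center=np.array(c2), k=k2, neighbors=(0, 0)),
        ]

    def test_identical_states_always_swap(self):
        windows = self._two_windows([0.0], [1.0])
        rng = np.random.default_rng(0)
        states = np.array([[0.5], [0.5]])
        log = ExchangeLog(n_edges=2)
        for s in range(50):
            _, log = lp.replica_exchange_sweep(
                windows, states, kT=0.6, rng=rng, log=log, sweep_index=s
            )
        assert log.accepts[0] == log.attempts[0]

    def test_identical_centers_always_swap(self):
        windows = self._two_windows([0.3], [0.3], k1=2.0, k2=2.0)
        rng = np.random.default_rng(1)
        states = np.array([[0.1], [0.9]])
        log = ExchangeLog(n_edges=2)
        for s in range(50):
            _, log = lp.replica_exchange_sweep(
                windows, states, kT=0.6, rng=rng, log=log, sweep_index=s
            )
        assert log.accepts[0] == log.attempts[0]

    def test_walker_count_mismatch(self):
        windows = self._two_windows([0.0], [1.0])
        with pytest.raises(ValueError):
            lp.replica_exchange_sweep(
                windows, np.zeros((3, 1)), 0.6, np.random.default_rng(0)
            )

    def test_acceptance_rate_matches_quadrature(self):
        # two harmonic windows on a flat potential: empirical swap rate vs
        # the Metropolis double integral, within 3 binomial standard errors
        kT, k, d = 0.6, 1.0, 1.2
        windows = self._two_windows([0.0], [d], k1=k, k2=k)
        sigma = math.sqrt(kT / (2 * k))

        def integrand(xj, xi):
            vi = lambda x: k * (x - 0.0) ** 2
            vj = lambda x: k * (x - d) ** 2
            delta = (vi(xj) + vj(xi) - vi(xi) - vj(xj)) / kT
            p = min(1.0, math.exp(-delta))
            gi = math.exp(-((xi - 0.0) ** 2) / (2 * sigma**2))
            gj = math.exp(-((xj - d) ** 2) / (2 * sigma**2))
            return p * gi * gj / (2 * math.pi * sigma**2)

        expected, _ = integrate.dblquad(
            integrand, -6 * sigma, d + 6 * sigma, -6 * sigma, d + 6 * sigma
        )
        rng = np.random.default_rng(17)
        n_trials = 4000
        accepted = 0
        for s in range(n_trials):
            states = np.array(
                [[rng.normal(0.0, sigma)], [rng.normal(d, sigma)]]
            )
            log = ExchangeLog(n_edges=2)
            lp.replica_exchange_sweep(windows, states, kT, rng, log, sweep_index=s)
            accepted += int(log.accepts[0])
        rate = accepted / n_trials
        se = math.sqrt(expected * (1 - expected) / n_trials)
        assert abs(rate - expected) < 3 * se

    def test_exchange_preserves_window_marginals(self, landscape):
        # with and without exchange, each window's long-run histogram is the
        # same restrained Boltzmann distribution (KS level 0.01 per window)
        path = lp.init_guiding_path(n=8, radius=2.0, active_index=4, interface_index=0)
        windows = lp.build_windows(path, k=0.48)
        common = dict(
            kT=lp.kt_at(300.0), dt=2.5e-4, friction=0.05, n_steps=30000,
            stride=240, equil_steps=3000,
        )
        with_ex = lp.run_reus(landscape, windows, exchange_interval=100, seed=31, **common)
        without = lp.run_reus(landscape, windows, exchange_interval=10**9, seed=32, **common)
        pvals = []
        for w in range(8):
            a = np.arctan2(with_ex.samples[w][:, 1], with_ex.samples[w][:, 0])
            b = np.arctan2(without.samples[w][:, 1], without.samples[w][:, 0])
            center = np.arctan2(windows[w].center[1], windows[w].center[0])
            a = np.mod(a - center + np.pi, 2 * np.pi)
            b = np.mod(b - center + np.pi, 2 * np.pi)
            pvals.append(stats.ks_2samp(a, b).pvalue)
        # Bonferroni over the 8 windows at family level 0.01
        assert min(pvals) > 0.01 / 8

    def test_window_means_near_centers(self, small_reus):
        windows, samples = small_reus
        kT = lp.kt_at(300.0)
        band = 3.0 * math.sqrt(kT / (2 * windows[0].k))
        for w, s in zip(windows, samples.samples):
            assert np.linalg.norm(s.mean(axis=0) - w.center) < band


class TestStringMethod:
    def test_fixed_point_on_ring_valley(self):
        # a path lying in the circular trough of a purely radial potential is
        # a fixed point of the deterministic update
        spec = MimeticLandscapeSpec(minima_offset=0.0, saddle_height=0.0, bump_height=0.0)
        ring = lp.make_ga2ox_mimetic_landscape(spec)
        path = lp.init_guiding_path(n=24, radius=2.0, active_index=12)
        res = lp.string_optimize(
            ring, path, k_string=2.39, rounds=3, samples_per_round=2000,
            smoothing=0.0, kT=0.0, dt=1e-3, friction=1.0, seed=4, tol=2e-3,
        )
        assert res.converged
        assert res.rounds_used == 1
        assert np.max(np.abs(np.linalg.norm(res.path.points, axis=1) - 2.0)) < 1e-3

    def test_converges_to_quadratic_trough(self):
        # low-temperature string relaxes a perturbed circle into the trough
        spec = MimeticLandscapeSpec(
            ring_radius=2.0, radial_stiffness=5.0, minima_offset=0.5,
            saddle_height=0.6, bump_width=0.35,
        )
        pot = lp.make_ga2ox_mimetic_landscape(spec)
        path = lp.init_guiding_path(n=24, radius=2.0, active_index=12)
        # bow the free points outward; the pinned minima stay in the trough
        bulge = path.points.copy()
        free = [i not in path.fixed_indices for i in range(24)]
        bulge[free] *= 1.3
        path = lp.GuidingPath(
            points=bulge, cyclic=True, fixed_indices=path.fixed_indices
        ).reparameterize()
        res = lp.string_optimize(
            pot, path, k_string=2.39, rounds=30, samples_per_round=4000,
            smoothing=0.1, kT=0.2, dt=2.5e-4, friction=0.05, seed=8, tol=0.04,
        )
        radii = np.linalg.norm(res.path.points, axis=1)
        assert np.max(np.abs(radii - 2.0)) < 0.05

    def test_passes_near_both_saddles(self, landscape):
        rng = np.random.default_rng(12)
        path = lp.init_guiding_path(n=48, radius=2.0)
        perturbed = lp.GuidingPath(
            points=path.points * (1 + rng.normal(0, 0.05, (48, 1))),
            cyclic=True, fixed_indices=path.fixed_indices,
        )
        res = lp.string_optimize(
            landscape, perturbed.reparameterize(), k_string=2.39, rounds=12,
            samples_per_round=6000, smoothing=0.1, kT=lp.kt_at(300.0),
            dt=2.5e-4, friction=0.05, seed=13, tol=0.06,
        )
        spacing = 2 * np.pi * 2.0 / 48
        t_up, t_lo = landscape.saddle_angles()
        for t_saddle in (t_up, t_lo):
            saddle = 2.0 * np.array([math.cos(t_saddle), math.sin(t_saddle)])
            dists = np.linalg.norm(res.path.points - saddle, axis=1)
            assert dists.min() < spacing

    def test_nonconvergence_warns(self, landscape):
        path = lp.init_guiding_path(n=16, radius=2.0, active_index=8)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = lp.string_optimize(
                landscape, path, rounds=2, samples_per_round=500,
                kT=lp.kt_at(300.0), dt=2.5e-4, friction=0.05, seed=3, tol=1e-9,
            )
        assert isinstance(res, StringResult) and not res.converged
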