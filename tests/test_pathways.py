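"""Minima detection, MFEP extraction, minimax oracle, barrier arithmetic."""

import numpy as np
import pytest
from scipy import stats

import loadpath as lp
from loadpath.pathways import Minimum


def _grid(nx=40, ny=40, spacing=0.1, origin=(-2.0, -2.0)):
    return lp.GridSpec(origin=origin, spacing=(spacing, spacing), shape=(nx, ny))


def _pmf_from_values(values, grid=None):
    values = np.asarray(values, dtype=float)
    grid = grid or lp.GridSpec(
        origin=(0.0, 0.0), spacing=(1.0, 1.0), shape=values.shape
    )
    return lp.PMFGrid(
        grid=grid,
        values=values - np.nanmin(values),
        counts=np.ones(values.shape, dtype=int),
        kT=0.6,
    )


class TestFindMinima:
    def test_mimetic_grid_has_exactly_two(self, analytic_pmf):
        minima = lp.find_minima(analytic_pmf, prominence=0.5)
        assert len(minima) == 2
        assert minima[0].value == pytest.approx(0.0, abs=1e-9)
        assert minima[1].value == pytest.approx(2.5, abs=0.05)  # cell-center offset
        # deepest at the active site (positive x), second at the interface
        assert minima[0].point[0] > 0 and minima[1].point[0] < 0

    def test_flat_surface_has_none(self):
        pmf = _pmf_from_values(np.zeros((12, 12)))
        assert lp.find_minima(pmf) == []

    def test_paraboloid_has_one_at_center(self):
        g = _grid(21, 21, 0.1, (-1.05, -1.05))
        pot = lp.make_test_potential("harmonic", k=1.0, center=(0.0, 0.0))
        pmf = lp.grid_from_potential(pot, g)
        minima = lp.find_minima(pmf, prominence=0.01)
        assert len(minima) == 1
        assert minima[0].cell == (10, 10)


class TestMinimax:
    def test_two_adjacent_cells(self):
        vals = np.array([[1.0, 3.0]])
        pmf = _pmf_from_values(vals)
        assert lp.minimax_barrier(pmf, (0, 0), (0, 1)) == pytest.approx(2.0)

    def test_start_equals_end(self):
        pmf = _pmf_from_values(np.array([[0.7]]))
        assert lp.minimax_barrier(pmf, (0, 0), (0, 0)) == pytest.approx(0.0)

    def test_disconnected_raises(self):
        vals = np.zeros((3, 3))
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = counts[2, 2] = 1
        pmf = lp.PMFGrid(grid=_grid(3, 3), values=vals, counts=counts, kT=0.6)
        with pytest.raises(ValueError, match="disconnected"):
            lp.minimax_barrier(pmf, (0, 0), (2, 2))

    def test_mimetic_saddle_height(self, analytic_pmf):
        minima = lp.find_minima(analytic_pmf, prominence=0.5)
        peak = lp.minimax_barrier(analytic_pmf, minima[0], minima[1])
        assert peak == pytest.approx(4.2, abs=0.1)


class TestMFEP:
    def test_start_equals_end_single_point(self, analytic_pmf):
        minima = lp.find_minima(analytic_pmf, prominence=0.5)
        path = lp.mfep_on_grid(analytic_pmf, minima[0], minima[0])
        assert path.points.shape[0] == 1
        report = lp.barrier_from_path(path, reference=minima[0])
        assert report.barrier == 0.0

    def test_branches_agree_on_symmetric_fixture(self, analytic_pmf):
        minima = lp.find_minima(analytic_pmf, prominence=0.5)
        up = lp.mfep_on_grid(analytic_pmf, minima[1], minima[0], branch="upper")
        lo = lp.mfep_on_grid(analytic_pmf, minima[1], minima[0], branch="lower")
        assert abs(up.peak - lo.peak) < 0.1
        # the two branches really run through opposite half-planes
        assert np.max(up.points[:, 1]) > 1.0 and np.min(lo.points[:, 1]) < -1.0

    def test_string_peak_vs_minimax_oracle(self, analytic_pmf):
        minima = lp.find_minima(analytic_pmf, prominence=0.5)
        oracle = lp.minimax_barrier(analytic_pmf, minima[0], minima[1])
        for branch in ("upper", "lower"):
            path = lp.mfep_on_grid(analytic_pmf, minima[1], minima[0], branch=branch)
            assert path.peak == pytest.approx(oracle, abs=0.15)
            # minimax is the grid-exact lower bound on any path's maximum
            assert path.peak >= oracle - 0.05

    def test_follows_quadratic_valley(self):
        # trough along y = 0.3 x^2 between minima at x = +/- 1
        g = lp.GridSpec(origin=(-1.6, -0.8), spacing=(0.05, 0.05), shape=(64, 40))

        class Valley(lp.Potential):
            dimensionality = 2
            name = "parabolic_valley"
            params = {}

            def energy_at(self, p):
                p = np.asarray(p, dtype=float)
                x, y = p[..., 0], p[..., 1]
                return 5.0 * (y - 0.3 * x * x) ** 2 + (x * x - 1.0) ** 2

            def gradient_at(self, p):  # pragma: no cover
                raise NotImplementedError

        pmf = lp.grid_from_potential(Valley(), g)
        minima = lp.find_minima(pmf, prominence=0.1)
        assert len(minima) == 2
        path = lp.mfep_on_grid(pmf, minima[0], minima[1])
        dev = np.abs(path.points[:, 1] - 0.3 * path.points[:, 0] ** 2)
        assert np.max(dev) < 0.05  # within one cell of the valley floor

    def test_unknown_branch(self, analytic_pmf):
        minima = lp.find_minima(analytic_pmf, prominence=0.5)
        with pytest.raises(ValueError, match="branch"):
            lp.mfep_on_grid(analytic_pmf, minima[0], minima[1], branch="sideways")


class TestBarrierReport:
    def test_flat_path(self):
        m = Minimum(cell=(0, 0), point=(0.0, 0.0), value=0.0)
        path = lp.Path(
            points=np.zeros((5, 2)), energies=np.zeros(5), branch="upper",
            endpoints=(m, m),
        )
        report = lp.barrier_from_path(path, reference=m)
        assert report.barrier == 0.0

    def test_monotone_path_barrier_is_endpoint_difference(self):
        a = Minimum(cell=(0, 0), point=(0.0, 0.0), value=0.0)
        b = Minimum(cell=(4, 0), point=(4.0, 0.0), value=2.0)
        path = lp.Path(
            points=np.stack([np.arange(5.0), np.zeros(5)], axis=-1),
            energies=np.linspace(0.0, 2.0, 5),
            branch="unconstrained",
            endpoints=(a, b),
        )
        report = lp.barrier_from_path(path, reference=a)
        assert report.barrier == pytest.approx(2.0)

    def test_arithmetic_identity(self, study_report):
        for rep in study_report.barriers.values():
            assert rep.barrier == rep.peak - rep.baseline

    def test_reference_must_be_endpoint(self, analytic_pmf):
        minima = lp.find_minima(analytic_pmf, prominence=0.5)
        path = lp.mfep_on_grid(analytic_pmf, minima[1], minima[0], branch="upper")
        stranger = Minimum(cell=(0, 0), point=(9.0, 9.0), value=1.0)
        with pytest.raises(ValueError, match="endpoint"):
            lp.barrier_from_path(path, reference=stranger)

    def test_empty_path(self):
        m = Minimum(cell=(0, 0), point=(0.0, 0.0), value=0.0)
        path = lp.Path(
            points=np.zeros((0, 2)), energies=np.zeros(0), branch="x",
            endpoints=(m, m),
        )
        with pytest.raises(ValueError, match="empty"):
            lp.barrier_from_path(path)


class TestTransitionResampling:
    def _setup(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (500, 2))
        grid = lp.GridSpec(origin=(0.0, 0.0), spacing=(0.5, 0.5), shape=(2, 2))
        w = np.ones(500) / 500
        return x, w, grid

    def test_default_count(self):
        x, w, grid = self._setup()
        idx = lp.resample_transition_ensemble(x, w, grid, (0, 0), seed=1)
        assert idx.shape == (100,)

    def test_single_sample_cell(self):
        x = np.array([[0.1, 0.1]])
        grid = lp.GridSpec(origin=(0.0, 0.0), spacing=(1.0, 1.0), shape=(1, 1))
        idx = lp.resample_transition_ensemble(x, np.ones(1), grid, (0, 0), n=7, seed=2)
        assert np.all(idx == 0)

    def test_empty_cell_raises(self):
        x, w, grid = self._setup()
        far = np.array([[0.1, 0.1]])
        small_grid = lp.GridSpec(origin=(0.0, 0.0), spacing=(0.05, 0.05), shape=(20, 20))
        with pytest.raises(ValueError, match="no samples"):
            lp.resample_transition_ensemble(far, np.ones(1), small_grid, (19, 19), seed=3)

    def test_uniform_weights_multinomial_frequencies(self):
        # chi-square at level 0.01 with n = 1e5 draws over m = 10 samples
        m, n = 10, 100_000
        x = np.column_stack([np.linspace(0.01, 0.09, m), np.full(m, 0.05)])
        grid = lp.GridSpec(origin=(0.0, 0.0), spacing=(0.1, 0.1), shape=(1, 1))
        idx = lp.resample_transition_ensemble(x, np.ones(m), grid, (0, 0), n=n, seed=4)
        observed = np.bincount(idx, minlength=m)
        chi2 = float(np.sum((observed - n / m) ** 2 / (n / m)))
        assert chi2 < stats.chi2(df=m - 1).ppf(0.99)

    def test_seed_determinism(self):
        x, w, grid = self._setup()
        a = lp.resample_transition_ensemble(x, w, grid, (1, 1), seed=9)
        b = lp.resample_transition_ensemble(x, w, grid, (1, 1), seed=9)
        assert np.array_equal(a, b)
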