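"""Residue selections, Kabsch superposition, RMSD series and windowed RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats
from scipy.spatial.transform import Rotation

import loadpath as lp

GATE_STUDY_SELECTION = (
    "89–92, 95, 98–105, 110–114, 176–181, 200–210, "
    "242, 243–245, 259–261, 274–278, 308–321"
)


class TestSelectionParser:
    def test_gate_study_selection_has_61_residues(self):
        sel = lp.parse_residue_selection(GATE_STUDY_SELECTION)
        assert len(sel) == 61

    def test_simple_range(self):
        sel = lp.parse_residue_selection("1-3")
        assert sel.indices.tolist() == [1, 2, 3]

    def test_deduplication(self):
        sel = lp.parse_residue_selection("5,5,4-6")
        assert sel.indices.tolist() == [4, 5, 6]

    @pytest.mark.parametrize("bad", ["7-3", "a-b", "1,,x", "3.5", ""])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            lp.parse_residue_selection(bad)

    @given(
        st.lists(
            st.integers(min_value=1, max_value=400), min_size=1, max_size=40
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_round_trip(self, indices):
        text = ",".join(str(i) for i in indices)
        once = lp.parse_residue_selection(text)
        again = lp.parse_residue_selection(once.to_string())
        assert np.array_equal(once.indices, again.indices)


def _random_frame(rng, n=12):
    return rng.normal(0, 3.0, (n, 3))


class TestKabsch:
    def test_identical_frames(self):
        rng = np.random.default_rng(0)
        a = _random_frame(rng)
        _, rmsd = lp.kabsch_rmsd(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        a = _random_frame(rng)
        rot = Rotation.random(random_state=2).as_matrix()
        b = a @ rot.T + np.array([3.0, -1.0, 7.0])
        (r, t), rmsd = lp.kabsch_rmsd(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(b @ r.T + t, a, atol=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = _random_frame(rng), _random_frame(rng)
        _, ab = lp.kabsch_rmsd(a, b)
        _, ba = lp.kabsch_rmsd(b, a)
        assert ab == pytest.approx(ba, rel=1e-10)

    def test_matches_rotation_grid_search_oracle(self):
        # two small fixed coordinate sets: brute-force minimization over
        # Euler angles (independent of the closed-form solution)
        a = np.array([[0.0, 0.0, 0.0], [1.2, 0.1, -0.3], [0.4, 1.5, 0.2],
                      [-0.8, 0.6, 1.1]])
        b = np.array([[0.1, -0.2, 0.05], [1.0, 0.3, 0.2], [0.6, 1.2, -0.4],
                      [-0.9, 0.8, 0.9]])
        _, rmsd = lp.kabsch_rmsd(a, b)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def cost(angles):
            rot = Rotation.from_euler("xyz", angles).as_matrix()
            return float(np.mean(np.sum((bc @ rot.T - ac) ** 2, axis=-1)))

        best = np.inf
        rng = np.random.default_rng(11)
        for _ in range(40):
            res = optimize.minimize(cost, rng.uniform(-np.pi, np.pi, 3),
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-14})
            best = min(best, np.sqrt(res.fun))
        assert rmsd == pytest.approx(best, abs=1e-4)

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            lp.kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degenerate(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            lp.kabsch_rmsd(line, line + 0.0)


class TestRMSDSeries:
    def _ensemble(self, coords, dt=1.0):
        return lp.CoordinateEnsemble(
            coords=coords, site_labels=np.arange(1, coords.shape[1] + 1),
            time_per_frame=dt,
        )

    def test_reference_against_itself(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(0, 1, (5, 10, 3))
        ens = self._ensemble(frames)
        _, series = lp.rmsd_series(ens, reference_frame=0)
        assert series[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_body_motion_gives_zero_series(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 2, (12, 3))
        frames = []
        for k in range(6):
            rot = Rotation.from_euler("z", 0.3 * k).as_matrix()
            frames.append(base @ rot.T + k * np.array([0.5, 0.0, -0.2]))
        ens = self._ensemble(np.stack(frames))
        _, series = lp.rmsd_series(ens, reference_frame=0)
        assert np.max(series) < 1e-10

    def test_gate_rmsd_grows_when_gate_destabilized(self):
        ens = lp.make_gate_ensemble(
            n_sites=60, gate_range="20-30", n_runs=1, frames_per_window=30,
            n_windows=4, sigma_base=0.2, gate_amplification=2.0, seed=4,
        )[0]
        gate = lp.parse_residue_selection("20-30").zero_based()
        _, series = lp.rmsd_series(ens, reference_frame=0, report_selection=gate)
        early, late = series[1:60], series[60:]
        test = stats.mannwhitneyu(late, early, alternative="greater")
        assert test.pvalue < 0.01

    def test_empty_report_selection(self):
        rng = np.random.default_rng(2)
        ens = self._ensemble(rng.normal(0, 1, (4, 8, 3)))
        with pytest.raises(ValueError, match="empty"):
            lp.rmsd_series(ens, report_selection=np.array([], dtype=int))


class TestRMSFWindows:
    def test_frozen_ensemble_is_all_zero(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(0, 2, (20, 3))
        ens = lp.CoordinateEnsemble(
            coords=np.tile(frame, (40, 1, 1)),
            site_labels=np.arange(1, 21), time_per_frame=1.0,
        )
        table = lp.rmsf_windows([ens], window_frames=10)
        assert np.max(table.per_run) < 1e-12

    def test_iid_jitter_closed_form(self):
        # per-axis sigma gives RMSF = sigma*sqrt(3); check the site-averaged
        # value within 3 standard errors of the mean over sites
        sigma, n_frames, n_sites = 0.4, 200, 120
        ens = lp.make_gate_ensemble(
            n_sites=n_sites, gate_range="1-1", n_runs=1,
            frames_per_window=n_frames, n_windows=1, sigma_base=sigma,
            gate_amplification=1.0, seed=9,
        )[0]
        table = lp.rmsf_windows([ens], window_frames=n_frames)
        expected = sigma * np.sqrt(3)
        per_site = table.per_run[0, 0]
        se_site = expected / np.sqrt(2 * 3 * n_frames)  # chi-distribution spread
        se_mean = se_site / np.sqrt(n_sites)
        assert abs(np.mean(per_site) - expected) < 3 * se_mean + expected / n_frames

    def test_null_amplification_gate_indistinguishable(self):
        ens = lp.make_gate_ensemble(
            n_sites=80, gate_range="10-20", n_runs=4, frames_per_window=25,
            n_windows=4, sigma_base=0.3, gate_amplification=1.0, seed=13,
        )
        table = lp.rmsf_windows(ens, window_frames=25)
        gate = lp.parse_residue_selection("10-20").zero_based()
        rest = np.setdiff1d(np.arange(80), gate)
        late = table.run_average[-1]
        t = stats.ttest_ind(late[gate], late[rest])
        assert t.pvalue > 0.01

    def test_zero_sigma_is_zero_everywhere(self):
        ens = lp.make_gate_ensemble(
            n_sites=30, gate_range="5-8", n_runs=2, frames_per_window=10,
            n_windows=2, sigma_base=0.0, gate_amplification=2.0, seed=3,
        )
        table = lp.rmsf_windows(ens, window_frames=10)
        assert np.max(table.per_run) < 1e-12

    def test_gate_amplification_doubles_late_rmsf(self):
        amp = 2.0
        ens = lp.make_gate_ensemble(
            n_sites=120, gate_range="40-60", n_runs=8, frames_per_window=50,
            n_windows=4, sigma_base=0.3, gate_amplification=amp, seed=21,
        )
        table = lp.rmsf_windows(ens, window_frames=50)
        gate = lp.parse_residue_selection("40-60").zero_based()
        early = np.mean(table.run_average[0][gate])
        late = np.mean(table.run_average[-1][gate])
        assert late / early == pytest.approx(amp, rel=0.05)

    def test_eight_run_gate_fixture_separates_gate_sites(self):
        ens = lp.make_gate_ensemble(seed=30)  # defaults: 330 sites, 8 runs
        table = lp.rmsf_windows(ens, window_frames=20)
        gate = lp.parse_residue_selection("96-106").zero_based()
        rest = np.setdiff1d(np.arange(330), gate)
        late = table.run_average[-1]
        assert np.mean(late[gate]) > 2.0 * np.mean(late[rest])

    def test_run_relabeling_invariance(self):
        ens = lp.make_gate_ensemble(
            n_sites=40, gate_range="10-12", n_runs=3, frames_per_window=15,
            n_windows=2, sigma_base=0.2, gate_amplification=1.5, seed=6,
        )
        a = lp.rmsf_windows(ens, window_frames=15)
        b = lp.rmsf_windows(ens[::-1], window_frames=15)
        assert np.allclose(a.run_average, b.run_average, atol=1e-12)

    def test_window_longer_than_run(self):
        ens = lp.make_gate_ensemble(
            n_sites=20, gate_range="2-4", n_runs=1, frames_per_window=5,
            n_windows=2, sigma_base=0.1, gate_amplification=1.0, seed=1,
        )
        with pytest.raises(ValueError, match="longer"):
            lp.rmsf_windows(ens, window_frames=100)


class TestGateFixtureContracts:
    def test_gate_range_bounds_checked(self):
        with pytest.raises(ValueError, match="outside"):
            lp.make_gate_ensemble(n_sites=50, gate_range="40-60", seed=1)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            lp.make_gate_ensemble()

    def test_amplification_below_one_rejected(self):
        with pytest.raises(ValueError):
            lp.make_gate_ensemble(gate_amplification=0.5, seed=1)
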