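"""State variables: geometry, spring law, pressure, entropy, temperature."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

import swarmstate as ss
from swarmstate.errors import InsufficientDataError
from swarmstate.state import LN2

from conftest import random_snapshot


def snap(positions, velocities=None, accelerations=None):
    positions = np.asarray(positions, dtype=float)
    return ss.FrameSnapshot(
        time=0.0,
        positions=positions,
        velocities=velocities,
        accelerations=accelerations,
        ids=np.arange(len(positions)),
    )


UNIT_TETRA = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


class TestCentreOfMass:
    def test_identity_and_symmetry(self):
        np.testing.assert_array_equal(ss.centre_of_mass(snap([[1, 2, 3]])), [1, 2, 3])
        np.testing.assert_array_equal(
            ss.centre_of_mass(snap([[1, 0, 0], [-1, 0, 0]])), [0, 0, 0]
        )

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 10, (8, 3))
        c = np.array([5.0, -3.0, 7.0])
        np.testing.assert_allclose(
            ss.centre_of_mass(snap(pts + c)), ss.centre_of_mass(snap(pts)) + c
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ss.centre_of_mass(snap(np.empty((0, 3))))


class TestConvexHullVolume:
    def test_unit_cube(self):
        corners = np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
        )
        assert ss.convex_hull_volume(snap(corners)) == pytest.approx(1.0)

    def test_unit_tetrahedron(self):
        assert ss.convex_hull_volume(snap(UNIT_TETRA)) == pytest.approx(1 / 6)

    def test_degenerate_configurations_flagged(self):
        assert np.isnan(ss.convex_hull_volume(snap(UNIT_TETRA[:3])))
        coplanar = np.column_stack([np.arange(6.0), np.arange(6.0) ** 2, np.zeros(6)])
        assert np.isnan(ss.convex_hull_volume(snap(coplanar)))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10.0))
    def test_rigid_motion_invariance_and_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 30, (50, 3))
        v0 = ss.convex_hull_volume(snap(pts))
        R = Rotation.random(random_state=seed).as_matrix()
        moved = pts @ R.T + rng.normal(0, 100, 3)
        assert ss.convex_hull_volume(snap(moved)) == pytest.approx(v0, rel=1e-9)
        assert ss.convex_hull_volume(snap(pts * scale)) == pytest.approx(
            v0 * scale**3, rel=1e-9
        )

    def test_monotone_under_point_deletion(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 30, (40, 3))
        full = ss.convex_hull_volume(snap(pts))
        assert ss.convex_hull_volume(snap(pts[:20])) <= full + 1e-12


class TestInstantaneousSpring:
    def test_pure_harmonic_recovers_k_exactly(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 50, (20, 3))
        x_rel = pts - pts.mean(axis=0)
        k0 = 10.0
        s = snap(pts, accelerations=-k0 * x_rel)
        assert ss.instantaneous_spring(s) == pytest.approx(k0, rel=1e-12)

    def test_perpendicular_accelerations_give_zero(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 50, (30, 3))
        x_rel = pts - pts.mean(axis=0)
        perp = np.cross(x_rel, rng.normal(0, 1, (30, 3)))
        assert ss.instantaneous_spring(snap(pts, accelerations=perp)) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_mixed_accelerations_match_brute_force(self):
        rng = np.random.default_rng(3)
        s = random_snapshot(rng, n=25)
        com = s.positions.mean(axis=0)
        vals = []
        for p, a in zip(s.positions, s.accelerations):
            rvec = p - com
            r = np.linalg.norm(rvec)
            vals.append(-np.dot(a, rvec / r) / r)
        assert ss.instantaneous_spring(s) == pytest.approx(np.mean(vals), rel=1e-12)


class TestSpringLaw:
    def test_exact_power_law_recovered(self):
        n = np.array([10, 20, 40, 80])
        law = ss.fit_spring_law(n, 5.0 * n ** (-0.8))
        assert law.a == pytest.approx(5.0, abs=1e-10)
        assert law.b == pytest.approx(-0.8, abs=1e-10)

    def test_noisy_exponent_within_band(self):
        rng = np.random.default_rng(11)
        n = np.linspace(10, 100, 30)
        k = 5.0 * n ** (-0.8) * np.exp(rng.normal(0, 0.1, 30))
        law = ss.fit_spring_law(n, k)
        assert abs(law.b - (-0.8)) < 0.1

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            ss.fit_spring_law([10, 20], [1.0, 0.5])
        with pytest.raises(ValueError):
            ss.fit_spring_law([10, 20, 30], [1.0, -0.5, 0.2])

    def test_constant_law(self):
        law = ss.SpringLaw.constant(4.0)
        assert law(10) == 4.0 and law(100) == 4.0


class TestVirialPressure:
    def test_zero_case(self):
        s = snap(UNIT_TETRA, velocities=np.zeros((4, 3)))
        assert ss.virial_pressure(s, k=0.0, volume=1 / 6) == 0.0

    def test_hand_evaluated_tetrahedron(self):
        v = np.zeros((4, 3))
        v[:, 0] = 1.0  # each speed 1 mm/s
        s = snap(UNIT_TETRA, velocities=v)
        assert ss.virial_pressure(s, k=0.0, volume=1 / 6) == pytest.approx(2.0)
        # sum r_i^2 about the centroid is 2.25, so P = (4 - 0.5*2.25)/2
        assert ss.virial_pressure(s, k=1.0, volume=1 / 6) == pytest.approx(1.4375)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_per_midge_sum(self, seed):
        rng = np.random.default_rng(seed)
        s = random_snapshot(rng, n=int(rng.integers(2, 30)))
        k, vol = 3.0, 1.7e6
        com = s.positions.mean(axis=0)
        total = 0.0
        for p, v in zip(s.positions, s.velocities):
            total += np.dot(v, v) - 0.5 * k * np.dot(p - com, p - com)
        expected = total / (3 * s.n * vol)
        assert ss.virial_pressure(s, k, vol) == pytest.approx(expected, rel=1e-12)

    def test_bad_volume_raises(self):
        s = snap(UNIT_TETRA, velocities=np.zeros((4, 3)))
        with pytest.raises(ValueError):
            ss.virial_pressure(s, k=1.0, volume=0.0)


class TestGaussianMoments:
    def test_monte_carlo_recovers_generating_sigma(self):
        rng = np.random.default_rng(5)
        snaps = [
            snap(
                rng.normal(0, 80, (100, 3)),
                velocities=rng.normal(0, 200, (100, 3)),
            )
            for _ in range(1000)
        ]
        m = ss.gaussian_moments(snaps)
        assert m.sigma_v == pytest.approx(200.0, abs=2.0)

    def test_constant_velocity_rms_about_zero(self):
        v = np.tile([3.0, 4.0, 0.0], (5, 1))
        rng = np.random.default_rng(6)
        m = ss.gaussian_moments([snap(rng.normal(0, 10, (5, 3)), velocities=v)])
        np.testing.assert_allclose(m.sigma_v_components, [3.0, 4.0, 0.0], atol=1e-12)

    def test_no_valid_frames_raises(self):
        with pytest.raises(InsufficientDataError):
            ss.gaussian_moments([snap([[0, 0, 0]], velocities=np.zeros((1, 3)))])


def numeric_entropy_bits(sigma_x, sigma_v, n):
    """Oracle: numerically integrate the 1D Gaussian differential entropies."""

    def h(sigma):
        def integrand(u):
            p = np.exp(-u**2 / (2 * sigma**2)) / np.sqrt(2 * np.pi * sigma**2)
            return -p * np.log2(p) if p > 0 else 0.0

        val, _ = quad(integrand, -12 * sigma, 12 * sigma, limit=200)
        return val

    return 3 * n * (h(sigma_x) + h(sigma_v))


class TestEntropy:
    def test_closed_form_matches_numerical_integration(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            sx = float(np.exp(rng.uniform(np.log(0.1), np.log(1000))))
            sv = float(np.exp(rng.uniform(np.log(0.1), np.log(1000))))
            n = int(rng.integers(1, 50))
            s_closed = ss.entropy((sx, sv), n)
            s_num = numeric_entropy_bits(sx, sv, n)
            assert abs(s_closed - s_num) <= 1e-3 * abs(s_num)

    def test_unit_sigmas_single_midge(self):
        assert ss.entropy((1.0, 1.0), 1) == pytest.approx(3 * np.log2(2 * np.pi * np.e))

    def test_doubling_sigma_x_adds_3n_bits(self):
        for n in (1, 7, 30):
            assert ss.entropy((2.0, 5.0), n) - ss.entropy((1.0, 5.0), n) == pytest.approx(
                3 * n
            )

    def test_extensivity(self):
        assert ss.entropy((3.0, 4.0), 10) * 2 == pytest.approx(ss.entropy((3.0, 4.0), 20))

    def test_bad_moments_raise(self):
        with pytest.raises(ValueError):
            ss.entropy((0.0, 1.0), 5)


class TestTemperature:
    def test_large_n_limit_is_sigma_sq_ln2(self):
        assert ss.temperature(1.0, 10**6) == pytest.approx(LN2, rel=1e-6)

    def test_single_midge_value(self):
        assert ss.temperature(1.0, 1) == pytest.approx(1.5 * (2 ** (2 / 3) - 1))

    def test_decreasing_toward_limit_and_within_2pct_beyond_20(self):
        vals = np.array([ss.temperature(1.0, n) for n in range(1, 201)])
        assert np.all(np.diff(vals) < 0)
        dev = vals / LN2 - 1.0
        assert np.all(dev[19:] < 0.02)
        assert np.all(dev >= 0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ss.temperature(1.0, 0)


class TestEnergies:
    def test_at_rest_at_centre(self):
        s = snap(np.zeros((3, 3)), velocities=np.zeros((3, 3)))
        assert ss.energies(s, k=2.0) == (0.0, 0.0, 0.0)

    def test_hand_value_single_midge(self):
        # one midge: COM coincides with it, so use two symmetric midges instead
        pts = np.array([[3.0, 0, 0], [-3.0, 0, 0]])
        v = np.array([[0, 2.0, 0], [0, -2.0, 0]])
        ek, ep, e = ss.energies(snap(pts, velocities=v), k=1.0)
        assert ek == pytest.approx(4.0)   # 2 * 0.5*4
        assert ep == pytest.approx(9.0)   # 2 * 0.5*1*9
        assert e == pytest.approx(13.0)

    def test_additive_over_disjoint_subsets(self):
        rng = np.random.default_rng(9)
        s = random_snapshot(rng, n=12)
        com = s.positions.mean(axis=0)
        # additivity holds for a fixed reference point: re-centre manually
        def energy(idx):
            p = s.positions[idx] - com
            v = s.velocities[idx]
            return 0.5 * np.sum(v**2) + 0.5 * 2.0 * np.sum(p**2)

        full = energy(np.arange(12))
        assert energy(np.arange(6)) + energy(np.arange(6, 12)) == pytest.approx(full)


class TestStateSeries:
    def test_series_covers_all_frames(self, sim_series, sim_recording):
        assert len(sim_series) == sim_recording.n_frames
        e = sim_series["E"]
        np.testing.assert_allclose(e, sim_series["Ek"] + sim_series["Ep"], rtol=1e-12)

    def test_degenerate_frames_flagged(self):
        # 3 midges only: hull degenerate at every frame, N still reported
        rng = np.random.default_rng(10)
        tracks = [
            ss.MidgeTrack(f"t{i}", 0, rng.normal(0, 50, (50, 3))) for i in range(3)
        ]
        rec = ss.differentiate(ss.SwarmRecording(tracks=tracks))
        series = ss.compute_state_series(rec, ss.SpringLaw.constant(4.0))
        assert np.all(series["N"] == 3)
        assert np.all(np.isnan(series["V"]))
        assert np.all(np.isnan(series["P"]))
        assert np.all(np.isfinite(series["E"]))

    def test_csv_round_trip(self, sim_series, tmp_path):
        path = tmp_path / "state.csv"
        sim_series.to_csv(path)
        back = ss.StateSeries.from_csv(path)
        np.testing.assert_allclose(back["P"], sim_series["P"], rtol=1e-12, equal_nan=True)
        header = path.read_text().splitlines()[0]
        assert header.startswith("time,N,V,P,S,T,Ek,Ep,E,sigma_x,sigma_v")

    def test_spring_recovery_from_simulation(self, sim_recording):
        tab = ss.spring_by_size(sim_recording)
        k_hat = float(np.average(tab["k"], weights=tab["count"]))
        assert k_hat == pytest.approx(4.0, rel=0.05)

    def test_empty_recording_raises(self):
        with pytest.raises(InsufficientDataError):
            ss.compute_state_series(
                ss.SwarmRecording(tracks=[]), ss.SpringLaw.constant(1.0)
            )
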