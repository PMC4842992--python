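import numpy as np
import pytest

import spisim as sp
from spisim import atomic, fixtures
from spisim.damage import DamageTrajectory, Snapshot
from spisim.diffraction import DetectorGeometry, quaternion_to_matrix
from spisim.pulse import BeamAtSample, Pulse

IDENTITY_Q = np.array([1.0, 0.0, 0.0, 0.0])


def brute_force_intensity(system, qmap, orientation, bound=None):
    """Independent direct-summation oracle over atoms (no chunking, no
    shared element tables)."""
    rot = quaternion_to_matrix(orientation)
    qv = qmap.q_vectors.reshape(-1, 3) @ rot
    qabs = np.linalg.norm(qv, axis=1)
    bound = system.bound_electrons if bound is None else bound
    amp = np.zeros(len(qv), dtype=complex)
    for j in range(system.n_atoms):
        f = atomic.form_factor(int(system.elements[j]), qabs)
        occ = bound[j] / system.elements[j]
        amp += occ * f * np.exp(1j * (qv @ system.positions[j]))
    shape = qmap.solid_angle.shape
    return (atomic.R_E_NM ** 2 * qmap.solid_angle
            * qmap.polarization * np.abs(amp.reshape(shape)) ** 2)


class TestQMap:
    def test_central_pixel_is_forward_direction(self, desk_geom, qmap):
        c = (desk_geom.n_slow - 1) // 2
        assert np.linalg.norm(qmap.q_vectors[c, c]) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_magnitude_matches_ewald_identity(self, desk_geom, qmap):
        """|q| = (4 pi / lambda) sin(theta) for every pixel."""
        lam = desk_geom.wavelength
        c = (desk_geom.n_slow - 1) / 2.0
        j, i = 5, 30
        r = desk_geom.pixel_size * np.hypot(i - c, j - c)
        two_theta = np.arctan2(r, desk_geom.distance)
        expected = 4 * np.pi / lam * np.sin(two_theta / 2)
        assert np.linalg.norm(qmap.q_vectors[j, i]) == pytest.approx(
            expected, rel=1e-12)

    def test_corner_pixel_hand_trigonometry(self):
        geom = DetectorGeometry(n_fast=81, n_slow=81, pixel_size=300e-6,
                                distance=0.13, gap_rows=0, wavelength=2.48)
        q = sp.build_qmap(geom)
        r = 40 * 300e-6 * np.sqrt(2.0)
        theta = 0.5 * np.arctan2(r, 0.13)
        expected = 4 * np.pi / 2.48 * np.sin(theta)
        assert np.linalg.norm(q.q_vectors[0, 0]) == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_q_within_wavelength_limit(self, desk_geom, qmap):
        assert qmap.q_max <= 4 * np.pi / desk_geom.wavelength

    def test_gap_rows_masked(self, desk_geom):
        c = (desk_geom.n_slow - 1) // 2
        assert not desk_geom.mask[c].any()
        assert not desk_geom.mask[c - 3].any()
        assert desk_geom.mask[c - 4].all()
        assert (~desk_geom.mask).sum() == 7 * desk_geom.n_fast


class TestCoherentIntensity:
    def test_no_atoms_zero(self, qmap):
        empty = sp.AtomicSystem(elements=np.empty(0, int),
                                positions=np.empty((0, 3)))
        I = sp.coherent_intensity(None, empty, qmap, IDENTITY_Q)
        assert np.all(I == 0)

    def test_single_atom_orientation_independent_form_factor(self, qmap):
        point = fixtures.make_fixture("point")
        i1 = sp.coherent_intensity(None, point, qmap, IDENTITY_Q)
        i2 = sp.coherent_intensity(None, point, qmap,
                                   np.array([0.5, 0.5, 0.5, 0.5]))
        assert np.allclose(i1, i2, rtol=1e-10)
        f = atomic.form_factor(6, qmap.q_magnitude)
        expected = atomic.R_E_NM ** 2 * qmap.solid_angle \
            * qmap.polarization * f ** 2
        assert np.allclose(i1, expected, rtol=1e-10)

    def test_two_atom_closed_form_interference(self, qmap):
        """I proportional to 4 f^2 cos^2(q_x d / 2) for a pair on x."""
        pair = fixtures.make_fixture("pair")
        I = sp.coherent_intensity(None, pair, qmap, IDENTITY_Q)
        qx = qmap.q_vectors[..., 0]
        f = atomic.form_factor(6, qmap.q_magnitude)
        closed = atomic.R_E_NM ** 2 * qmap.solid_angle * qmap.polarization \
            * 4 * f ** 2 * np.cos(qx * 10.0 / 2) ** 2
        assert np.max(np.abs(I - closed)) <= 1e-8 * closed.max()

    def test_matches_brute_force_oracle(self, qmap, cluster20):
        quat = np.array([0.8, 0.2, -0.4, 0.4])
        quat /= np.linalg.norm(quat)
        I = sp.coherent_intensity(None, cluster20, qmap, quat)
        ref = brute_force_intensity(cluster20, qmap, quat)
        assert np.max(np.abs(I - ref)) <= 1e-8 * ref.max()

    def test_friedel_symmetry_on_3d_grid(self, cluster20):
        """|F(q)|^2 = |F(-q)|^2 for real occupancy-scaled form factors."""
        rng = np.random.default_rng(0)
        q = rng.uniform(-2, 2, size=(40, 3))
        occ = cluster20.bound_electrons / cluster20.elements
        def ampl(qs):
            qabs = np.linalg.norm(qs, axis=1)
            a = np.zeros(len(qs), complex)
            for j in range(cluster20.n_atoms):
                a += occ[j] * atomic.form_factor(
                    int(cluster20.elements[j]), qabs) \
                    * np.exp(1j * (qs @ cluster20.positions[j]))
            return a
        assert np.allclose(np.abs(ampl(q)) ** 2, np.abs(ampl(-q)) ** 2,
                           rtol=1e-10)

    def test_non_unit_quaternion_rejected(self, qmap, cluster20):
        with pytest.raises(ValueError):
            sp.coherent_intensity(None, cluster20, qmap,
                                  np.array([1.0, 0.5, 0.0, 0.0]))


class TestIncoherentIntensity:
    def test_no_sources_zero(self, qmap):
        empty = sp.AtomicSystem(elements=np.empty(0, int),
                                positions=np.empty((0, 3)))
        snap = Snapshot(0.0, np.empty((0, 3)), np.empty(0), 0, 1.0)
        assert np.all(sp.incoherent_intensity(snap, empty, qmap) == 0)

    def test_free_electron_linearity(self, qmap):
        empty = sp.AtomicSystem(elements=np.empty(0, int),
                                positions=np.empty((0, 3)))
        one = Snapshot(0.0, np.empty((0, 3)), np.empty(0), 1, 1.0)
        five = Snapshot(0.0, np.empty((0, 3)), np.empty(0), 5, 1.0)
        i1 = sp.incoherent_intensity(one, empty, qmap)
        i5 = sp.incoherent_intensity(five, empty, qmap)
        assert np.allclose(i5, 5 * i1, rtol=1e-12)

    @pytest.mark.parametrize("z", [6, 7, 8, 16])
    def test_structure_factor_asymptotes(self, z):
        assert atomic.incoherent_structure_factor(z, np.array([0.0]))[0] == 0
        big = atomic.incoherent_structure_factor(z, np.array([50.0]))[0]
        assert big == pytest.approx(z, rel=0.05)


class TestPatternExpectation:
    def _single_snapshot_traj(self, system):
        snap = Snapshot(0.0, system.positions.copy(),
                        system.bound_electrons.copy(), 0, 1.0)
        return DamageTrajectory(snapshots=[snap], n_photoionisations=0)

    def _beam(self):
        times = np.arange(50) * 0.1 - 2.5
        flux = np.full(50, 1e10)
        p = Pulse(times=times, flux=flux, photon_energy=5000.0,
                  n_photons=flux.sum() * 0.1)
        return sp.apply_beamline(p, 1.0)

    def test_single_snapshot_reduces_to_coherent_times_fluence(
            self, desk_geom, qmap, cluster20):
        p, beam = self._beam()
        traj = self._single_snapshot_traj(cluster20)
        exp = sp.pattern_expectation(traj, cluster20, p, beam, desk_geom,
                                     IDENTITY_Q, include_compton=False)
        ref = sp.coherent_intensity(None, cluster20, qmap, IDENTITY_Q) \
            * beam.peak_fluence
        ref[~desk_geom.mask] = 0.0
        assert np.allclose(exp, ref, rtol=1e-12)

    def test_compton_adds_isotropic_nonnegative_field(
            self, desk_geom, cluster20):
        p, beam = self._beam()
        traj = self._single_snapshot_traj(cluster20)
        on = sp.pattern_expectation(traj, cluster20, p, beam, desk_geom,
                                    IDENTITY_Q, include_compton=True)
        off = sp.pattern_expectation(traj, cluster20, p, beam, desk_geom,
                                     IDENTITY_Q, include_compton=False)
        diff = on - off
        assert np.all(diff >= 0)
        assert diff[desk_geom.mask].max() > 0

    def test_two_snapshot_linearity(self, desk_geom, cluster20):
        """Expectation of a two-snapshot trajectory equals the weighted sum
        of its single-snapshot halves."""
        p, beam = self._beam()
        moved = cluster20.copy()
        moved.positions = moved.positions * 1.05
        s1 = Snapshot(-1.0, cluster20.positions.copy(),
                      cluster20.bound_electrons.copy(), 0, 0.3)
        s2 = Snapshot(1.0, moved.positions.copy(),
                      moved.bound_electrons.copy(), 0, 0.7)
        both = DamageTrajectory(snapshots=[s1, s2], n_photoionisations=0)
        exp = sp.pattern_expectation(both, cluster20, p, beam, desk_geom,
                                     IDENTITY_Q, include_compton=False)
        parts = 0.0
        for s in (s1, s2):
            solo = DamageTrajectory(snapshots=[Snapshot(s.time, s.positions,
                                                        s.bound_electrons, 0,
                                                        1.0)],
                                    n_photoionisations=0)
            part = sp.pattern_expectation(solo, cluster20, p, beam,
                                          desk_geom, IDENTITY_Q,
                                          include_compton=False)
            parts = parts + s.weight * part
        assert np.allclose(exp, parts, rtol=1e-12)

    def test_exploding_trajectory_loses_high_q_speckle_contrast(
            self, desk_geom, qmap, cluster20):
        """Coulomb-exploding snapshots wash out high-q speckle relative to a
        frozen molecule."""
        p, beam = self._beam()
        n_s = 8
        frozen_snaps, exploding_snaps = [], []
        for k in range(n_s):
            t = -2.0 + k * 0.5
            w = 1.0 / n_s
            frozen_snaps.append(Snapshot(t, cluster20.positions.copy(),
                                         cluster20.bound_electrons.copy(),
                                         0, w))
            grow = 1.0 + 0.12 * k
            exploding_snaps.append(Snapshot(
                t, cluster20.positions * grow,
                cluster20.bound_electrons.copy(), 0, w))
        frozen = DamageTrajectory(frozen_snaps, 0)
        boom = DamageTrajectory(exploding_snaps, 0)
        high_q = (qmap.q_magnitude > 0.6 * qmap.q_max) & desk_geom.mask
        out = {}
        for name, traj in [("frozen", frozen), ("boom", boom)]:
            e = sp.pattern_expectation(traj, cluster20, p, beam, desk_geom,
                                       IDENTITY_Q, include_compton=False)
            v = e[high_q]
            out[name] = v.std() / v.mean()
        assert out["boom"] < out["frozen"]

    def test_window_mismatch_rejected(self, desk_geom, cluster20):
        p, beam = self._beam()
        far = DamageTrajectory(snapshots=[Snapshot(
            500.0, cluster20.positions.copy(),
            cluster20.bound_electrons.copy(), 0, 1.0)],
            n_photoionisations=0)
        with pytest.raises(ValueError):
            sp.pattern_expectation(far, cluster20, p, beam, desk_geom,
                                   IDENTITY_Q)


class TestSamplePattern:
    def test_zero_expectation_zero_counts(self):
        pat = sp.sample_pattern(np.zeros((9, 9)), seed=0)
        assert pat.counts.sum() == 0

    def test_poisson_mean_within_three_standard_errors(self):
        expected = np.full((100, 100), 4.0)
        pat = sp.sample_pattern(expected, seed=123)
        se = np.sqrt(4.0 / expected.size)
        assert abs(pat.counts.mean() - 4.0) < 3 * se

    def test_deterministic_per_seed(self):
        e = np.random.default_rng(1).uniform(0, 5, (20, 20))
        a = sp.sample_pattern(e, seed=9)
        b = sp.sample_pattern(e, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_negative_expectation_rejected(self):
        with pytest.raises(ValueError):
            sp.sample_pattern(np.array([[-1.0]]), seed=0)

    def test_masked_pixels_stay_zero(self, desk_geom):
        e = np.full((desk_geom.n_slow, desk_geom.n_fast), 10.0)
        pat = sp.sample_pattern(e, seed=2, mask=desk_geom.mask)
        assert pat.counts[~desk_geom.mask].sum() == 0
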