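"""Geometric components: rotations, angles, moving frames, combinations."""

import math

import numpy as np
import pytest

from colvarkit.geometry import (Angle, AtomGroup, Distance, DistanceXY,
                                DistanceZ, EulerAngle, FittedComponent,
                                MovingFrameSpec, PolarPhi, PolarTheta,
                                PolynomialCombination, Rmsd, euler_angles,
                                euler_to_quaternion, polar_angles)
from colvarkit.rotation import (best_fit_rotation, matrix_to_quaternion,
                                quaternion_derivatives, quaternion_to_matrix)

from conftest import fd_gradient


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return quaternion_to_matrix(q)


class TestBestFitRotation:
    def test_identity(self, rng):
        ref = rng.normal(size=(6, 3))
        fit = best_fit_rotation(ref, ref)
        assert np.allclose(fit.quaternion, [1, 0, 0, 0], atol=1e-12)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_90_degrees_about_z(self, rng):
        pos = rng.normal(size=(5, 3))
        c, s = math.cos(math.pi / 2), math.sin(math.pi / 2)
        Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        ref = pos @ Rz.T  # reference = rotated positions
        fit = best_fit_rotation(pos, ref)
        assert np.allclose(fit.quaternion,
                           [math.sqrt(0.5), 0, 0, math.sqrt(0.5)], atol=1e-9)

    def test_recovers_known_rotation_and_beats_grid_search(self, rng):
        ref = rng.normal(size=(7, 3)) * 2.0
        R = random_rotation(rng)
        pos = ref @ R.T
        fit = best_fit_rotation(pos, ref)
        assert np.allclose(fit.matrix, R.T, atol=1e-8)
        # brute-force search over a coarse SO(3) grid never beats the fit
        best = np.inf
        for a in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            for b in np.linspace(0, np.pi, 7):
                for c in np.linspace(0, 2 * np.pi, 12, endpoint=False):
                    q = euler_to_quaternion(math.degrees(a), math.degrees(b) - 90,
                                            math.degrees(c))
                    Rg = quaternion_to_matrix(q)
                    x = pos - pos.mean(0)
                    y = ref - ref.mean(0)
                    best = min(best, float(np.sqrt(((x @ Rg.T - y) ** 2)
                                                   .sum(1).mean())))
        assert fit.rmsd <= best + 1e-12

    def test_quaternion_matrix_consistency(self, rng):
        pos = rng.normal(size=(6, 3))
        ref = rng.normal(size=(6, 3))
        fit = best_fit_rotation(pos, ref)
        assert np.allclose(quaternion_to_matrix(fit.quaternion), fit.matrix)
        assert np.allclose(fit.matrix @ fit.matrix.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(fit.matrix) == pytest.approx(1.0)
        assert np.allclose(matrix_to_quaternion(fit.matrix), fit.quaternion,
                           atol=1e-9)

    def test_inverse_property(self, rng):
        """Swapping positions and reference inverts the quaternion."""
        a = rng.normal(size=(6, 3)) * 2
        b = rng.normal(size=(6, 3)) * 2
        qa = best_fit_rotation(a, b).quaternion
        qb = best_fit_rotation(b, a).quaternion
        conj = np.array([qa[0], -qa[1], -qa[2], -qa[3]])
        if conj[0] < 0 or (conj[0] == 0 and conj[np.nonzero(conj)[0][0]] < 0):
            conj = -conj
        assert np.allclose(qb, conj, atol=1e-9)

    def test_degenerate_flagged(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        fit = best_fit_rotation(line, line)
        assert fit.degenerate
        with pytest.raises(ValueError):
            quaternion_derivatives(fit, line, line)

    def test_quaternion_derivatives_match_fd(self, rng):
        ref = rng.normal(size=(6, 3)) * 2
        pos = rng.normal(size=(6, 3)) * 2
        w = rng.uniform(0.5, 2.0, 6)
        fit = best_fit_rotation(pos, ref, w)
        dq = quaternion_derivatives(fit, pos, ref, w)
        h = 1e-6
        for a in range(6):
            for k in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[a, k] += h
                pm[a, k] -= h
                fd = (best_fit_rotation(pp, ref, w).quaternion
                      - best_fit_rotation(pm, ref, w).quaternion) / (2 * h)
                assert np.allclose(dq[a, k], fd, atol=1e-7)


class TestPolarAngles:
    def test_closed_forms(self):
        assert polar_angles([0, 0, 1]) == (0.0, 0.0)
        theta, phi = polar_angles([1, 0, 0])
        assert (theta, phi) == (pytest.approx(90.0), pytest.approx(0.0))
        theta, phi = polar_angles(np.ones(3) / math.sqrt(3))
        assert theta == pytest.approx(math.degrees(math.acos(1 / math.sqrt(3))))
        assert phi == pytest.approx(45.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            polar_angles([0, 0, 0])


class TestEulerAngles:
    def test_identity_and_yaw(self):
        assert euler_angles(np.array([1.0, 0, 0, 0])) == (0.0, 0.0, 0.0)
        q = np.array([math.sqrt(0.5), 0, 0, math.sqrt(0.5)])
        roll, pitch, yaw = euler_angles(q)
        assert (roll, pitch) == (pytest.approx(0.0), pytest.approx(0.0))
        assert yaw == pytest.approx(90.0)
        # cross-check the convention: R maps x onto y for a 90 deg yaw
        R = quaternion_to_matrix(q)
        assert np.allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_round_trip_away_from_gimbal(self, rng):
        for _ in range(50):
            roll = rng.uniform(-179, 179)
            pitch = rng.uniform(-85, 85)
            yaw = rng.uniform(-179, 179)
            q = euler_to_quaternion(roll, pitch, yaw)
            r2, p2, y2 = euler_angles(q)
            assert r2 == pytest.approx(roll, abs=1e-9)
            assert p2 == pytest.approx(pitch, abs=1e-9)
            assert y2 == pytest.approx(yaw, abs=1e-9)

    def test_gimbal_lock_clamped_with_warning(self):
        q = euler_to_quaternion(10.0, 90.0, 20.0)
        with pytest.warns(UserWarning):
            roll, pitch, yaw = euler_angles(q)
        assert pitch == pytest.approx(90.0, abs=1e-5)
        assert math.isfinite(roll) and math.isfinite(yaw)


def _groups(rng):
    g1 = AtomGroup([0, 1, 2], weights=rng.uniform(0.5, 2, 3))
    g2 = AtomGroup([3, 4])
    g3 = AtomGroup([5, 6, 7])
    return g1, g2, g3


class TestComponents:
    def test_distance_two_centers(self):
        pos = np.zeros((2, 3))
        pos[1, 0] = 3.0
        comp = Distance(AtomGroup([0]), AtomGroup([1]))
        v, g = comp.evaluate(pos)
        assert v == pytest.approx(3.0)
        assert np.allclose(g[0], [-1, 0, 0])
        assert np.allclose(g[1], [1, 0, 0])

    def test_distance_xy_vanishes_along_axis(self):
        pos = np.zeros((2, 3))
        pos[1, 2] = 5.0
        comp = DistanceXY(AtomGroup([0]), AtomGroup([1]), axis=(0, 0, 1))
        v, _ = comp.evaluate(pos)
        assert v == 0.0

    @pytest.mark.parametrize("build", [
        lambda g1, g2, g3, rng: Distance(g1, g2),
        lambda g1, g2, g3, rng: DistanceZ(g1, g2, axis=(1, 1, 0)),
        lambda g1, g2, g3, rng: DistanceXY(g1, g2, axis=(0, 0, 1)),
        lambda g1, g2, g3, rng: Angle(g1, g2, g3),
        lambda g1, g2, g3, rng: Rmsd(g1, rng.normal(size=(3, 3)) * 2),
        lambda g1, g2, g3, rng: PolarTheta(g1, g2),
        lambda g1, g2, g3, rng: PolarPhi(g1, g2),
        lambda g1, g2, g3, rng: EulerAngle(
            AtomGroup([0, 1, 2, 3, 4]), rng.normal(size=(5, 3)) * 2, "roll"),
        lambda g1, g2, g3, rng: EulerAngle(
            AtomGroup([0, 1, 2, 3, 4]), rng.normal(size=(5, 3)) * 2, "pitch"),
    ])
    def test_gradients_match_finite_differences(self, build, rng):
        g1, g2, g3 = _groups(rng)
        comp = build(g1, g2, g3, rng)
        pos = rng.normal(size=(8, 3)) * 2.0
        v, g = comp.evaluate(pos)
        fd = fd_gradient(comp, pos)
        assert np.allclose(g, fd, rtol=1e-6, atol=1e-7)

    def test_internal_gradients_sum_to_zero(self, rng):
        """Translation invariance of internal coordinates."""
        g1, g2, g3 = _groups(rng)
        pos = rng.normal(size=(8, 3)) * 2.0
        for comp in (Distance(g1, g2), Angle(g1, g2, g3),
                     Rmsd(g1, rng.normal(size=(3, 3)))):
            _, g = comp.evaluate(pos)
            assert np.allclose(g.sum(0), 0.0, atol=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            AtomGroup([])

    def test_rmsd_reference_mismatch(self):
        with pytest.raises(ValueError):
            Rmsd(AtomGroup([0, 1]), np.zeros((3, 3)))


class TestMovingFrame:
    def test_rigid_motion_invariance(self, rng):
        frame = MovingFrameSpec(AtomGroup([3, 4, 5, 6, 7]),
                                rng.normal(size=(5, 3)) * 2)
        comp = FittedComponent(Distance(AtomGroup([0]), AtomGroup([1, 2])),
                               frame)
        pos = rng.normal(size=(8, 3)) * 2
        R = random_rotation(rng)
        moved = pos @ R.T + np.array([3.0, -1.0, 2.0])
        assert comp.evaluate(pos)[0] == pytest.approx(
            comp.evaluate(moved)[0], abs=1e-10)

    def test_self_rmsd_fitting_gradients_zero(self, rng):
        ref = rng.normal(size=(5, 3)) * 2
        group = AtomGroup([0, 1, 2, 3, 4])
        comp = FittedComponent(Rmsd(group, ref), MovingFrameSpec(group, ref))
        pos = rng.normal(size=(5, 3)) * 2
        v, g = comp.evaluate(pos)
        fitted, _, R, _, _ = comp._transform(pos)
        _, g_inner = Rmsd(group, ref).evaluate(fitted)
        assert np.array_equal(g, g_inner @ R)  # exactly the plain gradient

    @pytest.mark.parametrize("inner_factory", [
        lambda rng: Distance(AtomGroup([0]), AtomGroup([1, 2])),
        lambda rng: DistanceZ(AtomGroup([0, 1]), axis=(0, 0, 1)),
        lambda rng: Rmsd(AtomGroup([0, 1, 2, 3]), rng.normal(size=(4, 3))),
        lambda rng: Angle(AtomGroup([0]), AtomGroup([1]), AtomGroup([2])),
    ])
    def test_full_gradient_matches_fd(self, inner_factory, rng):
        """Total gradient (CV atoms + fitting atoms) against central
        differences, including overlapping CV/fitting groups."""
        frame = MovingFrameSpec(AtomGroup([3, 4, 5, 6, 7]),
                                rng.normal(size=(5, 3)) * 2)
        comp = FittedComponent(inner_factory(rng), frame)
        pos = rng.normal(size=(8, 3)) * 2
        _, g = comp.evaluate(pos)
        fd = fd_gradient(comp, pos)
        assert np.allclose(g, fd, rtol=1e-5, atol=1e-6)


class TestPolynomialCombination:
    def test_identity_and_arithmetic(self):
        c = DistanceZ(AtomGroup([0]), axis=(1, 0, 0))
        pos = np.array([[3.0, 0, 0]])
        single = PolynomialCombination([c], [1.0], [1])
        assert single.evaluate(pos)[0] == pytest.approx(3.0)
        # c = (2, -1), p = (1, 2), zeta = (3, 2) -> 2*3 - 1*4 = 2
        c2 = DistanceZ(AtomGroup([1]), axis=(1, 0, 0))
        pos = np.array([[3.0, 0, 0], [2.0, 0, 0]])
        combo = PolynomialCombination([c, c2], [2.0, -1.0], [1, 2])
        assert combo.evaluate(pos)[0] == pytest.approx(2.0)

    def test_matches_naive_summation(self, rng):
        comps = [DistanceZ(AtomGroup([i]), axis=(1, 0, 0)) for i in range(4)]
        coeffs = rng.normal(size=4)
        exps = rng.integers(1, 4, size=4)
        combo = PolynomialCombination(comps, coeffs, exps)
        pos = rng.normal(size=(4, 3))
        naive = sum(c * pos[i, 0] ** p
                    for i, (c, p) in enumerate(zip(coeffs, exps)))
        assert combo.evaluate(pos)[0] == pytest.approx(naive, abs=1e-12)

    def test_exponent_validation(self):
        c = DistanceZ(AtomGroup([0]))
        with pytest.raises(ValueError):
            PolynomialCombination([c], [1.0], [0])
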