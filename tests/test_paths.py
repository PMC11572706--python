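"""Path CVs: arithmetic and geometric forms against projection oracles."""

import numpy as np
import pytest

from colvarkit.geometry import AtomGroup, DistanceZ
from colvarkit.paths import (ArithmeticPathCV, CartesianPathFrames,
                             GeometricPathCV, PathSpec, arithmetic_path,
                             default_lambda, geometric_path)


def projection_oracle(nodes, z, n_dense=200_001):
    """Dense-polyline projection: (s, perpendicular distance)."""
    best = (None, np.inf)
    n = len(nodes)
    for i in range(n - 1):
        t = np.linspace(0.0, 1.0, n_dense // (n - 1))
        seg = nodes[i][None, :] + t[:, None] * (nodes[i + 1] - nodes[i])[None, :]
        d = np.linalg.norm(seg - z[None, :], axis=1)
        j = int(np.argmin(d))
        if d[j] < best[1]:
            best = ((i + t[j]) / (n - 1), d[j])
    return best


class TestArithmeticPath:
    def test_matches_naive_three_term_sum(self):
        spec = PathSpec(np.array([[0.0], [1.0], [2.0]]), weights=[1.0], lam=1.0)
        pv = arithmetic_path(spec, [0.7])
        d = (0.7 - np.array([0.0, 1.0, 2.0])) ** 2
        w = np.exp(-d)
        assert pv.s == pytest.approx((np.arange(3) / 2 @ w) / w.sum(), abs=1e-12)
        assert pv.zeta == pytest.approx(-np.log(w.sum()), abs=1e-12)

    def test_two_node_symmetry(self):
        spec = PathSpec(np.array([[0.0], [2.0]]), lam=1.0)
        assert arithmetic_path(spec, [1.0]).s == pytest.approx(0.5)

    def test_dominant_node_limit(self):
        spec = PathSpec(np.arange(5.0)[:, None], lam=50.0)
        pv = arithmetic_path(spec, [3.0])
        assert pv.s == pytest.approx(0.75, abs=1e-6)
        assert pv.zeta == pytest.approx(0.0, abs=1e-6)

    def test_monotone_along_straight_path(self):
        spec = PathSpec(np.arange(8.0)[:, None])
        ss = [arithmetic_path(spec, [z]).s for z in np.linspace(0.2, 6.8, 60)]
        assert np.all(np.diff(ss) > 0)

    def test_softmax_stability_far_from_path(self):
        spec = PathSpec(np.arange(5.0)[:, None], lam=10.0)
        pv = arithmetic_path(spec, [1000.0])
        assert np.isfinite(pv.s) and np.isfinite(pv.zeta)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            PathSpec(np.arange(3.0)[:, None], lam=-1.0)

    def test_default_lambda_inverse_mean_square_spacing(self):
        nodes = np.arange(0.0, 10.0, 2.0)[:, None]
        assert default_lambda(nodes, np.ones(1)) == pytest.approx(1.0 / 4.0)


class TestGeometricPath:
    def test_on_node_values(self):
        spec = PathSpec(np.arange(11.0)[:, None])
        for n in (0, 3, 5, 10):
            pv = geometric_path(spec, [float(n)])
            assert pv.s == pytest.approx(n / 10.0, abs=1e-12)
            assert pv.zeta == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_between_nodes(self):
        spec = PathSpec(np.arange(11.0)[:, None])
        pv = geometric_path(spec, [3.5])
        assert pv.s == pytest.approx(0.35, abs=1e-12)

    def test_perpendicular_displacement(self):
        nodes = np.stack([np.arange(11.0), np.zeros(11)], axis=1)
        spec = PathSpec(nodes)
        pv = geometric_path(spec, [3.3, 0.8])
        assert pv.s == pytest.approx(0.33, abs=1e-12)
        assert pv.zeta == pytest.approx(0.8, abs=1e-12)

    def test_against_dense_projection_oracle(self, rng):
        nodes = np.stack([np.linspace(0, 5, 6),
                          0.3 * np.sin(np.linspace(0, 2.5, 6))], axis=1)
        spec = PathSpec(nodes)
        for _ in range(10):
            z = np.array([rng.uniform(0.5, 4.5), rng.uniform(-0.2, 0.4)])
            pv = geometric_path(spec, z)
            s_o, zeta_o = projection_oracle(nodes, z)
            assert pv.s == pytest.approx(s_o, abs=0.02)
            assert pv.zeta == pytest.approx(zeta_o, abs=0.02)

    def test_tie_breaks_toward_lower_index(self):
        spec = PathSpec(np.arange(5.0)[:, None])
        pv = geometric_path(spec, [1.5])  # exactly between nodes 1 and 2
        assert pv.nearest_index == 1

    def test_gradients_match_fd(self, rng):
        nodes = rng.normal(size=(6, 3)) * 2
        spec = PathSpec(nodes, weights=[1.0, 2.0, 0.5])
        z0 = rng.normal(size=3)
        h = 1e-6
        for fn in (arithmetic_path, geometric_path):
            pv = fn(spec, z0)
            for k in range(3):
                zp, zm = z0.copy(), z0.copy()
                zp[k] += h
                zm[k] -= h
                fds = (fn(spec, zp).s - fn(spec, zm).s) / (2 * h)
                fdz = (fn(spec, zp).zeta - fn(spec, zm).zeta) / (2 * h)
                assert pv.s_gradient[k] == pytest.approx(fds, rel=1e-5, abs=1e-8)
                assert pv.zeta_gradient[k] == pytest.approx(fdz, rel=1e-5, abs=1e-8)

    def test_needs_three_nodes(self):
        with pytest.raises(ValueError):
            geometric_path(PathSpec(np.arange(2.0)[:, None]), [0.5])


class TestFormulationsAgree:
    def test_near_straight_path_with_default_lambda(self):
        nodes = np.arange(9.0)[:, None]
        spec = PathSpec(nodes)  # lambda from mean squared spacing
        for z in np.linspace(1.2, 6.8, 12):
            sa = arithmetic_path(spec, [z]).s
            sg = geometric_path(spec, [z]).s
            assert abs(sa - sg) < 1.0 / 8.0  # within one node spacing


class TestCartesianVariants:
    def test_equals_cv_space_on_aligned_coordinates(self, rng):
        """Cartesian path == CV-space path fed the superposed coordinates.

        The frames differ by an internal deformation (atom 0 sliding along
        x) so the best-fit superposition does not absorb the progress."""
        base = rng.normal(size=(4, 3)) * 2
        frames = []
        for i in range(5):
            f = base.copy()
            f[0, 0] += 0.5 * i
            frames.append(f)
        frames = np.array(frames)
        cart = CartesianPathFrames(frames)
        spec = cart.spec(lam=0.05)
        # configuration 2.4 node spacings along the deformation
        pos = base.copy()
        pos[0, 0] += 1.2
        zvec = cart.cv_vector(pos)
        pv_geo = geometric_path(spec, zvec)
        assert pv_geo.s == pytest.approx(2.4 / 4.0, abs=0.02)
        pv = arithmetic_path(spec, zvec)
        assert 0.0 < pv.s < 1.0

    def test_alignment_removes_rigid_motion(self, rng):
        base = rng.normal(size=(5, 3))
        frames = np.array([base, base + 0.3, base + 0.6])
        cart = CartesianPathFrames(frames)
        from colvarkit.rotation import quaternion_to_matrix
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        moved = base @ quaternion_to_matrix(q).T + np.array([5.0, 1.0, -2.0])
        assert np.allclose(cart.cv_vector(moved), cart.cv_vector(base),
                           atol=1e-8)


class TestPathCVComponents:
    def test_atom_gradients_via_chain_rule(self, rng):
        from conftest import fd_gradient

        nodes = np.stack([np.linspace(1.0, 3.0, 5),
                          np.linspace(-1.0, 1.0, 5)], axis=1)
        comps = [DistanceZ(AtomGroup([0]), axis=(1, 0, 0)),
                 DistanceZ(AtomGroup([1]), axis=(0, 1, 0))]
        for cls in (ArithmeticPathCV, GeometricPathCV):
            cv = cls(PathSpec(nodes), comps)

            class SWrap:
                def evaluate(self, positions):
                    pv, (gs, gz) = cv.evaluate(positions)
                    return pv.s, gs

            pos = rng.normal(size=(2, 3)) + np.array([[2.0, 0, 0], [0, 0.3, 0]])
            w = SWrap()
            _, g = w.evaluate(pos)
            assert np.allclose(g, fd_gradient(w, pos), rtol=1e-5, atol=1e-7)
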