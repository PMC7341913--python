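"""Procrustes superimposition, distances, partial warps, deformation grids."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import foxmorph as fm
from foxmorph.superimpose import _optimal_rotation, bending_energy_matrix, similarity_basis

from conftest import random_configs


def rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert fm.centroid_size(square) == pytest.approx(np.sqrt(2))

    def test_collinear_points(self):
        # (0,0),(1,0),(2,0): centroid (1,0); squared distances 1+0+1
        pts = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        assert fm.centroid_size(pts) == pytest.approx(np.sqrt(2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 999))
    def test_homogeneity(self, scale, seed):
        pts = random_configs(np.random.default_rng(seed), 1, 6)[0]
        assert fm.centroid_size(pts * scale) == pytest.approx(
            scale * fm.centroid_size(pts), rel=1e-9
        )

    def test_degenerate_configuration_errors(self):
        with pytest.raises(ValueError, match="zero size"):
            fm.centroid_size(np.ones((4, 2)))


class TestProcrustesDistance:
    def test_identical_shapes(self):
        a = random_configs(np.random.default_rng(0), 1, 5)[0]
        assert fm.procrustes_distance(a, a) == 0.0

    def test_three_four_five(self):
        a = random_configs(np.random.default_rng(1), 1, 5)[0]
        b = a.copy()
        b[2] += [0.3, 0.4]
        assert fm.procrustes_distance(a, b) == pytest.approx(0.5)

    def test_matches_landmarkwise_sum(self):
        rng = np.random.default_rng(2)
        a, b = random_configs(rng, 2, 9)
        total = 0.0
        for i in range(9):  # brute-force landmark-by-landmark accumulation
            total += (a[i, 0] - b[i, 0]) ** 2 + (a[i, 1] - b[i, 1]) ** 2
        assert fm.procrustes_distance(a, b) == pytest.approx(np.sqrt(total), rel=1e-12)

    def test_mismatched_k_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            fm.procrustes_distance(np.zeros((4, 2)), np.zeros((5, 2)))


class TestGpa:
    def test_identical_shapes_align_exactly(self):
        tri = np.array([[0, 0], [2, 0], [1, 1.5]], dtype=float)
        other = tri @ rot(np.pi / 2) + [5.0, -3.0]
        space = fm.gpa(np.stack([tri, other]))
        assert fm.procrustes_distance(space.aligned[0], space.aligned[1]) < 1e-10

    def test_rigid_transform_invariance_of_distances(self):
        rng = np.random.default_rng(3)
        configs = random_configs(rng, 6, 8)
        space1 = fm.gpa(configs)
        moved = np.stack(
            [
                c @ rot(rng.uniform(0, 2 * np.pi)) * rng.uniform(0.5, 2.0)
                + rng.uniform(-5, 5, 2)
                for c in configs
            ]
        )
        space2 = fm.gpa(moved)

        def pairwise(space):
            return np.array(
                [
                    fm.procrustes_distance(space.aligned[i], space.aligned[j])
                    for i in range(6)
                    for j in range(i + 1, 6)
                ]
            )

        np.testing.assert_allclose(pairwise(space1), pairwise(space2), atol=1e-8)

    def test_rotation_matches_brute_force_grid(self):
        """The analytic orthogonal-fit rotation agrees with a fine grid search."""
        rng = np.random.default_rng(4)
        src = random_configs(rng, 1, 7)[0]
        src = (src - src.mean(0)) / fm.centroid_size(src)
        tgt = random_configs(rng, 1, 7)[0]
        tgt = (tgt - tgt.mean(0)) / fm.centroid_size(tgt)
        r = _optimal_rotation(src, tgt)
        analytic = np.degrees(np.arctan2(r[0, 1], r[0, 0]))

        grid = np.arange(-180.0, 180.0, 0.001)
        cos = np.cos(np.radians(grid))[:, None]
        sin = np.sin(np.radians(grid))[:, None]
        x = src[:, 0][None, :]
        y = src[:, 1][None, :]
        rx = x * cos - y * sin
        ry = x * sin + y * cos
        sq = ((rx - tgt[:, 0]) ** 2).sum(1) + ((ry - tgt[:, 1]) ** 2).sum(1)
        best = grid[np.argmin(sq)]
        wrapped = ((analytic - best + 180.0) % 360.0) - 180.0
        assert wrapped == pytest.approx(0.0, abs=0.01)

    def test_unit_size_and_centering_invariants(self):
        space = fm.gpa(random_configs(np.random.default_rng(5), 8, 10))
        assert np.abs(space.aligned.mean(axis=1)).max() < 1e-9
        sizes = np.sqrt((space.aligned**2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-9)
        np.testing.assert_allclose(
            space.consensus, space.aligned.mean(axis=0), atol=1e-6
        )

    def test_consensus_invariant_to_specimen_order(self):
        configs = random_configs(np.random.default_rng(6), 7, 9)
        s1 = fm.gpa(configs)
        s2 = fm.gpa(configs[::-1])
        np.testing.assert_allclose(s1.consensus, s2.consensus, atol=1e-7)

    def test_alignment_reduces_scatter(self):
        """The GPA objective never exceeds the pre-rotation objective."""
        configs = random_configs(np.random.default_rng(7), 10, 8)
        centred = configs - configs.mean(axis=1, keepdims=True)
        scaled = centred / np.sqrt((centred**2).sum(axis=(1, 2)))[:, None, None]
        naive = ((scaled - scaled.mean(0)) ** 2).sum()
        space = fm.gpa(configs)
        fitted = ((space.aligned - space.consensus) ** 2).sum()
        assert fitted <= naive + 1e-12

    def test_degenerate_specimen_named(self):
        configs = random_configs(np.random.default_rng(8), 3, 5)
        configs[1] = 7.7
        with pytest.raises(ValueError, match="1"):
            fm.gpa(configs, ids=["a", "1", "c"])


class TestPartialWarps:
    def test_dimension_is_2k_minus_4(self, balanced_space):
        space, _ = balanced_space
        warps = fm.partial_warps(space)
        assert warps.p == 2 * space.k - 4
        assert warps.basis.shape == (warps.p, 2 * space.k)
        # orthonormal basis
        np.testing.assert_allclose(warps.basis @ warps.basis.T, np.eye(warps.p), atol=1e-10)

    def test_zero_scores_for_identical_shapes(self):
        tri = random_configs(np.random.default_rng(9), 1, 8)[0]
        space = fm.gpa(np.stack([tri, tri @ rot(0.3) + 2.0, tri * 3.0]))
        warps = fm.partial_warps(space)
        assert np.abs(warps.scores).max() < 1e-9

    def test_scores_are_centred(self, balanced_space):
        space, _ = balanced_space
        warps = fm.partial_warps(space)
        np.testing.assert_allclose(warps.scores.sum(axis=0), 0.0, atol=1e-10)

    def test_projection_is_isometric_on_tangent_residuals(self, balanced_space):
        """Score-vector distances equal tangent-residual distances."""
        space, _ = balanced_space
        warps = fm.partial_warps(space)
        tangent = space.tangent_coords()
        for i, j in [(0, 1), (2, 9), (5, 17)]:
            d_scores = np.linalg.norm(warps.scores[i] - warps.scores[j])
            d_resid = np.linalg.norm(tangent[i] - tangent[j])
            assert d_scores == pytest.approx(d_resid, abs=1e-8)

    def test_reconstruction_roundtrip(self, balanced_space):
        space, _ = balanced_space
        warps = fm.partial_warps(space)
        recon = warps.reconstruct()
        np.testing.assert_allclose(
            recon.reshape(space.n, -1), space.tangent_coords(), atol=1e-8
        )
        # out-of-tangent component is O(rho^2), far smaller than the signal
        gap = np.abs(space.tangent_coords() - space.coords_matrix()).max()
        scatter = np.abs(space.coords_matrix() - space.consensus.reshape(-1)).max()
        assert gap < 0.05 * scatter

    def test_bending_energy_structure(self, balanced_space):
        space, _ = balanced_space
        k = space.k
        warps = fm.partial_warps(space)
        assert (warps.bending_energies[: 2 * k - 6] > 0).all()
        np.testing.assert_allclose(warps.bending_energies[-2:], 0.0)
        # bending-energy matrix annihilates affine functions of the consensus
        be = bending_energy_matrix(space.consensus)
        affine = np.column_stack([np.ones(k), space.consensus])
        np.testing.assert_allclose(be @ affine, 0.0, atol=1e-8)

    def test_collinear_consensus_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 6), np.zeros(6)])
        with pytest.raises(ValueError):
            fm.superimpose.partial_warp_basis(line)


class TestDeformationGrid:
    def setup_method(self):
        self.cons = random_configs(np.random.default_rng(10), 1, 9)[0]

    def test_identity_when_target_is_consensus(self):
        lattice, warped = fm.deformation_grid(self.cons, self.cons, grid_shape=(8, 8))
        np.testing.assert_allclose(warped, lattice, atol=1e-9)

    def test_translation_is_rigid(self):
        target = self.cons + [0.7, -0.2]
        lattice, warped = fm.deformation_grid(self.cons, target, grid_shape=(8, 8))
        np.testing.assert_allclose(warped, lattice + [0.7, -0.2], atol=1e-9)

    def test_magnification_linearity(self):
        rng = np.random.default_rng(11)
        d = 0.02 * rng.standard_normal(self.cons.shape)
        _, w3 = fm.deformation_grid(self.cons, self.cons + d, magnification=3.0)
        _, w1 = fm.deformation_grid(self.cons, self.cons + 3 * d, magnification=1.0)
        np.testing.assert_allclose(w3, w1, atol=1e-9)

    def test_negative_magnification_rejected(self):
        with pytest.raises(ValueError):
            fm.deformation_grid(self.cons, self.cons, magnification=-1.0)
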