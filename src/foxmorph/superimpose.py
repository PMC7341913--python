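"""Generalized Procrustes analysis, Procrustes distances, thin-plate-spline
partial warps, and deformation grids.

Shape is what remains of a landmark configuration after removing location,
scale and orientation.  GPA iteratively centres every configuration,
rescales it to unit centroid size (full Procrustes scaling), and rotates it
— proper rotations only — onto the evolving consensus until the consensus
stabilises.  Shape variables for statistics are either the aligned
coordinates themselves or the partial-warp scores, an orthonormal 2k−4
dimensional basis of the tangent space built from the thin-plate-spline
bending-energy matrix of the consensus (2k−6 non-uniform components plus the
two uniform/affine components estimated by the complement method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .landmark_io import LandmarkDataset

logger = logging.getLogger(__name__)

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


# ---------------------------------------------------------------------------
# basic geometry
# ---------------------------------------------------------------------------

def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"expected (k, 2) coordinates, got {coords.shape}")
    if coords.shape[0] < 3:
        raise ValueError("centroid size needs at least 3 landmarks")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centred**2)))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks identical (zero size)")
    return cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||source @ R - target||_F (Kabsch)."""
    m = source.T @ target
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Square root of summed squared landmark-wise differences.

    Both shapes must already live in a common superimposition; no
    re-alignment happens here.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------

@dataclass
class ShapeSpace:
    """Procrustes-aligned configurations with consensus and centroid sizes.

    ``aligned`` is ``(n, k, 2)``: every configuration centred at the origin
    and scaled to unit centroid size.  ``centroid_sizes`` retains the
    original sizes.  ``metadata`` (optional) carries the specimen table for
    downstream grouping.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    ids: list
    metadata: "object | None" = None  # pandas DataFrame indexed by specimen_id

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def coords_matrix(self) -> np.ndarray:
        """Aligned coordinates flattened to (n, 2k), row order x1,y1,x2,y2…"""
        return self.aligned.reshape(self.n, -1)

    def tangent_coords(self) -> np.ndarray:
        """Orthogonal projection of aligned coordinates into the tangent
        space at the consensus (component along the consensus and its
        in-plane rotation removed from the residuals)."""
        basis = similarity_basis(self.consensus)  # (2k, 4)
        flat = self.coords_matrix()
        cons = self.consensus.reshape(-1)
        resid = flat - cons
        proj = resid - (resid @ basis) @ basis.T
        return proj + cons

    def meta_column(self, name: str) -> np.ndarray:
        if self.metadata is None:
            raise ValueError("ShapeSpace carries no metadata")
        return self.metadata.loc[self.ids, name].to_numpy()


def similarity_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k × 4) of the similarity directions at a shape:
    the two translations, scaling (the shape itself) and in-plane rotation."""
    k = consensus.shape[0]
    tx = np.zeros((k, 2))
    tx[:, 0] = 1.0
    ty = np.zeros((k, 2))
    ty[:, 1] = 1.0
    centred = consensus - consensus.mean(axis=0)
    rot = np.column_stack([-centred[:, 1], centred[:, 0]])
    raw = np.column_stack(
        [tx.reshape(-1), ty.reshape(-1), centred.reshape(-1), rot.reshape(-1)]
    )
    q, _ = np.linalg.qr(raw)
    return q


def gpa(
    data: "LandmarkDataset | np.ndarray",
    ids: "list | None" = None,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
) -> ShapeSpace:
    """Generalized Procrustes analysis with full Procrustes scaling.

    Each configuration is centred, scaled to unit centroid size and rotated
    (proper rotations only) to least-squares fit the consensus; the
    consensus is the coordinate-wise mean, renormalised to unit size, and
    the cycle repeats until it moves by less than ``tol``.  The final
    orientation is canonicalized (consensus major axis along x, first
    landmark toward positive x) so the result does not depend on specimen
    order.
    """
    metadata = None
    if isinstance(data, LandmarkDataset):
        configs = data.coords_array()
        ids = data.ids
        try:
            metadata = data.metadata_frame()
        except KeyError:
            metadata = None
        if metadata is not None and metadata.shape[1] == 0:
            metadata = None
    else:
        configs = np.asarray(data, dtype=float)
        if ids is None:
            ids = list(range(configs.shape[0]))
    if configs.ndim != 3 or configs.shape[2] != 2:
        raise ValueError(f"expected (n, k, 2) array, got {configs.shape}")
    n, k, _ = configs.shape
    if n < 2:
        raise ValueError("GPA needs at least two configurations")

    centred = configs - configs.mean(axis=1, keepdims=True)
    cs = np.sqrt((centred**2).sum(axis=(1, 2)))
    for i, size in enumerate(cs):
        if size <= 0 or not np.isfinite(size):
            raise ValueError(f"degenerate configuration (zero size): specimen {ids[i]!r}")
    scaled = centred / cs[:, None, None]

    consensus = scaled[0].copy()
    aligned = scaled.copy()
    for _ in range(max_iter):
        for i in range(n):
            aligned[i] = scaled[i] @ _optimal_rotation(scaled[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        delta = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if delta < tol:
            break

    # final pass so every configuration is optimally rotated to the
    # converged consensus; the reported consensus is the plain coordinate
    # mean of the aligned configurations (no renormalization)
    for i in range(n):
        aligned[i] = scaled[i] @ _optimal_rotation(scaled[i], consensus)
    consensus = aligned.mean(axis=0)

    aligned, consensus = _canonical_orientation(aligned, consensus)
    return ShapeSpace(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=cs,
        ids=list(ids),
        metadata=metadata,
    )


def _canonical_orientation(aligned: np.ndarray, consensus: np.ndarray):
    """Rotate the whole solution so the consensus major principal axis lies
    along x, signed so landmark 1 projects non-negatively on it.  Depends
    only on the consensus, so the orientation is invariant to specimen
    order."""
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if consensus[0] @ major < 0:
        major = -major
    minor = np.array([-major[1], major[0]])
    rot = np.column_stack([major, minor])  # proper rotation by construction
    if np.linalg.det(rot) < 0:
        rot[:, 1] = -rot[:, 1]  # unreachable for the construction above
    return aligned @ rot, consensus @ rot


def align_to(space: ShapeSpace, reference_consensus: np.ndarray) -> ShapeSpace:
    """Rigidly rotate a ShapeSpace so its consensus best fits a reference
    consensus (ordinary Procrustes rotation; no rescaling).  Used to place
    two separately superimposed datasets into one orientation before
    comparing divergence vectors across them."""
    rot = _optimal_rotation(space.consensus, np.asarray(reference_consensus, float))
    return ShapeSpace(
        aligned=space.aligned @ rot,
        consensus=space.consensus @ rot,
        centroid_sizes=space.centroid_sizes,
        ids=list(space.ids),
        metadata=space.metadata,
    )


# ---------------------------------------------------------------------------
# thin-plate spline machinery
# ---------------------------------------------------------------------------

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r² log r², with U(0) = 0 (argument is r squared)."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


def bending_energy_matrix(points: np.ndarray) -> np.ndarray:
    """Bending-energy matrix L_k⁻¹ of a 2D reference configuration: the
    upper-left k×k block of the inverse of the full TPS system matrix.
    Symmetric PSD with exactly three zero eigenvalues (the affine part)."""
    points = np.asarray(points, dtype=float)
    k = points.shape[0]
    diff = points[:, None, :] - points[None, :, :]
    r2 = (diff**2).sum(axis=-1)
    kmat = _tps_kernel(r2)
    p = np.column_stack([np.ones(k), points])
    l_full = np.zeros((k + 3, k + 3))
    l_full[:k, :k] = kmat
    l_full[:k, k:] = p
    l_full[k:, :k] = p.T
    try:
        l_inv = np.linalg.inv(l_full)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "TPS undefined for this reference (collinear or coincident landmarks)"
        ) from exc
    be = l_inv[:k, :k]
    return (be + be.T) / 2.0


@dataclass
class PartialWarpScores:
    """Partial-warp scores in the 2k−4 dimensional tangent basis.

    ``scores @ basis`` reconstructs the tangent-projected Procrustes
    residuals; columns are ordered non-uniform warps (descending bending
    energy, x then y within each warp) followed by the two uniform
    components (bending energy 0).
    """

    scores: np.ndarray          # (n, 2k-4)
    basis: np.ndarray           # (2k-4, 2k) orthonormal rows
    bending_energies: np.ndarray  # (2k-4,), 0 for the uniform pair
    consensus: np.ndarray       # (k, 2)

    @property
    def p(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Consensus + reconstructed residuals, as (n, k, 2)."""
        flat = self.consensus.reshape(-1) + self.scores @ self.basis
        return flat.reshape(self.scores.shape[0], -1, 2)


def partial_warp_basis(consensus: np.ndarray):
    """Orthonormal shape-space basis from the consensus TPS bending energy.

    Returns ``(basis, bending_energies)`` with basis of shape (2k−4, 2k):
    2k−6 principal-warp directions (each eigenvector of the bending-energy
    matrix applied to x and to y) plus 2 uniform components obtained by the
    complement method (affine shear/stretch displacements of the consensus
    orthogonalized against the similarity and non-uniform subspaces).
    """
    consensus = np.asarray(consensus, dtype=float)
    k = consensus.shape[0]
    if k < 4:
        raise ValueError("partial warps need at least 4 landmarks")
    be = bending_energy_matrix(consensus)
    evals, evecs = np.linalg.eigh(be)
    # three (near-)zero eigenvalues span the affine part; keep the k-3 others
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(evals.max(), 1.0) * 1e-10
    nonzero = evals > tol
    if nonzero.sum() != k - 3:
        raise ValueError(
            f"bending-energy matrix has {int(nonzero.sum())} positive eigenvalues, "
            f"expected {k - 3}; consensus may be degenerate"
        )
    warps = evecs[:, nonzero]          # (k, k-3), descending bending energy
    energies = evals[nonzero]

    # expand each principal warp into x- and y-displacement directions
    nonuniform = np.zeros((2 * (k - 3), 2 * k))
    nu_energy = np.zeros(2 * (k - 3))
    for j in range(k - 3):
        ex = np.zeros((k, 2))
        ex[:, 0] = warps[:, j]
        ey = np.zeros((k, 2))
        ey[:, 1] = warps[:, j]
        nonuniform[2 * j] = ex.reshape(-1)
        nonuniform[2 * j + 1] = ey.reshape(-1)
        nu_energy[2 * j] = energies[j]
        nu_energy[2 * j + 1] = energies[j]

    # uniform components: affine stretch/shear displacements of the
    # consensus, orthogonalized against similarity + non-uniform directions
    sim = similarity_basis(consensus)
    centred = consensus - consensus.mean(axis=0)
    stretch = np.column_stack([centred[:, 0], -centred[:, 1]]).reshape(-1)
    shear = np.column_stack([centred[:, 1], centred[:, 0]]).reshape(-1)
    uni = np.column_stack([stretch, shear])
    uni = uni - sim @ (sim.T @ uni)
    uni = uni - nonuniform.T @ (nonuniform @ uni)
    q, r = np.linalg.qr(uni)
    if np.abs(np.diag(r)).min() < 1e-12:
        raise ValueError("uniform component degenerate for this consensus")
    uniform = q.T                      # (2, 2k)

    basis = np.vstack([nonuniform, uniform])
    bending = np.concatenate([nu_energy, np.zeros(2)])
    return basis, bending


def partial_warps(space: ShapeSpace) -> PartialWarpScores:
    """Project Procrustes residuals onto the partial-warp basis.

    Residuals are first orthogonally projected into the tangent space at
    the consensus (removing the O(ρ²) out-of-tangent component that full
    Procrustes scaling leaves along the consensus direction), then expressed
    in the 2k−4 orthonormal warp basis; the projection is an isometry on
    that subspace.
    """
    basis, bending = partial_warp_basis(space.consensus)
    resid = space.coords_matrix() - space.consensus.reshape(-1)
    scores = resid @ basis.T
    return PartialWarpScores(
        scores=scores, basis=basis, bending_energies=bending, consensus=space.consensus.copy()
    )


# ---------------------------------------------------------------------------
# deformation grids
# ---------------------------------------------------------------------------

def _tps_fit(source: np.ndarray, target: np.ndarray):
    k = source.shape[0]
    diff = source[:, None, :] - source[None, :, :]
    kmat = _tps_kernel((diff**2).sum(axis=-1))
    p = np.column_stack([np.ones(k), source])
    l_full = np.zeros((k + 3, k + 3))
    l_full[:k, :k] = kmat
    l_full[:k, k:] = p
    l_full[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        params = np.linalg.solve(l_full, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("TPS undefined (degenerate source landmarks)") from exc
    return params[:k], params[k:]


def _tps_evaluate(source, weights, affine, points):
    diff = points[:, None, :] - source[None, :, :]
    u = _tps_kernel((diff**2).sum(axis=-1))
    return affine[0] + points @ affine[1:] + u @ weights


def deformation_grid(
    consensus: np.ndarray,
    target: np.ndarray,
    grid_shape: tuple[int, int] = (20, 20),
    magnification: float = 1.0,
    margin: float = 0.1,
):
    """Thin-plate-spline deformation grid from the consensus to a target.

    Fits the interpolant mapping the consensus landmarks onto
    ``consensus + magnification × (target − consensus)`` and evaluates it on
    a rectangular lattice over the consensus bounding box (expanded by
    ``margin``).  Returns ``(lattice, warped)``, both ``(m·m, 2)``.
    """
    consensus = np.asarray(consensus, dtype=float)
    target = np.asarray(target, dtype=float)
    if consensus.shape != target.shape:
        raise ValueError("consensus and target must share dimensions")
    if magnification < 0:
        raise ValueError("magnification must be ≥ 0")
    goal = consensus + magnification * (target - consensus)
    weights, affine = _tps_fit(consensus, goal)

    mins = consensus.min(axis=0)
    maxs = consensus.max(axis=0)
    span = maxs - mins
    lo = mins - margin * span
    hi = maxs + margin * span
    gx = np.linspace(lo[0], hi[0], grid_shape[0])
    gy = np.linspace(lo[1], hi[1], grid_shape[1])
    xx, yy = np.meshgrid(gx, gy)
    lattice = np.column_stack([xx.reshape(-1), yy.reshape(-1)])
    warped = _tps_evaluate(consensus, weights, affine, lattice)
    return lattice, warped
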