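"""Multivariate phylogenetic signal: Blomberg's K generalized to
high-dimensional traits, with a star-phylogeny null and a power estimate.

The statistic is the distance-based multivariate generalization of
Blomberg's K: the ratio of the summed squared Euclidean deviations of tip
values from the phylogenetically weighted ancestral estimate, to the same
quantity after whitening by the inverse phylogenetic covariance, scaled by
its expectation under Brownian motion,

    K = (MSE0 / MSE) / ((tr C − N / 1ᵀC⁻¹1) / (N − 1)),

with C[i, j] the shared root-to-MRCA branch length.  It reduces exactly to
univariate K for one trait, requires no inversion in trait space (p may
exceed N: 2k shape coordinates on a 12-taxon clade), equals 1 on average
under Brownian motion, and falls toward 0 as phylogenetic structure
disappears.  The null distribution follows the star-phylogeny construction:
tip values drawn i.i.d. (matching the observed trait covariance) carry no
signal, and K evaluated on the real tree under that draw is the no-signal
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .landmark_io import Phylogeny

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phylogenetic covariance
# ---------------------------------------------------------------------------

def phylo_covariance(phy: Phylogeny, order: list[str] | None = None):
    """Brownian-motion covariance matrix C of a tree's tips.

    ``C[i, j]`` is the branch length shared from the root to the MRCA of
    tips i and j.  Returns ``(labels, C)`` with rows in ``order`` (default:
    the tree's own tip order).
    """
    tree = phy.tree
    labels = phy.tips
    if order is not None:
        missing = sorted(set(order) - set(labels))
        if missing:
            raise ValueError(f"tips not in tree: {missing}")
        extra = sorted(set(labels) - set(order))
        if extra:
            raise ValueError(f"data rows missing for tips: {extra}")
        labels = list(order)

    tree.calc_node_root_distances()
    depth = {
        leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()
    }
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    c = np.zeros((n, n))
    for i, a in enumerate(labels):
        c[i, i] = depth[a]
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            c[i, j] = c[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return labels, c


# ---------------------------------------------------------------------------
# the K statistic
# ---------------------------------------------------------------------------

def _kmult_ingredients(c: np.ndarray):
    n = c.shape[0]
    try:
        cinv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance matrix is singular") from exc
    ones = np.ones(n)
    w = cinv @ ones
    denom = float(ones @ w)
    expected = (np.trace(c) - n / denom) / (n - 1)
    return cinv, w, denom, expected


def _kmult_from_parts(y: np.ndarray, cinv, w, denom, expected) -> float:
    anc = (w @ y) / denom            # phylogenetically weighted root estimate
    r = y - anc
    mse0 = float(np.sum(r * r))
    mse = float(np.sum(r * (cinv @ r)))
    if mse0 <= 0 or mse <= 0:
        logger.warning("degenerate trait data (no variation among tips); K set to 0")
        return 0.0
    return (mse0 / mse) / expected


def _kmult_many(ys: np.ndarray, cinv, w, denom, expected) -> np.ndarray:
    """Vectorized K over a (B, N, p) stack of datasets."""
    anc = np.einsum("n,bnp->bp", w, ys) / denom
    r = ys - anc[:, None, :]
    mse0 = np.einsum("bnp,bnp->b", r, r)
    cr = np.einsum("nm,bmp->bnp", cinv, r)
    mse = np.einsum("bnp,bnp->b", r, cr)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (mse0 / mse) / expected
    k[~np.isfinite(k)] = 0.0
    return k


def k_mult(
    data: np.ndarray, phy: Phylogeny, labels: list[str] | None = None
) -> float:
    """Multivariate Blomberg's K for (N tips × p traits) data on a tree.

    If ``labels`` is given, data rows are matched to tips by name;
    otherwise rows are assumed to follow the tree's tip order.
    """
    y = np.atleast_2d(np.asarray(data, dtype=float))
    if y.shape[0] == 1 and y.shape[1] == phy.n_tips:
        y = y.T
    _, c = phylo_covariance(phy, order=labels)
    if y.shape[0] != c.shape[0]:
        raise ValueError(
            f"data has {y.shape[0]} rows but tree has {c.shape[0]} tips"
        )
    parts = _kmult_ingredients(c)
    return _kmult_from_parts(y, *parts)


# ---------------------------------------------------------------------------
# Brownian-motion simulation
# ---------------------------------------------------------------------------

def _psd_factor(mat: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        evals, evecs = np.linalg.eigh(mat)
        if evals.min() < -1e-8 * max(evals.max(), 1.0):
            raise ValueError("rate matrix is not positive semi-definite")
        evals = np.clip(evals, 0.0, None)
        return evecs * np.sqrt(evals)


def simulate_bm(
    phy: Phylogeny,
    p: int,
    rate: float | np.ndarray = 1.0,
    seed=None,
    n_datasets: int | None = None,
    root: float | np.ndarray = 0.0,
):
    """Simulate multivariate Brownian motion on a tree.

    Tip data are multivariate Gaussian with covariance C ⊗ R, where C is
    the tree covariance and R the (scalar or p×p) trait rate matrix.
    Returns (N, p), or (n_datasets, N, p) when ``n_datasets`` is given.
    Accepts a seeded ``numpy.random.Generator`` in place of ``seed``.
    """
    _, c = phylo_covariance(phy)
    n = c.shape[0]
    if np.isscalar(rate):
        if rate < 0:
            raise ValueError("rate must be nonnegative")
        r_factor = np.sqrt(float(rate)) * np.eye(p)
    else:
        rate = np.asarray(rate, dtype=float)
        if rate.shape != (p, p):
            raise ValueError(f"rate matrix must be ({p}, {p})")
        r_factor = _psd_factor(rate)
    c_factor = _psd_factor(c)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    squeeze = n_datasets is None
    b = 1 if squeeze else n_datasets
    z = rng.standard_normal((b, n, p))
    tips = np.einsum("nm,bmp->bnp", c_factor, z) @ r_factor.T + root
    return tips[0] if squeeze else tips


# ---------------------------------------------------------------------------
# hypothesis test and power
# ---------------------------------------------------------------------------

@dataclass
class KmultResult:
    k_mult: float
    p_value: float
    null_distribution: np.ndarray
    n_sim: int
    power: float

    def to_dict(self) -> dict:
        return {
            "k_mult": self.k_mult,
            "p_value": self.p_value,
            "n_sim": self.n_sim,
            "power": self.power,
        }


def k_mult_test(
    data: np.ndarray,
    phy: Phylogeny,
    n_sim: int = 1000,
    seed=None,
    labels: list[str] | None = None,
) -> KmultResult:
    """Test K against a no-signal null, with a Brownian-motion power estimate.

    Null: tip values drawn i.i.d. across tips from a Gaussian matching the
    observed trait covariance — the star-phylogeny construction — and K
    evaluated against the real tree; one-sided
    p = (count of null K ≥ observed + 1)/(n_sim + 1).  Power: the fraction
    of Brownian-motion datasets (rate matrix estimated from the data) whose
    K exceeds the null's 95th percentile.
    """
    y = np.asarray(data, dtype=float)
    if n_sim < 100:
        logger.warning("n_sim=%d is small; the p-value will be coarse", n_sim)
    order, c = phylo_covariance(phy, order=labels)
    if y.shape[0] != c.shape[0]:
        raise ValueError("data rows must match tree tips")
    parts = _kmult_ingredients(c)
    cinv, w, denom, expected = parts
    k_obs = _kmult_from_parts(y, *parts)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, p = y.shape

    # star-phylogeny null: i.i.d. tips matching the observed trait covariance
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    factor = vt.T * (s / np.sqrt(n - 1))       # (p, r): factor of sample cov
    z = rng.standard_normal((n_sim, n, factor.shape[1]))
    null_data = z @ factor.T
    null_k = _kmult_many(null_data, cinv, w, denom, expected)
    p_value = (int(np.sum(null_k >= k_obs)) + 1) / (n_sim + 1)

    # power: BM alternative with the evolutionary rate matrix estimated
    # from the data, rejected when K clears the null 95th percentile
    crit = float(np.percentile(null_k, 95.0))
    anc = (w @ y) / denom
    r = y - anc
    rate_hat = (r.T @ cinv @ r) / n
    rate_factor = _psd_factor(rate_hat)
    c_factor = _psd_factor(c)
    z2 = rng.standard_normal((n_sim, n, p))
    bm = np.einsum("nm,bmp->bnp", c_factor, z2) @ rate_factor.T
    bm_k = _kmult_many(bm, cinv, w, denom, expected)
    power = float(np.mean(bm_k > crit))

    return KmultResult(
        k_mult=float(k_obs),
        p_value=float(p_value),
        null_distribution=null_k,
        n_sim=n_sim,
        power=power,
    )
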