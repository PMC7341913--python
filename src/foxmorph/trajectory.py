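"""Micro- versus macroevolutionary divergence trajectories in shape space.

The microevolutionary trajectory is the habitat canonical axis (adjusted
for sex) of the within-species sample; the macroevolutionary trajectory is
PC1 of the clade's species-mean shapes.  Each is turned into a scale-free
divergence vector by regressing every shape coordinate on the axis scores
and normalizing the slope vector; the observed angle between the two unit
vectors is the arc cosine of their dot product.  Uncertainty comes from 900
bootstraps resampling each dataset independently; magnitude differences
along a common trajectory are tested with a randomized residual permutation
procedure (RRPP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from ._util import percentile_ci
from .shape_stats import _sscp_effects, pca

logger = logging.getLogger(__name__)


@dataclass
class DivergenceVector:
    direction: np.ndarray   # unit vector in shape-coordinate space
    magnitude: float        # norm of the raw regression-slope vector
    source: str             # "micro" | "macro"
    axis_used: str          # "canonical-habitat" | "PC1"


def divergence_vector(
    coords: np.ndarray,
    axis_scores: np.ndarray,
    source: str = "micro",
    axis_used: str = "canonical-habitat",
) -> DivergenceVector:
    """Scale-free divergence vector: per-coordinate regression slopes of the
    shape data on the axis scores, normalized to unit length.

    An affine rescaling of the scores rescales the magnitude but leaves the
    direction unchanged.
    """
    y = np.asarray(coords, dtype=float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    s = np.asarray(axis_scores, dtype=float)
    if s.shape[0] != y.shape[0]:
        raise ValueError("axis_scores length must match the number of shapes")
    sc = s - s.mean()
    sxx = float(sc @ sc)
    if sxx <= 0:
        raise ValueError("axis scores are constant; divergence vector undefined")
    slopes = (sc @ (y - y.mean(axis=0))) / sxx
    mag = float(np.linalg.norm(slopes))
    if mag == 0:
        raise ValueError("zero slope vector; no shape change along the axis")
    return DivergenceVector(
        direction=slopes / mag, magnitude=mag, source=source, axis_used=axis_used
    )


def angle_between(a, b) -> float:
    """Angle in degrees, on [0, 180] without folding, between unit vectors
    (or DivergenceVectors)."""
    va = a.direction if isinstance(a, DivergenceVector) else np.asarray(a, float)
    vb = b.direction if isinstance(b, DivergenceVector) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    for name, v in (("a", va), ("b", vb)):
        if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
            raise ValueError(f"vector {name} is not unit-norm")
    dot = float(np.clip(va @ vb, -1.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


# ---------------------------------------------------------------------------
# axis-score helpers (robust to rank-deficient coordinate data)
# ---------------------------------------------------------------------------

def habitat_canonical_scores(
    coords: np.ndarray, habitat: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """Canonical habitat scores (adjusted for sex) from possibly
    rank-deficient aligned coordinates.

    Aligned coordinates occupy at most a 2k−4 dimensional subspace, so the
    data are first reduced by SVD to their full-rank component.  On
    bootstrap resamples the error SSCP is structurally singular (duplicated
    specimens pull the design vectors into the data column space), so the
    generalized eigenproblem is solved on the range of E — the
    pseudo-inverse canonical variate solution — which coincides with the
    exact solution whenever E is nonsingular.
    """
    y = np.asarray(coords, dtype=float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    keep = s > max(s.max(), 1e-300) * 1e-9
    z = u[:, keep] * s[keep]

    h, e, _ = _sscp_effects(z, np.asarray(habitat), np.asarray(sex))
    evals, evecs = np.linalg.eigh(e)
    rng_mask = evals > max(evals.max(), 1e-300) * 1e-9
    if rng_mask.sum() < 1:
        raise ValueError("error SSCP has empty range; cannot form canonical axis")
    b = evecs[:, rng_mask]
    h2 = b.T @ h["habitat"] @ b
    e2 = b.T @ e @ b
    gev, gvec = linalg.eigh(h2, e2)
    w = b @ gvec[:, np.argmax(gev)]
    w /= np.linalg.norm(w)
    scores = (z - z.mean(axis=0)) @ w
    labels = np.asarray(habitat)
    levels = sorted(set(labels.tolist()))
    if scores[labels == levels[-1]].mean() < scores[labels == levels[0]].mean():
        scores = -scores
    return scores


def pc1_scores(coords: np.ndarray) -> np.ndarray:
    y = np.asarray(coords, dtype=float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    return pca(y).scores[:, 0]


# ---------------------------------------------------------------------------
# observed comparison + bootstrap
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryComparison:
    theta_obs: float
    ci_boot: tuple[float, float]          # sign-aligned replicate angles
    ci_boot_unaligned: tuple[float, float]
    n_boot: int
    verdict: str                          # "inside" | "outside"
    micro: DivergenceVector
    macro: DivergenceVector
    boot_angles: np.ndarray
    boot_angles_unaligned: np.ndarray
    n_redrawn: int

    def to_dict(self) -> dict:
        return {
            "theta_obs": self.theta_obs,
            "ci_boot": list(self.ci_boot),
            "ci_boot_unaligned": list(self.ci_boot_unaligned),
            "n_boot": self.n_boot,
            "verdict": self.verdict,
            "micro_magnitude": self.micro.magnitude,
            "macro_magnitude": self.macro.magnitude,
            "n_redrawn": self.n_redrawn,
        }


def _micro_vector(coords, habitat, sex):
    scores = habitat_canonical_scores(coords, habitat, sex)
    return divergence_vector(coords, scores, "micro", "canonical-habitat")


def _macro_vector(coords):
    scores = pc1_scores(coords)
    return divergence_vector(coords, scores, "macro", "PC1")


def compare_trajectories(
    micro_coords: np.ndarray,
    habitat: np.ndarray,
    sex: np.ndarray,
    macro_coords: np.ndarray,
    n_boot: int = 900,
    seed=None,
    max_redraw: int = 100,
) -> TrajectoryComparison:
    """Observed micro/macro angle with a 900-bootstrap confidence interval.

    Per replicate, micro specimens are resampled with replacement stratified
    by habitat and macro species-mean rows are resampled with replacement,
    each dataset independently; the canonical axis and PC1 are recomputed on
    the resamples, slopes and unit vectors rebuilt, each replicate vector
    sign-aligned to the observed vector of its own dataset (axes carry an
    arbitrary sign), and the replicate angle recorded.  The unaligned angles
    are kept as well.  The verdict follows the observed-angle-versus-CI rule:
    ``outside`` the percentile interval means the trajectories differ.
    Replicates with a degenerate axis are redrawn (counted).
    """
    micro = np.asarray(micro_coords, dtype=float)
    if micro.ndim == 3:
        micro = micro.reshape(micro.shape[0], -1)
    macro = np.asarray(macro_coords, dtype=float)
    if macro.ndim == 3:
        macro = macro.reshape(macro.shape[0], -1)
    habitat = np.asarray(habitat)
    sex = np.asarray(sex)
    if micro.shape[1] != macro.shape[1]:
        raise ValueError("micro and macro data must share a shape space")

    v_micro = _micro_vector(micro, habitat, sex)
    v_macro = _macro_vector(macro)
    theta_obs = angle_between(v_micro, v_macro)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strata = [np.flatnonzero(habitat == h) for h in sorted(set(habitat))]
    n_macro = macro.shape[0]

    angles = np.empty(n_boot)
    angles_raw = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(max_redraw):
            try:
                idx = np.concatenate(
                    [st[rng.integers(0, st.size, st.size)] for st in strata]
                )
                bm = _micro_vector(micro[idx], habitat[idx], sex[idx])
                jdx = rng.integers(0, n_macro, n_macro)
                if np.unique(macro[jdx], axis=0).shape[0] < 2:
                    raise ValueError("degenerate macro resample")
                bv = _macro_vector(macro[jdx])
                break
            except (ValueError, np.linalg.LinAlgError):
                n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap replicate")
        d_micro = bm.direction
        d_macro = bv.direction
        angles_raw[b] = angle_between(d_micro, d_macro)
        if d_micro @ v_micro.direction < 0:
            d_micro = -d_micro
        if d_macro @ v_macro.direction < 0:
            d_macro = -d_macro
        angles[b] = angle_between(d_micro, d_macro)
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", n_redrawn)

    ci = percentile_ci(angles)
    ci_raw = percentile_ci(angles_raw)
    verdict = "inside" if ci[0] <= theta_obs <= ci[1] else "outside"
    return TrajectoryComparison(
        theta_obs=theta_obs,
        ci_boot=(float(ci[0]), float(ci[1])),
        ci_boot_unaligned=(float(ci_raw[0]), float(ci_raw[1])),
        n_boot=n_boot,
        verdict=verdict,
        micro=v_micro,
        macro=v_macro,
        boot_angles=angles,
        boot_angles_unaligned=angles_raw,
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# RRPP magnitude / common-trajectory test
# ---------------------------------------------------------------------------

@dataclass
class RrppResult:
    micro_mag: float
    macro_mag: float
    p_magnitude: float
    angle_obs: float
    p_angle: float
    n_perm: int

    def to_dict(self) -> dict:
        return {
            "micro_mag": self.micro_mag,
            "macro_mag": self.macro_mag,
            "p_magnitude": self.p_magnitude,
            "angle_obs": self.angle_obs,
            "p_angle": self.p_angle,
            "n_perm": self.n_perm,
        }


def rrpp_pairwise(
    coords: np.ndarray,
    groups: np.ndarray,
    scores: np.ndarray,
    n_perm: int = 1000,
    seed=None,
) -> RrppResult:
    """RRPP comparison of divergence magnitude and direction between two
    groupings sharing a shape space.

    ``coords`` stacks both datasets' shapes, ``groups`` labels their rows
    (two levels, e.g. micro/macro), ``scores`` carries each row's own axis
    score (canonical or PC1), standardized to unit variance within group so
    slope norms are comparable.  The full model fits a per-group intercept
    and per-group slope vector; observed statistics are the absolute
    difference of slope-vector norms and the angle between slope vectors.
    The reduced (null) model — shared trajectory with a common slope — has
    its residuals permuted across all rows; refitting the full model on each
    permuted response gives the null distributions.  p-values use
    (count ≥ observed + 1)/(n_perm + 1).
    """
    y = np.asarray(coords, dtype=float)
    if y.ndim == 3:
        y = y.reshape(y.shape[0], -1)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values will be coarse", n_perm)
    s = np.asarray(scores, dtype=float).copy()
    masks = [groups == lev for lev in levels]
    for mask in masks:
        sub = s[mask]
        sd = sub.std(ddof=1)
        if sd <= 0:
            raise ValueError("constant axis scores within a group")
        s[mask] = (sub - sub.mean()) / sd

    g0 = masks[0].astype(float)
    g1 = masks[1].astype(float)
    x_full = np.column_stack([g0, g1, s * g0, s * g1])
    x_red = np.column_stack([g0, g1, s])

    def fit(x, yy):
        beta, *_ = np.linalg.lstsq(x, yy, rcond=None)
        return beta

    def stats_from(yy):
        beta = fit(x_full, yy)
        b0, b1 = beta[2], beta[3]
        m0, m1 = np.linalg.norm(b0), np.linalg.norm(b1)
        dmag = abs(m0 - m1)
        denom = m0 * m1
        if denom == 0:
            return dmag, 180.0, m0, m1
        cosang = np.clip((b0 @ b1) / denom, -1.0, 1.0)
        return dmag, float(np.degrees(np.arccos(cosang))), m0, m1

    dmag_obs, angle_obs, m0, m1 = stats_from(y)

    beta_red = fit(x_red, y)
    fitted_red = x_red @ beta_red
    resid_red = y - fitted_red

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = y.shape[0]
    count_mag = 0
    count_ang = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted_red + resid_red[perm]
        dmag, ang, *_ = stats_from(y_star)
        if dmag >= dmag_obs:
            count_mag += 1
        if ang >= angle_obs:
            count_ang += 1
    p_mag = (count_mag + 1) / (n_perm + 1)
    p_ang = (count_ang + 1) / (n_perm + 1)

    # report magnitudes in the order (micro, macro) when labelled that way
    if levels == ["macro", "micro"]:
        m_micro, m_macro = m1, m0
    else:
        m_micro, m_macro = m0, m1
    return RrppResult(
        micro_mag=float(m_micro),
        macro_mag=float(m_macro),
        p_magnitude=float(p_mag),
        angle_obs=float(angle_obs),
        p_angle=float(p_ang),
        n_perm=n_perm,
    )
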