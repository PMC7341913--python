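"""Multivariate statistics on shape variables.

The study design is a 2×2 factorial (habitat × sex) on high-dimensional
shape responses.  Effects are tested with Pillai's trace from Type II sums
of squares and cross-products (each main effect adjusted for the other,
the interaction adjusted for both); canonical axes are the discriminant
directions of one factor's hypothesis SSCP against the error SSCP of the
same two-way model, so habitat scores are adjusted for sex and vice versa.
Allometry is the multivariate regression of aligned coordinates on log
centroid size, summarised by a pooled r², a Goodall-style F, and a
permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .superimpose import ShapeSpace

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------

@dataclass
class ManovaEffect:
    effect: str
    pillai: float
    approx_f: float
    num_df: int
    den_df: int
    p_value: float
    effect_df: int
    residual_df: int


@dataclass
class ManovaResult:
    effects: dict[str, ManovaEffect]
    n: int
    p_vars: int

    def table(self) -> str:
        """ANOVA-style text table: Pillai's trace, approx F, Num DF, Den DF, p."""
        lines = [f"{'effect':<14}{'Pillai':>9}{'approx F':>10}{'Num DF':>8}{'Den DF':>8}{'p':>10}"]
        for eff in self.effects.values():
            lines.append(
                f"{eff.effect:<14}{eff.pillai:>9.4f}{eff.approx_f:>10.3f}"
                f"{eff.num_df:>8d}{eff.den_df:>8d}{eff.p_value:>10.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            name: {
                "pillai": e.pillai,
                "approx_F": e.approx_f,
                "num_df": e.num_df,
                "den_df": e.den_df,
                "p_value": e.p_value,
                "effect_df": e.effect_df,
                "residual_df": e.residual_df,
            }
            for name, e in self.effects.items()
        }


def _two_level_codes(labels: np.ndarray, name: str) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(
            f"factor {name!r} must have exactly 2 levels, got {levels} "
            "(the design is 2×2)"
        )
    codes = np.where(np.asarray(labels) == levels[1], 0.5, -0.5)
    return codes, levels


def _projector(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _pillai_f(v: float, q: int, p: int, df_e: int):
    """Pillai approximate F with its standard degrees of freedom."""
    s = min(q, p)
    m = (abs(p - q) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    num_df = int(round(s * (2 * m + s + 1)))
    den_df = int(round(s * (2 * nn + s + 1)))
    if den_df <= 0 or s - v <= 0:
        return np.inf, num_df, max(den_df, 1), 0.0
    f = (den_df / num_df) * (v / (s - v))
    p_value = float(stats.f.sf(f, num_df, den_df))
    return float(f), num_df, den_df, p_value


def _sscp_effects(y: np.ndarray, habitat: np.ndarray, sex: np.ndarray):
    """Type II hypothesis SSCPs and the full-model error SSCP."""
    n = y.shape[0]
    a, _ = _two_level_codes(habitat, "habitat")
    b, _ = _two_level_codes(sex, "sex")
    cells = pd.crosstab(pd.Series(habitat), pd.Series(sex))
    if cells.shape != (2, 2) or (cells.to_numpy() == 0).any():
        raise ValueError("the two-way design requires all four habitat×sex cells")

    one = np.ones(n)
    x_full = np.column_stack([one, a, b, a * b])
    x_ab = np.column_stack([one, a, b])
    x_a = np.column_stack([one, a])
    x_b = np.column_stack([one, b])

    yc = y - y.mean(axis=0)  # projections all include the intercept; centering is neutral
    p_full = _projector(x_full)
    p_ab = _projector(x_ab)
    p_a = _projector(x_a)
    p_b = _projector(x_b)

    e = y.T @ (np.eye(n) - p_full) @ y
    h = {
        "habitat": y.T @ (p_ab - p_b) @ y,
        "sex": y.T @ (p_ab - p_a) @ y,
        "habitat:sex": y.T @ (p_full - p_ab) @ y,
    }
    df_e = n - 4
    return h, e, df_e


def manova_two_way(
    scores: np.ndarray, habitat: np.ndarray, sex: np.ndarray
) -> ManovaResult:
    """Two-way factorial MANOVA (habitat, sex, interaction) on shape scores.

    Pillai's trace = tr(H (H+E)⁻¹) with Type II hypothesis SSCPs; the
    approximate F and its degrees of freedom follow the standard Pillai
    formulas.
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim != 2:
        raise ValueError("scores must be a 2D (n × p) matrix")
    n, p = y.shape
    h, e, df_e = _sscp_effects(y, np.asarray(habitat), np.asarray(sex))

    total_scale = np.trace(e) + sum(np.trace(m) for m in h.values())
    if total_scale <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        # no variation anywhere: every effect is exactly zero
        effects = {
            name: ManovaEffect(name, 0.0, 0.0, p, max(df_e - p + 1, 1), 1.0, 1, df_e)
            for name in h
        }
        return ManovaResult(effects=effects, n=n, p_vars=p)

    if np.linalg.matrix_rank(e, tol=None) < p:
        raise ValueError(
            "error SSCP is singular (more shape variables than residual "
            "degrees of freedom); reduce dimensionality before the MANOVA"
        )

    effects = {}
    for name, hm in h.items():
        q = 1  # every term in the 2×2 factorial has one degree of freedom
        v = float(np.trace(hm @ np.linalg.inv(hm + e)))
        v = max(v, 0.0)
        f, num_df, den_df, p_value = _pillai_f(v, q, p, df_e)
        effects[name] = ManovaEffect(
            effect=name,
            pillai=v,
            approx_f=f,
            num_df=num_df,
            den_df=den_df,
            p_value=p_value,
            effect_df=q,
            residual_df=df_e,
        )
    return ManovaResult(effects=effects, n=n, p_vars=p)


# ---------------------------------------------------------------------------
# canonical axes
# ---------------------------------------------------------------------------

@dataclass
class CanonicalAxis:
    effect: str
    vector: np.ndarray       # unit-norm direction in score space
    scores: np.ndarray       # n canonical scores, zero grand mean
    group_means: dict[str, float]


def canonical_axis(
    scores: np.ndarray, effect: str, habitat: np.ndarray, sex: np.ndarray
) -> CanonicalAxis:
    """Leading discriminant direction for one factor of the two-way model.

    Solves the generalized eigenproblem of the factor's Type II hypothesis
    SSCP against the full-model error SSCP; with two levels there is exactly
    one canonical dimension.  The returned vector has unit Euclidean norm in
    score space; canonical scores are projections of the centred data, with
    sign fixed so the alphabetically later level has positive mean
    (urban > rural, M > F).
    """
    if effect not in ("habitat", "sex"):
        raise ValueError(f"effect must be 'habitat' or 'sex', got {effect!r}")
    y = np.asarray(scores, dtype=float)
    habitat = np.asarray(habitat)
    sex = np.asarray(sex)
    h, e, _ = _sscp_effects(y, habitat, sex)
    p = y.shape[1]
    if np.linalg.matrix_rank(e) < p:
        raise ValueError("error SSCP singular; reduce dimensionality first")
    evals, evecs = linalg.eigh(h[effect], e)
    vec = evecs[:, np.argmax(evals)]
    vec = vec / np.linalg.norm(vec)

    centred = y - y.mean(axis=0)
    proj = centred @ vec
    labels = habitat if effect == "habitat" else sex
    levels = sorted(pd.unique(labels))
    means = {lev: float(proj[labels == lev].mean()) for lev in levels}
    if means[levels[-1]] < means[levels[0]]:
        vec = -vec
        proj = -proj
        means = {lev: -m for lev, m in means.items()}
    return CanonicalAxis(effect=effect, vector=vec, scores=proj, group_means=means)


# ---------------------------------------------------------------------------
# allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometryResult:
    r_squared: float
    f_statistic: float
    p_value: float
    slopes: np.ndarray           # (2k,) shape change per unit predictor
    residual_shapes: np.ndarray  # (n, k, 2) allometry-minimized configurations
    predictor: str
    n_perm: int

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "F": self.f_statistic,
            "p_value": self.p_value,
            "predictor": self.predictor,
            "n_perm": self.n_perm,
        }


def allometry_regression(
    space: ShapeSpace,
    n_perm: int = 999,
    seed: int | None = None,
    predictor: str = "logcs",
) -> AllometryResult:
    """Multivariate regression of shape on (log) centroid size.

    r² is SS_model/SS_total pooled over all coordinates; F is the
    Goodall-style ratio of mean squares pooled the same way; the p-value
    comes from permuting the size values (``(count+1)/(n_perm+1)``).
    Residual shapes are the consensus plus the residual deviations, and have
    exactly zero sample covariance with the predictor.
    """
    if space.n < 3:
        raise ValueError("allometry regression needs at least 3 specimens")
    cs = np.asarray(space.centroid_sizes, dtype=float)
    if predictor == "logcs":
        x = np.log(cs)
    elif predictor == "cs":
        x = cs.copy()
    else:
        raise ValueError("predictor must be 'logcs' or 'cs'")
    if np.std(x) == 0:
        raise ValueError("centroid size does not vary; allometry undefined")

    y = space.coords_matrix()
    yc = y - y.mean(axis=0)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slopes = (xc @ yc) / sxx
    ss_total = float(np.sum(yc**2))
    ss_model = float(np.sum(slopes**2)) * sxx
    ss_res = ss_total - ss_model
    n = space.n
    r2 = ss_model / ss_total
    f_stat = (ss_model / 1.0) / (ss_res / (n - 2))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        xp = rng.permutation(xc)
        sm = float(np.sum(((xp @ yc) / sxx) ** 2)) * sxx
        fp = (sm / 1.0) / ((ss_total - sm) / (n - 2))
        if fp >= f_stat:
            count += 1
    p_value = (count + 1) / (n_perm + 1)

    resid = yc - np.outer(xc, slopes)
    residual_shapes = (space.consensus.reshape(-1) + resid).reshape(n, -1, 2)
    return AllometryResult(
        r_squared=r2,
        f_statistic=f_stat,
        p_value=p_value,
        slopes=slopes,
        residual_shapes=residual_shapes,
        predictor=predictor,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# species means and PCA
# ---------------------------------------------------------------------------

def species_mean_shapes(
    coords: np.ndarray, species: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Coordinate-wise mean configuration per species.

    ``coords`` is (n, k, 2) aligned (typically allometry-minimized)
    configurations.  Returns species labels (sorted) and an (s, k, 2) array
    of means in that order.
    """
    coords = np.asarray(coords, dtype=float)
    species = np.asarray(species)
    labels = sorted(pd.unique(species))
    means = np.stack([coords[species == lab].mean(axis=0) for lab in labels])
    return [str(lab) for lab in labels], means


@dataclass
class PcaResult:
    eigenvectors: np.ndarray  # (p, m) columns, orthonormal
    eigenvalues: np.ndarray   # (m,) nonincreasing, nonnegative
    scores: np.ndarray        # (n, m)
    mean: np.ndarray          # (p,)


def pca(data: np.ndarray) -> PcaResult:
    """PCA by eigendecomposition of the sample covariance (ddof=1).

    Component signs follow a fixed convention — the largest-magnitude
    loading of each component is positive — so downstream angle tests see a
    reproducible orientation.  Scores of component j have variance equal to
    eigenvalue j.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("PCA needs an (n ≥ 2) × p matrix")
    mean = y.mean(axis=0)
    yc = y - mean
    # SVD route: stable when p >> n (species means in shape space)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    evals = s**2 / (y.shape[0] - 1)
    evecs = vt.T
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = yc @ evecs
    return PcaResult(eigenvectors=evecs, eigenvalues=evals, scores=scores, mean=mean)
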