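"""Calibration experiments that check the pipeline against known theory.

Two quantities with known expected values are recomputed from scratch:

* the mean of the multivariate Blomberg's K statistic over many datasets
  simulated under Brownian motion on a 12-taxon pure-birth tree — K has
  expectation 1 under Brownian motion;
* the empirical coverage of the 95% percentile bootstrap confidence
  interval for the male–female Procrustes distance under a Gaussian
  landmark model with known true dimorphism — nominally 95%.
"""

from __future__ import annotations

import numpy as np

from ._util import percentile_ci
from .phylosignal import _kmult_from_parts, _kmult_ingredients, phylo_covariance, simulate_bm
from .synthetic import default_base_shape, pure_birth_tree, tangent_unit_vector


def bm_k_calibration(
    n_sims: int = 300,
    n_tips: int = 12,
    n_traits: int = 6,
    seed: int = 0,
) -> dict:
    """Mean multivariate K over BM-simulated trait datasets on one tree.

    One pure-birth tree is generated from the seed; ``n_sims`` independent
    ``n_traits``-dimensional Brownian datasets (unit rate) are simulated on
    it and K computed for each.  Under Brownian motion K should average 1.
    """
    rng = np.random.default_rng(seed)
    phy = pure_birth_tree(n_tips=n_tips, depth=15.0, seed=rng)
    _, c = phylo_covariance(phy)
    parts = _kmult_ingredients(c)
    tips = simulate_bm(phy, p=n_traits, rate=1.0, seed=rng, n_datasets=n_sims)
    ks = np.array([_kmult_from_parts(tips[i], *parts) for i in range(n_sims)])
    return {"mean_k": float(ks.mean()), "sd_k": float(ks.std(ddof=1)), "n": n_sims}


def dimorphism_ci_coverage(
    n_replicates: int = 200,
    n_boot: int = 400,
    n_per_sex: int = 30,
    k: int = 12,
    effect_norm: float = 0.04,
    noise_sd: float = 0.0004,
    seed: int = 0,
) -> dict:
    """Coverage of the percentile bootstrap CI for the sex-mean distance.

    A fixed ``k``-landmark mean shape and a fixed sex displacement vector of
    norm ``effect_norm`` define the truth; each replicate draws
    ``n_per_sex`` specimens per sex with isotropic Gaussian landmark noise,
    computes the male–female mean-shape Procrustes distance and its
    ``n_boot``-bootstrap 95% percentile interval.  Coverage is the percent
    of replicates whose interval contains the true distance.  The planted
    effect is large relative to the noise so the distance estimator's
    small-sample bias is negligible and the experiment isolates the
    bootstrap machinery itself.
    """
    setup_rng = np.random.default_rng(7421)  # the model is a fixed constant
    base = default_base_shape(k).reshape(-1)
    delta = effect_norm * tangent_unit_vector(base.reshape(k, 2), setup_rng)
    true_distance = float(np.linalg.norm(delta))

    rng = np.random.default_rng(seed)
    mean_f = base - delta / 2.0
    mean_m = base + delta / 2.0
    hits = 0
    for _ in range(n_replicates):
        females = mean_f + noise_sd * rng.standard_normal((n_per_sex, 2 * k))
        males = mean_m + noise_sd * rng.standard_normal((n_per_sex, 2 * k))
        idx_f = rng.integers(0, n_per_sex, (n_boot, n_per_sex))
        idx_m = rng.integers(0, n_per_sex, (n_boot, n_per_sex))
        boot_d = np.linalg.norm(
            males[idx_m].mean(axis=1) - females[idx_f].mean(axis=1), axis=1
        )
        lo, hi = percentile_ci(boot_d)
        if lo <= true_distance <= hi:
            hits += 1
    return {
        "coverage_percent": 100.0 * hits / n_replicates,
        "true_distance": true_distance,
        "n_replicates": n_replicates,
        "n_boot": n_boot,
    }
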