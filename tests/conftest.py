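"""Shared fixtures: small synthetic shape datasets built at test time."""

import numpy as np
import pytest

import foxmorph as fm


@pytest.fixture(scope="session")
def balanced_space():
    """GPA of a small balanced 2×2 synthetic population (k=12, n=40) with
    modest planted habitat and sex effects."""
    spec = fm.SyntheticSpec(
        k=12,
        cell_counts={(h, s): 10 for h in ("urban", "rural") for s in ("F", "M")},
        habitat_norm=0.03,
        sex_norm=0.02,
        noise_sd=0.008,
        seed=11,
    )
    ds, truth = fm.generate_population(spec)
    space = fm.gpa(ds)
    return space, truth


@pytest.fixture(scope="session")
def study_tree():
    return fm.pure_birth_tree(n_tips=12, depth=15.0, seed=21)


def random_configs(rng, n, k, scale=1.0, jitter=0.15):
    """Random non-degenerate landmark configurations around a polygon."""
    theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
    base = np.column_stack([1.5 * np.cos(theta), np.sin(theta)])
    out = base[None, :, :] + jitter * rng.standard_normal((n, k, 2))
    return out * scale
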