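"""Synthetic landmark datasets and phylogenies with known, planted structure.

Every downstream stage of the pipeline — GPA, the two-way shape MANOVA,
dimorphism bootstraps, allometry, phylogenetic signal, and the micro/macro
trajectory comparison — can be validated against the ground truth emitted
alongside the generated data.  Specimens are built in shape space as

    base + a_h·v_hab + a_s·v_sex + a_h·a_s·v_int
         + slope·(log CS − mean log CS) + N(0, σ²) per coordinate,

with a_h, a_s = ±1/2 coding habitat (urban +) and sex (M +), then given a
random size (log-normal centroid size), rotation and translation so the
superimposition has real work to do.  Effect vectors live in the tangent
space of the base shape (orthogonal to its similarity transforms), so the
planted displacement survives Procrustes alignment.  Species means for the
clade dataset evolve by Brownian motion on a supplied or simulated
pure-birth tree, optionally with a planted macroevolutionary axis.

Default dimensions mirror the study design this generator emulates: 36
dorsal landmarks; 111 specimens in cells urban (38 F, 37 M) and rural
(19 F, 17 M); a 12-taxon fox clade sampled by 163 specimens with uneven
per-species sample sizes; a time-calibrated tree about 15 Myr deep.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .landmark_io import LandmarkConfiguration, LandmarkDataset, Phylogeny
from .phylosignal import simulate_bm
from .superimpose import centroid_size, similarity_basis

DEFAULT_CELL_COUNTS = {
    ("urban", "F"): 38,
    ("urban", "M"): 37,
    ("rural", "F"): 19,
    ("rural", "M"): 17,
}

VULPINI_SPECIES = (
    "Vulpes_vulpes",
    "Vulpes_cana",
    "Vulpes_chama",
    "Vulpes_corsac",
    "Vulpes_ferrilata",
    "Vulpes_macrotis",
    "Vulpes_lagopus",
    "Vulpes_rueppellii",
    "Vulpes_velox",
    "Vulpes_zerda",
    "Otocyon_megalotis",
    "Nyctereutes_procyonoides",
)

# uneven museum-style sampling totalling 163 clade specimens
DEFAULT_CLADE_SAMPLES = (30, 20, 18, 15, 14, 12, 11, 10, 9, 9, 8, 7)


def default_base_shape(k: int = 36) -> np.ndarray:
    """An elongate convex polygon standing in for a skull outline in dorsal
    view: points around a 1.8:1 ellipse with a fixed mild radial
    perturbation, centred, unit centroid size.  Deterministic in k."""
    rng = np.random.default_rng(7421)  # fixed: the template is a constant
    theta = np.linspace(0.0, 2 * np.pi, k, endpoint=False)
    radii = 1.0 + 0.08 * rng.standard_normal(k)
    pts = np.column_stack([1.8 * radii * np.cos(theta), radii * np.sin(theta)])
    pts -= pts.mean(axis=0)
    return pts / centroid_size(pts)


def tangent_unit_vector(base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector in the tangent space of ``base`` (orthogonal to
    translations, scaling and rotation of the base shape)."""
    k2 = base.size
    sim = similarity_basis(base)
    v = rng.standard_normal(k2)
    v -= sim @ (sim.T @ v)
    return v / np.linalg.norm(v)


def project_to_tangent(vec: np.ndarray, base: np.ndarray) -> np.ndarray:
    sim = similarity_basis(base)
    v = np.asarray(vec, float).reshape(-1).copy()
    v -= sim @ (sim.T @ v)
    return v


def allometry_slope_norm_for_r2(
    r2: float, k: int, noise_sd: float, logcs_sd: float
) -> float:
    """Slope-vector norm that plants a target pooled allometry r².

    Balances the allometric sum of squares ‖slope‖²·(n−1)·sd(logCS)²
    against the shape-noise sum of squares that survives superimposition,
    ≈ (n−1)·(2k−4)·σ² (alignment absorbs the four similarity degrees of
    freedom).  Assumes no other planted effects.
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    return float(
        np.sqrt(r2 / (1.0 - r2) * (2 * k - 4) * noise_sd**2 / logcs_sd**2)
    )


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Effect vectors may be given explicitly (length-2k arrays, ideally in
    the base shape's tangent space) or left ``None`` to be drawn as random
    tangent directions with the stated norms.  ``dimorphism_ratio``, when
    set, derives the interaction vector from the sex vector so that the
    urban male–female distance is exactly that multiple of the rural one.
    Norms are in Procrustes (unit-centroid-size shape) units.
    """

    k: int = 36
    cell_counts: dict = field(default_factory=lambda: dict(DEFAULT_CELL_COUNTS))
    base_shape: np.ndarray | None = None
    habitat_vector: np.ndarray | None = None
    sex_vector: np.ndarray | None = None
    interaction_vector: np.ndarray | None = None
    habitat_norm: float = 0.02
    sex_norm: float = 0.015
    interaction_norm: float = 0.0
    dimorphism_ratio: float | None = None
    allometry_vector: np.ndarray | None = None
    allometry_norm: float = 0.0
    logcs_mean: float = 5.7      # log centroid size; e^5.7 ≈ 300 (units of the photos)
    logcs_sd: float = 0.1
    noise_sd: float = 0.01       # isotropic per-coordinate landmark noise, shape units
    rotation_jitter_deg: float = 30.0  # photography jitter; ±30° unless full_circle
    full_circle_rotations: bool = False
    # clade parameters
    species: tuple = VULPINI_SPECIES
    clade_samples: tuple = DEFAULT_CLADE_SAMPLES
    tree: Phylogeny | None = None
    tree_depth: float = 15.0     # Myr
    bm_rate: float = 9.3e-6      # per-coordinate, per Myr: clade spread ≫ habitat effect
    macro_vector: np.ndarray | None = None
    macro_norm: float = 0.0
    macro_score_sd: float = 1.0
    species_logcs_sd: float = 0.3
    seed: int = 0

    def resolve_base(self) -> np.ndarray:
        if self.base_shape is not None:
            return np.asarray(self.base_shape, dtype=float)
        return default_base_shape(self.k)


def _spawn_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """One documented split point: every stage gets its own child stream of
    the top-level seed, so stages are independently reproducible."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _resolve_vector(explicit, norm, base, rng, k2):
    if explicit is not None:
        v = np.asarray(explicit, dtype=float).reshape(-1)
        if v.size != k2:
            raise ValueError(f"effect vector has length {v.size}, expected {k2}")
        return v
    if norm == 0.0:
        return np.zeros(k2)
    return norm * tangent_unit_vector(base, rng)


def _rotate(points: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return points @ np.array([[c, s], [-s, c]])


def generate_population(spec: SyntheticSpec):
    """Generate the two-habitat, two-sex landmark sample plus ground truth.

    Returns ``(dataset, truth)``: a :class:`LandmarkDataset` with metadata
    populated and a dict holding the planted vectors, the per-habitat
    dimorphism distances, the dimorphism percent reduction, and the
    expected allometry r² implied by the realized sizes.
    """
    base = spec.resolve_base()
    k = base.shape[0]
    k2 = 2 * k
    rngs = _spawn_rngs(spec.seed, ["vectors", "cs", "noise", "pose", "tree", "bm", "macro"])
    rv = rngs["vectors"]

    v_hab = _resolve_vector(spec.habitat_vector, spec.habitat_norm, base, rv, k2)
    v_sex = _resolve_vector(spec.sex_vector, spec.sex_norm, base, rv, k2)
    if spec.dimorphism_ratio is not None:
        r = spec.dimorphism_ratio
        c = 2.0 * (r - 1.0) / (r + 1.0)
        v_int = c * v_sex
    else:
        v_int = _resolve_vector(spec.interaction_vector, spec.interaction_norm, base, rv, k2)
    v_allo = _resolve_vector(spec.allometry_vector, spec.allometry_norm, base, rv, k2)

    rows = []
    for (habitat, sex), count in spec.cell_counts.items():
        for _ in range(count):
            rows.append((habitat, sex))
    n = len(rows)
    a_h = np.array([0.5 if h == "urban" else -0.5 for h, _ in rows])
    a_s = np.array([0.5 if s == "M" else -0.5 for _, s in rows])

    logcs = spec.logcs_mean + spec.logcs_sd * rngs["cs"].standard_normal(n)
    cs = np.exp(logcs)
    x_allo = logcs - logcs.mean()

    effects = (
        np.outer(a_h, v_hab)
        + np.outer(a_s, v_sex)
        + np.outer(a_h * a_s, v_int)
        + np.outer(x_allo, v_allo)
    )
    noise = spec.noise_sd * rngs["noise"].standard_normal((n, k2))
    shapes = base.reshape(-1) + effects + noise

    configs = []
    pose = rngs["pose"]
    for i, (habitat, sex) in enumerate(rows):
        pts = shapes[i].reshape(k, 2)
        if spec.full_circle_rotations:
            theta = pose.uniform(0, 2 * np.pi)
        else:
            theta = np.deg2rad(pose.uniform(-spec.rotation_jitter_deg, spec.rotation_jitter_deg))
        pts = _rotate(pts, theta) * cs[i]
        pts = pts + pose.uniform(-10.0, 10.0, size=2) * np.exp(spec.logcs_mean) / 100.0
        configs.append(
            LandmarkConfiguration(
                specimen_id=f"fox_{i:03d}",
                coords=pts,
                metadata={
                    "habitat": habitat,
                    "sex": sex,
                    "species": "Vulpes_vulpes",
                    "aspect": "dorsal",
                    "adult": True,
                },
            )
        )
    dataset = LandmarkDataset(configurations=configs, aspect="dorsal")

    d_urban = float(np.linalg.norm(v_sex + 0.5 * v_int))
    d_rural = float(np.linalg.norm(v_sex - 0.5 * v_int))
    ss_x = float(np.sum(x_allo**2))
    ss_allo = float(np.sum(v_allo**2)) * ss_x

    def _ss(codes, vec):
        cc = codes - codes.mean()
        return float(np.sum(cc**2) * np.sum(vec**2))

    ss_effects = _ss(a_h, v_hab) + _ss(a_s, v_sex) + _ss(a_h * a_s, v_int)
    ss_noise = (n - 1) * (k2 - 4) * spec.noise_sd**2
    denom = ss_allo + ss_effects + ss_noise
    truth = {
        "habitat_vector": v_hab,
        "sex_vector": v_sex,
        "interaction_vector": v_int,
        "allometry_vector": v_allo,
        "d_rural": d_rural,
        "d_urban": d_urban,
        "percent_reduction": 100.0 * (d_rural - d_urban) / d_rural if d_rural > 0 else np.nan,
        "allometry_r2_expected": ss_allo / denom if denom > 0 else 0.0,
        "logcs": logcs,
        "base_shape": base,
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# clade / macroevolution
# ---------------------------------------------------------------------------

def pure_birth_tree(
    n_tips: int = 12,
    labels: tuple | None = None,
    depth: float = 15.0,
    seed: int | np.random.Generator = 0,
) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree and rescale it to a fixed depth.

    Coalescent-style construction: lineages split at exponential waiting
    times; the result is made ultrametric by extending tips to the present
    and rescaling total depth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = tuple(f"t{i + 1}" for i in range(n_tips))
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    # forward-time Yule: start with two lineages, split a random lineage at
    # exponential times until n_tips exist, then extend all to the present
    t = 0.0
    active = [dendropy.Node(), dendropy.Node()]
    tree = dendropy.Tree()
    tree.seed_node.add_child(active[0])
    tree.seed_node.add_child(active[1])
    birth = {id(nd): 0.0 for nd in active}
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(0, len(active))
        parent = active.pop(idx)
        parent.edge.length = t - birth[id(parent)]
        kids = [dendropy.Node(), dendropy.Node()]
        for kid in kids:
            parent.add_child(kid)
            birth[id(kid)] = t
            active.append(kid)
    t_end = t + rng.exponential(1.0 / len(active))
    for nd in active:
        nd.edge.length = t_end - birth[id(nd)]

    # scale to the requested depth and name the tips
    scale = depth / t_end
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    order = list(rng.permutation(len(labels)))
    for leaf, which in zip(tree.leaf_node_iter(), order):
        taxon = ns.new_taxon(label=labels[which])
        leaf.taxon = taxon
    return Phylogeny(tree=tree, is_ultrametric=True)


def generate_clade(spec: SyntheticSpec, individuals: bool = False):
    """Species mean shapes evolved by Brownian motion on the clade tree.

    Returns ``(labels, means, phylogeny, truth)`` where ``means`` is
    (n_species, k, 2); with ``individuals=True`` a fifth element — a
    :class:`LandmarkDataset` of per-species specimens drawn around the
    means with allometry and landmark noise — is appended.
    """
    base = spec.resolve_base()
    k = base.shape[0]
    k2 = 2 * k
    rngs = _spawn_rngs(spec.seed, ["vectors", "cs", "noise", "pose", "tree", "bm", "macro"])
    rv = rngs["vectors"]
    # burn the population draws so clade vectors are decoupled but the
    # macro vector stays reproducible for a given seed
    _ = _resolve_vector(None, 1.0, base, rv, k2)
    _ = _resolve_vector(None, 1.0, base, rv, k2)

    phy = spec.tree
    if phy is None:
        phy = pure_birth_tree(
            n_tips=len(spec.species),
            labels=spec.species,
            depth=spec.tree_depth,
            seed=rngs["tree"],
        )
    labels = phy.tips

    disp = simulate_bm(phy, p=k2, rate=spec.bm_rate, seed=rngs["bm"])
    v_macro = _resolve_vector(spec.macro_vector, spec.macro_norm, base, rngs["macro"], k2)
    scores = spec.macro_score_sd * rngs["macro"].standard_normal(len(labels))
    scores -= scores.mean()
    flat_means = base.reshape(-1) + disp + np.outer(scores, v_macro)
    means = flat_means.reshape(len(labels), k, 2)

    truth = {
        "macro_vector": v_macro,
        "macro_scores": scores,
        "bm_rate": spec.bm_rate,
        "bm_displacements": disp,
        "base_shape": base,
    }
    if not individuals:
        return labels, means, phy, truth

    v_allo = _resolve_vector(spec.allometry_vector, spec.allometry_norm, base, rv, k2)
    counts = spec.clade_samples
    if len(counts) != len(labels):
        raise ValueError("clade_samples must have one count per species")
    pose = rngs["pose"]
    noise_rng = rngs["noise"]
    cs_rng = rngs["cs"]
    species_logcs = spec.logcs_mean + spec.species_logcs_sd * cs_rng.standard_normal(len(labels))
    species_of = np.repeat(np.arange(len(labels)), counts)
    n_ind = species_of.size
    logcs_arr = species_logcs[species_of] + spec.logcs_sd * cs_rng.standard_normal(n_ind)
    x_allo = logcs_arr - logcs_arr.mean()

    configs = []
    for idx in range(n_ind):
        s_i = species_of[idx]
        flat = (
            flat_means[s_i]
            + x_allo[idx] * v_allo
            + noise_rng.standard_normal(k2) * spec.noise_sd
        )
        pts = flat.reshape(k, 2)
        theta = np.deg2rad(pose.uniform(-spec.rotation_jitter_deg, spec.rotation_jitter_deg))
        pts = _rotate(pts, theta) * np.exp(logcs_arr[idx])
        pts = pts + pose.uniform(-10.0, 10.0, size=2) * np.exp(spec.logcs_mean) / 100.0
        sex = "F" if idx % 2 == 0 else "M"
        configs.append(
            LandmarkConfiguration(
                specimen_id=f"{labels[s_i]}_{idx:03d}",
                coords=pts,
                metadata={
                    "habitat": "rural",
                    "sex": sex,
                    "species": labels[s_i],
                    "aspect": "dorsal",
                    "adult": True,
                },
            )
        )
    dataset = LandmarkDataset(configurations=configs, aspect="dorsal")
    truth["species_logcs"] = species_logcs
    return labels, means, phy, truth, dataset
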