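"""Reading and writing landmark data, specimen metadata, and phylogenies.

Landmark configurations travel in the TPS dialect written by the tpsUtil /
tpsRelw family of tools: records of ``LM=k`` followed by ``k`` lines of two
whitespace-separated floats, with optional ``ID=``, ``IMAGE=`` and ``SCALE=``
keys.  ``SCALE`` is an image-scale factor and is applied multiplicatively to
the coordinates at read time.  Metadata (habitat, sex, species, aspect,
adult) arrive as a delimited table keyed by specimen id, and trees as
Newick; Newick handling is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HABITATS = frozenset({"urban", "rural"})
SEXES = frozenset({"F", "M"})
ASPECTS = frozenset({"dorsal", "ventral"})

_KNOWN_TPS_KEYS = {"LM", "ID", "IMAGE", "SCALE"}

METADATA_COLUMNS = ("specimen_id", "habitat", "sex", "species", "aspect", "adult")


class TpsParseError(ValueError):
    """Structured failure while parsing a TPS file (names record / line)."""


class MetadataError(ValueError):
    """Invalid or incomplete specimen metadata."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmarks plus identity metadata.

    ``coords`` is a ``(k, 2)`` float array with any ``SCALE`` factor already
    applied.  ``metadata`` holds habitat/sex/species/aspect/adult when known.
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coords must be (k, 2), "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinates")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """An ordered collection of configurations sharing aspect and k."""

    configurations: list[LandmarkConfiguration]
    aspect: str | None = None

    def __post_init__(self) -> None:
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise ValueError(f"inconsistent landmark counts in dataset: {sorted(ks)}")
        ids = [c.specimen_id for c in self.configurations]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate specimen ids: {sorted(dupes)}")

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        if not self.configurations:
            return 0
        return self.configurations[0].k

    @property
    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an ``(n, k, 2)`` array."""
        return np.stack([c.coords for c in self.configurations])

    def metadata_frame(self) -> pd.DataFrame:
        rows = [{"specimen_id": c.specimen_id, **c.metadata} for c in self.configurations]
        return pd.DataFrame(rows).set_index("specimen_id")

    def subset(self, keep: Iterable[int]) -> "LandmarkDataset":
        keep = list(keep)
        return LandmarkDataset(
            configurations=[self.configurations[i] for i in keep], aspect=self.aspect
        )


@dataclass
class Phylogeny:
    """A rooted, branch-length-bearing tree; thin wrapper over dendropy.

    ``is_ultrametric`` records whether all root-to-tip path lengths agree
    (the time-calibrated supertrees used for comparative work are).
    """

    tree: dendropy.Tree
    is_ultrametric: bool = False

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def root_to_tip_lengths(self) -> dict[str, float]:
        # include any root edge (pruning can leave one) so depths are
        # measured from the original root
        self.tree.calc_node_root_distances(return_leaf_distances_only=True)
        stem = self.tree.seed_node.edge.length or 0.0
        return {
            leaf.taxon.label: leaf.root_distance + stem
            for leaf in self.tree.leaf_node_iter()
        }

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def _finish_record(records, pending, n_record, path):
    if pending["coords"] is None:
        return
    coords = np.asarray(pending["coords"], dtype=float)
    if coords.shape[0] != pending["lm"]:
        raise TpsParseError(
            f"{path}: record {n_record} declares LM={pending['lm']} but has "
            f"{coords.shape[0]} coordinate lines"
        )
    scale = pending["scale"]
    if scale is not None:
        coords = coords * scale
    specimen_id = pending["id"] if pending["id"] is not None else f"specimen_{n_record}"
    records.append(
        LandmarkConfiguration(specimen_id=specimen_id, coords=coords, scale=scale)
    )


def read_tps(path: str | Path, aspect: str | None = None) -> LandmarkDataset:
    """Parse a TPS file into a :class:`LandmarkDataset`.

    Records are returned in file order.  Supported keys: LM, ID, IMAGE,
    SCALE; unknown keys are ignored with a warning.  Errors name the
    offending record or line.
    """
    path = Path(path)
    records: list[LandmarkConfiguration] = []
    pending = {"lm": 0, "coords": None, "id": None, "scale": None}
    n_record = 0

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if "=" in line and not _looks_like_coords(line):
                key, _, value = line.partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "LM":
                    _finish_record(records, pending, n_record, path)
                    n_record += 1
                    try:
                        lm = int(value)
                    except ValueError as exc:
                        raise TpsParseError(
                            f"{path}:{lineno}: bad LM count {value!r}"
                        ) from exc
                    pending = {"lm": lm, "coords": [], "id": None, "scale": None}
                elif key == "ID":
                    pending["id"] = value
                elif key == "SCALE":
                    try:
                        pending["scale"] = float(value)
                    except ValueError as exc:
                        raise TpsParseError(
                            f"{path}:{lineno}: bad SCALE {value!r}"
                        ) from exc
                elif key == "IMAGE":
                    if pending["id"] is None and value:
                        pending["id"] = Path(value).stem
                else:
                    logger.warning("%s:%d: ignoring unknown TPS key %r", path, lineno, key)
            else:
                if pending["coords"] is None:
                    raise TpsParseError(
                        f"{path}:{lineno}: coordinate line before any LM= record"
                    )
                parts = line.split()
                if len(parts) != 2:
                    raise TpsParseError(
                        f"{path}:{lineno}: expected two coordinates, got {line!r}"
                    )
                try:
                    xy = (float(parts[0]), float(parts[1]))
                except ValueError as exc:
                    raise TpsParseError(
                        f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                    ) from exc
                pending["coords"].append(xy)
    _finish_record(records, pending, n_record, path)

    ks = [c.k for c in records]
    if len(set(ks)) > 1:
        bad = next(i for i, k in enumerate(ks, start=1) if k != ks[0])
        raise TpsParseError(
            f"{path}: record {bad} has LM={ks[bad - 1]} but record 1 has LM={ks[0]}"
        )
    return LandmarkDataset(configurations=records, aspect=aspect)


def _looks_like_coords(line: str) -> bool:
    # a line like "1.0 2.0" never contains '='; defensive helper kept for
    # dialects that put '=' in IMAGE paths
    head = line.split("=", 1)[0].strip()
    try:
        float(head)
        return True
    except ValueError:
        return False


def write_tps(ds: LandmarkDataset, path: str | Path, decimals: int = 6) -> None:
    """Write a dataset in the TPS dialect (round-trips through read_tps)."""
    path = Path(path)
    with open(path, "w") as fh:
        for conf in ds.configurations:
            fh.write(f"LM={conf.k}\n")
            for x, y in conf.coords:
                fh.write(f"{x:.{decimals}f} {y:.{decimals}f}\n")
            fh.write(f"ID={conf.specimen_id}\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a specimen metadata table (CSV/TSV autodetected by pandas)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"metadata table missing columns: {sorted(missing)}")
    return df


def _normalize_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "yes", "y", "1"}:
        return True
    if text in {"false", "f", "no", "n", "0"}:
        return False
    raise MetadataError(f"cannot interpret adult flag {value!r}")


def attach_metadata(ds: LandmarkDataset, table: pd.DataFrame | str | Path) -> LandmarkDataset:
    """Join a metadata table onto a dataset by specimen id.

    The join is case-insensitive on specimen id.  Habitat and sex values are
    case-normalized (``urban``/``rural`` lower-case, ``F``/``M`` upper-case);
    anything outside those vocabularies raises.  Table rows absent from the
    dataset are ignored with a warning; specimens absent from the table are
    an error.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_metadata(table)
    table = table.copy()
    table["__key"] = table["specimen_id"].astype(str).str.strip().str.lower()
    if table["__key"].duplicated().any():
        dupes = sorted(table.loc[table["__key"].duplicated(), "specimen_id"].unique())
        raise MetadataError(f"duplicate metadata rows for specimen ids: {dupes}")
    lookup = table.set_index("__key")

    missing = [
        c.specimen_id
        for c in ds.configurations
        if c.specimen_id.strip().lower() not in lookup.index
    ]
    if missing:
        raise MetadataError(f"no metadata row for specimens: {missing}")

    used_keys = {c.specimen_id.strip().lower() for c in ds.configurations}
    extra = sorted(set(lookup.index) - used_keys)
    if extra:
        logger.warning("metadata rows ignored (no matching specimen): %s", extra)

    new_configs = []
    for conf in ds.configurations:
        row = lookup.loc[conf.specimen_id.strip().lower()]
        habitat = str(row["habitat"]).strip().lower()
        if habitat not in HABITATS:
            raise MetadataError(
                f"specimen {conf.specimen_id!r}: habitat {row['habitat']!r} "
                f"not in {sorted(HABITATS)}"
            )
        sex = str(row["sex"]).strip().upper()
        if sex not in SEXES:
            raise MetadataError(
                f"specimen {conf.specimen_id!r}: sex {row['sex']!r} not in {sorted(SEXES)}"
            )
        aspect = str(row["aspect"]).strip().lower()
        if aspect not in ASPECTS:
            raise MetadataError(
                f"specimen {conf.specimen_id!r}: aspect {row['aspect']!r} "
                f"not in {sorted(ASPECTS)}"
            )
        meta = {
            "habitat": habitat,
            "sex": sex,
            "species": str(row["species"]).strip(),
            "aspect": aspect,
            "adult": _normalize_bool(row["adult"]),
        }
        new_configs.append(replace(conf, metadata={**conf.metadata, **meta}))
    return LandmarkDataset(configurations=new_configs, aspect=ds.aspect)


def filter_adults(ds: LandmarkDataset) -> LandmarkDataset:
    """Keep only specimens flagged adult (fused basi-sphenoid sutures)."""
    for conf in ds.configurations:
        if "adult" not in conf.metadata:
            raise MetadataError(
                f"specimen {conf.specimen_id!r} has no adult flag; attach metadata first"
            )
    keep = [i for i, c in enumerate(ds.configurations) if c.metadata["adult"]]
    out = ds.subset(keep)
    logger.info("adult filter kept %d of %d specimens", out.n, ds.n)
    if out.n == 0:
        logger.warning("adult filter removed every specimen")
    return out


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _check_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    depths = [leaf.root_distance for leaf in tree.leaf_node_iter()]
    if not depths:
        return False
    span = max(depths) - min(depths)
    scale = max(abs(max(depths)), 1e-300)
    return span <= rel_tol * scale


def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length} in {path}")
    return Phylogeny(tree=tree, is_ultrametric=_check_ultrametric(tree))


def phylogeny_from_newick_string(newick: str) -> Phylogeny:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return Phylogeny(tree=tree, is_ultrametric=_check_ultrametric(tree))


def prune(phy: Phylogeny, keep: Sequence[str]) -> Phylogeny:
    """Prune a tree to the named tips, conserving root-to-tip path lengths.

    Unifurcations created by pruning are suppressed by summing the adjacent
    branch lengths (dendropy's default), so retained tips keep their depth.
    """
    keep = list(keep)
    present = {t for t in phy.tips}
    absent = sorted(set(keep) - present)
    if absent:
        raise ValueError(f"tips not in tree: {absent}")
    tree = phy.tree.clone(depth=1)
    taxa = [tree.taxon_namespace.get_taxon(label) for label in keep]
    tree.retain_taxa(taxa)
    tree.purge_taxon_namespace()
    return Phylogeny(tree=tree, is_ultrametric=_check_ultrametric(tree))
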