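"""Data model and IO for host-tree surveys of atmospheric bromeliads.

The unit of observation is one sampled tree: its identity (patch, plot,
species), size (DBH, height), the leaf area index of its plot, a set of
species-level functional traits, and the per-epiphyte-species counts of
bromeliad individuals split by attachment site (trunk vs branches).

Three plain-text inputs describe a survey:

* ``trees.csv``    — one row per tree; epiphyte counts in paired columns
  ``trunk:<species>`` / ``branch:<species>``.
* ``traits.csv``   — one row per tree species; trait kinds (categorical,
  binary, quantitative) are declared, never inferred.
* ``phylogeny.nwk``— Newick tree with branch lengths over the tree species.
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HostTreeRecord",
    "Phylogeny",
    "TraitTable",
    "Dataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "community_from_records",
    "PUBLISHED_ABUNDANCES",
    "TRUNK_PREFIX",
    "BRANCH_PREFIX",
    "DEFAULT_TRAIT_KINDS",
]

TRUNK_PREFIX = "trunk:"
BRANCH_PREFIX = "branch:"

#: Declared kinds for the functional traits of tree species.  Kinds are part
#: of the data contract: a categorical trait silently treated as quantitative
#: would corrupt every downstream split and dissimilarity.
DEFAULT_TRAIT_KINDS: dict[str, str] = {
    "deciduousness": "categorical",
    "bark": "categorical",
    "peeling": "binary",
    "light_guild": "categorical",
    "thorns": "binary",
    "needles": "binary",
}

#: Published per-patch abundances of the four atmospheric bromeliad species
#: (Tillandsia) across the five vegetation patches: Eucalyptus plantation
#: (EP), Tabebuia grove (TP), Pinus elliottii plantation (PP), reforestation
#: (RP) and secondary forest (SF).  Used as a fixture for the single-dominant
#: abundance skew that the survey design exhibits.
PUBLISHED_ABUNDANCES = pd.DataFrame(
    {
        "T_recurvata": [76, 15927, 570, 44, 52],
        "T_pohliana": [40, 207, 159, 5, 40],
        "T_tricholepsis": [7, 336, 17, 0, 4],
        "T_loliacea": [9, 207, 72, 5, 3],
    },
    index=pd.Index(["EP", "TP", "PP", "RP", "SF"], name="patch"),
)


class DatasetError(ValueError):
    """Raised when a survey table violates the data contract."""


@dataclasses.dataclass
class HostTreeRecord:
    """One sampled tree with its traits and epiphyte counts.

    ``counts`` maps epiphyte species to ``(trunk_count, branch_count)``.
    A tree is a *host* iff it carries at least one bromeliad individual.
    """

    tree_id: str
    patch: str
    plot: str
    species: str
    dbh: float
    height: float
    lai: float
    traits: dict[str, object]
    counts: dict[str, tuple[int, int]]

    @property
    def a_trunk(self) -> int:
        return sum(t for t, _ in self.counts.values())

    @property
    def a_branch(self) -> int:
        return sum(b for _, b in self.counts.values())

    @property
    def a_total(self) -> int:
        return self.a_trunk + self.a_branch

    @property
    def ab_abund(self) -> int:
        return self.a_total

    @property
    def is_host(self) -> bool:
        return self.a_total > 0


class Phylogeny:
    """Rooted phylogeny with branch lengths, wrapping a dendropy tree.

    Leaf labels must be unique; every analysed tree species must map to
    exactly one leaf.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise DatasetError(f"duplicate leaf labels in phylogeny: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
            elif edge.length < 0:
                raise DatasetError("negative branch length in phylogeny")
        self._tree = tree
        self._labels = labels

    @classmethod
    def from_newick(cls, source: str | os.PathLike | io.TextIOBase) -> "Phylogeny":
        if isinstance(source, io.TextIOBase):
            text = source.read()
        elif isinstance(source, str) and source.lstrip().startswith("("):
            text = source
        else:
            with open(source) as fh:
                text = fh.read()
        try:
            tree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as err:
            raise DatasetError(f"could not parse Newick phylogeny (duplicate or malformed labels?): {err}") from err
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def check_labels(self, labels: Iterable[str]) -> None:
        missing = sorted(set(labels) - set(self._labels))
        if missing:
            raise DatasetError(
                f"species absent from phylogeny: {missing}"
            )

    def total_length(self) -> float:
        return sum(e.length for e in self._tree.preorder_edge_iter() if e.length)

    def shuffled_labels(self, rng: np.random.Generator) -> "Phylogeny":
        """Return a copy with leaf labels permuted uniformly at random."""
        clone = self._tree.clone(depth=1)
        leaves = list(clone.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        perm = rng.permutation(len(labels))
        for lf, i in zip(leaves, perm):
            lf.taxon = dendropy.Taxon(label=labels[i])
        return Phylogeny(clone)


class TraitTable:
    """Species × trait table with declared trait kinds.

    Categorical level order is first-appearance order in the input file so
    that dummy coding and split enumeration are deterministic.
    """

    def __init__(self, table: pd.DataFrame, kinds: Mapping[str, str]):
        unknown = set(kinds) - set(table.columns)
        if unknown:
            raise DatasetError(f"declared kinds for absent traits: {sorted(unknown)}")
        undeclared = [c for c in table.columns if c not in kinds]
        if undeclared:
            raise DatasetError(f"traits with undeclared kind: {undeclared}")
        bad = {k: v for k, v in kinds.items() if v not in ("categorical", "binary", "quantitative")}
        if bad:
            raise DatasetError(f"unknown trait kinds: {bad}")
        if table.index.duplicated().any():
            raise DatasetError("duplicate species in trait table")
        if table.isna().any().any():
            missing = table.columns[table.isna().any()].tolist()
            raise DatasetError(f"missing trait values in columns: {missing}")
        table = table.copy()
        levels: dict[str, list] = {}
        for trait, kind in kinds.items():
            if kind == "binary":
                table[trait] = _coerce_bool(table[trait], trait)
            elif kind == "quantitative":
                table[trait] = pd.to_numeric(table[trait], errors="raise")
            else:
                seen = list(dict.fromkeys(table[trait].astype(str)))
                levels[trait] = seen
                table[trait] = table[trait].astype(str)
        self.table = table
        self.kinds = dict(kinds)
        self.levels = levels

    @property
    def species(self) -> list[str]:
        return list(self.table.index)

    def __getitem__(self, trait: str) -> pd.Series:
        return self.table[trait]


def _coerce_bool(s: pd.Series, name: str) -> pd.Series:
    mapping = {
        True: True, False: False, 1: True, 0: False,
        "true": True, "false": False, "yes": True, "no": False, "1": True, "0": False,
    }
    out = s.map(lambda v: mapping.get(v if not isinstance(v, str) else v.strip().lower()))
    if out.isna().any():
        raise DatasetError(f"non-boolean values in binary trait {name!r}")
    return out.astype(bool)


@dataclasses.dataclass
class Dataset:
    """A validated survey: tree table, trait table, phylogeny.

    ``trees`` is indexed by ``tree_id`` and carries the derived columns
    ``a_trunk``, ``a_branch``, ``a_total`` (= AB_abund).  Per-epiphyte
    counts live in the aligned frames ``trunk_counts`` / ``branch_counts``.
    """

    trees: pd.DataFrame
    trunk_counts: pd.DataFrame
    branch_counts: pd.DataFrame
    traits: TraitTable
    phylogeny: Phylogeny

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        t = self.trees
        for col in ("patch", "plot", "species", "dbh", "height", "lai"):
            if col not in t.columns:
                raise DatasetError(f"missing required column {col!r}")
        if t.index.duplicated().any():
            dupes = t.index[t.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate tree_id: {dupes}")
        if (t["dbh"] <= 0).any() or (t["height"] <= 0).any():
            raise DatasetError("dbh and height must be positive")
        if (t["lai"] < 0).any():
            raise DatasetError("lai must be nonnegative")
        for frame, what in ((self.trunk_counts, "trunk"), (self.branch_counts, "branch")):
            if not frame.index.equals(t.index):
                raise DatasetError(f"{what} counts not aligned with tree table")
            arr = frame.to_numpy()
            if (arr < 0).any():
                raise DatasetError(f"negative {what} count")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise DatasetError(f"non-integer {what} count")
        if list(self.trunk_counts.columns) != list(self.branch_counts.columns):
            raise DatasetError("trunk/branch count columns disagree")
        missing = sorted(set(t["species"]) - set(self.traits.species))
        if missing:
            raise DatasetError(f"species absent from trait table: {missing}")
        self.phylogeny.check_labels(t["species"])
        # derived columns
        self.trees = t = t.copy()
        t["a_trunk"] = self.trunk_counts.sum(axis=1).astype(int)
        t["a_branch"] = self.branch_counts.sum(axis=1).astype(int)
        t["a_total"] = t["a_trunk"] + t["a_branch"]

    # -- views --------------------------------------------------------------
    @property
    def epiphyte_species(self) -> list[str]:
        return list(self.trunk_counts.columns)

    @property
    def hosts(self) -> pd.DataFrame:
        """Trees carrying at least one bromeliad individual."""
        return self.trees[self.trees["a_total"] > 0]

    def records(self) -> list[HostTreeRecord]:
        trait_cols = self.traits.kinds
        joined = self.trees.join(self.traits.table, on="species")
        recs = []
        for tid, row in joined.iterrows():
            counts = {
                sp: (int(self.trunk_counts.at[tid, sp]), int(self.branch_counts.at[tid, sp]))
                for sp in self.epiphyte_species
            }
            recs.append(
                HostTreeRecord(
                    tree_id=str(tid),
                    patch=row["patch"],
                    plot=row["plot"],
                    species=row["species"],
                    dbh=float(row["dbh"]),
                    height=float(row["height"]),
                    lai=float(row["lai"]),
                    traits={k: row[k] for k in trait_cols},
                    counts=counts,
                )
            )
        return recs

    def predictor_frame(self) -> pd.DataFrame:
        """Per-tree predictors: species traits joined with dbh/height/lai."""
        out = self.trees.join(self.traits.table, on="species")
        cols = list(self.traits.kinds) + ["dbh", "height", "lai"]
        return out[cols]

    def predictor_kinds(self) -> dict[str, str]:
        kinds = dict(self.traits.kinds)
        kinds.update({"dbh": "quantitative", "height": "quantitative", "lai": "quantitative"})
        return kinds


# ---------------------------------------------------------------------------
# IO


def _split_count_columns(columns: Iterable[str]) -> list[str]:
    eps: list[str] = []
    for c in columns:
        if c.startswith(TRUNK_PREFIX):
            eps.append(c[len(TRUNK_PREFIX):])
    return eps


def read_dataset(
    trees_path: str | os.PathLike,
    traits_path: str | os.PathLike,
    phylo_path: str | os.PathLike,
    config_path: str | os.PathLike | None = None,
) -> Dataset:
    """Read and validate a survey from ``trees.csv``/``traits.csv``/Newick.

    An optional YAML sidecar declares trait kinds (``trait_kinds``) and
    categorical level order (``categorical_levels``); otherwise the standard
    trait set is assumed and level order is first appearance.
    """
    kinds = dict(DEFAULT_TRAIT_KINDS)
    levels_cfg: dict[str, list[str]] = {}
    if config_path is not None:
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kinds = dict(cfg.get("trait_kinds", kinds))
        levels_cfg = cfg.get("categorical_levels", {})

    trees = pd.read_csv(trees_path, dtype={"tree_id": str, "patch": str, "plot": str})
    if "tree_id" not in trees.columns:
        raise DatasetError("missing required column 'tree_id'")
    trees = trees.set_index("tree_id")
    eps = _split_count_columns(trees.columns)
    if not eps:
        raise DatasetError("no epiphyte count columns (expected 'trunk:<sp>'/'branch:<sp>')")
    for sp in eps:
        if BRANCH_PREFIX + sp not in trees.columns:
            raise DatasetError(f"missing branch count column for {sp!r}")
    trunk = trees[[TRUNK_PREFIX + sp for sp in eps]].copy()
    trunk.columns = eps
    branch = trees[[BRANCH_PREFIX + sp for sp in eps]].copy()
    branch.columns = eps
    for frame in (trunk, branch):
        if frame.isna().any().any():
            raise DatasetError("missing epiphyte counts")
    trunk = trunk.astype(int)
    branch = branch.astype(int)
    meta = trees[[c for c in trees.columns if not c.startswith((TRUNK_PREFIX, BRANCH_PREFIX))]]

    traits_df = pd.read_csv(traits_path)
    if "species" not in traits_df.columns:
        raise DatasetError("missing required column 'species' in trait table")
    traits_df = traits_df.set_index("species")
    # restrict declared kinds to present columns only when a sidecar was given
    kinds = {k: v for k, v in kinds.items() if k in traits_df.columns} if config_path is None else kinds
    traits = TraitTable(traits_df, kinds)
    for trait, lv in levels_cfg.items():
        observed = set(traits.levels.get(trait, []))
        if not observed <= set(lv):
            raise DatasetError(f"levels of {trait!r} outside declared list")
        traits.levels[trait] = list(lv)

    phylo = Phylogeny.from_newick(phylo_path)
    return Dataset(meta, trunk, branch, traits, phylo)


def write_dataset(dataset: Dataset, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write trees.csv, traits.csv, phylogeny.nwk and config.yaml to a directory."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "trees": os.path.join(out_dir, "trees.csv"),
        "traits": os.path.join(out_dir, "traits.csv"),
        "phylogeny": os.path.join(out_dir, "phylogeny.nwk"),
        "config": os.path.join(out_dir, "config.yaml"),
    }
    trees = dataset.trees.drop(columns=["a_trunk", "a_branch", "a_total"])
    tr = dataset.trunk_counts.add_prefix(TRUNK_PREFIX)
    br = dataset.branch_counts.add_prefix(BRANCH_PREFIX)
    pd.concat([trees, tr, br], axis=1).to_csv(paths["trees"], index_label="tree_id")
    dataset.traits.table.to_csv(paths["traits"], index_label="species")
    with open(paths["phylogeny"], "w") as fh:
        fh.write(dataset.phylogeny.to_newick() + "\n")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {"trait_kinds": dataset.traits.kinds,
             "categorical_levels": dataset.traits.levels},
            fh, sort_keys=False,
        )
    return paths


# ---------------------------------------------------------------------------
# Community matrices


def community_from_records(
    records: Iterable[HostTreeRecord],
    sample_by: str = "plot",
    count_of: str = "host_tree_species",
) -> pd.DataFrame:
    """Aggregate tree records into a samples × species abundance matrix.

    ``count_of='host_tree_species'`` counts bromeliad individuals per host
    tree species (the community the phylogenetic structure tests look at);
    ``count_of='epiphyte_species'`` counts them per bromeliad species.
    """
    records = list(records)
    if not records:
        raise DatasetError("no records")
    if sample_by not in ("plot", "patch"):
        raise DatasetError(f"unknown sample_by {sample_by!r}")
    if count_of not in ("host_tree_species", "epiphyte_species"):
        raise DatasetError(f"unknown count_of {count_of!r}")

    samples = list(dict.fromkeys(getattr(r, sample_by) for r in records))
    if count_of == "host_tree_species":
        species = sorted({r.species for r in records})
    else:
        species = sorted({sp for r in records for sp in r.counts})
    mat = pd.DataFrame(0, index=pd.Index(samples, name=sample_by), columns=species, dtype=int)
    for r in records:
        s = getattr(r, sample_by)
        if count_of == "host_tree_species":
            mat.at[s, r.species] += r.a_total
        else:
            for sp, (t, b) in r.counts.items():
                mat.at[s, sp] += t + b
    return mat
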