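"""Diversity and co-occurrence metrics for host-tree communities.

Covers the per-tree distribution statistic AB_dst = A_trunk / A_total,
Faith's phylogenetic diversity, functional diversity as branch length on a
Gower/UPGMA trait dendrogram, the phylogenetic-species family of metrics
(PSV, PSR, PSE, PSC), and Schoener's index of co-occurrence together with
its correlation against phylogenetic distance.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, HostTreeRecord, Phylogeny, TraitTable

__all__ = [
    "UndefinedStatisticError",
    "ab_dst",
    "BranchIncidence",
    "branch_incidence",
    "faith_pd",
    "gower_dissimilarity",
    "Dendrogram",
    "functional_dendrogram",
    "functional_fd",
    "PhyloStructure",
    "phylo_structure",
    "psd_metrics",
    "schoener_matrix",
    "phylo_cooccurrence_correlation",
    "metrics_report",
]


class UndefinedStatisticError(ValueError):
    """A statistic was requested on inputs where it has no defined value."""


def ab_dst(record: HostTreeRecord) -> float:
    """Trunk-attached share of a host tree's bromeliads.

    1 means every individual sits on the trunk, 0 means every individual
    sits on the branches.  Undefined for trees hosting nothing.
    """
    if record.a_total == 0:
        raise UndefinedStatisticError(
            f"AB_dst undefined for non-host tree {record.tree_id!r}"
        )
    return record.a_trunk / record.a_total


# ---------------------------------------------------------------------------
# Branch-length spanning sums (PD / FD)


@dataclasses.dataclass
class BranchIncidence:
    """Edge × species incidence of root paths in a rooted tree.

    ``matrix[e, s]`` is True when edge ``e`` lies on the path from species
    ``s``'s leaf to the root.  The spanning branch length of a species set
    (include-root convention) is then the length-weighted union of the
    corresponding columns, which turns Faith-style PD into two matrix
    operations — cheap enough to evaluate for thousands of null replicates.
    """

    lengths: np.ndarray  # (E,)
    matrix: np.ndarray  # (E, S) boolean
    species: list[str]

    def spanning_length(self, species_set: Iterable[str]) -> float:
        idx = self._index(species_set)
        if idx.size == 0:
            raise UndefinedStatisticError("empty species set")
        union = self.matrix[:, idx].any(axis=1)
        return float(self.lengths @ union)

    def spanning_length_many(self, presence: np.ndarray) -> np.ndarray:
        """Spanning lengths for many sets at once; presence is (R, S) boolean."""
        covered = presence.astype(np.float64) @ self.matrix.T.astype(np.float64)
        return (covered > 0).astype(np.float64) @ self.lengths

    def _index(self, species_set: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.species)}
        out = []
        for s in species_set:
            if s not in pos:
                raise UndefinedStatisticError(f"unknown taxon label {s!r}")
            out.append(pos[s])
        return np.asarray(sorted(set(out)), dtype=int)

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


def branch_incidence(phylo: Phylogeny) -> BranchIncidence:
    """Precompute the root-path edge incidence of a phylogeny."""
    tree = phylo.tree
    leaves = list(tree.leaf_node_iter())
    species = [lf.taxon.label for lf in leaves]
    edges = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    eidx = {id(nd): i for i, nd in enumerate(edges)}
    lengths = np.array([nd.edge.length or 0.0 for nd in edges])
    mat = np.zeros((len(edges), len(species)), dtype=bool)
    for s, lf in enumerate(leaves):
        nd = lf
        while nd.parent_node is not None:
            mat[eidx[id(nd)], s] = True
            nd = nd.parent_node
    return BranchIncidence(lengths, mat, species)


def faith_pd(species_set: Iterable[str], phylo: Phylogeny | BranchIncidence) -> float:
    """Faith's phylogenetic diversity of a species set.

    Total branch length of the minimal rooted subtree connecting the set
    *and the root* (include-root convention), so a single species has
    PD equal to its root-path length.
    """
    inc = phylo if isinstance(phylo, BranchIncidence) else branch_incidence(phylo)
    return inc.spanning_length(species_set)


# ---------------------------------------------------------------------------
# Functional dendrogram (Gower + UPGMA)


def gower_dissimilarity(traits: TraitTable) -> pd.DataFrame:
    """Gower dissimilarity over mixed traits, equal weights.

    Quantitative traits are range-normalised over the species pool;
    categorical and binary traits contribute simple matching (0/1).  A
    quantitative trait with zero range contributes 0 for every pair.
    """
    species = traits.species
    n = len(species)
    total = np.zeros((n, n))
    for trait, kind in traits.kinds.items():
        col = traits.table[trait]
        if kind == "quantitative":
            x = col.to_numpy(dtype=float)
            rng = x.max() - x.min()
            if rng > 0:
                total += np.abs(x[:, None] - x[None, :]) / rng
        else:
            x = col.to_numpy()
            total += (x[:, None] != x[None, :]).astype(float)
    d = total / len(traits.kinds)
    return pd.DataFrame(d, index=species, columns=species)


@dataclasses.dataclass
class _DendroNode:
    height: float
    members: tuple[str, ...]
    children: tuple[int, int] | None  # indices into node list; None for leaves
    label: str | None = None


class Dendrogram:
    """UPGMA dendrogram supporting spanning branch-length queries.

    The branch length of a node is the height difference to its parent;
    functional diversity of a species set is the summed branch length of
    the minimal rooted subtree spanning the set (include-root convention,
    mirroring Faith's PD on the phylogeny).
    """

    def __init__(self, nodes: list[_DendroNode], root: int):
        self.nodes = nodes
        self.root = root
        self.species = [nd.label for nd in nodes if nd.children is None]
        self._incidence = self._build_incidence()

    def _build_incidence(self) -> BranchIncidence:
        parent = {}
        order = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            ch = self.nodes[i].children
            if ch:
                for c in ch:
                    parent[c] = i
                stack.extend(ch)
        non_root = [i for i in order if i != self.root]
        lengths = np.array(
            [self.nodes[parent[i]].height - self.nodes[i].height for i in non_root]
        )
        mat = np.zeros((len(non_root), len(self.species)), dtype=bool)
        eidx = {i: e for e, i in enumerate(non_root)}
        for s, label in enumerate(self.species):
            i = [j for j, nd in enumerate(self.nodes) if nd.children is None and nd.label == label][0]
            while i != self.root:
                mat[eidx[i], s] = True
                i = parent[i]
        return BranchIncidence(lengths, mat, list(self.species))

    @property
    def incidence(self) -> BranchIncidence:
        return self._incidence

    @property
    def total_length(self) -> float:
        return self._incidence.total_length

    def cophenetic(self) -> pd.DataFrame:
        """Ultrametric fusion-height distances between species (2 × height)."""
        n = len(self.species)
        d = np.zeros((n, n))
        pos = {s: i for i, s in enumerate(self.species)}
        for nd in self.nodes:
            if nd.children is None:
                continue
            a, b = nd.children
            for sa in self.nodes[a].members:
                for sb in self.nodes[b].members:
                    d[pos[sa], pos[sb]] = d[pos[sb], pos[sa]] = 2 * nd.height
        return pd.DataFrame(d, index=self.species, columns=self.species)

    def merge_heights(self) -> list[float]:
        return sorted(nd.height for nd in self.nodes if nd.children is not None)


def functional_dendrogram(traits: TraitTable) -> Dendrogram:
    """Gower dissimilarity + UPGMA agglomeration of the species pool.

    Ties in the minimum inter-cluster distance are broken by merging the
    pair whose (lexicographically smallest member, then second member)
    sorts first, so the dendrogram is deterministic.
    """
    if len(traits.species) < 2:
        raise UndefinedStatisticError("need at least two species")
    d = gower_dissimilarity(traits)
    if np.allclose(d.to_numpy(), 0):
        raise UndefinedStatisticError("all species functionally identical (zero dissimilarity)")

    nodes: list[_DendroNode] = []
    active: dict[int, int] = {}  # cluster id -> node index
    dist: dict[tuple[int, int], float] = {}
    key_of: dict[int, tuple[str, ...]] = {}
    for label in traits.species:
        i = len(nodes)
        nodes.append(_DendroNode(0.0, (label,), None, label))
        active[i] = i
        key_of[i] = (label,)
    ids = sorted(active)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            dist[(ids[a], ids[b])] = float(d.iat[a, b])

    def pair_key(i: int, j: int) -> tuple:
        return tuple(sorted((min(key_of[i]), min(key_of[j]))))

    while len(active) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], pair_key(*kv[0])),
        )
        (i, j), h = best
        new_id = len(nodes)
        members = tuple(sorted(nodes[active[i]].members + nodes[active[j]].members))
        nodes.append(_DendroNode(h / 2.0, members, (active[i], active[j])))
        ni, nj = len(nodes[active[i]].members), len(nodes[active[j]].members)
        del active[i], active[j]
        # average-linkage update
        new_d = {}
        for k in active:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            new_d[(k, new_id)] = (ni * dik + nj * djk) / (ni + nj)
        dist = {kv: v for kv, v in dist.items() if i not in kv and j not in kv}
        dist.update(new_d)
        active[new_id] = new_id
        key_of[new_id] = members
    root = active.popitem()[1]
    return Dendrogram(nodes, root)


def functional_fd(species_set: Iterable[str], dendrogram: Dendrogram) -> float:
    """Functional diversity: dendrogram branch length spanning the set."""
    return dendrogram.incidence.spanning_length(species_set)


# ---------------------------------------------------------------------------
# Phylogenetic species metrics


@dataclasses.dataclass
class PhyloStructure:
    """Correlation (C) and path-distance (D) matrices of a phylogeny.

    C is the shared root-to-ancestor depth scaled by total depth after
    ultrametricising the tree by extending terminal branches to the
    maximum depth, so the diagonal is exactly 1.  D keeps the original
    (unextended) path distances.
    """

    C: pd.DataFrame
    D: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.C.index)


def phylo_structure(phylo: Phylogeny) -> PhyloStructure:
    tree = phylo.tree
    depth: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
    leaves = list(tree.leaf_node_iter())
    species = [lf.taxon.label for lf in leaves]
    pos = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(species)
    cov = np.zeros((n, n))
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd._leafset = [pos[id(nd)]]
            continue
        sets = [c._leafset for c in nd.child_nodes()]
        d = depth[id(nd)]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    cov[i, np.asarray(sets[b])] = d
                    cov[np.asarray(sets[b]), i] = d
        nd._leafset = [i for s in sets for i in s]
    tip_depth = np.array([depth[id(lf)] for lf in leaves])
    T = tip_depth.max()
    if T <= 0:
        raise UndefinedStatisticError("phylogeny has zero total depth")
    C = cov / T
    np.fill_diagonal(C, 1.0)
    D = tip_depth[:, None] + tip_depth[None, :] - 2 * cov
    np.fill_diagonal(D, 0.0)
    return PhyloStructure(
        pd.DataFrame(C, index=species, columns=species),
        pd.DataFrame(D, index=species, columns=species),
    )


def psd_metrics(
    comm_row: pd.Series | Sequence[float],
    phylo: Phylogeny | PhyloStructure,
    species: Sequence[str] | None = None,
) -> dict[str, float]:
    """PSV, PSR, PSE and PSC of one community (abundance vector).

    PSV is one minus the mean off-diagonal phylogenetic correlation of the
    species present; PSR = richness × PSV; PSE weights the correlations by
    abundance (and equals PSV when abundances are even); PSC is one minus
    the mean nearest-relative correlation.
    """
    struct = phylo if isinstance(phylo, PhyloStructure) else phylo_structure(phylo)
    if isinstance(comm_row, pd.Series):
        labels = list(comm_row.index)
        a = comm_row.to_numpy(dtype=float)
    else:
        if species is None:
            raise UndefinedStatisticError("species labels required for a bare vector")
        labels = list(species)
        a = np.asarray(comm_row, dtype=float)
    present = a > 0
    labels_p = [s for s, p in zip(labels, present) if p]
    n = len(labels_p)
    if n < 2:
        raise UndefinedStatisticError("PSV family needs >= 2 species present")
    C = struct.C.loc[labels_p, labels_p].to_numpy()
    a = a[present]

    psv = (n * n - C.sum()) / (n * (n - 1))
    psr = n * psv
    N = a.sum()
    mbar = N / n
    pse = (N * a.sum() - a @ C @ a) / (N * N - N * mbar)
    Coff = C - np.eye(n)
    psc = 1.0 - float(np.mean(Coff.max(axis=1)))
    return {"psv": float(psv), "psr": float(psr), "pse": float(pse), "psc": float(psc)}


# ---------------------------------------------------------------------------
# Co-occurrence


def schoener_matrix(comm: pd.DataFrame) -> pd.DataFrame:
    """Schoener's co-occurrence index for every species pair.

    S_ij = 1 − ½ Σ_k |p_ik − p_jk| where p_ik is species i's share of its
    own total abundance found in sample k.  1 means identical relative
    use of samples, 0 means fully disjoint.
    """
    totals = comm.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise UndefinedStatisticError(
            f"species with zero total abundance: {list(zero.index)}"
        )
    p = comm.to_numpy(dtype=float) / totals.to_numpy()[None, :]
    diff = np.abs(p[:, :, None] - p[:, None, :]).sum(axis=0)
    S = 1.0 - 0.5 * diff
    return pd.DataFrame(S, index=comm.columns, columns=comm.columns)


def phylo_cooccurrence_correlation(
    comm: pd.DataFrame,
    phylo: Phylogeny | PhyloStructure,
) -> float:
    """Pearson correlation between pairwise co-occurrence and phylogenetic distance."""
    if comm.shape[1] < 3:
        raise UndefinedStatisticError("need >= 3 species for a pairwise correlation")
    struct = phylo if isinstance(phylo, PhyloStructure) else phylo_structure(phylo)
    S = schoener_matrix(comm)
    sp = list(comm.columns)
    D = struct.D.loc[sp, sp].to_numpy()
    iu = np.triu_indices(len(sp), k=1)
    s, d = S.to_numpy()[iu], D[iu]
    if np.ptp(s) == 0 or np.ptp(d) == 0:
        raise UndefinedStatisticError("zero variance in co-occurrence or distance")
    return float(np.corrcoef(s, d)[0, 1])


# ---------------------------------------------------------------------------
# Report


def metrics_report(dataset: Dataset) -> dict[str, pd.DataFrame]:
    """Per-tree AB statistics and per-plot/patch diversity summaries."""
    trees = dataset.trees
    per_tree = trees[["patch", "plot", "species", "a_trunk", "a_total"]].copy()
    per_tree["ab_abund"] = per_tree["a_total"]
    with np.errstate(invalid="ignore"):
        per_tree["ab_dst"] = np.where(
            per_tree["a_total"] > 0, per_tree["a_trunk"] / per_tree["a_total"], np.nan
        )

    inc = branch_incidence(dataset.phylogeny)
    dend = functional_dendrogram(dataset.traits)
    struct = phylo_structure(dataset.phylogeny)
    rows = []
    for (patch, plot), grp in trees.groupby(["patch", "plot"], sort=False):
        sp = sorted(set(grp["species"]))
        abund = grp.groupby("species")["a_total"].sum()
        abund = abund.reindex(struct.species, fill_value=0)
        row = {
            "patch": patch,
            "plot": plot,
            "richness": len(sp),
            "pd": inc.spanning_length(sp),
            "fd": dend.incidence.spanning_length(sp),
        }
        try:
            row.update(psd_metrics(abund, struct))
        except UndefinedStatisticError:
            row.update({k: np.nan for k in ("psv", "psr", "pse", "psc")})
        rows.append(row)
    per_sample = pd.DataFrame(rows)
    return {"per_tree": per_tree, "per_sample": per_sample}
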