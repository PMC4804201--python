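import numpy as np
import pandas as pd
import pytest

from epihost.data import (
    DEFAULT_TRAIT_KINDS,
    PUBLISHED_ABUNDANCES,
    Dataset,
    Phylogeny,
    TraitTable,
)

# 5-taxon ultrametric fixture used throughout the metric tests:
# depths: (A,B) join at 2, (D,E) at 2, (C,(D,E)) at 1, root at 0; tips at 3.
FIVE_TAXON_NEWICK = "((A:1,B:1):2,(C:2,(D:1,E:1):1):1);"


@pytest.fixture
def five_taxon_phylo() -> Phylogeny:
    return Phylogeny.from_newick(FIVE_TAXON_NEWICK)


def make_trait_table(species, seed=0) -> TraitTable:
    rng = np.random.default_rng(seed)
    decid = ["deciduous", "semi-deciduous", "evergreen"]
    barks = ["smooth", "grooved", "reticulated", "flaky"]
    df = pd.DataFrame(
        {
            "deciduousness": rng.choice(decid, len(species)),
            "bark": rng.choice(barks, len(species)),
            "peeling": rng.random(len(species)) < 0.5,
            "light_guild": rng.choice(["heliophyte", "esciophyte"], len(species)),
            "thorns": rng.random(len(species)) < 0.3,
            "needles": rng.random(len(species)) < 0.2,
        },
        index=pd.Index(list(species), name="species"),
    )
    return TraitTable(df, DEFAULT_TRAIT_KINDS)


@pytest.fixture
def five_taxon_traits() -> TraitTable:
    return make_trait_table(list("ABCDE"), seed=3)


def make_dataset(counts, species=None, phylo=None, patch="P1", seed=0) -> Dataset:
    """Small dataset from a list of (trunk, branch) count pairs per tree."""
    n = len(counts)
    species = species or [f"s{i % 3 + 1}" for i in range(n)]
    uniq = sorted(set(species))
    trees = pd.DataFrame(
        {
            "patch": patch,
            "plot": f"{patch}-1",
            "species": species,
            "dbh": np.linspace(10, 40, n),
            "height": np.linspace(5, 12, n),
            "lai": 1.2,
        },
        index=pd.Index([f"t{i+1}" for i in range(n)], name="tree_id"),
    )
    trunk = pd.DataFrame({"T_recurvata": [c[0] for c in counts]}, index=trees.index)
    branch = pd.DataFrame({"T_recurvata": [c[1] for c in counts]}, index=trees.index)
    traits = make_trait_table(uniq, seed=seed)
    if phylo is None:
        newick = "(" + ",".join(f"{s}:1.0" for s in uniq) + "):0.0;"
        phylo = Phylogeny.from_newick(newick)
    return Dataset(trees, trunk, branch, traits, phylo)


def write_published_survey(tmp_path):
    """Survey CSVs whose per-patch epiphyte totals equal the published table.

    One tree per patch carries that patch's four species counts (split
    arbitrarily between trunk and branch).
    """
    eps = list(PUBLISHED_ABUNDANCES.columns)
    rows = []
    for i, (patch, counts) in enumerate(PUBLISHED_ABUNDANCES.iterrows()):
        row = {
            "tree_id": f"h{i+1}", "patch": patch, "plot": f"{patch}-1",
            "species": f"host{i+1}", "dbh": 20.0, "height": 8.0, "lai": 1.0,
        }
        for sp in eps:
            t = counts[sp] // 2
            row[f"trunk:{sp}"] = t
            row[f"branch:{sp}"] = counts[sp] - t
        rows.append(row)
    trees_path = tmp_path / "trees.csv"
    pd.DataFrame(rows).to_csv(trees_path, index=False)
    traits = make_trait_table([f"host{i+1}" for i in range(5)], seed=1)
    traits_path = tmp_path / "traits.csv"
    traits.table.to_csv(traits_path, index_label="species")
    phylo_path = tmp_path / "phylogeny.nwk"
    phylo_path.write_text("(" + ",".join(f"host{i+1}:1.0" for i in range(5)) + "):0.0;\n")
    return trees_path, traits_path, phylo_path
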