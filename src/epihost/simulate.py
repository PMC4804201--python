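"""Synthetic surveys with the statistical structure the analysis assumes.

A scenario describes a survey design (patches × plots × trees), a species
pool with trait syndromes, a rule tree mapping trait combinations to
Poisson abundance means, allocation rules mapping traits to the
probability that an individual attaches to the trunk, and a skewed
epiphyte species mix dominated by a single species (as atmospheric
bromeliad assemblages typically are, with *T. recurvata* contributing the
overwhelming majority of individuals).

Five named scenarios ship with the package:

``null``
    No trait drives abundance or allocation; every tree draws from the
    same Poisson mean and attaches individuals 50/50.  The recursive
    trait tree should find nothing here.
``deciduousness_only``
    One categorical trait (deciduousness) separates high-abundance
    (mean 400) from low-abundance (mean 3) trees; everything else is held
    fixed.  A one-split tree is the ground truth.
``two_stage``
    Deciduousness gates a second, quantitative rule: deciduous trees with
    DBH at or below 30 cm carry mean 400, all other trees mean 3.  The
    generating rule tree is a root split on deciduousness followed by a
    DBH median split inside the deciduous arm; other traits are held
    fixed so the recovery of exactly this topology can be scored.
``tp_like``
    Five functionally contrasted patches emulating the monodominant
    silviculture design (a hyperabundant deciduous small-DBH patch with
    reticulated bark and trunk probability 0.04, so most individuals end
    up on branches).
``mixed_forest``
    Diverse pools in every patch with mild trait effects on abundance and
    bark-driven allocation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .data import DEFAULT_TRAIT_KINDS, Dataset, Phylogeny, TraitTable

__all__ = [
    "ScenarioConfig",
    "simulate_phylogeny",
    "simulate_dataset",
    "named_scenarios",
    "uniform_placement_dataset",
]

#: Single-dominant epiphyte mix (shares of individuals per bromeliad species).
DEFAULT_EPIPHYTE_MIX = {
    "T_recurvata": 0.94,
    "T_pohliana": 0.03,
    "T_tricholepsis": 0.02,
    "T_loliacea": 0.01,
}

_RULE_KEYS = ("dbh_max", "dbh_min", "height_max", "height_min", "lai_max", "lai_min")


@dataclasses.dataclass
class ScenarioConfig:
    """Full description of one synthetic survey."""

    name: str
    species_pool: dict[str, dict]  # species -> trait dict (may carry 'dbh_range'/'height_range')
    patch_species: dict[str, dict[str, float]]  # patch -> species -> sampling weight
    abundance_rules: list[dict]  # [{'when': {...}, 'mean': float}], first match wins
    default_mean: float
    allocation_rules: list[dict]  # [{'when': {...}, 'p': float}]
    default_p: float = 0.5
    plots_per_patch: int = 5
    trees_per_plot: int = 8
    epiphyte_mix: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EPIPHYTE_MIX)
    )
    dbh_range: tuple[float, float] = (5.0, 60.0)
    height_range: tuple[float, float] = (3.0, 15.0)
    lai_range: tuple[float, float] = (0.5, 2.5)
    phylo_model: str = "yule"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.species_pool:
            raise ValueError("empty species pool")
        trait_names = set(DEFAULT_TRAIT_KINDS)
        for sp, traits in self.species_pool.items():
            missing = trait_names - set(traits)
            if missing:
                raise ValueError(f"species {sp!r} missing traits {sorted(missing)}")
        for patch, freqs in self.patch_species.items():
            unknown = set(freqs) - set(self.species_pool)
            if unknown:
                raise ValueError(f"patch {patch!r} uses undeclared species {sorted(unknown)}")
            if not all(f >= 0 for f in freqs.values()) or sum(freqs.values()) <= 0:
                raise ValueError(f"invalid species weights for patch {patch!r}")
        for rule in self.abundance_rules:
            if rule.get("mean", -1) < 0:
                raise ValueError("Poisson means must be >= 0")
            self._check_rule(rule)
        if self.default_mean < 0:
            raise ValueError("default_mean must be >= 0")
        for rule in self.allocation_rules:
            if not 0 <= rule.get("p", -1) <= 1:
                raise ValueError("allocation probabilities must lie in [0, 1]")
            self._check_rule(rule)
        if not 0 <= self.default_p <= 1:
            raise ValueError("default_p must lie in [0, 1]")
        total = sum(self.epiphyte_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("epiphyte mix must sum to 1")
        if self.phylo_model not in ("yule", "star"):
            raise ValueError(f"unknown phylogeny model {self.phylo_model!r}")

    def _check_rule(self, rule: dict) -> None:
        for key in rule.get("when", {}):
            if key in _RULE_KEYS:
                continue
            if key not in DEFAULT_TRAIT_KINDS:
                raise ValueError(f"rule references undeclared trait {key!r}")

    def rule_tree_text(self) -> str:
        """Human-readable serialization of the generating abundance rules."""
        lines = []
        for rule in self.abundance_rules:
            cond = " & ".join(f"{k}={v}" for k, v in rule["when"].items())
            lines.append(f"if {cond}: mean={rule['mean']}")
        lines.append(f"else: mean={self.default_mean}")
        return "\n".join(lines)


def _match(rule_when: dict, traits: dict, dbh: float, height: float, lai: float) -> bool:
    for key, val in rule_when.items():
        if key == "dbh_max":
            if not dbh <= val:
                return False
        elif key == "dbh_min":
            if not dbh > val:
                return False
        elif key == "height_max":
            if not height <= val:
                return False
        elif key == "height_min":
            if not height > val:
                return False
        elif key == "lai_max":
            if not lai <= val:
                return False
        elif key == "lai_min":
            if not lai > val:
                return False
        elif traits.get(key) != val:
            return False
    return True


def abundance_mean(config: ScenarioConfig, traits: dict, dbh: float, height: float, lai: float) -> float:
    for rule in config.abundance_rules:
        if _match(rule.get("when", {}), traits, dbh, height, lai):
            return float(rule["mean"])
    return float(config.default_mean)


def trunk_probability(config: ScenarioConfig, traits: dict, dbh: float, height: float, lai: float) -> float:
    for rule in config.allocation_rules:
        if _match(rule.get("when", {}), traits, dbh, height, lai):
            return float(rule["p"])
    return float(config.default_p)


# ---------------------------------------------------------------------------
# Phylogeny simulation


def simulate_phylogeny(
    n_species: int,
    model: str = "yule",
    seed: int | None = None,
    labels: list[str] | None = None,
) -> Phylogeny:
    """Random ultrametric phylogeny: pure-birth ('yule') or star topology."""
    if n_species < 2:
        raise ValueError("need >= 2 species")
    if labels is not None and len(labels) != n_species:
        raise ValueError("label count must equal n_species")
    names = labels or [f"sp{i+1:02d}" for i in range(n_species)]
    if model == "star":
        newick = "(" + ",".join(f"{n}:1.0" for n in names) + "):0.0;"
        return Phylogeny.from_newick(newick)
    if model != "yule":
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    # pure-birth coalescent-style construction: start from n lineages at the
    # present, merge two uniformly chosen lineages at exponential waiting
    # times; yields an ultrametric rooted tree with unit birth rate.
    nodes = [dendropy.Node() for _ in range(n_species)]
    taxon_ns = dendropy.TaxonNamespace()
    for nd, name in zip(nodes, names):
        nd.taxon = taxon_ns.new_taxon(label=name)
    ages = {id(nd): 0.0 for nd in nodes}
    t = 0.0
    active = list(nodes)
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent = dendropy.Node()
        ages[id(parent)] = t
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = t - ages[id(child)]
        active = [nd for nd in active if nd not in (a, b)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=active[0])
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# Dataset simulation


def simulate_dataset(config: ScenarioConfig, seed: int | None = None) -> Dataset:
    """Draw a full survey from a scenario.

    Each tree's total bromeliad count is Poisson with the mean given by the
    first matching abundance rule; counts are split across the epiphyte
    mix multinomially and each per-species count splits binomially into
    trunk vs branch attachment with the tree's allocation probability.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    eps = list(config.epiphyte_mix)
    mix = np.array([config.epiphyte_mix[e] for e in eps], dtype=float)

    rows = []
    trunk_rows = []
    branch_rows = []
    tid = 0
    for patch, freqs in config.patch_species.items():
        sp_names = list(freqs)
        w = np.array([freqs[s] for s in sp_names], dtype=float)
        w = w / w.sum()
        for p in range(config.plots_per_patch):
            plot = f"{patch}-{p+1}"
            lai = float(rng.uniform(*config.lai_range))
            for _ in range(config.trees_per_plot):
                tid += 1
                species = sp_names[int(rng.choice(len(sp_names), p=w))]
                traits = config.species_pool[species]
                dbh_rng = traits.get("dbh_range", config.dbh_range)
                height_rng = traits.get("height_range", config.height_range)
                dbh = float(rng.uniform(*dbh_rng))
                height = float(rng.uniform(*height_rng))
                mean = abundance_mean(config, traits, dbh, height, lai)
                total = int(rng.poisson(mean))
                counts = rng.multinomial(total, mix) if total > 0 else np.zeros(len(eps), int)
                p_trunk = trunk_probability(config, traits, dbh, height, lai)
                trunk = np.array([rng.binomial(c, p_trunk) for c in counts])
                rows.append({
                    "tree_id": f"t{tid:04d}", "patch": patch, "plot": plot,
                    "species": species, "dbh": round(dbh, 2),
                    "height": round(height, 2), "lai": round(lai, 3),
                })
                trunk_rows.append(trunk)
                branch_rows.append(counts - trunk)

    trees = pd.DataFrame(rows).set_index("tree_id")
    trunk_counts = pd.DataFrame(np.array(trunk_rows), index=trees.index, columns=eps)
    branch_counts = pd.DataFrame(np.array(branch_rows), index=trees.index, columns=eps)

    pool = list(config.species_pool)
    trait_names = list(DEFAULT_TRAIT_KINDS)
    traits_df = pd.DataFrame(
        {t: [config.species_pool[s][t] for s in pool] for t in trait_names},
        index=pd.Index(pool, name="species"),
    )
    traits = TraitTable(traits_df, DEFAULT_TRAIT_KINDS)
    phylo_seed = int(np.random.SeedSequence(config.seed if seed is None else seed).generate_state(1)[0] % (2**31))
    phylo = simulate_phylogeny(len(pool), config.phylo_model, seed=phylo_seed, labels=pool)
    return Dataset(trees, trunk_counts, branch_counts, traits, phylo)


def uniform_placement_dataset(
    n_species: int = 30,
    n_individuals: int = 40,
    clustered: bool = False,
    seed: int | None = None,
) -> Dataset:
    """One patch of one tree per species, individuals placed uniformly.

    The data-generating mechanism is exactly the individual-randomisation
    null (every individual thrown independently and uniformly over the
    trees), so envelopes computed on such data should cover the observed
    statistic at their nominal rate.  With ``clustered=True`` every
    individual lands on the first tree instead — the maximally clustered
    alternative the null model must flag.
    """
    rng = np.random.default_rng(seed)
    species = [f"sp{i+1:02d}" for i in range(n_species)]
    decid = ["deciduous", "semi-deciduous", "evergreen"]
    barks = ["smooth", "grooved", "reticulated", "flaky"]
    trees = pd.DataFrame({
        "patch": "P1",
        "plot": "P1-1",
        "species": species,
        "dbh": np.round(rng.uniform(10, 50, n_species), 2),
        "height": np.round(rng.uniform(4, 15, n_species), 2),
        "lai": 1.5,
    }, index=pd.Index([f"t{i+1:03d}" for i in range(n_species)], name="tree_id"))
    if clustered:
        per_tree = np.zeros(n_species, dtype=int)
        per_tree[0] = n_individuals
    else:
        per_tree = rng.multinomial(n_individuals, np.full(n_species, 1.0 / n_species))
    trunk = np.array([rng.binomial(c, 0.5) for c in per_tree])
    trunk_counts = pd.DataFrame({"T_recurvata": trunk}, index=trees.index)
    branch_counts = pd.DataFrame({"T_recurvata": per_tree - trunk}, index=trees.index)
    traits_df = pd.DataFrame({
        "deciduousness": [decid[i % 3] for i in range(n_species)],
        "bark": [barks[i % 4] for i in range(n_species)],
        "peeling": [i % 2 == 0 for i in range(n_species)],
        "light_guild": ["heliophyte" if i % 2 else "esciophyte" for i in range(n_species)],
        "thorns": [i % 5 == 0 for i in range(n_species)],
        "needles": [i % 7 == 0 for i in range(n_species)],
    }, index=pd.Index(species, name="species"))
    traits = TraitTable(traits_df, DEFAULT_TRAIT_KINDS)
    phylo_seed = int(np.random.SeedSequence(0 if seed is None else seed).generate_state(1)[0] % (2**31))
    phylo = simulate_phylogeny(n_species, "yule", seed=phylo_seed, labels=species)
    return Dataset(trees, trunk_counts, branch_counts, traits, phylo)


# ---------------------------------------------------------------------------
# Named scenarios


def _traits(deciduousness="deciduous", bark="grooved", peeling=False,
            light_guild="heliophyte", thorns=False, needles=False, **extra) -> dict:
    d = {
        "deciduousness": deciduousness, "bark": bark, "peeling": peeling,
        "light_guild": light_guild, "thorns": thorns, "needles": needles,
    }
    d.update(extra)
    return d


def _uniform_patches(species: list[str], patches: list[str]) -> dict:
    return {p: {s: 1.0 for s in species} for p in patches}


def named_scenarios() -> dict[str, ScenarioConfig]:
    """The five shipped scenarios (see module docstring)."""
    five = ["EP", "TP", "PP", "RP", "SF"]

    diverse_pool = {
        "sp_dec_grooved": _traits("deciduous", "grooved"),
        "sp_dec_smooth": _traits("deciduous", "smooth", peeling=True),
        "sp_semi_retic": _traits("semi-deciduous", "reticulated", thorns=True),
        "sp_semi_grooved": _traits("semi-deciduous", "grooved", light_guild="esciophyte"),
        "sp_ever_flaky": _traits("evergreen", "flaky", needles=True),
        "sp_ever_smooth": _traits("evergreen", "smooth", light_guild="esciophyte"),
        "sp_dec_flaky": _traits("deciduous", "flaky", peeling=True, thorns=True),
        "sp_semi_smooth": _traits("semi-deciduous", "smooth"),
    }

    two_level_pool = {
        "sp_dec_a": _traits("deciduous"),
        "sp_dec_b": _traits("deciduous"),
        "sp_semi_a": _traits("semi-deciduous"),
        "sp_semi_b": _traits("semi-deciduous"),
    }

    scenarios = {}

    scenarios["null"] = ScenarioConfig(
        name="null",
        species_pool=diverse_pool,
        patch_species=_uniform_patches(list(diverse_pool), five),
        abundance_rules=[],
        default_mean=5.0,
        allocation_rules=[],
        default_p=0.5,
        trees_per_plot=6,
    )

    scenarios["deciduousness_only"] = ScenarioConfig(
        name="deciduousness_only",
        species_pool=two_level_pool,
        patch_species=_uniform_patches(list(two_level_pool), five),
        abundance_rules=[{"when": {"deciduousness": "deciduous"}, "mean": 400.0}],
        default_mean=3.0,
        allocation_rules=[],
        default_p=0.5,
        trees_per_plot=8,
        # hold size and canopy covariates fixed so deciduousness is the only
        # varying candidate besides DBH
        dbh_range=(10.0, 50.0),
        height_range=(8.0, 8.0),
        lai_range=(1.5, 1.5),
    )

    scenarios["two_stage"] = ScenarioConfig(
        name="two_stage",
        species_pool=two_level_pool,
        patch_species=_uniform_patches(list(two_level_pool), five),
        abundance_rules=[
            {"when": {"deciduousness": "deciduous", "dbh_max": 30.0}, "mean": 400.0},
        ],
        default_mean=3.0,
        allocation_rules=[],
        default_p=0.5,
        trees_per_plot=16,
        dbh_range=(10.0, 50.0),
        height_range=(8.0, 8.0),
        lai_range=(1.5, 1.5),
    )

    tp_pool = {
        "eucalyptus_like": _traits("evergreen", "smooth", peeling=True,
                                   dbh_range=(30.0, 60.0), height_range=(15.0, 25.0)),
        "tabebuia_like": _traits("deciduous", "reticulated",
                                 dbh_range=(8.0, 25.0), height_range=(4.0, 8.0)),
        "pinus_like": _traits("evergreen", "flaky", needles=True,
                              dbh_range=(25.0, 55.0), height_range=(12.0, 22.0)),
        "forest_dec": _traits("deciduous", "grooved", dbh_range=(10.0, 40.0)),
        "forest_semi": _traits("semi-deciduous", "grooved", light_guild="esciophyte",
                               dbh_range=(10.0, 40.0)),
        "forest_ever": _traits("evergreen", "smooth", light_guild="esciophyte",
                               dbh_range=(10.0, 40.0)),
    }
    scenarios["tp_like"] = ScenarioConfig(
        name="tp_like",
        species_pool=tp_pool,
        patch_species={
            "EP": {"eucalyptus_like": 1.0},
            "TP": {"tabebuia_like": 1.0},
            "PP": {"pinus_like": 1.0},
            "RP": {"forest_dec": 1.0, "forest_semi": 2.0, "forest_ever": 1.0},
            "SF": {"forest_dec": 1.0, "forest_semi": 1.0, "forest_ever": 1.0,
                   "tabebuia_like": 0.5},
        },
        abundance_rules=[
            {"when": {"deciduousness": "deciduous", "dbh_max": 30.0}, "mean": 400.0},
            {"when": {"needles": True}, "mean": 30.0},
        ],
        default_mean=2.0,
        allocation_rules=[
            {"when": {"bark": "reticulated"}, "p": 0.04},
            {"when": {"bark": "smooth"}, "p": 0.97},
            {"when": {"needles": True}, "p": 0.9},
        ],
        default_p=0.5,
        trees_per_plot=8,
    )

    scenarios["mixed_forest"] = ScenarioConfig(
        name="mixed_forest",
        species_pool=diverse_pool,
        patch_species=_uniform_patches(list(diverse_pool), five),
        abundance_rules=[{"when": {"deciduousness": "deciduous"}, "mean": 20.0}],
        default_mean=2.0,
        allocation_rules=[
            {"when": {"bark": "reticulated"}, "p": 0.04},
            {"when": {"bark": "smooth"}, "p": 0.9},
        ],
        default_p=0.5,
        trees_per_plot=8,
    )
    return scenarios
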