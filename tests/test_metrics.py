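import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from epihost.data import DEFAULT_TRAIT_KINDS, Phylogeny, TraitTable
from epihost.metrics import (
    Dendrogram,
    UndefinedStatisticError,
    ab_dst,
    branch_incidence,
    faith_pd,
    functional_dendrogram,
    functional_fd,
    gower_dissimilarity,
    phylo_cooccurrence_correlation,
    phylo_structure,
    psd_metrics,
    schoener_matrix,
)
from epihost.simulate import simulate_phylogeny

from conftest import make_dataset, make_trait_table


class TestAbDst:
    @pytest.mark.parametrize("trunk,branch,expected", [(5, 5, 0.5), (0, 7, 0.0), (9, 0, 1.0)])
    def test_closed_form(self, trunk, branch, expected):
        ds = make_dataset([(trunk, branch)])
        assert ab_dst(ds.records()[0]) == pytest.approx(expected)

    def test_undefined_for_non_host(self):
        ds = make_dataset([(0, 0)])
        with pytest.raises(UndefinedStatisticError):
            ab_dst(ds.records()[0])

    def test_trunk_and_branch_shares_sum_to_one(self):
        ds = make_dataset([(3, 11)])
        r = ds.records()[0]
        assert ab_dst(r) + r.a_branch / r.a_total == pytest.approx(1.0)


def _brute_pd(phylo: Phylogeny, subset):
    """Mark every edge on each leaf's root path; sum marked lengths."""
    tree = phylo.tree
    marked = set()
    lengths = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in subset:
            continue
        nd = leaf
        while nd.parent_node is not None:
            marked.add(id(nd))
            lengths[id(nd)] = nd.edge.length or 0.0
            nd = nd.parent_node
    return sum(lengths[i] for i in marked)


class TestFaithPD:
    def test_full_set_equals_total_length(self, five_taxon_phylo):
        assert faith_pd(list("ABCDE"), five_taxon_phylo) == pytest.approx(
            five_taxon_phylo.total_length()
        )

    def test_star_pair(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1):0.0;")
        assert faith_pd(["A", "B"], star) == pytest.approx(2.0)

    def test_random_subsets_match_marked_edge_brute_force(self):
        phylo = simulate_phylogeny(8, "yule", seed=11)
        rng = np.random.default_rng(5)
        labels = phylo.leaf_labels
        inc = branch_incidence(phylo)
        for _ in range(20):
            subset = list(rng.choice(labels, size=4, replace=False))
            assert inc.spanning_length(subset) == pytest.approx(
                _brute_pd(phylo, set(subset)), abs=1e-10
            )

    def test_monotone_under_inclusion(self, five_taxon_phylo):
        inc = branch_incidence(five_taxon_phylo)
        labels = list("ABCDE")
        for k in range(1, 5):
            for subset in itertools.combinations(labels, k):
                for extra in set(labels) - set(subset):
                    assert inc.spanning_length(subset + (extra,)) >= inc.spanning_length(subset)

    def test_unknown_taxon_rejected(self, five_taxon_phylo):
        with pytest.raises(UndefinedStatisticError, match="X"):
            faith_pd(["X"], five_taxon_phylo)


class TestGowerUpgma:
    def test_all_traits_differ_gives_unit_dissimilarity(self):
        df = pd.DataFrame(
            {
                "deciduousness": ["deciduous", "evergreen"],
                "bark": ["smooth", "flaky"],
                "peeling": [True, False],
                "light_guild": ["heliophyte", "esciophyte"],
                "thorns": [False, True],
                "needles": [True, False],
            },
            index=pd.Index(["u", "v"], name="species"),
        )
        tt = TraitTable(df, DEFAULT_TRAIT_KINDS)
        assert gower_dissimilarity(tt).loc["u", "v"] == pytest.approx(1.0)
        dend = functional_dendrogram(tt)
        # a single fusion at dissimilarity 1 -> node height 0.5
        assert dend.merge_heights() == [pytest.approx(0.5)]

    def test_half_mismatch(self):
        kinds = {"a": "binary", "b": "binary", "c": "binary", "d": "binary"}
        df = pd.DataFrame(
            {"a": [True, False], "b": [True, False], "c": [True, True], "d": [False, False]},
            index=pd.Index(["u", "v"], name="species"),
        )
        tt = TraitTable(df, kinds)
        assert gower_dissimilarity(tt).loc["u", "v"] == pytest.approx(0.5)

    def test_identical_species_rejected(self):
        df = pd.DataFrame(
            {"a": [True, True], "b": [False, False]},
            index=pd.Index(["u", "v"], name="species"),
        )
        with pytest.raises(UndefinedStatisticError):
            functional_dendrogram(TraitTable(df, {"a": "binary", "b": "binary"}))

    def test_upgma_matches_scipy_average_linkage(self):
        """Fusion heights equal scipy's average linkage on tie-free data."""
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            rng.normal(size=(6, 3)),
            index=pd.Index([f"s{i}" for i in range(6)], name="species"),
            columns=["q1", "q2", "q3"],
        )
        tt = TraitTable(df, {c: "quantitative" for c in df.columns})
        dend = functional_dendrogram(tt)
        d = gower_dissimilarity(tt)
        iu = np.triu_indices(6, k=1)
        Z = linkage(d.to_numpy()[iu], method="average")
        assert np.allclose(sorted(np.asarray(dend.merge_heights()) * 2), sorted(Z[:, 2]))

    def test_fd_full_set_equals_total_and_monotone(self, five_taxon_traits):
        dend = functional_dendrogram(five_taxon_traits)
        assert functional_fd(list("ABCDE"), dend) == pytest.approx(dend.total_length)
        assert functional_fd(["A", "B"], dend) <= functional_fd(["A", "B", "C"], dend)


class TestPsdMetrics:
    def test_star_phylogeny_maximal(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1):0.0;")
        row = pd.Series([1, 2, 3, 4], index=list("ABCD"))
        m = psd_metrics(row, star)
        assert m["psv"] == pytest.approx(1.0)
        assert m["psc"] == pytest.approx(1.0)
        assert m["psr"] == pytest.approx(4.0)

    def test_two_species_psv_is_one_minus_correlation(self):
        # (A,B) share depth 2 of 3 -> c = 2/3
        phylo = Phylogeny.from_newick("((A:1,B:1):2,C:3);")
        row = pd.Series([1, 1, 0], index=list("ABC"))
        assert psd_metrics(row, phylo)["psv"] == pytest.approx(1 - 2 / 3)

    def test_matches_picante_reference_values(self, five_taxon_phylo):
        """Frozen outputs of the standard R implementation on this fixture."""
        m1 = psd_metrics(pd.Series([1, 1, 2, 3, 5], index=list("ABCDE")), five_taxon_phylo)
        assert m1["psv"] == pytest.approx(0.8, abs=1e-10)
        assert m1["psr"] == pytest.approx(4.0, abs=1e-10)
        assert m1["pse"] == pytest.approx(0.625, abs=1e-10)
        assert m1["psc"] == pytest.approx(0.4, abs=1e-10)
        m2 = psd_metrics(pd.Series([0, 2, 0, 1, 4], index=list("ABCDE")), five_taxon_phylo)
        assert m2["psv"] == pytest.approx(0.777777777778, abs=1e-10)
        assert m2["psr"] == pytest.approx(2.33333333333, abs=1e-9)
        assert m2["pse"] == pytest.approx(0.69387755102, abs=1e-10)
        assert m2["psc"] == pytest.approx(0.555555555556, abs=1e-10)

    def test_pse_individual_expansion_brute_force(self, five_taxon_phylo):
        """PSE numerator equals the explicit individual-level matrix sum."""
        abund = pd.Series([1, 1, 2, 3, 5], index=list("ABCDE"))
        struct = phylo_structure(five_taxon_phylo)
        C = struct.C.to_numpy()
        reps = np.repeat(np.arange(5), abund.to_numpy())
        M = len(reps)  # 12 individuals
        Cind = np.ones((M, M))
        for i in range(M):
            for j in range(M):
                if reps[i] != reps[j]:
                    Cind[i, j] = C[reps[i], reps[j]]
        numer = M * np.trace(Cind) - Cind.sum()
        denom = M * M - M * (M / 5)
        assert psd_metrics(abund, five_taxon_phylo)["pse"] == pytest.approx(
            numer / denom, abs=1e-10
        )

    def test_pse_equals_psv_for_even_abundances(self, five_taxon_phylo):
        row = pd.Series([3, 3, 3, 3, 3], index=list("ABCDE"))
        m = psd_metrics(row, five_taxon_phylo)
        assert m["pse"] == pytest.approx(m["psv"], abs=1e-12)

    def test_bounds(self, five_taxon_phylo):
        rng = np.random.default_rng(9)
        for _ in range(20):
            row = pd.Series(rng.integers(0, 10, 5), index=list("ABCDE"))
            if (row > 0).sum() < 2:
                continue
            m = psd_metrics(row, five_taxon_phylo)
            for k in ("psv", "pse", "psc"):
                assert 0.0 <= m[k] <= 1.0

    def test_single_species_undefined(self, five_taxon_phylo):
        with pytest.raises(UndefinedStatisticError):
            psd_metrics(pd.Series([5, 0, 0, 0, 0], index=list("ABCDE")), five_taxon_phylo)


class TestSchoener:
    def test_closed_form_cases(self):
        comm = pd.DataFrame(
            {"i": [5, 5, 0], "j": [20, 0, 0], "k": [0, 0, 3]},
            index=["p1", "p2", "p3"],
        )
        S = schoener_matrix(comm)
        # p_i=(.5,.5,0) vs p_j=(1,0,0): 1-0.5(0.5+0.5)=0.5; disjoint -> 0
        assert S.loc["i", "j"] == pytest.approx(0.5)
        assert S.loc["i", "k"] == pytest.approx(0.0)
        assert S.loc["i", "i"] == pytest.approx(1.0)

    def test_identical_distributions_give_one(self):
        comm = pd.DataFrame({"i": [2, 4], "j": [3, 6]}, index=["p1", "p2"])
        assert schoener_matrix(comm).loc["i", "j"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        comm = pd.DataFrame(rng.integers(1, 9, (4, 3)), columns=list("xyz"))
        S1 = schoener_matrix(comm)
        comm2 = comm.copy()
        comm2["y"] *= 13
        S2 = schoener_matrix(comm2)
        assert np.allclose(S1.to_numpy(), S2.to_numpy())

    def test_zero_total_species_named(self):
        comm = pd.DataFrame({"x": [1, 2], "dead": [0, 0]})
        with pytest.raises(UndefinedStatisticError, match="dead"):
            schoener_matrix(comm)


class TestCooccurrenceCorrelation:
    def test_constant_index_rejected(self, five_taxon_phylo):
        comm = pd.DataFrame(
            {s: [1, 1] for s in "ABCDE"}, index=["p1", "p2"]
        )
        with pytest.raises(UndefinedStatisticError):
            phylo_cooccurrence_correlation(comm, five_taxon_phylo)

    def test_hand_computed_pearson_and_sign(self, five_taxon_phylo):
        """Close relatives sharing samples exactly gives a negative slope."""
        comm = pd.DataFrame(
            {"A": [9, 0], "B": [8, 0], "D": [0, 7], "E": [0, 6]},
            index=["p1", "p2"],
        )
        struct = phylo_structure(five_taxon_phylo)
        S = schoener_matrix(comm)
        sp = list(comm.columns)
        pairs = list(itertools.combinations(range(4), 2))
        s = [S.iloc[i, j] for i, j in pairs]
        d = [struct.D.loc[sp[i], sp[j]] for i, j in pairs]
        expected = np.corrcoef(s, d)[0, 1]
        got = phylo_cooccurrence_correlation(comm, five_taxon_phylo)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got < 0

    def test_joint_relabeling_invariance(self, five_taxon_phylo):
        rng = np.random.default_rng(3)
        comm = pd.DataFrame(rng.integers(0, 9, (3, 5)) + 1, columns=list("ABCDE"))
        base = phylo_cooccurrence_correlation(comm, five_taxon_phylo)
        perm = ["C", "A", "E", "B", "D"]
        assert phylo_cooccurrence_correlation(comm[perm], five_taxon_phylo) == pytest.approx(base)


class TestPhyloStructure:
    def test_correlation_matrix_properties(self):
        phylo = simulate_phylogeny(10, "yule", seed=4)
        struct = phylo_structure(phylo)
        C = struct.C.to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        off = C[~np.eye(10, dtype=bool)]
        assert off.min() >= 0 and off.max() <= 1
        D = struct.D.to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
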