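import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from epihost.association import (
    assignment_crosstab_tests,
    compact_letter_display,
    diversity_regressions,
    lr_chi2_2x2,
    patch_comparison,
    pattern_pca,
    plot_summaries,
    score_glm,
)
from epihost.metrics import UndefinedStatisticError
from epihost.simulate import named_scenarios, simulate_dataset

from conftest import make_dataset


@pytest.fixture(scope="module")
def tp_like():
    return simulate_dataset(named_scenarios()["tp_like"], seed=11)


def _multi_patch_dataset(counts_by_patch):
    """Concatenate single-patch toy datasets into one multi-patch dataset."""
    import pandas as pd

    from epihost.data import Dataset, Phylogeny

    from conftest import make_trait_table

    frames, trunks, branches, species = [], [], [], []
    for i, (patch, counts) in enumerate(counts_by_patch.items()):
        n = len(counts)
        idx = pd.Index([f"{patch}_t{j}" for j in range(n)], name="tree_id")
        frames.append(pd.DataFrame({
            "patch": patch, "plot": f"{patch}-1", "species": f"sp{i}",
            "dbh": 20.0, "height": 8.0, "lai": 1.0,
        }, index=idx))
        trunks.append(pd.DataFrame({"T_recurvata": [c[0] for c in counts]}, index=idx))
        branches.append(pd.DataFrame({"T_recurvata": [c[1] for c in counts]}, index=idx))
        species.append(f"sp{i}")
    trees = pd.concat(frames)
    newick = "(" + ",".join(f"{s}:1.0" for s in species) + "):0.0;"
    return Dataset(trees, pd.concat(trunks), pd.concat(branches),
                   make_trait_table(species, seed=2), Phylogeny.from_newick(newick))


class TestPatchComparison:
    def test_identical_patches_give_zero_chi2(self):
        ds = _multi_patch_dataset({"P1": [(3, 0)] * 4, "P2": [(3, 0)] * 4})
        overall, _, letters = patch_comparison(ds, "abund")
        assert overall.chi2 == pytest.approx(0.0, abs=1e-8)
        assert letters["P1"] == letters["P2"]

    def test_separated_patches_get_distinct_letters(self):
        ds = _multi_patch_dataset({"P1": [(0, 0)] * 8, "P2": [(10, 0)] * 8})
        overall, _, letters = patch_comparison(ds, "abund")
        assert overall.p < 0.001
        assert letters["P1"] != letters["P2"]

    def test_hyperabundant_patch_alone_in_top_group(self):
        """One patch with mean 400 vs 1/30/2/2 sits alone in its letter group."""
        rng = np.random.default_rng(14)
        counts = {
            p: [(int(c), 0) for c in rng.poisson(mu, 25)]
            for p, mu in zip(["A", "B", "C", "D", "E"], [1, 400, 30, 2, 2])
        }
        ds = _multi_patch_dataset(counts)
        overall, _, letters = patch_comparison(ds, "abund")
        top = letters["B"]
        assert all(set(top).isdisjoint(letters[p]) for p in "ACDE")

    def test_row_order_invariance(self, tp_like):
        overall1, _, _ = patch_comparison(tp_like, "abund")
        shuffled = tp_like
        import copy

        ds2 = copy.copy(shuffled)
        perm = np.random.default_rng(0).permutation(len(tp_like.trees))
        ds2.trees = tp_like.trees.iloc[perm]
        ds2.trunk_counts = tp_like.trunk_counts.iloc[perm]
        ds2.branch_counts = tp_like.branch_counts.iloc[perm]
        overall2, _, _ = patch_comparison(ds2, "abund")
        assert overall1.chi2 == pytest.approx(overall2.chi2, rel=1e-9)

    def test_holm_adjustment_monotone(self, tp_like):
        _, pairwise, _ = patch_comparison(tp_like, "abund")
        ordered = pairwise.sort_values("p_raw")
        assert ordered["p_holm"].is_monotonic_increasing
        assert (pairwise["p_holm"] >= pairwise["p_raw"] - 1e-15).all()


class TestDiversityRegressions:
    def test_exact_linear_relationship(self):
        df = pd.DataFrame({"richness": np.arange(1.0, 9.0)})
        df["ab_abund"] = 2.0 * df["richness"]
        res = diversity_regressions(df, "ab_abund", predictors=("richness",))
        assert res.loc[0, "slope"] == pytest.approx(2.0)
        assert res.loc[0, "p"] < 1e-10

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"richness": np.ones(5), "ab_abund": np.arange(5.0)})
        with pytest.raises(UndefinedStatisticError):
            diversity_regressions(df, "ab_abund", predictors=("richness",))

    def test_null_calibration_p_uniform(self):
        """Independent response: ~5% of F-tests reject at the 5% level."""
        rng = np.random.default_rng(15)
        rejected = 0
        reps = 500
        for _ in range(reps):
            df = pd.DataFrame({"richness": rng.normal(size=12),
                               "ab_abund": rng.normal(size=12)})
            res = diversity_regressions(df, "ab_abund", predictors=("richness",))
            rejected += res.loc[0, "p"] < 0.05
        assert 10 <= rejected <= 45  # binomial 99.9% band around 25/500

    def test_mixed_forest_shows_no_diversity_relationship(self):
        """Trait-driven abundance is unrelated to plot diversity.

        Individual regressions reject at the nominal 5% rate, so the check
        aggregates over seeds: the large majority of richness/PD/FD tests
        must be non-significant and no predictor may be consistently so.
        """
        pvals = []
        for seed in (16, 17, 18, 19, 20):
            ds = simulate_dataset(named_scenarios()["mixed_forest"], seed=seed)
            res = diversity_regressions(plot_summaries(ds), "ab_abund")
            pvals.extend(res["p"].tolist())
        pvals = np.asarray(pvals)
        assert (pvals > 0.05).mean() >= 0.8
        assert pvals.mean() > 0.15


class TestPatternPca:
    def _asg(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"best": rng.random(n) < 0.2, "worst": rng.random(n) < 0.5,
             "trunk": rng.random(n) < 0.4, "branches": rng.random(n) < 0.2},
            index=[f"t{i}" for i in range(n)],
        )

    def test_single_axis_of_variation_explains_everything(self):
        best = np.tile([True, False], 10)
        asg = pd.DataFrame({"best": best, "worst": ~best,
                            "trunk": True, "branches": False})
        pca = pattern_pca(asg)
        assert pca.pct_variance == pytest.approx(100.0)

    def test_best_loading_sign_fixed_negative(self):
        pca = pattern_pca(self._asg())
        assert pca.loadings["best"] <= 0

    def test_variance_share_matches_direct_eigendecomposition(self):
        asg = self._asg(seed=3)
        pca = pattern_pca(asg)
        cov = np.cov(asg.astype(float).to_numpy(), rowvar=False, ddof=1)
        vals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert pca.pct_variance == pytest.approx(100 * vals[0] / vals.sum(), abs=1e-10)

    def test_reconstruction_from_scores_and_loadings(self):
        asg = self._asg(seed=4)
        mat = asg.astype(float)
        centered = (mat - mat.mean(axis=0)).to_numpy()
        cov = np.cov(centered, rowvar=False, ddof=1)
        vals, vecs = np.linalg.eigh(cov)
        scores_full = centered @ vecs
        assert np.allclose(scores_full @ vecs.T, centered, atol=1e-10)

    def test_constant_matrix_rejected(self):
        asg = pd.DataFrame({"best": [True] * 5, "worst": [False] * 5,
                            "trunk": [True] * 5, "branches": [False] * 5})
        with pytest.raises(UndefinedStatisticError):
            pattern_pca(asg)


class TestScoreGlm:
    def test_constant_scores_give_zero_chi2(self, tp_like):
        scores = pd.Series(1.0, index=tp_like.trees.index)
        res = score_glm(tp_like, scores, "abund")
        assert res.chi2 == 0.0

    def test_poisson_slope_recovery(self):
        """log-linear slope 0.8 recovered within ±0.1 at n=500."""
        rng = np.random.default_rng(17)
        n = 500
        scores = pd.Series(rng.normal(size=n), index=[f"t{i}" for i in range(n)])
        y = rng.poisson(np.exp(1.0 + 0.8 * scores.to_numpy()))
        ds = make_dataset([(int(v), 0) for v in y])
        ds.trees.index = scores.index
        ds.trunk_counts.index = scores.index
        ds.branch_counts.index = scores.index
        res = score_glm(ds, scores, "abund")
        assert res.slope == pytest.approx(0.8, abs=0.1)
        assert res.p < 1e-6

    def test_binomial_direction_positive_when_trunk_share_rises(self):
        rng = np.random.default_rng(18)
        n = 300
        scores = pd.Series(np.linspace(-2, 2, n), index=[f"t{i}" for i in range(n)])
        p = 1 / (1 + np.exp(-1.5 * scores.to_numpy()))
        trunk = rng.binomial(20, p)
        ds = make_dataset([(int(t), int(20 - t)) for t in trunk])
        ds.trees.index = scores.index
        ds.trunk_counts.index = scores.index
        ds.branch_counts.index = scores.index
        res = score_glm(ds, scores, "dist")
        assert res.slope > 0
        assert res.p < 1e-6


class TestCrosstabs:
    def test_lr_chi2_matches_hand_formula(self):
        a, b, c, d = 30, 5, 10, 55
        obs = np.array([[a, b], [c, d]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        expected = 2 * np.sum(obs * np.log(obs / exp))
        assert lr_chi2_2x2(a, b, c, d) == pytest.approx(expected, abs=1e-10)

    def test_lr_chi2_matches_statsmodels_binomial_glm(self):
        a, b, c, d = 30, 5, 10, 55
        x = np.repeat([1, 1, 0, 0], [a, b, c, d])
        y = np.repeat([1, 0, 1, 0], [a, b, c, d])
        full = sm.GLM(y, sm.add_constant(x.astype(float)),
                      family=sm.families.Binomial()).fit()
        null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
        assert lr_chi2_2x2(a, b, c, d) == pytest.approx(
            null.deviance - full.deviance, abs=1e-8
        )

    def test_perfect_nesting_maximal_and_positive(self):
        asg = pd.DataFrame({
            "best": [True] * 10 + [False] * 10,
            "branches": [True] * 10 + [False] * 10,
            "worst": [False] * 20,
            "trunk": [True, False] * 10,
        })
        res = assignment_crosstab_tests(asg[["best", "branches"]])
        row = res.iloc[0]
        assert row["direction"] == "likely"
        assert row["p"] < 1e-5

    def test_degenerate_margin_reported_untestable(self):
        asg = pd.DataFrame({"best": [True] * 6, "worst": [False, True] * 3})
        res = assignment_crosstab_tests(asg)
        assert res.iloc[0]["direction"] == "untestable"
        assert np.isnan(res.iloc[0]["chi2"])

    def test_independence_calibration(self):
        """Independent random assignments reject at ~5%."""
        rng = np.random.default_rng(19)
        rejected = 0
        reps = 400
        for _ in range(reps):
            asg = pd.DataFrame({"x": rng.random(200) < 0.4,
                                "y": rng.random(200) < 0.4})
            res = assignment_crosstab_tests(asg)
            rejected += res.iloc[0]["p"] < 0.05
        assert 6 <= rejected <= 40  # wide binomial band around 20/400


class TestCompactLetters:
    def test_all_different_gives_distinct_letters(self):
        pairwise = pd.DataFrame({"a": ["x", "x", "y"], "b": ["y", "z", "z"],
                                 "p_raw": [0.0] * 3, "p_holm": [0.0] * 3})
        means = pd.Series({"x": 3.0, "y": 2.0, "z": 1.0})
        letters = compact_letter_display(["x", "y", "z"], pairwise, means)
        assert len({letters[g] for g in "xyz"}) == 3

    def test_no_differences_gives_one_letter(self):
        pairwise = pd.DataFrame({"a": ["x", "x", "y"], "b": ["y", "z", "z"],
                                 "p_raw": [1.0] * 3, "p_holm": [1.0] * 3})
        means = pd.Series({"x": 3.0, "y": 2.0, "z": 1.0})
        letters = compact_letter_display(["x", "y", "z"], pairwise, means)
        assert letters["x"] == letters["y"] == letters["z"] == "a"
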