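"""Downstream association statistics.

Patch-level GLM comparisons of bromeliad abundance and within-crown
distribution, ordinary least-squares regressions of those responses on
plot diversity (richness, PD, FD), PCA of the host-pattern assignment
matrix, GLMs of the responses on the first component scores, and the
pairwise likelihood-ratio tests between pattern assignments.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import Dataset
from .metrics import UndefinedStatisticError, branch_incidence, functional_dendrogram

__all__ = [
    "GlmTestResult",
    "PcaSummary",
    "patch_comparison",
    "plot_summaries",
    "diversity_regressions",
    "pattern_pca",
    "score_glm",
    "assignment_crosstab_tests",
    "compact_letter_display",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class GlmTestResult:
    """Likelihood-ratio test of a GLM term: χ², df, p, slope, deviance R²."""

    chi2: float
    df: int
    p: float
    slope: float | None = None
    r2: float | None = None


def _response_frame(dataset: Dataset, response: str) -> pd.DataFrame:
    t = dataset.trees
    if response == "abund":
        return t[["patch", "plot", "a_total"]].copy()
    if response == "dist":
        hosts = t[t["a_total"] > 0]
        return hosts[["patch", "plot", "a_trunk", "a_branch"]].copy()
    raise ValueError(f"unknown response {response!r}")


def _glm_fit(df: pd.DataFrame, response: str, exog: pd.DataFrame):
    if response == "abund":
        endog = df["a_total"].to_numpy(dtype=float)
        family = sm.families.Poisson()
    else:
        endog = df[["a_trunk", "a_branch"]].to_numpy(dtype=float)
        family = sm.families.Binomial()
    return sm.GLM(endog, exog, family=family).fit()


def patch_comparison(dataset: Dataset, response: str = "abund"):
    """GLM comparison of a response among vegetation patches.

    Poisson for abundance counts (all trees), binomial on the
    (trunk, branch) count pair for the distribution (hosts only).  Returns
    the overall likelihood-ratio result, the Holm-adjusted pairwise patch
    contrasts, and a compact letter display (patches sharing a letter are
    statistically indistinguishable).
    """
    df = _response_frame(dataset, response)
    if response == "dist":
        counts = df.groupby("patch").size()
        empty = sorted(set(dataset.trees["patch"]) - set(counts.index))
        if empty:
            log.info("patches without hosts dropped from distribution comparison: %s", empty)
    patches = list(dict.fromkeys(df["patch"]))
    if len(patches) < 2:
        raise ValueError("need >= 2 patches")
    X_full = pd.get_dummies(df["patch"], drop_first=True, dtype=float)
    X_full = sm.add_constant(X_full)
    full = _glm_fit(df, response, X_full)
    null = _glm_fit(df, response, np.ones((len(df), 1)))
    chi2 = float(null.deviance - full.deviance)
    dfree = len(patches) - 1
    overall = GlmTestResult(
        chi2=chi2, df=dfree, p=float(stats.chi2.sf(chi2, dfree)),
        r2=float(1 - full.deviance / null.deviance) if null.deviance > 0 else np.nan,
    )

    pairs = list(itertools.combinations(patches, 2))
    raw = []
    for a, b in pairs:
        sub = df[df["patch"].isin((a, b))]
        Xp = sm.add_constant((sub["patch"] == b).to_numpy(dtype=float))
        try:
            f = _glm_fit(sub, response, Xp)
            n0 = _glm_fit(sub, response, np.ones((len(sub), 1)))
            c2 = max(float(n0.deviance - f.deviance), 0.0)
            raw.append(float(stats.chi2.sf(c2, 1)))
        except Exception:  # perfectly separated pair: maximally different
            raw.append(0.0)
    adj = multipletests(raw, method="holm")[1] if raw else []
    pairwise = pd.DataFrame(
        {"a": [p[0] for p in pairs], "b": [p[1] for p in pairs],
         "p_raw": raw, "p_holm": adj}
    )
    means = df.groupby("patch", sort=False).apply(
        lambda g: g["a_total"].mean() if response == "abund"
        else g["a_trunk"].sum() / (g["a_trunk"].sum() + g["a_branch"].sum()),
        include_groups=False,
    )
    letters = compact_letter_display(patches, pairwise, means)
    return overall, pairwise, letters


def compact_letter_display(
    groups: list[str], pairwise: pd.DataFrame, means: pd.Series, alpha: float = 0.05
) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise p-values."""
    order = list(means.sort_values(ascending=False).index)
    differ = {
        frozenset((r.a, r.b)) for r in pairwise.itertuples() if r.p_holm < alpha
    }
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in differ for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for s, ch in zip(letter_sets, alphabet):
        for g in s:
            out[g] += ch
    return {g: "".join(sorted(v)) for g, v in out.items()}


# ---------------------------------------------------------------------------
# Diversity regressions


def plot_summaries(dataset: Dataset) -> pd.DataFrame:
    """Per-plot response and diversity summary.

    ``ab_abund`` is the plot's total bromeliad count, ``ab_dst`` the pooled
    trunk share over its hosts; richness/PD/FD describe all trees of the
    plot (hosts and non-hosts).
    """
    inc = branch_incidence(dataset.phylogeny)
    dend = functional_dendrogram(dataset.traits)
    rows = []
    for (patch, plot), grp in dataset.trees.groupby(["patch", "plot"], sort=False):
        sp = sorted(set(grp["species"]))
        trunk = grp["a_trunk"].sum()
        total = grp["a_total"].sum()
        rows.append({
            "patch": patch,
            "plot": plot,
            "ab_abund": int(total),
            "ab_dst": trunk / total if total > 0 else np.nan,
            "richness": len(sp),
            "pd": inc.spanning_length(sp),
            "fd": dend.incidence.spanning_length(sp),
        })
    return pd.DataFrame(rows)


def diversity_regressions(
    summaries: pd.DataFrame,
    response: str = "ab_abund",
    predictors: tuple[str, ...] = ("richness", "pd", "fd"),
) -> pd.DataFrame:
    """Simple OLS of a response on each diversity predictor, F-tested."""
    data = summaries.dropna(subset=[response])
    if len(data) < 3:
        raise UndefinedStatisticError("need >= 3 plots")
    rows = []
    y = data[response].to_numpy(dtype=float)
    for pred in predictors:
        x = data[pred].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise UndefinedStatisticError(f"constant predictor {pred!r}")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append({
            "predictor": pred,
            "slope": float(model.params[1]),
            "F": float(model.fvalue),
            "p": float(model.f_pvalue),
            "r2": float(model.rsquared),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pattern PCA and GLMs


@dataclasses.dataclass
class PcaSummary:
    """First principal component of the 0/1 pattern-assignment matrix."""

    loadings: pd.Series
    scores: pd.Series
    pct_variance: float
    eigenvalues: np.ndarray


def pattern_pca(assignment: pd.DataFrame, subset: str = "all",
                hosts: pd.Index | None = None) -> PcaSummary:
    """Centered (covariance) PCA of the boolean assignment matrix.

    The sign is fixed so the 'best' loading is negative.  ``subset='hosts'``
    restricts rows to the given host index.
    """
    mat = assignment.astype(float)
    if subset == "hosts":
        if hosts is None:
            raise ValueError("subset='hosts' needs the host index")
        mat = mat.loc[mat.index.intersection(hosts)]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if len(mat.drop_duplicates()) < 2:
        raise UndefinedStatisticError("assignment matrix has no variation")
    centered = mat - mat.mean(axis=0)
    cov = np.cov(centered.to_numpy(), rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    v1 = vecs[:, 0]
    if v1[list(mat.columns).index("best")] > 0:
        v1 = -v1
    scores = centered.to_numpy() @ v1
    return PcaSummary(
        loadings=pd.Series(v1, index=mat.columns),
        scores=pd.Series(scores, index=mat.index),
        pct_variance=float(100.0 * vals[0] / vals.sum()),
        eigenvalues=vals,
    )


def score_glm(dataset: Dataset, scores: pd.Series, response: str = "abund") -> GlmTestResult:
    """GLM of a survey response on PC1 scores (LR χ², slope, deviance R²)."""
    df = _response_frame(dataset, response)
    df = df.loc[df.index.intersection(scores.index)]
    x = scores.loc[df.index].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return GlmTestResult(chi2=0.0, df=1, p=1.0, slope=0.0, r2=0.0)
    X = sm.add_constant(x)
    full = _glm_fit(df, response, X)
    null = _glm_fit(df, response, np.ones((len(df), 1)))
    chi2 = max(float(null.deviance - full.deviance), 0.0)
    return GlmTestResult(
        chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)),
        slope=float(full.params[1]),
        r2=float(1 - full.deviance / null.deviance) if null.deviance > 0 else np.nan,
    )


# ---------------------------------------------------------------------------
# Pattern cross-tabulations


def lr_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Likelihood-ratio χ² of a 2×2 table ((a, b), (c, d)): 2 Σ O ln(O/E)."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * terms.sum())


def assignment_crosstab_tests(assignment: pd.DataFrame) -> pd.DataFrame:
    """Pairwise association between host-pattern assignments.

    For each unordered pattern pair a 2×2 likelihood-ratio χ² with one
    degree of freedom; the direction (likely / unlikely to co-occur) is the
    sign of the log odds ratio.  Pairs with a degenerate margin are
    reported untestable (NaN statistics) rather than raised.
    """
    cols = list(assignment.columns)
    rows = []
    for x, yv in itertools.combinations(cols, 2):
        xs = assignment[x].astype(bool)
        ys = assignment[yv].astype(bool)
        a = int((xs & ys).sum())
        b = int((xs & ~ys).sum())
        c = int((~xs & ys).sum())
        d = int((~xs & ~ys).sum())
        if min(a + b, c + d, a + c, b + d) == 0:
            rows.append({"x": x, "y": yv, "chi2": np.nan, "df": 1, "p": np.nan,
                         "direction": "untestable"})
            continue
        chi2 = lr_chi2_2x2(a, b, c, d)
        log_or = np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
        rows.append({
            "x": x, "y": yv, "chi2": chi2, "df": 1,
            "p": float(stats.chi2.sf(chi2, 1)),
            "direction": "likely" if log_or > 0 else "unlikely",
        })
    return pd.DataFrame(rows)
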