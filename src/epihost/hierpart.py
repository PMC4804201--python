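"""Hierarchical partitioning of GLM goodness of fit.

For k predictors the 2^k possible models are fitted and each predictor's
*independent contribution* I_x is the average, over all k! orderings of
entry, of the increase in goodness of fit when x enters — computed by
level-averaging over the 2^(k-1) subsets not containing x, weighted by
s!(k-1-s)!/k!.  The contributions sum exactly to the full-model fit.
Goodness of fit is R² for gaussian responses and deviance explained
(1 − D_model/D_null) for poisson and binomial responses.  Significance
comes from a randomisation test: the response is permuted, the partition
recomputed, and each predictor scored z = (I_obs − mean I_null)/sd I_null
with the one-tailed 95% criterion z ≥ 1.65.

A categorical predictor enters and leaves model subsets as a whole dummy
block — one trait is one explanatory unit.

All model fits run through a small batched IRLS so that the thousands of
(subset × permutation) fits of the randomisation test stay fast; tests
cross-check single fits against statsmodels.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "PartitionResult",
    "HierarchicalPartitioner",
    "goodness_of_fit",
    "partition",
    "randomization_test",
    "build_blocks",
    "Z_CRITICAL",
    "MAX_PREDICTORS",
]

log = logging.getLogger(__name__)

Z_CRITICAL = 1.65  # upper one-tailed 95% criterion
MAX_PREDICTORS = 12

FAMILIES = ("gaussian", "poisson", "binomial")


class FitError(RuntimeError):
    """A GLM fit failed; carries the offending predictor subset."""

    def __init__(self, subset, msg):
        super().__init__(f"fit failed for subset {sorted(subset)}: {msg}")
        self.subset = subset


# ---------------------------------------------------------------------------
# Design construction


def infer_kinds(X: pd.DataFrame) -> dict[str, str]:
    kinds = {}
    for c in X.columns:
        s = X[c]
        if s.dtype == bool:
            kinds[c] = "binary"
        elif s.dtype.kind in "ifu":
            kinds[c] = "quantitative"
        else:
            kinds[c] = "categorical"
    return kinds


def build_blocks(X: pd.DataFrame, kinds: dict[str, str] | None = None):
    """Dummy-code each predictor into a column block.

    Categorical: one indicator per non-reference level, reference = first
    appearance.  Binary: one 0/1 column.  Quantitative: the column itself.
    """
    if kinds is None:
        kinds = infer_kinds(X)
    blocks: dict[str, np.ndarray] = {}
    for name in X.columns:
        kind = kinds.get(name, "quantitative")
        col = X[name]
        if kind == "quantitative":
            blocks[name] = col.to_numpy(dtype=float).reshape(-1, 1)
        elif kind == "binary":
            blocks[name] = col.astype(bool).to_numpy(dtype=float).reshape(-1, 1)
        else:
            levels = list(dict.fromkeys(col.astype(str)))
            cols = [(col.astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]]
            blocks[name] = (
                np.column_stack(cols) if cols else np.zeros((len(col), 0))
            )
    return blocks


# ---------------------------------------------------------------------------
# Batched GLM deviance


def _solve_batched(XtWX: np.ndarray, XtWz: np.ndarray) -> np.ndarray:
    # tiny ridge guards exact collinearity without moving well-posed fits
    p = XtWX.shape[-1]
    ridge = 1e-10 * np.trace(XtWX, axis1=-2, axis2=-1)[..., None, None] / p
    A = XtWX + ridge * np.eye(p)
    return np.linalg.solve(A, XtWz[..., None])[..., 0]


def _gaussian_fit(Xd: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """R² for each column of Y given design Xd (with intercept)."""
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    resid = Y - Xd @ beta
    rss = (resid**2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    return np.clip(r2, 0.0, 1.0)


def _poisson_deviance(Y: np.ndarray, Mu: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(Y > 0, Y * np.log(Y / Mu), 0.0)
    return 2.0 * (term - (Y - Mu)).sum(axis=0)


def _poisson_fit(Xd: np.ndarray, Y: np.ndarray, max_iter=60, tol=1e-10) -> np.ndarray:
    """Deviance explained for Poisson log-link fits, batched over Y columns."""
    n, B = Y.shape
    ybar = Y.mean(axis=0)
    null_dev = _poisson_deviance(Y, np.broadcast_to(ybar, Y.shape))
    Mu = np.maximum(Y, 0.0) + 0.5
    Eta = np.log(Mu)
    dev = _poisson_deviance(Y, Mu)
    for _ in range(max_iter):
        W = Mu
        Z = Eta + (Y - Mu) / Mu
        XtWX = np.einsum("np,nb,nq->bpq", Xd, W, Xd, optimize=True)
        XtWz = np.einsum("np,nb->bp", Xd, W * Z, optimize=True)
        Beta = _solve_batched(XtWX, XtWz)
        Eta = np.clip(Xd @ Beta.T, -30.0, 30.0)
        Mu = np.exp(Eta)
        new_dev = _poisson_deviance(Y, Mu)
        if np.all(np.abs(new_dev - dev) <= tol * (np.abs(dev) + 1.0)):
            dev = new_dev
            break
        dev = new_dev
    with np.errstate(divide="ignore", invalid="ignore"):
        expl = np.where(null_dev > 0, 1.0 - dev / null_dev, 0.0)
    return np.clip(expl, 0.0, 1.0)


def _binomial_deviance(S: np.ndarray, T: np.ndarray, P: np.ndarray) -> np.ndarray:
    F = T - S
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(S > 0, S * np.log(S / (T * P)), 0.0)
        b = np.where(F > 0, F * np.log(F / (T * (1.0 - P))), 0.0)
    return 2.0 * (a + b).sum(axis=0)


def _binomial_fit(Xd, S, T, max_iter=80, tol=1e-10) -> np.ndarray:
    """Deviance explained for binomial (successes, trials) logit fits."""
    pbar = S.sum(axis=0) / T.sum(axis=0)
    null_dev = _binomial_deviance(S, T, np.broadcast_to(pbar, S.shape))
    P = (S + 0.5) / (T + 1.0)
    Eta = np.log(P / (1.0 - P))
    dev = _binomial_deviance(S, T, P)
    for _ in range(max_iter):
        W = np.maximum(T * P * (1.0 - P), 1e-10)
        Z = Eta + (S - T * P) / W
        XtWX = np.einsum("np,nb,nq->bpq", Xd, W, Xd, optimize=True)
        XtWz = np.einsum("np,nb->bp", Xd, W * Z, optimize=True)
        Beta = _solve_batched(XtWX, XtWz)
        Eta = np.clip(Xd @ Beta.T, -30.0, 30.0)
        P = 1.0 / (1.0 + np.exp(-Eta))
        new_dev = _binomial_deviance(S, T, P)
        if np.all(np.abs(new_dev - dev) <= tol * (np.abs(dev) + 1.0)):
            dev = new_dev
            break
        dev = new_dev
    with np.errstate(divide="ignore", invalid="ignore"):
        expl = np.where(null_dev > 0, 1.0 - dev / null_dev, 0.0)
    return np.clip(expl, 0.0, 1.0)


def _fit_subset(cols: np.ndarray | None, y, family: str, n: int) -> np.ndarray:
    """Goodness of fit for one predictor subset, batched over response columns.

    ``y`` is (n, B) for gaussian/poisson, or a pair (S, T) of (n, B) arrays
    for binomial.  The empty subset fits the intercept-only model, which
    has goodness of fit 0 by definition.
    """
    intercept = np.ones((n, 1))
    Xd = intercept if cols is None or cols.shape[1] == 0 else np.hstack([intercept, cols])
    if family == "gaussian":
        r = _gaussian_fit(Xd, y)
    elif family == "poisson":
        r = _poisson_fit(Xd, y)
    elif family == "binomial":
        r = _binomial_fit(Xd, y[0], y[1])
    else:
        raise ValueError(f"unknown family {family!r}")
    if not np.all(np.isfinite(r)):
        raise FitError((), "non-finite goodness of fit")
    return r


# ---------------------------------------------------------------------------
# Public fit values


def _prepare_response(y, family: str):
    if family == "binomial":
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("binomial response must be an (n, 2) array of (successes, failures)")
        S = arr[:, :1]
        T = arr.sum(axis=1, keepdims=True)
        if np.any(T <= 0):
            raise ValueError("binomial trials must be positive")
        return (S, T)
    arr = np.asarray(y, dtype=float).reshape(-1, 1)
    return arr


def goodness_of_fit(y, X: pd.DataFrame, family: str = "gaussian",
                    kinds: dict[str, str] | None = None) -> float:
    """R² (gaussian) or deviance explained (poisson/binomial) of y ~ X.

    An empty predictor set returns 0 by definition.
    """
    yp = _prepare_response(y, family)
    n = yp[0].shape[0] if family == "binomial" else yp.shape[0]
    if X is None or X.shape[1] == 0:
        return 0.0
    blocks = build_blocks(X, kinds)
    cols = np.hstack(list(blocks.values()))
    return float(_fit_subset(cols, yp, family, n)[0])


def _ordering_weights(k: int) -> dict[int, float]:
    return {s: math.factorial(s) * math.factorial(k - 1 - s) / math.factorial(k) for s in range(k)}


@dataclasses.dataclass
class PartitionResult:
    """Independent/joint contributions of each predictor.

    ``independent`` are the I_x (goodness-of-fit units), ``joint`` the
    J_x = R({x}) − I_x, ``pct`` the I_x as a percentage of their sum.
    ``z``/``sig`` are filled by the randomisation test.
    """

    predictors: list[str]
    family: str
    r_full: float
    independent: pd.Series
    joint: pd.Series
    pct: pd.Series
    z: pd.Series | None = None
    sig: pd.Series | None = None
    n_rand: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"I": self.independent, "J": self.joint, "pct": self.pct})
        if self.z is not None:
            out["z"] = self.z
            out["sig"] = self.sig
        return out


class HierarchicalPartitioner(BaseEstimator):
    """Sklearn-style estimator for hierarchical partitioning.

    Parameters
    ----------
    family : {'gaussian', 'poisson', 'binomial'}
        Response distribution.  Binomial expects ``y`` as an (n, 2) array
        of (successes, failures) counts.
    n_rand : int
        Number of response permutations for the randomisation z-test;
        0 skips the test.
    random_state : int or numpy Generator, optional
        Seed for the permutations.
    kinds : dict, optional
        Predictor kinds ('categorical'/'binary'/'quantitative'); inferred
        from dtypes when omitted.

    Attributes (after ``fit``)
    --------------------------
    predictors_, r_full_, independent_, joint_, pct_, z_, sig_, result_
    """

    def __init__(self, family: str = "gaussian", n_rand: int = 0,
                 random_state=None, kinds: dict[str, str] | None = None):
        self.family = family
        self.n_rand = n_rand
        self.random_state = random_state
        self.kinds = kinds

    # -- internals ----------------------------------------------------------
    def _all_subset_fits(self, blocks, yp, n):
        names = list(blocks)
        k = len(names)
        fits: dict[frozenset, np.ndarray] = {}
        for r in range(k + 1):
            for combo in combinations(names, r):
                key = frozenset(combo)
                cols = (
                    np.hstack([blocks[c] for c in combo]) if combo else None
                )
                try:
                    fits[key] = _fit_subset(cols, yp, self.family, n)
                except FitError as err:
                    raise FitError(key, str(err)) from err
        return fits

    @staticmethod
    def _independent(fits, names) -> dict[str, np.ndarray]:
        k = len(names)
        w = _ordering_weights(k)
        out = {}
        for x in names:
            rest = [c for c in names if c != x]
            acc = 0.0
            for r in range(k):
                for combo in combinations(rest, r):
                    key = frozenset(combo)
                    acc = acc + w[r] * (fits[key | {x}] - fits[key])
            out[x] = acc
        return out

    # -- API ----------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        names = list(X.columns)
        k = len(names)
        if k < 1:
            raise ValueError("need at least one predictor")
        if k > MAX_PREDICTORS:
            raise ValueError(
                f"{k} predictors would need 2^{k} model fits; reduce to <= {MAX_PREDICTORS}"
            )
        yp = _prepare_response(y, self.family)
        n = yp[0].shape[0] if self.family == "binomial" else yp.shape[0]
        blocks = build_blocks(X, self.kinds)

        fits = self._all_subset_fits(blocks, yp, n)
        indep = {x: float(v[0]) for x, v in self._independent(fits, names).items()}
        r_full = float(fits[frozenset(names)][0])
        total_i = sum(indep.values())
        self.predictors_ = names
        self.r_full_ = r_full
        self.independent_ = pd.Series(indep, index=names, name="I")
        self.joint_ = pd.Series(
            {x: float(fits[frozenset([x])][0]) - indep[x] for x in names}, index=names, name="J"
        )
        self.pct_ = pd.Series(
            {x: 100.0 * indep[x] / total_i if total_i > 0 else np.nan for x in names},
            index=names, name="pct",
        )

        self.z_ = None
        self.sig_ = None
        self.perm_p_ = None
        self.null_independent_ = None
        if self.n_rand:
            if self.n_rand < 99:
                raise ValueError("n_rand must be >= 99 for a meaningful z-test")
            rng = (
                self.random_state
                if isinstance(self.random_state, np.random.Generator)
                else np.random.default_rng(self.random_state)
            )
            if self.family == "binomial":
                S, T = yp
                perm_rows = np.stack([rng.permutation(n) for _ in range(self.n_rand)], axis=1)
                Sp = S[:, 0][perm_rows]
                Tp = T[:, 0][perm_rows]
                ypb = (Sp, Tp)
            else:
                perm_rows = np.stack([rng.permutation(n) for _ in range(self.n_rand)], axis=1)
                ypb = yp[:, 0][perm_rows]
            fits_null = {}
            for key in fits:
                cols = np.hstack([blocks[c] for c in sorted(key)]) if key else None
                fits_null[key] = _fit_subset(cols, ypb, self.family, n)
            indep_null = self._independent(fits_null, names)
            z = {}
            sig = {}
            perm_p = {}
            for x in names:
                draws = indep_null[x]
                perm_p[x] = (1.0 + float(np.sum(draws >= indep[x]))) / (self.n_rand + 1.0)
                sd = float(np.std(draws, ddof=1))
                # sd at float-noise level means the predictor explains
                # nothing under any permutation (e.g. a constant trait)
                if sd <= 1e-12:
                    log.warning("null sd of I is 0 for predictor %r; z undefined", x)
                    z[x] = np.nan
                    sig[x] = False
                else:
                    z[x] = (indep[x] - float(np.mean(draws))) / sd
                    sig[x] = bool(z[x] >= Z_CRITICAL)
            self.z_ = pd.Series(z, index=names, name="z")
            self.sig_ = pd.Series(sig, index=names, name="sig")
            self.perm_p_ = pd.Series(perm_p, index=names, name="perm_p")
            self.null_independent_ = {x: indep_null[x] for x in names}

        self.result_ = PartitionResult(
            predictors=names,
            family=self.family,
            r_full=r_full,
            independent=self.independent_,
            joint=self.joint_,
            pct=self.pct_,
            z=self.z_,
            sig=self.sig_,
            n_rand=self.n_rand,
        )
        return self


def partition(y, X: pd.DataFrame, family: str = "gaussian",
              kinds: dict[str, str] | None = None) -> PartitionResult:
    """Independent and joint contributions without the randomisation test."""
    est = HierarchicalPartitioner(family=family, kinds=kinds).fit(X, y)
    return est.result_


def randomization_test(y, X: pd.DataFrame, family: str = "gaussian",
                       n_rand: int = 1000, seed=None,
                       kinds: dict[str, str] | None = None) -> PartitionResult:
    """Partition plus permutation z-scores (sig at z ≥ 1.65, one-tailed)."""
    est = HierarchicalPartitioner(
        family=family, n_rand=n_rand, random_state=seed, kinds=kinds
    ).fit(X, y)
    return est.result_


def brute_force_independent(y, X: pd.DataFrame, family: str = "gaussian",
                            kinds: dict[str, str] | None = None) -> pd.Series:
    """All-orderings enumeration of I_x (oracle; use only for small k)."""
    names = list(X.columns)
    k = len(names)
    yp = _prepare_response(y, family)
    n = yp[0].shape[0] if family == "binomial" else yp.shape[0]
    blocks = build_blocks(X, kinds)
    cache: dict[frozenset, float] = {}

    def fit_of(sub: frozenset) -> float:
        if sub not in cache:
            cols = np.hstack([blocks[c] for c in sorted(sub)]) if sub else None
            cache[sub] = float(_fit_subset(cols, yp, family, n)[0])
        return cache[sub]

    acc = {x: 0.0 for x in names}
    count = 0
    for order in permutations(names):
        sofar: frozenset = frozenset()
        for x in order:
            acc[x] += fit_of(sofar | {x}) - fit_of(sofar)
            sofar = sofar | {x}
        count += 1
    return pd.Series({x: acc[x] / count for x in names}, index=names)
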