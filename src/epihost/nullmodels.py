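"""Randomisation null models for host-tree community structure.

Three procedures, each returning observed statistics with empirical
95% envelopes:

* individual randomisation — every bromeliad individual of a vegetation
  patch is re-assigned independently and uniformly to one of the patch's
  trees; host richness, Faith's PD and functional diversity of the
  receiving species are recomputed per replicate,
* tip shuffling — phylogeny leaf labels are permuted and the correlation
  between Schoener co-occurrence and phylogenetic distance recomputed,
* frequency-preserving abundance shuffling — abundances are permuted
  within species columns (conserving each species' total and number of
  occupied samples) and the PSV/PSR/PSE/PSC metrics recomputed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .data import Dataset, DatasetError
from .metrics import (
    PhyloStructure,
    branch_incidence,
    functional_dendrogram,
    phylo_structure,
    psd_metrics,
    schoener_matrix,
)

__all__ = [
    "NullEnvelope",
    "randomize_individuals_null",
    "tip_shuffle_test",
    "frequency_preserving_shuffle",
    "psd_null_test",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class NullEnvelope:
    """An observed statistic against its randomisation distribution.

    Quantiles are the empirical 2.5% / 97.5% points (type-7 linear
    interpolation, numpy's default).  The verdict places the observed
    value below, within, or above the envelope.
    """

    observed: float
    null_draws: np.ndarray
    q_low: float = dataclasses.field(init=False)
    q_high: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        draws = np.asarray(self.null_draws, dtype=float)
        self.null_draws = draws
        self.q_low = float(np.quantile(draws, 0.025))
        self.q_high = float(np.quantile(draws, 0.975))

    @property
    def verdict(self) -> str:
        if self.observed < self.q_low:
            return "below"
        if self.observed > self.q_high:
            return "above"
        return "within"


def _check_reps(n: int, what: str) -> None:
    if n < 1:
        raise DatasetError(f"{what} must be positive")
    if n < 100:
        log.warning("%s=%d is low; envelope quantiles will be noisy", what, n)


def randomize_individuals_null(
    dataset: Dataset,
    patch: str,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> dict[str, NullEnvelope]:
    """Uniform re-assignment of all of a patch's bromeliad individuals.

    Each replicate throws the patch's total number of individuals
    independently and uniformly over its individual trees and recomputes
    host-species richness, PD and FD of the species receiving at least one
    individual.  The total individual count is conserved by construction.
    """
    _check_reps(n_reps, "n_reps")
    trees = dataset.trees[dataset.trees["patch"] == patch]
    if len(trees) < 2:
        raise DatasetError(f"patch {patch!r} needs >= 2 trees")
    n_ind = int(trees["a_total"].sum())
    if n_ind == 0:
        raise DatasetError(f"patch {patch!r} has no bromeliad individuals")

    inc = branch_incidence(dataset.phylogeny)
    dend = functional_dendrogram(dataset.traits)
    species = sorted(set(trees["species"]))
    obs_hosts = sorted(set(trees.loc[trees["a_total"] > 0, "species"]))
    observed = {
        "richness": float(len(obs_hosts)),
        "pd": inc.spanning_length(obs_hosts),
        "fd": dend.incidence.spanning_length(obs_hosts),
    }

    rng = np.random.default_rng(seed)
    n_trees = len(trees)
    draws = rng.multinomial(n_ind, np.full(n_trees, 1.0 / n_trees), size=n_reps)
    # tree -> species indicator, then species presence per replicate
    sp_pos = {s: i for i, s in enumerate(species)}
    indicator = np.zeros((n_trees, len(species)))
    for j, s in enumerate(trees["species"]):
        indicator[j, sp_pos[s]] = 1.0
    presence = (draws @ indicator) > 0  # (n_reps, n_species)

    order_pd = [inc.species.index(s) for s in species]
    order_fd = [dend.incidence.species.index(s) for s in species]
    pres_pd = np.zeros((n_reps, len(inc.species)), dtype=bool)
    pres_pd[:, order_pd] = presence
    pres_fd = np.zeros((n_reps, len(dend.incidence.species)), dtype=bool)
    pres_fd[:, order_fd] = presence

    null = {
        "richness": presence.sum(axis=1).astype(float),
        "pd": inc.spanning_length_many(pres_pd),
        "fd": dend.incidence.spanning_length_many(pres_fd),
    }
    return {k: NullEnvelope(observed[k], null[k]) for k in observed}


def tip_shuffle_test(
    comm: pd.DataFrame,
    phylo,
    n_runs: int = 1000,
    seed: int | None = None,
) -> NullEnvelope:
    """Label-shuffling null for the co-occurrence / distance correlation.

    Leaf labels are permuted uniformly at random; the Schoener matrix is
    label-independent, so each run only re-indexes the phylogenetic
    distance matrix.
    """
    _check_reps(n_runs, "n_runs")
    struct = phylo if isinstance(phylo, PhyloStructure) else phylo_structure(phylo)
    sp = list(comm.columns)
    if len(sp) < 3:
        raise DatasetError("need >= 3 species")
    S = schoener_matrix(comm)
    all_sp = struct.species
    pos = [all_sp.index(s) for s in sp]
    Dfull = struct.D.to_numpy()
    iu = np.triu_indices(len(sp), k=1)
    s_vec = S.to_numpy()[iu]
    if np.ptp(s_vec) == 0:
        raise DatasetError("zero variance in co-occurrence index")

    def corr_for(index: np.ndarray) -> float:
        d = Dfull[np.ix_(index, index)][iu]
        if np.ptp(d) == 0:
            return np.nan
        return float(np.corrcoef(s_vec, d)[0, 1])

    pos = np.asarray(pos)
    observed = corr_for(pos)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_runs)
    for r in range(n_runs):
        sigma = rng.permutation(len(all_sp))
        draws[r] = corr_for(sigma[pos])
    return NullEnvelope(observed, draws)


def frequency_preserving_shuffle(
    comm: pd.DataFrame,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permute abundances within each species column across samples.

    Column sums and occurrence counts (number of nonzero cells per
    species) are preserved exactly.
    """
    if comm.size == 0:
        raise DatasetError("empty community matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = comm.to_numpy().copy()
    for j in range(arr.shape[1]):
        arr[:, j] = arr[rng.permutation(arr.shape[0]), j]
    return pd.DataFrame(arr, index=comm.index, columns=comm.columns)


_PSD_VERDICT = {"below": "Underdispersed", "within": "Random", "above": "Overdispersed"}


def psd_null_test(
    comm: pd.DataFrame,
    phylo,
    row: str,
    n_reps: int = 1000,
    seed: int | None = None,
) -> dict[str, NullEnvelope]:
    """Frequency-preserving null for PSV/PSR/PSE/PSC of one sample row.

    Each replicate shuffles abundances within species columns across the
    matrix rows and recomputes the four metrics on the focal row.  Use
    :func:`psd_verdict_label` for the dispersion wording of a verdict.
    """
    _check_reps(n_reps, "n_reps")
    struct = phylo if isinstance(phylo, PhyloStructure) else phylo_structure(phylo)
    observed = psd_metrics(comm.loc[row], struct)
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {k: [] for k in observed}
    for _ in range(n_reps):
        shuffled = frequency_preserving_shuffle(comm, rng)
        try:
            vals = psd_metrics(shuffled.loc[row], struct)
        except Exception:
            vals = {k: np.nan for k in observed}
        for k, v in vals.items():
            draws[k].append(v)
    return {k: NullEnvelope(observed[k], np.asarray(draws[k])) for k in observed}


def psd_verdict_label(envelope: NullEnvelope) -> str:
    """Dispersion wording for a PSV-family envelope verdict."""
    return _PSD_VERDICT[envelope.verdict]
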