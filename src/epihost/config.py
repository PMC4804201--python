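"""Run configuration and pipeline orchestration.

A YAML run config points at the survey inputs, toggles stages, sets
replication counts and pattern thresholds, and fixes one global seed.
The seed is expanded into independent per-stage streams so that turning
a stage off never changes another stage's draws.  Every run writes a
manifest listing its artifacts with SHA-256 checksums; a rerun with the
same config and seed reproduces all stochastic outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import association, metrics, nullmodels, traittree
from .data import Dataset, community_from_records, read_dataset
from .hierpart import randomization_test
from .traittree import PatternThresholds

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

STAGES = ("metrics", "nullmodels", "hierpart", "traittree", "patterns", "association")


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    trees: str
    traits: str
    phylogeny: str
    out_dir: str
    dataset_config: str | None = None
    stages: tuple[str, ...] = STAGES
    n_reps: int = 10_000
    n_runs: int = 1000
    n_rand: int = 1000
    min_node: int = 10
    alpha: float = 0.05
    thresholds: PatternThresholds = dataclasses.field(default_factory=PatternThresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "stages"},
                  stages=tuple(raw.get("stages", STAGES)))
        if thr:
            cfg.thresholds = PatternThresholds(**thr)
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        for path, what in ((self.trees, "trees"), (self.traits, "traits"),
                           (self.phylogeny, "phylogeny")):
            if not os.path.exists(path):
                raise PipelineError(f"{what} input not found: {path}")

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[idx]
        return int(child.generate_state(1)[0] % (2**31))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, out_dir: str, name: str, seed: int,
               manifest: dict, index=False) -> str:
    path = os.path.join(out_dir, name)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=index)
    manifest[name] = _sha256(path)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages in dependency order; return the manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    dataset = read_dataset(config.trees, config.traits, config.phylogeny,
                           config.dataset_config)
    manifest: dict[str, str] = {}
    status = "ok"
    try:
        if "metrics" in config.stages:
            _stage_metrics(dataset, config, manifest)
        if "nullmodels" in config.stages:
            _stage_nullmodels(dataset, config, manifest)
        assignment = None
        if "hierpart" in config.stages:
            _stage_hierpart(dataset, config, manifest)
        if "traittree" in config.stages or "patterns" in config.stages:
            assignment = _stage_traittree(dataset, config, manifest)
        if "association" in config.stages:
            _stage_association(dataset, config, manifest, assignment)
    except Exception as err:  # partial manifest on stage failure
        status = f"failed: {err}"
        log.error("pipeline aborted: %s", err)
        raise
    finally:
        out = {"seed": config.seed, "status": status, "artifacts": manifest}
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
    return out


def _stage_metrics(dataset: Dataset, config: RunConfig, manifest: dict) -> None:
    seed = config.stage_seed("metrics")
    rep = metrics.metrics_report(dataset)
    _write_csv(rep["per_tree"], config.out_dir, "metrics_per_tree.csv", seed, manifest, index=True)
    _write_csv(rep["per_sample"], config.out_dir, "metrics_per_sample.csv", seed, manifest)


def _stage_nullmodels(dataset: Dataset, config: RunConfig, manifest: dict) -> None:
    seed = config.stage_seed("nullmodels")
    rows = []
    patches = list(dict.fromkeys(dataset.trees["patch"]))
    for i, patch in enumerate(patches):
        sub = dataset.trees[dataset.trees["patch"] == patch]
        if sub["a_total"].sum() == 0 or len(sub) < 2:
            log.info("skipping individual-randomisation null for patch %r", patch)
            continue
        envs = nullmodels.randomize_individuals_null(
            dataset, patch, n_reps=config.n_reps, seed=seed + i
        )
        for metric, env in envs.items():
            rows.append({"patch": patch, "metric": metric, "observed": env.observed,
                         "q2.5": env.q_low, "q97.5": env.q_high, "verdict": env.verdict})
    comm = community_from_records(dataset.records(), sample_by="patch",
                                  count_of="host_tree_species")
    comm = comm.loc[:, comm.sum(axis=0) > 0]
    if comm.shape[1] >= 3:
        env = nullmodels.tip_shuffle_test(comm, dataset.phylogeny,
                                          n_runs=config.n_runs, seed=seed + 1000)
        rows.append({"patch": "(all)", "metric": "cooccurrence_corr",
                     "observed": env.observed, "q2.5": env.q_low,
                     "q97.5": env.q_high, "verdict": env.verdict})
        for i, patch in enumerate(patches):
            if comm.loc[patch].gt(0).sum() < 2:
                continue
            envs = nullmodels.psd_null_test(comm, dataset.phylogeny, row=patch,
                                            n_reps=config.n_runs, seed=seed + 2000 + i)
            for metric, env in envs.items():
                rows.append({"patch": patch, "metric": metric, "observed": env.observed,
                             "q2.5": env.q_low, "q97.5": env.q_high,
                             "verdict": nullmodels.psd_verdict_label(env)})
    _write_csv(pd.DataFrame(rows), config.out_dir, "nullmodels.csv", seed, manifest)


def _stage_hierpart(dataset: Dataset, config: RunConfig, manifest: dict) -> None:
    seed = config.stage_seed("hierpart")
    X = dataset.predictor_frame()
    kinds = dataset.predictor_kinds()
    frames = []
    y = dataset.trees["a_total"].to_numpy(dtype=float)
    res = randomization_test(y, X, family="poisson", n_rand=config.n_rand,
                             seed=seed, kinds=kinds)
    f = res.to_frame().reset_index(names="predictor")
    f.insert(0, "response", "abund")
    frames.append(f)
    hosts = dataset.trees["a_total"] > 0
    if hosts.sum() >= 10:
        yd = dataset.trees.loc[hosts, ["a_trunk", "a_branch"]].to_numpy(dtype=float)
        res = randomization_test(yd, X[hosts], family="binomial",
                                 n_rand=config.n_rand, seed=seed + 1, kinds=kinds)
        f = res.to_frame().reset_index(names="predictor")
        f.insert(0, "response", "dist")
        frames.append(f)
    _write_csv(pd.concat(frames), config.out_dir, "hierpart.csv", seed, manifest)


def _stage_traittree(dataset: Dataset, config: RunConfig, manifest: dict):
    seed = config.stage_seed("traittree")
    abund = traittree.grow_tree(dataset, "abund", min_node=config.min_node,
                                n_rand=config.n_rand, alpha=config.alpha, seed=seed)
    dist = traittree.grow_tree(dataset, "dist", min_node=config.min_node,
                               n_rand=config.n_rand, alpha=config.alpha, seed=seed + 1)
    for name, tree in (("abund", abund), ("dist", dist)):
        path = os.path.join(config.out_dir, f"traittree_{name}.json")
        with open(path, "w") as fh:
            fh.write(tree.to_json(indent=2))
        manifest[os.path.basename(path)] = _sha256(path)
        path = os.path.join(config.out_dir, f"traittree_{name}.txt")
        with open(path, "w") as fh:
            fh.write(tree.render() + "\n")
        manifest[os.path.basename(path)] = _sha256(path)
    assignment = traittree.assign_patterns(abund, dist, config.thresholds)
    _write_csv(assignment, config.out_dir, "patterns.csv", seed, manifest, index=True)
    species_of = dataset.trees["species"].to_dict()
    overlaps = traittree.pattern_overlap_counts(assignment, species_of)
    euler = pd.DataFrame(
        [{"combination": "+".join(k), "species": v} for k, v in sorted(overlaps.items())]
    )
    _write_csv(euler, config.out_dir, "euler_counts.csv", seed, manifest)
    return assignment


def _stage_association(dataset: Dataset, config: RunConfig, manifest: dict,
                       assignment: pd.DataFrame | None) -> None:
    seed = config.stage_seed("association")
    rows = []
    for response in ("abund", "dist"):
        try:
            overall, pairwise, letters = association.patch_comparison(dataset, response)
        except ValueError as err:
            log.info("patch comparison skipped for %s: %s", response, err)
            continue
        rows.append({"response": response, "chi2": overall.chi2, "df": overall.df,
                     "p": overall.p, "letters": ";".join(f"{k}={v}" for k, v in letters.items())})
    _write_csv(pd.DataFrame(rows), config.out_dir, "patch_comparison.csv", seed, manifest)

    summaries = association.plot_summaries(dataset)
    frames = []
    for response in ("ab_abund", "ab_dst"):
        try:
            reg = association.diversity_regressions(summaries, response)
        except Exception as err:
            log.info("diversity regression skipped for %s: %s", response, err)
            continue
        reg.insert(0, "response", response)
        frames.append(reg)
    if frames:
        _write_csv(pd.concat(frames), config.out_dir, "diversity_lm.csv", seed, manifest)

    if assignment is not None:
        hosts = dataset.trees.index[dataset.trees["a_total"] > 0]
        pca_rows, glm_rows = [], []
        for subset, response in (("all", "abund"), ("hosts", "dist")):
            try:
                pca = association.pattern_pca(assignment, subset, hosts=hosts)
            except Exception as err:
                log.info("pattern PCA skipped (%s): %s", subset, err)
                continue
            pca_rows.append({"subset": subset, "pct_variance": pca.pct_variance,
                             **{f"loading_{k}": v for k, v in pca.loadings.items()}})
            g = association.score_glm(dataset, pca.scores, response)
            glm_rows.append({"subset": subset, "response": response, "chi2": g.chi2,
                             "df": g.df, "p": g.p, "slope": g.slope, "r2": g.r2})
        if pca_rows:
            _write_csv(pd.DataFrame(pca_rows), config.out_dir, "pca.csv", seed, manifest)
        if glm_rows:
            _write_csv(pd.DataFrame(glm_rows), config.out_dir, "glm.csv", seed, manifest)
        cross = association.assignment_crosstab_tests(assignment)
        _write_csv(cross, config.out_dir, "crosstabs.csv", seed, manifest)
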