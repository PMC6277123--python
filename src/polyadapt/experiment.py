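"""Experiment configuration, presets, grid expansion and orchestration.

An experiment is a Cartesian grid over trait parameters (sigma_m, V_S, psi)
and demography scenarios (bottleneck fraction, final-size multiple), run for
a number of replicates each.  Equilibrium burn-ins depend only on
(sigma_m, V_S) and are shared across psi values and demographies; one neutral
null is built per demography and cached.  All randomness derives from a
single master seed through a fixed spawning order, so re-running a
configuration reproduces every output byte for byte, independent of the
worker count.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import architecture as arch
from . import importance as imp
from . import summaries
from .neutral_null import simulate_neutral_sojourns, sweep_threshold
from .sweep_classify import classify_fixations, sweep_summary
from .sim_engine import (DemographyModel, QTLLayout, TraitParams,
                         run_adaptation, run_burn_in)

__all__ = ["ParamSet", "ExperimentConfig", "PRESETS", "preset",
           "published_config", "run_experiment", "write_report"]


@dataclass(frozen=True)
class ParamSet:
    """One cell of the experiment grid."""

    sigma_m: float
    v_s: float
    psi: float
    bottleneck_fraction: float
    final_multiple: float

    @property
    def set_id(self) -> str:
        return (f"sm{self.sigma_m:g}_vs{self.v_s:g}_psi{self.psi:g}"
                f"_b{self.bottleneck_fraction:g}_f{self.final_multiple:g}")

    def trait_params(self) -> TraitParams:
        return TraitParams(sigma_m=self.sigma_m, v_s=self.v_s, psi=self.psi)

    def demography(self, n_anc: int) -> DemographyModel:
        return DemographyModel(n_anc=n_anc,
                               bottleneck_fraction=self.bottleneck_fraction,
                               final_multiple=self.final_multiple)


@dataclass
class ExperimentConfig:
    """Structured experiment description (one YAML file per experiment)."""

    name: str = "experiment"
    n_anc: int = 1_000
    replicates: int = 5
    seed: int = 1
    sigma_m: tuple = (0.05,)
    v_s: tuple = (1.0,)
    psi: tuple = (0.0,)
    bottleneck_fraction: tuple = (1.0,)
    final_multiple: tuple = (1.0,)
    burn_in_generations: int | None = None  # default 10 * n_anc
    null_fixations: int = 1_000
    record_snapshots: bool = True
    background_variance: str = "population"  # population | midparent_pair
    importance_targets: tuple = (
        "time_to_optimum", "adaptation_rate", "v_g_final", "n_fixations",
        "mean_effect_fixations", "prop_sweeps", "prop_standing",
        "n_segregating", "prop_negative_seg",
    )

    def __post_init__(self) -> None:
        for name in ("sigma_m", "v_s", "psi", "bottleneck_fraction",
                     "final_multiple", "importance_targets"):
            value = getattr(self, name)
            if not isinstance(value, (list, tuple)):
                value = [value]
            setattr(self, name, tuple(value))
        if self.background_variance not in ("population", "midparent_pair"):
            raise ValueError("background_variance must be 'population' or "
                             "'midparent_pair'")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}

    def param_sets(self) -> list[ParamSet]:
        """Cartesian expansion of the grid, in a fixed deterministic order."""
        return [
            ParamSet(sm, vs, ps, bf, fm)
            for sm, vs, ps, bf, fm in itertools.product(
                self.sigma_m, self.v_s, self.psi,
                self.bottleneck_fraction, self.final_multiple)
        ]

    def burn_in_length(self) -> int:
        return (10 * self.n_anc if self.burn_in_generations is None
                else self.burn_in_generations)


def published_config() -> ExperimentConfig:
    """The full published-scale grid: 1,200 parameter sets (5 sigma_m x
    5 V_S x 4 psi x 12 demographies), 100 replicates each at N_anc=10,000.
    This is an overnight-scale configuration."""
    return ExperimentConfig(
        name="published-grid",
        n_anc=10_000,
        replicates=100,
        sigma_m=(0.01, 0.05, 0.1, 0.3, 0.9),
        v_s=(1.0, 5.0, 10.0, 20.0, 50.0),
        psi=(0.0, 0.1, 0.5, 0.95),
        bottleneck_fraction=(1.0, 0.10, 0.05, 0.01),
        final_multiple=(1.0, 3.0, 10.0),
        null_fixations=10_000,
    )


# Desk-scale presets: same model, reduced N_anc and replicates.
PRESETS: dict[str, ExperimentConfig] = {
    "single-scenario": ExperimentConfig(
        name="single-scenario", sigma_m=(0.05,), v_s=(1.0,), psi=(0.0,),
        bottleneck_fraction=(1.0,), final_multiple=(1.0,)),
    "maize-trait1": ExperimentConfig(
        name="maize-trait1", sigma_m=(0.01,), v_s=(1.0,), psi=(0.0,),
        bottleneck_fraction=(0.05,), final_multiple=(10.0,)),
    "maize-trait2": ExperimentConfig(
        name="maize-trait2", sigma_m=(0.9,), v_s=(50.0,), psi=(0.0,),
        bottleneck_fraction=(0.05,), final_multiple=(10.0,)),
}


def preset(name: str) -> ExperimentConfig:
    try:
        return dataclasses.replace(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def _run_one(ps: ParamSet, replicate: int, state, null_threshold: float,
             config: ExperimentConfig, seed: np.random.SeedSequence,
             out_dir: Path | None):
    """Adaptive phase + classification + summaries for one replicate."""
    rng = np.random.default_rng(seed)
    pop = state.copy()
    pop.params = replace(pop.params, psi=ps.psi,
                         background_variance=config.background_variance)
    demography = ps.demography(config.n_anc)
    result = run_adaptation(pop, demography, rng,
                            record_snapshots=config.record_snapshots)
    classified = classify_fixations(result.fixations, null_threshold)
    sw = sweep_summary(classified,
                       result.params.z_opt_new - result.params.z_opt_initial)
    row = summaries.summary_row(result, classified, sw)
    row["set_id"] = ps.set_id
    row["replicate"] = replicate
    if out_dir is not None:
        rep_dir = out_dir / "sets" / ps.set_id / f"rep{replicate}"
        _write_tsv(result.trajectory, rep_dir / "trajectory.tsv")
        _write_tsv(classified, rep_dir / "fixations.tsv")
        _write_tsv(result.segregating, rep_dir / "segregating.tsv")
        if config.record_snapshots:
            snaps = []
            for snap in result.snapshots:
                tab = snap.mutations.copy()
                tab.insert(0, "generation", snap.generation)
                snaps.append(tab)
            if snaps:
                _write_tsv(pd.concat(snaps, ignore_index=True),
                           rep_dir / "snapshots.tsv")
    return row, result.segregating[["effect", "frequency"]]


def run_experiment(config: ExperimentConfig, out_dir=None, n_jobs: int = 1) -> dict:
    """Run every stage of an experiment: shared burn-ins, neutral nulls,
    adaptive runs, classification, summaries, architecture matrices,
    pairwise correlations, and (when the grid is large enough) random-forest
    importances.  Returns a result dictionary; writes TSV tables and a JSON
    manifest when ``out_dir`` is given."""
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    layout = QTLLayout()
    sets = config.param_sets()
    burnin_keys = sorted({(ps.sigma_m, ps.v_s) for ps in sets})
    demographies = sorted({(ps.bottleneck_fraction, ps.final_multiple) for ps in sets})

    master = np.random.SeedSequence(config.seed)
    ss_burn, ss_null, ss_runs = master.spawn(3)
    burn_seeds = ss_burn.spawn(len(burnin_keys) * config.replicates)
    null_seeds = ss_null.spawn(len(demographies))
    run_seeds = ss_runs.spawn(len(sets) * config.replicates)

    # --- shared burn-ins: one equilibrium per (sigma_m, V_S) per replicate
    def _burn(key, seed):
        sm, vs = key
        rng = np.random.default_rng(seed)
        params = TraitParams(sigma_m=sm, v_s=vs, psi=0.0)
        pop, traj = run_burn_in(params, layout, config.n_anc, rng,
                                generations=config.burn_in_length())
        return pop, float(traj["var_g"].iloc[-1])

    burn_tasks = [(key, rep) for key in burnin_keys
                  for rep in range(config.replicates)]
    burn_results = Parallel(n_jobs=n_jobs)(
        delayed(_burn)(key, seed) for (key, _), seed in zip(burn_tasks, burn_seeds))
    equilibria = {task: res[0] for task, res in zip(burn_tasks, burn_results)}

    # --- neutral nulls, one per demography
    def _null(dem_key, seed):
        bf, fm = dem_key
        demography = DemographyModel(n_anc=config.n_anc, bottleneck_fraction=bf,
                                     final_multiple=fm)
        rng = np.random.default_rng(seed)
        return simulate_neutral_sojourns(
            demography, n_fixations=config.null_fixations, rng=rng,
            burn_in_generations=config.burn_in_length())

    nulls_list = Parallel(n_jobs=n_jobs)(
        delayed(_null)(key, seed) for key, seed in zip(demographies, null_seeds))
    nulls = dict(zip(demographies, nulls_list))
    thresholds = {key: sweep_threshold(null) for key, null in nulls.items()}
    if out_path is not None:
        for key, null in nulls.items():
            _write_tsv(pd.DataFrame({"demography": null.demography_id,
                                     "sojourn": null.sojourn_times}),
                       out_path / f"null_{null.demography_id}.tsv")

    # --- adaptive runs
    run_tasks = [(ps, rep) for ps in sets for rep in range(config.replicates)]
    run_out = Parallel(n_jobs=n_jobs)(
        delayed(_run_one)(ps, rep, equilibria[((ps.sigma_m, ps.v_s), rep)],
                          thresholds[(ps.bottleneck_fraction, ps.final_multiple)],
                          config, seed, out_path)
        for (ps, rep), seed in zip(run_tasks, run_seeds))
    rows = [row for row, _ in run_out]
    summary = pd.DataFrame(rows)
    front = ["set_id", "replicate"]
    summary = summary[front + [c for c in summary.columns if c not in front]]

    # --- per-set architecture matrices from pooled replicate effects
    matrices: dict[str, np.ndarray] = {}
    edges_by_set: dict[str, np.ndarray] = {}
    for ps in sets:
        seg_tables = [seg for (ps2, _), (_, seg) in zip(run_tasks, run_out)
                      if ps2 == ps]
        pooled = pd.concat(seg_tables, ignore_index=True)
        try:
            edges = arch.effect_bin_edges(pooled["effect"].to_numpy())
        except ValueError:
            continue  # too few segregating sites to bin; noted in manifest
        reps = [arch.build_architecture_matrix(seg, edges) for seg in seg_tables
                if len(seg)]
        if not reps:
            continue
        matrices[ps.set_id] = arch.mean_matrix(reps)
        edges_by_set[ps.set_id] = edges

    correlations = (arch.pairwise_correlations(matrices)
                    if len(matrices) >= 2 else None)

    # --- random-forest importances on the replicate-level summary table
    importance_rows = []
    if len(sets) >= 10:
        for target in config.importance_targets:
            if target not in summary.columns:
                continue
            try:
                res = imp.fit_importance(summary, target, seed=config.seed)
            except ValueError:
                continue
            for feature, value in res.importances.items():
                importance_rows.append({
                    "target": target, "feature": feature, "importance": value,
                    "cv_r2": res.cv_r2, "nrmsd": res.nrmsd, "n": res.n_rows,
                })
    importance_table = pd.DataFrame(importance_rows)

    aggregate = (summary.drop(columns=["replicate"])
                 .groupby("set_id").agg(["mean", "std"]))
    aggregate.columns = [f"{a}_{b}" for a, b in aggregate.columns]
    aggregate = aggregate.reset_index()

    manifest = {
        "config": config.to_dict(),
        "n_parameter_sets": len(sets),
        "n_runs": len(run_tasks),
        "null_thresholds": {nulls[k].demography_id: thresholds[k]
                            for k in demographies},
        "sets_without_architecture": sorted(
            ps.set_id for ps in sets if ps.set_id not in matrices),
        "seeds": {
            "master": config.seed,
            "burn_in": [list(map(int, s.generate_state(2))) for s in burn_seeds],
            "null": [list(map(int, s.generate_state(2))) for s in null_seeds],
            "runs": [list(map(int, s.generate_state(2))) for s in run_seeds],
        },
    }

    if out_path is not None:
        _write_tsv(summary, out_path / "summary.tsv")
        _write_tsv(aggregate, out_path / "aggregate.tsv")
        for set_id, matrix in matrices.items():
            _write_tsv(arch.matrix_to_frame(matrix, edges_by_set[set_id]),
                       out_path / "architecture" / f"{set_id}.tsv")
        if correlations is not None:
            correlations.rename_axis("set_id").reset_index().to_csv(
                out_path / "correlations.tsv", sep="\t", index=False)
        if len(importance_table):
            _write_tsv(importance_table, out_path / "importance.tsv")
        with open(out_path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "summary": summary,
        "aggregate": aggregate,
        "matrices": matrices,
        "correlations": correlations,
        "importance": importance_table,
        "nulls": {nulls[k].demography_id: nulls[k] for k in demographies},
        "manifest": manifest,
    }


def write_report(out_dir) -> pd.DataFrame:
    """Recompute the per-set aggregate table from a run directory's
    summary.tsv (the ``polyadapt report`` command)."""
    out_path = Path(out_dir)
    summary = pd.read_csv(out_path / "summary.tsv", sep="\t")
    aggregate = (summary.drop(columns=["replicate"])
                 .groupby("set_id").agg(["mean", "std"]))
    aggregate.columns = [f"{a}_{b}" for a, b in aggregate.columns]
    aggregate = aggregate.reset_index()
    _write_tsv(aggregate, out_path / "aggregate.tsv")
    return aggregate
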