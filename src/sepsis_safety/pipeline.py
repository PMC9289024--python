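"""End-to-end pipeline: simulate -> prepare -> flag -> train -> retrain-safe
-> audit -> ope -> report.

Each stage reads its upstream artifacts from a run directory, writes its
outputs plus a JSON manifest (parameters, seeds, input hashes, package
version), and fails with an actionable error naming the stage to run first
when an upstream artifact is missing. A full run under a fixed
:class:`RunConfig` is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (ActionGrid, StateModel, discretize_actions,
                     fit_state_clusters, assign_states, read_cohort, write_cohort,
                     DEFAULT_STATE_FEATURES)
from .hazards import (DEFAULT_MAP_SWEEP_GRIDS, default_scenarios,
                      flag_cohort, sweep_thresholds)
from .mdp import (RewardSpec, build_reward, estimate_mdp, greedy_policy,
                  q_learning)
from .ope import (bootstrap_value, estimate_behaviour_policy, soften_greedy,
                  stay_returns, stay_weights)
from .simulate import SimConfig, generate_cohort, ground_truth_summary
from .stats import (StatsError, attribution, compare_policies,
                    fit_unsafe_classifier, significance_sweep)

logger = logging.getLogger("sepsis_safety")

__all__ = ["RunConfig", "PipelineError", "run_stage", "run_all", "STAGES"]

STAGES = ("simulate", "prepare", "flag", "train", "retrain-safe",
          "audit", "ope", "report")


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage to run first."""


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serializable to/from YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    k: int = 20                      # state cluster count (750 at full scale)
    cluster_seed: int = 11
    min_count: int = 5
    on_no_admissible: str = "relax"  # pipeline default; library default errors
    gamma: float = 0.99
    terminal_magnitude: float = 100.0
    penalty: float = 30.0
    penalty_mode: str = "fraction"
    q_alpha0: float = 0.6
    q_decay: float = 0.05
    q_tol: float = 1e-4
    q_max_sweeps: int = 20000
    q_seed: int = 23
    ope_epsilon: float = 0.01
    ope_smoothing: float = 0.01
    ope_B: int = 2000
    ope_seed: int = 37
    attribution_seed: int = 41
    sweep_sided: str = "one-sided"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(sim=SimConfig(**sim_raw), **raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, params: dict,
                    inputs: list[Path], outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "params": params,
        "inputs": {p.name: _hash_file(p) for p in inputs if p.exists()},
        "outputs": {p.name: _hash_file(p) for p in outputs if p.exists()},
    }
    path = outdir / f"manifest_{stage.replace('-', '_')}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _require(outdir: Path, filename: str, produced_by: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise PipelineError(
            f"missing artifact '{filename}' in {outdir}; run the "
            f"'{produced_by}' stage first")
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> None:
    cohort, gt = generate_cohort(config.sim)
    cohort_path = write_cohort(cohort, outdir / "cohort.csv")
    (outdir / "ground_truth.json").write_text(gt.to_json())
    ground_truth_summary(gt).to_csv(outdir / "ground_truth_summary.csv", index=False)
    logger.info("simulate: %d stays, %d steps, mortality %.3f",
                gt.n_stays, gt.n_steps, gt.mortality)
    _write_manifest(outdir, "simulate", asdict(config.sim), [],
                    [cohort_path, outdir / "ground_truth.json"])


def _load_prepared(config: RunConfig, outdir: Path):
    cohort = read_cohort(_require(outdir, "cohort.csv", "simulate"))
    grid = ActionGrid.from_json(_require(outdir, "action_grid.json", "prepare").read_text())
    model = StateModel.from_json(_require(outdir, "state_model.json", "prepare").read_text())
    sa = pd.read_csv(_require(outdir, "states_actions.csv", "prepare"))
    return cohort, grid, model, sa["state_id"].to_numpy(), sa["action_index"].to_numpy()


def stage_prepare(config: RunConfig, outdir: Path) -> None:
    cohort_path = _require(outdir, "cohort.csv", "simulate")
    cohort = read_cohort(cohort_path)
    grid, action_idx = discretize_actions(cohort, step_hours=config.sim.step_hours)
    model = fit_state_clusters(cohort, k=config.k, seed=config.cluster_seed)
    state_ids = assign_states(model, cohort)
    (outdir / "action_grid.json").write_text(grid.to_json())
    (outdir / "state_model.json").write_text(model.to_json())
    pd.DataFrame({"stay_id": cohort.table["stay_id"],
                  "step_index": cohort.table["step_index"],
                  "state_id": state_ids,
                  "action_index": action_idx}).to_csv(
        outdir / "states_actions.csv", index=False)
    logger.info("prepare: k=%d states, %d/25 fluid/vaso bins in use",
                config.k, grid.fluid.n_bins * grid.vaso.n_bins)
    _write_manifest(outdir, "prepare",
                    {"k": config.k, "seed": config.cluster_seed,
                     "features": list(DEFAULT_STATE_FEATURES)},
                    [cohort_path],
                    [outdir / "action_grid.json", outdir / "state_model.json",
                     outdir / "states_actions.csv"])


def stage_flag(config: RunConfig, outdir: Path) -> None:
    cohort = read_cohort(_require(outdir, "cohort.csv", "simulate"))
    ft = flag_cohort(cohort, default_scenarios(), step_hours=config.sim.step_hours)
    ft.to_csv(outdir / "flags.csv")
    counts = {sid: ft.counts(sid) for sid in ft.scenario_ids}
    logger.info("flag: per-scenario (N, x_human) = %s; union %d",
                counts, ft.union_count("human"))
    _write_manifest(outdir, "flag", {"scenarios": list(ft.scenario_ids)},
                    [outdir / "cohort.csv"], [outdir / "flags.csv"])


def _train_policy(config: RunConfig, outdir: Path, penalty: float, name: str) -> None:
    cohort, grid, model, state_ids, action_idx = _load_prepared(config, outdir)
    flags = pd.read_csv(_require(outdir, "flags.csv", "flag"))
    mdp = estimate_mdp(cohort, model, state_ids, action_idx, gamma=config.gamma,
                       min_count=config.min_count,
                       on_no_admissible=config.on_no_admissible)
    spec = RewardSpec(terminal_magnitude=config.terminal_magnitude,
                      penalty=penalty, mode=config.penalty_mode)
    rewards = build_reward(mdp, flags["unsafe_human_any"].to_numpy(),
                           spec, state_ids, action_idx)
    qt = q_learning(mdp, rewards, alpha0=config.q_alpha0, decay=config.q_decay,
                    tol=config.q_tol, max_sweeps=config.q_max_sweeps,
                    seed=config.q_seed)
    policy = greedy_policy(qt)
    qdf = pd.DataFrame({
        "state": np.repeat(np.arange(mdp.k), mdp.n_actions),
        "action": np.tile(np.arange(mdp.n_actions), mdp.k),
        "q": qt.q.ravel(),
        "greedy": (policy[np.repeat(np.arange(mdp.k), mdp.n_actions)]
                   == np.tile(np.arange(mdp.n_actions), mdp.k)).astype(int),
    })
    qdf.to_csv(outdir / f"qtable_{name}.csv", index=False)
    pd.DataFrame({"state": np.arange(mdp.k), "action": policy}).to_csv(
        outdir / f"policy_{name}.csv", index=False)
    logger.info("%s: Q-learning converged in %d sweeps (penalty=%g)",
                name, qt.sweeps, penalty)
    _write_manifest(outdir, "train" if name == "original" else "retrain-safe",
                    {"gamma": config.gamma, "penalty": penalty,
                     "terminal_magnitude": config.terminal_magnitude,
                     "penalty_mode": config.penalty_mode,
                     "alpha0": config.q_alpha0, "decay": config.q_decay,
                     "tol": config.q_tol, "seed": config.q_seed,
                     "sweeps": qt.sweeps, "min_count": config.min_count},
                    [outdir / "states_actions.csv", outdir / "flags.csv"],
                    [outdir / f"policy_{name}.csv", outdir / f"qtable_{name}.csv"])


def stage_train(config: RunConfig, outdir: Path) -> None:
    _train_policy(config, outdir, penalty=0.0, name="original")


def stage_retrain_safe(config: RunConfig, outdir: Path) -> None:
    _train_policy(config, outdir, penalty=config.penalty, name="safe")


def _load_policies(outdir: Path) -> dict[str, np.ndarray]:
    policies = {}
    for name, stage in (("original", "train"), ("safe", "retrain-safe")):
        df = pd.read_csv(_require(outdir, f"policy_{name}.csv", stage))
        policies[name] = df["action"].to_numpy()
    return policies


def stage_audit(config: RunConfig, outdir: Path) -> None:
    cohort, grid, model, state_ids, action_idx = _load_prepared(config, outdir)
    policies = _load_policies(outdir)
    scenarios = default_scenarios()
    ft = flag_cohort(cohort, scenarios, policies=policies, state_ids=state_ids,
                     action_grid=grid, step_hours=config.sim.step_hours)
    ft.to_csv(outdir / "flags_all_agents.csv")
    props, tests = compare_policies(ft, sided=config.sweep_sided)
    props.to_csv(outdir / "proportions.csv", index=False)
    pd.DataFrame([{"scenario": sid, "policy": agent, **dataclasses.asdict(t)}
                  for (sid, agent), t in tests.items()]).to_csv(
        outdir / "tests.csv", index=False)

    for sid, sc in scenarios.items():
        sw = sweep_thresholds(cohort, sc, DEFAULT_MAP_SWEEP_GRIDS[sid],
                              policies=policies, state_ids=state_ids,
                              action_grid=grid, step_hours=config.sim.step_hours)
        sw = significance_sweep(sw, policy="original", sided=config.sweep_sided)
        sw.to_csv(outdir / f"sweep_{sid}.csv", index=False)

    # feature attribution of unsafe *clinician* decisions, per scenario
    features = [c for c in DEFAULT_STATE_FEATURES]
    for sid in scenarios:
        risk = ft.df[f"at_risk_{sid}"].to_numpy()
        if risk.sum() == 0:
            logger.info("audit: scenario %s has no at-risk steps; attribution skipped", sid)
            continue
        X = cohort.table.loc[risk, features]
        y = ft.df.loc[risk, f"unsafe_human_{sid}"].to_numpy()
        try:
            model_s = fit_unsafe_classifier(X, y, seed=config.attribution_seed)
        except StatsError as exc:
            logger.info("audit: scenario %s attribution skipped (%s)", sid, exc)
            continue
        attribution(model_s, X).ranking().to_csv(
            outdir / f"attribution_{sid}.csv", index=False)
    _write_manifest(outdir, "audit",
                    {"sided": config.sweep_sided, "seed": config.attribution_seed},
                    [outdir / "cohort.csv", outdir / "policy_original.csv",
                     outdir / "policy_safe.csv"],
                    [outdir / "proportions.csv", outdir / "tests.csv"])


def stage_ope(config: RunConfig, outdir: Path) -> None:
    cohort, grid, model, state_ids, action_idx = _load_prepared(config, outdir)
    policies = _load_policies(outdir)
    mdp = estimate_mdp(cohort, model, state_ids, action_idx, gamma=config.gamma,
                       min_count=config.min_count,
                       on_no_admissible=config.on_no_admissible)
    spec = RewardSpec(terminal_magnitude=config.terminal_magnitude, penalty=0.0)
    rewards = build_reward(mdp, np.zeros(cohort.n_steps), spec, state_ids, action_idx)
    behaviour = estimate_behaviour_policy(mdp, smoothing=config.ope_smoothing)
    stay_of_step = cohort.table["stay_id"].to_numpy()
    survived = cohort.outcomes().to_numpy()
    returns = stay_returns(mdp, rewards, stay_of_step, state_ids, action_idx, survived)

    results = {}
    w_b = stay_weights(behaviour, behaviour, stay_of_step, state_ids, action_idx)
    est = bootstrap_value(w_b, returns, B=config.ope_B, seed=config.ope_seed)
    results["behaviour"] = {"value": est.value, "median": est.median, "iqr": est.iqr}
    for name, pol in policies.items():
        soft = soften_greedy(pol, mdp, epsilon=config.ope_epsilon)
        w = stay_weights(soft, behaviour, stay_of_step, state_ids, action_idx)
        est = bootstrap_value(w, returns, B=config.ope_B, seed=config.ope_seed)
        results[name] = {"value": est.value, "median": est.median, "iqr": est.iqr}
    (outdir / "ope.json").write_text(json.dumps(
        results | {"B": config.ope_B, "epsilon": config.ope_epsilon,
                   "smoothing": config.ope_smoothing, "reward": "unpenalized"},
        indent=1))
    logger.info("ope: %s", {k: round(v["value"], 2) for k, v in results.items()
                            if isinstance(v, dict)})
    _write_manifest(outdir, "ope",
                    {"B": config.ope_B, "epsilon": config.ope_epsilon,
                     "smoothing": config.ope_smoothing, "seed": config.ope_seed},
                    [outdir / "cohort.csv"], [outdir / "ope.json"])


def _action_histogram(policy: np.ndarray, n_actions: int = 25) -> np.ndarray:
    defined = policy[policy >= 0]
    return np.bincount(defined, minlength=n_actions)


def stage_report(config: RunConfig, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    props = pd.read_csv(_require(outdir, "proportions.csv", "audit"))
    ope = json.loads(_require(outdir, "ope.json", "ope").read_text())
    policies = _load_policies(outdir)

    lines = ["# Safety audit report", "",
             "## Unsafe-decision proportions (shared at-risk N per scenario)", ""]
    lines.append(props.to_string(index=False))
    lines.append("")
    for sid in sorted(props["scenario"].unique()):
        block = props[props["scenario"] == sid]
        if block["N"].iloc[0] == 0:
            lines.append(f"Scenario {sid}: not evaluable (no at-risk steps).")
    lines.append("")
    lines.append("## Off-policy policy value (unpenalized reward; median [IQR])")
    for agent in ("behaviour", "original", "safe"):
        if agent in ope:
            v = ope[agent]
            lines.append(f"- {agent}: {v['median']:.2f} "
                         f"[{v['iqr'][0]:.2f}, {v['iqr'][1]:.2f}]")
    lines.append("")
    lines.append("## Policy action histograms (counts over states, 25 actions)")
    for name, pol in policies.items():
        hist = _action_histogram(pol)
        lines.append(f"- {name}: {hist.tolist()} (sum {hist.sum()})")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")

    # Figure analogs: threshold sweeps, proportions, action histograms
    fig, axes = plt.subplots(2, 4, figsize=(16, 6), sharex="col")
    for j, sid in enumerate(("A", "B", "C", "D")):
        path = outdir / f"sweep_{sid}.csv"
        if not path.exists():
            continue
        sw = pd.read_csv(path)
        ax = axes[0, j]
        ax.plot(sw["map_threshold"], sw["x_human"], "o-", label="human")
        if "x_original" in sw:
            ax.plot(sw["map_threshold"], sw["x_original"], "s-", label="original AI")
        if "x_safe" in sw:
            ax.plot(sw["map_threshold"], sw["x_safe"], "^-", label="safe AI")
        ax.set_title(f"Scenario {sid}")
        ax.set_ylabel("unsafe decisions")
        ax.legend(fontsize=7)
        ax2 = axes[1, j]
        ax2.plot(sw["map_threshold"], sw["p_value"], "k.-")
        ax2.axhline(0.05, color="r", ls="--", lw=0.8)
        ax2.set_yscale("log")
        ax2.set_xlabel("MAP threshold (mm Hg)")
        ax2.set_ylabel("p value")
    fig.tight_layout()
    fig.savefig(outdir / "fig_threshold_sweeps.png", dpi=120)
    plt.close(fig)

    fig, (axp, axh) = plt.subplots(1, 2, figsize=(11, 4))
    pivot = props.pivot(index="scenario", columns="agent", values="proportion")
    pivot = pivot[[c for c in ("human", "original", "safe") if c in pivot.columns]]
    pivot.plot.bar(ax=axp)
    axp.set_ylabel("unsafe proportion among at-risk steps")
    width = 0.4
    for off, (name, pol) in zip((-width / 2, width / 2), policies.items()):
        hist = _action_histogram(pol)
        axh.bar(np.arange(25) + off, hist, width=width, label=name)
    axh.set_xlabel("composed action index (5*fluid_bin + vaso_bin)")
    axh.set_ylabel("states recommending action")
    axh.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig_policy_comparison.png", dpi=120)
    plt.close(fig)

    _write_manifest(outdir, "report", {},
                    [outdir / "proportions.csv", outdir / "ope.json"],
                    [outdir / "report.md", outdir / "fig_threshold_sweeps.png",
                     outdir / "fig_policy_comparison.png"])


_STAGE_FN = {
    "simulate": stage_simulate,
    "prepare": stage_prepare,
    "flag": stage_flag,
    "train": stage_train,
    "retrain-safe": stage_retrain_safe,
    "audit": stage_audit,
    "ope": stage_ope,
    "report": stage_report,
}


def run_stage(name: str, config: RunConfig, outdir: str | Path) -> Path:
    """Run one named stage into ``outdir`` (created if needed)."""
    if name not in _STAGE_FN:
        raise PipelineError(f"unknown stage {name!r}; stages are {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.yaml").write_text(config.to_yaml())
    _STAGE_FN[name](config, outdir)
    return outdir


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Run the full pipeline in order."""
    for name in STAGES:
        run_stage(name, config, outdir)
    return Path(outdir)
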