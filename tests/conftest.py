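"""Shared fixtures: a small cohort for unit tests and a full-scale prepared
bundle (cohort, discretizations, MDP, flags, trained policies) reused by the
end-to-end tests so the expensive pipeline runs once per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from sepsis_safety.cohort import (ActionGrid, Cohort, StateModel,
                                  assign_states, discretize_actions,
                                  fit_state_clusters)
from sepsis_safety.hazards import FlagTable, flag_cohort
from sepsis_safety.mdp import (DiscreteMDP, RewardSpec, build_reward,
                               estimate_mdp, greedy_policy, q_learning)
from sepsis_safety.simulate import GroundTruth, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> tuple[Cohort, GroundTruth]:
    return generate_cohort(SimConfig(n_stays=300, seed=7))


@dataclass
class PreparedRun:
    """Everything the audit needs, computed once on the full-scale cohort."""

    cohort: Cohort
    gt: GroundTruth
    grid: ActionGrid
    action_idx: np.ndarray
    model: StateModel
    state_ids: np.ndarray
    mdp: DiscreteMDP
    human_flags: FlagTable
    policies: dict[str, np.ndarray]
    all_flags: FlagTable


@pytest.fixture(scope="session")
def prepared_run() -> PreparedRun:
    """Full study-scale run: 2000 stays, k=20 states, default propensities."""
    cohort, gt = generate_cohort(SimConfig(n_stays=2000, seed=1))
    grid, action_idx = discretize_actions(cohort)
    model = fit_state_clusters(cohort, k=20, seed=11)
    state_ids = assign_states(model, cohort)
    mdp = estimate_mdp(cohort, model, state_ids, action_idx,
                       min_count=5, on_no_admissible="relax")
    human_flags = flag_cohort(cohort)
    unsafe_any = human_flags.df["unsafe_human_any"].to_numpy()
    policies = {}
    for name, penalty in (("original", 0.0), ("safe", 30.0)):
        rewards = build_reward(mdp, unsafe_any, RewardSpec(penalty=penalty),
                               state_ids, action_idx)
        policies[name] = greedy_policy(q_learning(mdp, rewards, seed=5))
    all_flags = flag_cohort(cohort, policies=policies, state_ids=state_ids,
                            action_grid=grid)
    return PreparedRun(cohort=cohort, gt=gt, grid=grid, action_idx=action_idx,
                       model=model, state_ids=state_ids, mdp=mdp,
                       human_flags=human_flags, policies=policies,
                       all_flags=all_flags)
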