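"""Discrete MDP estimation, safety-reshaped rewards, and policy learning.

The treatment problem is modelled as a finite MDP: ``k`` clustered patient
states plus two absorbing terminals (survival, death), and 25 composed dose
actions. Transition probabilities are empirical frequencies from recorded
trajectories; state-action pairs observed fewer than ``min_count`` times are
inadmissible and never recommended.

Rewards are terminal +/-R on survival/death. Safety reshaping subtracts an
intermediate penalty ``P * f(s, a)`` where ``f`` is the fraction of observed
instances of (s, a) that were unsafe under any hazard scenario, preserving
the mean of the instance-level penalty across a heterogeneous cluster (a
binary majority-flagged mode is also available). Setting ``P = 0`` reproduces
the original reward exactly.

Policies are learnt two independent ways: model-free Q-learning over the
shuffled empirical transition list (the production path) and exact value
iteration on the estimated transition model (the verification oracle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .cohort import Cohort, StateModel

__all__ = [
    "MDPError",
    "DiscreteMDP",
    "RewardSpec",
    "RewardTable",
    "QTable",
    "mdp_from_transitions",
    "estimate_mdp",
    "state_action_flag_fraction",
    "build_reward",
    "transition_rewards",
    "q_learning",
    "exact_solve",
    "evaluate_policy",
    "greedy_policy",
    "sample_episodes",
    "make_random_mdp",
]


class MDPError(ValueError):
    """MDP estimation or solving failed."""


@dataclass
class DiscreteMDP:
    """Estimated finite MDP over ``k`` cluster states + 2 terminals.

    ``t_*`` arrays are the raw empirical transition list restricted to
    admissible (s, a); ``u_*`` arrays are the grouped unique transitions with
    their estimated probabilities P(s'|s, a) = count(s, a, s') / count(s, a).
    """

    k: int
    n_actions: int
    gamma: float
    t_state: np.ndarray
    t_action: np.ndarray
    t_next: np.ndarray
    u_state: np.ndarray
    u_action: np.ndarray
    u_next: np.ndarray
    u_prob: np.ndarray
    counts: np.ndarray        # (k, n_actions) observation counts
    admissible: np.ndarray    # (k, n_actions) bool

    @property
    def survival_state(self) -> int:
        return self.k

    @property
    def death_state(self) -> int:
        return self.k + 1

    @property
    def n_states(self) -> int:
        return self.k + 2

    def transition_probability(self, s: int, a: int, s_next: int) -> float:
        mask = (self.u_state == s) & (self.u_action == a) & (self.u_next == s_next)
        return float(self.u_prob[mask].sum())


def mdp_from_transitions(
    s: np.ndarray,
    a: np.ndarray,
    s_next: np.ndarray,
    k: int,
    n_actions: int,
    gamma: float = 0.99,
    min_count: int = 5,
    on_no_admissible: str = "error",
) -> DiscreteMDP:
    """Build an empirical MDP from raw (s, a, s') transitions.

    Terminal states are ``k`` (survival) and ``k + 1`` (death); they may only
    appear as successors. ``on_no_admissible``: 'error' raises when a visited
    state has every action below ``min_count``; 'relax' admits the state's
    most-observed action instead (useful for small pilot cohorts).
    """
    s = np.asarray(s, dtype=np.int64)
    a = np.asarray(a, dtype=np.int64)
    s_next = np.asarray(s_next, dtype=np.int64)
    if not (len(s) == len(a) == len(s_next)):
        raise MDPError("transition arrays must have equal length")
    if (s >= k).any() or (s < 0).any():
        raise MDPError("source states must be cluster states in [0, k)")
    if (s_next < 0).any() or (s_next >= k + 2).any():
        raise MDPError("successor states out of range")

    counts = np.zeros((k, n_actions), dtype=np.int64)
    np.add.at(counts, (s, a), 1)
    admissible = counts >= min_count
    visited = counts.sum(axis=1) > 0
    orphan = visited & ~admissible.any(axis=1)
    if orphan.any():
        states = np.flatnonzero(orphan)
        if on_no_admissible == "relax":
            best = counts[states].argmax(axis=1)
            admissible[states, best] = True
        else:
            raise MDPError(
                "state(s) with no admissible action under min_count="
                f"{min_count}: {states.tolist()}")

    keep = admissible[s, a]
    s, a, s_next = s[keep], a[keep], s_next[keep]

    # group (s, a, s') triples
    flat = (s * n_actions + a) * (k + 2) + s_next
    uniq, uc = np.unique(flat, return_counts=True)
    u_next = uniq % (k + 2)
    sa = uniq // (k + 2)
    u_state, u_action = sa // n_actions, sa % n_actions
    u_prob = uc / counts[u_state, u_action]

    return DiscreteMDP(k=k, n_actions=n_actions, gamma=gamma,
                       t_state=s, t_action=a, t_next=s_next,
                       u_state=u_state, u_action=u_action, u_next=u_next,
                       u_prob=u_prob, counts=counts, admissible=admissible)


def estimate_mdp(
    cohort: Cohort,
    state_model: StateModel,
    state_ids: np.ndarray,
    action_idx: np.ndarray,
    gamma: float = 0.99,
    min_count: int = 5,
    on_no_admissible: str = "error",
) -> DiscreteMDP:
    """Estimate the MDP from a cohort's assigned states and actions.

    Within a stay, each step transitions to the next step's state; the last
    step transitions to the survival or death terminal per the stay outcome.
    """
    state_ids = np.asarray(state_ids, dtype=np.int64)
    action_idx = np.asarray(action_idx, dtype=np.int64)
    if len(state_ids) != cohort.n_steps or len(action_idx) != cohort.n_steps:
        raise MDPError("state/action assignments do not match the cohort length")
    table = cohort.table
    s_next = np.empty(cohort.n_steps, dtype=np.int64)
    same_stay = table["stay_id"].to_numpy()[1:] == table["stay_id"].to_numpy()[:-1]
    s_next[:-1] = np.where(same_stay, state_ids[1:], 0)
    terminal_rows = np.ones(cohort.n_steps, dtype=bool)
    terminal_rows[:-1] = ~same_stay
    survived = table["survived_90d"].to_numpy().astype(bool)
    s_next[terminal_rows] = np.where(survived[terminal_rows],
                                     state_model.survival_state,
                                     state_model.death_state)
    return mdp_from_transitions(state_ids, action_idx, s_next,
                                k=state_model.k, n_actions=25, gamma=gamma,
                                min_count=min_count,
                                on_no_admissible=on_no_admissible)


# ---------------------------------------------------------------------------
# Rewards
# ---------------------------------------------------------------------------

@dataclass
class RewardSpec:
    """Reward configuration: terminal magnitude, safety penalty, penalty mode.

    ``terminal_magnitude`` R is +R on entering the survival terminal and -R
    on death. ``penalty`` P >= 0 scales the intermediate safety penalty;
    ``mode`` 'fraction' uses -P*f(s,a), 'majority' uses -P*[f(s,a) > 0.5].
    """

    terminal_magnitude: float = 100.0
    penalty: float = 30.0
    mode: str = "fraction"

    def __post_init__(self):
        if self.penalty < 0:
            raise MDPError("penalty must be >= 0")
        if self.mode not in ("fraction", "majority"):
            raise MDPError(f"unknown penalty mode {self.mode!r}")


@dataclass
class RewardTable:
    """Per-(s, a) intermediate reward and the terminal bonus magnitude."""

    r_sa: np.ndarray            # (k, n_actions)
    terminal_magnitude: float
    flagged_fraction: np.ndarray | None = None


def state_action_flag_fraction(
    mdp: DiscreteMDP,
    state_ids: np.ndarray,
    action_idx: np.ndarray,
    unsafe_any: np.ndarray,
) -> np.ndarray:
    """f(s, a): share of observed instances of (s, a) flagged unsafe (union
    over scenarios, so an instance unsafe under several scenarios counts once).
    """
    state_ids = np.asarray(state_ids, dtype=np.int64)
    action_idx = np.asarray(action_idx, dtype=np.int64)
    unsafe_any = np.asarray(unsafe_any, dtype=float)
    if not (len(state_ids) == len(action_idx) == len(unsafe_any)):
        raise MDPError("flag table does not match the state/action assignments")
    total = np.zeros((mdp.k, mdp.n_actions))
    flagged = np.zeros((mdp.k, mdp.n_actions))
    np.add.at(total, (state_ids, action_idx), 1.0)
    np.add.at(flagged, (state_ids, action_idx), unsafe_any)
    with np.errstate(invalid="ignore"):
        f = np.where(total > 0, flagged / np.maximum(total, 1.0), 0.0)
    return f


def build_reward(
    mdp: DiscreteMDP,
    flag_unsafe_any: np.ndarray,
    spec: RewardSpec,
    state_ids: np.ndarray,
    action_idx: np.ndarray,
) -> RewardTable:
    """Build the (optionally safety-penalized) reward table.

    ``flag_unsafe_any`` is the per-step any-scenario unsafe indicator for the
    behaviour data the MDP was estimated from (same row order).
    """
    f = state_action_flag_fraction(mdp, state_ids, action_idx, flag_unsafe_any)
    if spec.mode == "majority":
        eff = (f > 0.5).astype(float)
    else:
        eff = f
    r_sa = -spec.penalty * eff
    return RewardTable(r_sa=r_sa, terminal_magnitude=spec.terminal_magnitude,
                       flagged_fraction=f)


def transition_rewards(mdp: DiscreteMDP, rewards: RewardTable) -> np.ndarray:
    """Immediate reward of each empirical transition (penalty + terminal)."""
    r = rewards.r_sa[mdp.t_state, mdp.t_action].astype(float).copy()
    r[mdp.t_next == mdp.survival_state] += rewards.terminal_magnitude
    r[mdp.t_next == mdp.death_state] -= rewards.terminal_magnitude
    return r


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

@dataclass
class QTable:
    """Action values with an admissibility mask.

    ``q`` is (k, n_actions) with ``-inf`` on inadmissible pairs. ``sweeps``
    records Q-learning sweeps (0 for the exact solver).
    """

    q: np.ndarray
    admissible: np.ndarray
    sweeps: int = 0
    converged: bool = True

    def state_values(self) -> np.ndarray:
        return np.max(self.q, axis=1)


@njit(cache=True)
def _q_core(s, a, snxt, r, is_term, Q, admissible, gamma,
            alpha0, decay, tol, max_sweeps, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    nT = s.shape[0]
    nS, nA = Q.shape
    visits = np.zeros((nS, nA), dtype=np.int64)
    order = np.arange(nT)
    Qprev = Q.copy()
    sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        np.random.shuffle(order)
        for ii in range(nT):
            i = order[ii]
            si = s[i]
            ai = a[i]
            if is_term[i]:
                target = r[i]
            else:
                sn = snxt[i]
                m = -1e300
                for an in range(nA):
                    if admissible[sn, an] and Q[sn, an] > m:
                        m = Q[sn, an]
                target = r[i] + gamma * m
            visits[si, ai] += 1
            alpha = alpha0 / (1.0 + decay * visits[si, ai])
            Q[si, ai] += alpha * (target - Q[si, ai])
        sweeps = sweep + 1
        delta = 0.0
        for si in range(nS):
            for an in range(nA):
                if admissible[si, an]:
                    d = abs(Q[si, an] - Qprev[si, an])
                    if d > delta:
                        delta = d
        if delta < tol:
            converged = True
            break
        Qprev[:, :] = Q
    return sweeps, converged


def q_learning(
    mdp: DiscreteMDP,
    rewards: RewardTable,
    alpha0: float = 0.6,
    decay: float = 0.05,
    tol: float = 1e-4,
    max_sweeps: int = 20_000,
    seed: int = 0,
    strict: bool = True,
) -> QTable:
    """Model-free Q-learning over the shuffled empirical transition list.

    Learning rate per (s, a): ``alpha0 / (1 + decay * visit_count)``. Stops
    when the sup-norm Q change between consecutive full sweeps drops below
    ``tol``. Raises :class:`MDPError` on non-convergence when ``strict``.
    """
    if len(mdp.t_state) == 0:
        raise MDPError("empty transition list")
    r = transition_rewards(mdp, rewards)
    is_term = (mdp.t_next >= mdp.k)
    Q = np.zeros((mdp.k, mdp.n_actions))
    sweeps, converged = _q_core(
        mdp.t_state, mdp.t_action, mdp.t_next, r, is_term, Q,
        mdp.admissible, float(mdp.gamma), float(alpha0), float(decay),
        float(tol), int(max_sweeps), int(seed) % (2 ** 31))
    if strict and not converged:
        raise MDPError(
            f"Q-learning did not converge: sup-norm sweep change still >= {tol} "
            f"after {sweeps} sweeps (alpha0={alpha0}, decay={decay})")
    Q = np.where(mdp.admissible, Q, -np.inf)
    return QTable(q=Q, admissible=mdp.admissible.copy(),
                  sweeps=int(sweeps), converged=bool(converged))


def _expected_next(mdp: DiscreteMDP, rewards: RewardTable, V: np.ndarray) -> np.ndarray:
    """Per admissible (s, a): E[bonus(s') + gamma * V(s')], flattened (k*nA)."""
    bonus = np.zeros(mdp.n_states)
    bonus[mdp.survival_state] = rewards.terminal_magnitude
    bonus[mdp.death_state] = -rewards.terminal_magnitude
    Vfull = np.zeros(mdp.n_states)
    Vfull[:mdp.k] = V
    contrib = mdp.u_prob * (bonus[mdp.u_next] + mdp.gamma * Vfull[mdp.u_next])
    flat = mdp.u_state * mdp.n_actions + mdp.u_action
    return np.bincount(flat, weights=contrib, minlength=mdp.k * mdp.n_actions)


def exact_solve(mdp: DiscreteMDP, rewards: RewardTable, tol: float = 1e-10,
                max_iter: int = 1_000_000) -> QTable:
    """Value iteration on the estimated model (verification oracle).

    Iterates the Bellman optimality operator to a sup-norm fixed point.
    """
    V = np.zeros(mdp.k)
    r_flat = rewards.r_sa.ravel()
    adm_flat = mdp.admissible.ravel()
    for _ in range(max_iter):
        Qf = r_flat + _expected_next(mdp, rewards, V)
        Qf = np.where(adm_flat, Qf, -np.inf)
        Vnew = Qf.reshape(mdp.k, mdp.n_actions).max(axis=1)
        Vnew = np.where(np.isfinite(Vnew), Vnew, 0.0)
        if np.max(np.abs(Vnew - V)) < tol:
            V = Vnew
            break
        V = Vnew
    Qf = r_flat + _expected_next(mdp, rewards, V)
    Q = np.where(adm_flat, Qf, -np.inf).reshape(mdp.k, mdp.n_actions)
    return QTable(q=Q, admissible=mdp.admissible.copy())


def evaluate_policy(mdp: DiscreteMDP, rewards: RewardTable, policy_probs: np.ndarray,
                    tol: float = 1e-12, max_iter: int = 1_000_000) -> np.ndarray:
    """Exact state values of a stochastic policy on the estimated model."""
    policy_probs = np.asarray(policy_probs, dtype=float)
    if policy_probs.shape != (mdp.k, mdp.n_actions):
        raise MDPError("policy shape does not match the MDP")
    r_flat = rewards.r_sa.ravel()
    V = np.zeros(mdp.k)
    for _ in range(max_iter):
        Qf = (r_flat + _expected_next(mdp, rewards, V)).reshape(mdp.k, mdp.n_actions)
        Vnew = (policy_probs * np.where(policy_probs > 0, Qf, 0.0)).sum(axis=1)
        if np.max(np.abs(Vnew - V)) < tol:
            return Vnew
        V = Vnew
    return V


def greedy_policy(qtable: QTable) -> np.ndarray:
    """Greedy action per state; exact ties break to the lowest action index
    (the lowest composed doses). States with no admissible action get -1.
    """
    has_action = qtable.admissible.any(axis=1)
    policy = np.full(qtable.q.shape[0], -1, dtype=np.int64)
    if has_action.any():
        policy[has_action] = np.argmax(qtable.q[has_action], axis=1)
    return policy


# ---------------------------------------------------------------------------
# Simulation utilities (for verification and OPE experiments)
# ---------------------------------------------------------------------------

def sample_episodes(
    mdp: DiscreteMDP,
    policy_probs: np.ndarray,
    n_episodes: int,
    seed: int,
    start_dist: np.ndarray | None = None,
    max_len: int = 500,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Sample episodes (s, a, s') from the estimated model under a policy.

    Episodes end on reaching a terminal or after ``max_len`` steps. Returns a
    list of (states, actions, successors) arrays per episode.
    """
    rng = np.random.default_rng(seed)
    if start_dist is None:
        start_dist = np.zeros(mdp.k)
        np.add.at(start_dist, mdp.t_state, 1.0)
        start_dist /= start_dist.sum()
    # successor lookup per admissible (s, a)
    succ: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for s, a in zip(*np.nonzero(mdp.admissible)):
        m = (mdp.u_state == s) & (mdp.u_action == a)
        succ[(int(s), int(a))] = (mdp.u_next[m], mdp.u_prob[m])
    episodes = []
    for _ in range(n_episodes):
        s = int(rng.choice(mdp.k, p=start_dist))
        ss, aa, nn = [], [], []
        for _ in range(max_len):
            p = policy_probs[s]
            a = int(rng.choice(mdp.n_actions, p=p))
            nxt, prob = succ[(s, a)]
            sn = int(rng.choice(nxt, p=prob))
            ss.append(s)
            aa.append(a)
            nn.append(sn)
            if sn >= mdp.k:
                break
            s = sn
        episodes.append((np.array(ss), np.array(aa), np.array(nn)))
    return episodes


def make_random_mdp(
    n_states: int,
    n_actions: int,
    seed: int,
    terminal_prob: float = 0.15,
    n_episodes: int = 1500,
) -> tuple[DiscreteMDP, RewardTable]:
    """Random episodic MDP realized as an empirical transition dataset.

    Each (s, a) reaches a terminal with probability ``terminal_prob`` (sign of
    the terminal split at random) and otherwise moves to a random state drawn
    from a Dirichlet row. The returned MDP is *estimated from sampled
    episodes* under a uniform policy, so Q-learning on its transition list and
    value iteration on its model target the same empirical object.
    """
    rng = np.random.default_rng(seed)
    probs = np.zeros((n_states, n_actions, n_states + 2))
    for s in range(n_states):
        for a in range(n_actions):
            row = rng.dirichlet(np.ones(n_states)) * (1.0 - terminal_prob)
            term = terminal_prob * rng.uniform()
            probs[s, a, :n_states] = row
            probs[s, a, n_states] = term
            probs[s, a, n_states + 1] = terminal_prob - term
    r_sa = rng.uniform(0.0, 10.0, size=(n_states, n_actions))

    ss, aa, nn = [], [], []
    for _ in range(n_episodes):
        s = int(rng.integers(n_states))
        for _ in range(200):
            a = int(rng.integers(n_actions))
            sn = int(rng.choice(n_states + 2, p=probs[s, a]))
            ss.append(s)
            aa.append(a)
            nn.append(sn)
            if sn >= n_states:
                break
            s = sn
    mdp = mdp_from_transitions(np.array(ss), np.array(aa), np.array(nn),
                               k=n_states, n_actions=n_actions, gamma=0.9,
                               min_count=1)
    rewards = RewardTable(r_sa=r_sa, terminal_magnitude=rng.uniform(5.0, 20.0))
    return mdp, rewards
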