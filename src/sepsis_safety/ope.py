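"""Off-policy policy evaluation with weighted importance sampling.

Estimates the value of a target treatment policy from trajectories generated
by a different (behaviour) policy. Per-stay importance weights are products of
per-step probability ratios; the value estimate is the self-normalized
(weighted) average of discounted returns, which trades a small bias for much
lower variance than plain importance sampling. Confidence bounds come from a
seeded stay-level bootstrap (stays are the independent sampling units).

By default returns are computed under the *unpenalized* reward (terminal
+/-R only) so that behaviour, original, and safety-constrained policies are
compared on a common scale; the penalized reward is available by flag, noting
that it mechanically lowers the value of any policy evaluated in the
penalized world.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mdp import DiscreteMDP, RewardTable

__all__ = [
    "OPEError",
    "SoftPolicy",
    "OPEEstimate",
    "estimate_behaviour_policy",
    "soften_greedy",
    "stay_returns",
    "stay_weights",
    "wis_value",
    "bootstrap_value",
]


class OPEError(ValueError):
    """Off-policy evaluation failed."""


@dataclass
class SoftPolicy:
    """A stochastic policy: per-state probability vector over the 25 actions.

    ``defined`` marks states the policy covers; rows of undefined states are
    zero. Every action observed in data at a defined state has positive
    probability for the (smoothed) behaviour estimate.
    """

    probs: np.ndarray
    defined: np.ndarray
    epsilon: float = 0.0

    def __post_init__(self):
        row_sums = self.probs[self.defined].sum(axis=1)
        if self.defined.any() and not np.allclose(row_sums, 1.0, atol=1e-9):
            raise OPEError("policy rows must sum to 1 on defined states")


def estimate_behaviour_policy(
    mdp: DiscreteMDP,
    smoothing: float = 0.01,
) -> SoftPolicy:
    """Empirical per-state action frequencies with additive smoothing.

    Smoothing mass ``smoothing`` is added to every *admissible* action of a
    visited state before renormalizing, so importance ratios stay finite for
    any evaluated policy restricted to admissible actions. States never
    visited are excluded with a warning.
    """
    counts = mdp.counts.astype(float)
    visited = counts.sum(axis=1) > 0
    if not visited.all():
        warnings.warn(f"{int((~visited).sum())} state(s) never visited; "
                      "excluded from the behaviour policy", stacklevel=2)
    probs = np.zeros_like(counts)
    smooth = counts + smoothing * mdp.admissible
    # a state can have observations only on inadmissible actions when
    # min_count masking relaxed them away; keep raw frequencies there
    rows = smooth.sum(axis=1)
    use_smooth = visited & (mdp.admissible.any(axis=1))
    probs[use_smooth] = smooth[use_smooth] / rows[use_smooth, None]
    only_raw = visited & ~use_smooth
    probs[only_raw] = counts[only_raw] / counts[only_raw].sum(axis=1, keepdims=True)
    return SoftPolicy(probs=probs, defined=visited, epsilon=smoothing)


def soften_greedy(policy: np.ndarray, mdp: DiscreteMDP, epsilon: float = 0.01) -> SoftPolicy:
    """Soften a deterministic policy: greedy action gets ``1 - epsilon``, the
    remainder spread uniformly over the other admissible actions.
    """
    if not 0.0 <= epsilon < 1.0:
        raise OPEError("epsilon must be in [0, 1)")
    policy = np.asarray(policy)
    k, nA = mdp.admissible.shape
    probs = np.zeros((k, nA))
    defined = policy >= 0
    for s in np.flatnonzero(defined):
        a = int(policy[s])
        others = np.flatnonzero(mdp.admissible[s])
        others = others[others != a]
        if others.size and epsilon > 0:
            probs[s, a] = 1.0 - epsilon
            probs[s, others] = epsilon / others.size
        else:
            probs[s, a] = 1.0
    return SoftPolicy(probs=probs, defined=defined, epsilon=epsilon)


def _stay_slices(stay_of_step: np.ndarray) -> list[np.ndarray]:
    _, starts = np.unique(stay_of_step, return_index=True)
    starts = np.sort(starts)
    bounds = np.append(starts, len(stay_of_step))
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(len(starts))]


def stay_returns(
    mdp: DiscreteMDP,
    rewards: RewardTable,
    stay_of_step: np.ndarray,
    state_ids: np.ndarray,
    action_idx: np.ndarray,
    survived: np.ndarray,
    unsafe_any: np.ndarray | None = None,
    penalty: float = 0.0,
) -> np.ndarray:
    """Discounted return of each stay's recorded trajectory.

    Terminal reward ±R arrives with the last step's discount. When
    ``penalty > 0`` an instance-level penalty is charged at every step whose
    recorded decision was unsafe (any scenario).
    """
    gamma = mdp.gamma
    slices = _stay_slices(np.asarray(stay_of_step))
    out = np.empty(len(slices))
    unsafe = np.zeros(len(state_ids)) if unsafe_any is None else np.asarray(unsafe_any, float)
    for j, rows in enumerate(slices):
        Tn = len(rows)
        disc = gamma ** np.arange(Tn)
        ret = -penalty * float(disc @ unsafe[rows])
        ret += disc[-1] * (rewards.terminal_magnitude if survived[j] else -rewards.terminal_magnitude)
        out[j] = ret
    return out


def stay_weights(
    eval_policy: SoftPolicy,
    behaviour: SoftPolicy,
    stay_of_step: np.ndarray,
    state_ids: np.ndarray,
    action_idx: np.ndarray,
) -> np.ndarray:
    """Per-stay importance weight: product over steps of eval(a|s)/beh(a|s)."""
    state_ids = np.asarray(state_ids)
    action_idx = np.asarray(action_idx)
    b = behaviour.probs[state_ids, action_idx]
    if (b <= 0).any():
        bad = int(np.flatnonzero(b <= 0)[0])
        raise OPEError(
            f"behaviour probability is zero for observed action {int(action_idx[bad])} "
            f"in state {int(state_ids[bad])}; increase smoothing")
    e = eval_policy.probs[state_ids, action_idx]
    log_ratio = np.log(np.maximum(e, 1e-300)) - np.log(b)
    slices = _stay_slices(np.asarray(stay_of_step))
    w = np.array([np.exp(log_ratio[rows].sum()) for rows in slices])
    return w


def wis_value(weights: np.ndarray, returns: np.ndarray) -> float:
    """Self-normalized importance-sampling estimate sum(w*G)/sum(w)."""
    weights = np.asarray(weights, float)
    returns = np.asarray(returns, float)
    if len(weights) != len(returns) or len(weights) == 0:
        raise OPEError("weights and returns must be equal-length and non-empty")
    total = weights.sum()
    if total <= 0:
        raise OPEError("all importance weights are zero")
    return float((weights * returns).sum() / total)


@dataclass
class OPEEstimate:
    """A WIS value with its stay-level bootstrap distribution."""

    value: float
    replicates: np.ndarray
    B: int
    seed: int
    median: float = field(init=False)
    iqr: tuple[float, float] = field(init=False)

    def __post_init__(self):
        self.median = float(np.median(self.replicates))
        q1, q3 = np.percentile(self.replicates, [25.0, 75.0])
        self.iqr = (float(q1), float(q3))


def bootstrap_value(
    weights: np.ndarray,
    returns: np.ndarray,
    B: int = 2000,
    seed: int = 0,
) -> OPEEstimate:
    """Stay-level bootstrap of the WIS estimate (median and IQR reported)."""
    if B < 1:
        raise OPEError("B must be >= 1")
    weights = np.asarray(weights, float)
    returns = np.asarray(returns, float)
    n = len(weights)
    if n == 0:
        raise OPEError("empty cohort")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    w = weights[idx]
    g = returns[idx]
    denom = w.sum(axis=1)
    # a resample of all-zero weights is degenerate; fall back to the point value
    point = wis_value(weights, returns)
    with np.errstate(invalid="ignore", divide="ignore"):
        reps = np.where(denom > 0, (w * g).sum(axis=1) / denom, point)
    return OPEEstimate(value=point, replicates=reps, B=B, seed=seed)
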