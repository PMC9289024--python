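"""Human-vs-AI unsafe-decision statistics and feature attribution.

The core comparison models each agent's unsafe decisions among the N at-risk
steps as Bernoulli(p) draws and tests H0: p_human = p_ai with the two-sample
proportion z statistic

    z = (p̂_AI - p̂_Human) / sqrt( p̂ (1 - p̂) * 2 / N ),

where p̂_AI = x_AI / N, p̂_Human = x_Human / N and p̂ = (p̂_Human + p̂_AI) / 2 is
the pooled proportion (both agents are evaluated on the same N at-risk
steps). p values use the standard Gaussian CDF; the default alternative is
one-sided "AI less unsafe than human".

Feature attribution of unsafe *clinician* decisions uses gradient-boosted
trees (one model per scenario, fitted on at-risk steps) explained with exact
TreeSHAP per-observation attributions; features are ranked by mean absolute
attribution, reported relative to the top feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import norm

from .hazards import FlagTable

__all__ = [
    "StatsError",
    "ProportionTest",
    "ztest_components",
    "two_proportion_ztest",
    "compare_policies",
    "significance_sweep",
    "unsafe_rate_percent",
    "relative_reduction_percent",
    "fit_unsafe_classifier",
    "AttributionReport",
    "attribution",
]


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass
class ProportionTest:
    """The two-proportion z-test record for one scenario and agent pair."""

    n: int
    x_human: int
    x_ai: int
    p_human: float
    p_ai: float
    p_pooled: float
    z: float
    p_value: float
    sided: str


def ztest_components(x_human, x_ai, n):
    """Vectorized z statistic of the pooled two-proportion test.

    Degenerate pooled proportions (0 or 1) give z = 0 when the counts agree
    and ±inf otherwise.
    """
    x_human = np.asarray(x_human, dtype=float)
    x_ai = np.asarray(x_ai, dtype=float)
    n = np.asarray(n, dtype=float)
    p_h = x_human / n
    p_a = x_ai / n
    pooled = (p_h + p_a) / 2.0
    var = pooled * (1.0 - pooled) * 2.0 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p_a - p_h) / np.sqrt(var)
    degenerate = var == 0
    if np.ndim(z) == 0:
        if degenerate:
            z = 0.0 if x_ai == x_human else np.copysign(np.inf, p_a - p_h)
        return float(z), float(p_h), float(p_a), float(pooled)
    with np.errstate(invalid="ignore"):
        z = np.where(degenerate, np.where(x_ai == x_human, 0.0,
                                          np.sign(p_a - p_h) * np.inf), z)
    return z, p_h, p_a, pooled


def two_proportion_ztest(x_human: int, x_ai: int, n: int,
                         sided: str = "one-sided") -> ProportionTest:
    """Test H0: p_human = p_ai from counts on a shared at-risk denominator.

    ``sided``: 'one-sided' tests the alternative p_AI < p_Human (small p
    favours the AI being safer); 'two-sided' uses 2 * Phi(-|z|).
    """
    if n <= 0:
        raise StatsError("undefined test: at-risk count N must be positive")
    if not (0 <= x_human <= n and 0 <= x_ai <= n):
        raise StatsError("unsafe counts must lie in [0, N]")
    if sided not in ("one-sided", "two-sided"):
        raise StatsError(f"unknown sidedness {sided!r}")
    z, p_h, p_a, pooled = ztest_components(x_human, x_ai, n)
    if sided == "one-sided":
        p_value = float(norm.cdf(z))      # Phi(±inf) handles degenerate z
    else:
        p_value = float(2.0 * norm.cdf(-abs(z)))
    return ProportionTest(n=int(n), x_human=int(x_human), x_ai=int(x_ai),
                          p_human=p_h, p_ai=p_a, p_pooled=pooled,
                          z=float(z), p_value=p_value, sided=sided)


def compare_policies(
    flag_table: FlagTable,
    sided: str = "one-sided",
) -> tuple[pd.DataFrame, dict[tuple[str, str], ProportionTest]]:
    """Per-scenario unsafe proportions for every agent, plus pairwise tests.

    Returns a tidy frame (scenario, agent, N, x, proportion) and a dict of
    human-vs-policy :class:`ProportionTest` keyed by (scenario, policy). All
    agents share the same at-risk denominator by construction of the flags.
    """
    rows = []
    tests: dict[tuple[str, str], ProportionTest] = {}
    for sid in flag_table.scenario_ids:
        n, x_h = flag_table.counts(sid, "human")
        rows.append({"scenario": sid, "agent": "human", "N": n, "x": x_h,
                     "proportion": x_h / n if n else np.nan})
        for agent in flag_table.agents[1:]:
            n2, x = flag_table.counts(sid, agent)
            if n2 != n:
                raise StatsError(
                    f"at-risk N mismatch for scenario {sid}: {n} vs {n2}")
            rows.append({"scenario": sid, "agent": agent, "N": n, "x": x,
                         "proportion": x / n if n else np.nan})
            if n > 0:
                tests[(sid, agent)] = two_proportion_ztest(x_h, x, n, sided=sided)
    return pd.DataFrame(rows), tests


def significance_sweep(sweep: pd.DataFrame, policy: str = "ai",
                       sided: str = "one-sided") -> pd.DataFrame:
    """Attach z and p to a threshold sweep (one test per threshold).

    Thresholds with N = 0 are kept but recorded as undefined (NaN). No
    multiplicity adjustment is applied by default; pass the result through
    :func:`bonferroni` if a corrected column is wanted.
    """
    col = f"x_{policy}"
    if col not in sweep.columns:
        raise StatsError(f"sweep has no column {col!r}")
    zs, ps = [], []
    for _, row in sweep.iterrows():
        if row["N"] == 0:
            zs.append(np.nan)
            ps.append(np.nan)
            continue
        t = two_proportion_ztest(int(row["x_human"]), int(row[col]),
                                 int(row["N"]), sided=sided)
        zs.append(t.z)
        ps.append(t.p_value)
    out = sweep.copy()
    out["z"] = zs
    out["p_value"] = ps
    return out


def bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni-corrected p values across a sweep (off by default)."""
    p = np.asarray(p_values, float)
    m = np.isfinite(p).sum()
    return np.clip(p * m, 0.0, 1.0)


def unsafe_rate_percent(x: int, n: int) -> float:
    """Unsafe (or at-risk) count as a percentage of its denominator."""
    if n <= 0:
        raise StatsError("denominator must be positive")
    return 100.0 * x / n


def relative_reduction_percent(x_reference: int, x_new: int) -> float:
    """Relative reduction of a count versus a reference, in percent."""
    if x_reference <= 0:
        raise StatsError("reference count must be positive")
    return 100.0 * (x_reference - x_new) / x_reference


# ---------------------------------------------------------------------------
# Gradient boosting + TreeSHAP attribution
# ---------------------------------------------------------------------------

_GBM_DEFAULTS = dict(n_estimators=150, max_depth=3, learning_rate=0.1,
                     subsample=1.0, n_jobs=1, tree_method="hist",
                     eval_metric="logloss")


def fit_unsafe_classifier(features: pd.DataFrame, unsafe: np.ndarray,
                          seed: int = 0, **overrides) -> xgb.XGBClassifier:
    """Fit a gradient-boosted tree classifier of unsafe clinician decisions.

    One model per scenario is intended: fit on that scenario's at-risk steps
    with the step's feature vector as input and the unsafe flag as label.
    Deterministic under a fixed seed.
    """
    y = np.asarray(unsafe).astype(int)
    if len(np.unique(y)) < 2:
        raise StatsError("labels are single-class; cannot fit the classifier")
    params = _GBM_DEFAULTS | overrides
    model = xgb.XGBClassifier(random_state=int(seed) % (2 ** 31), **params)
    model.fit(features, y)
    return model


@dataclass
class AttributionReport:
    """Ranked per-feature attribution of a fitted unsafe-decision model.

    ``values`` holds per-observation signed attributions (log-odds scale,
    positive pushes toward 'unsafe'); ``mean_abs`` the global importance;
    ``relative`` the importance normalized to the top feature; ``direction``
    the sign of the feature-vs-attribution correlation (+1 when high feature
    values push toward unsafe).
    """

    features: list[str]
    mean_abs: np.ndarray
    relative: np.ndarray
    direction: np.ndarray
    values: np.ndarray

    def ranking(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.features,
                             "mean_abs_attribution": self.mean_abs,
                             "relative_importance": self.relative,
                             "direction": self.direction})


def attribution(model: xgb.XGBClassifier, features: pd.DataFrame) -> AttributionReport:
    """Exact TreeSHAP attributions of the fitted model on a feature table.

    Rows of the returned ranking are sorted by mean |attribution| descending.
    """
    trained = list(model.get_booster().feature_names or [])
    if trained and trained != list(features.columns):
        raise StatsError(
            "feature table does not match the training schema: "
            f"expected {trained}, got {list(features.columns)}")
    contribs = model.get_booster().predict(
        xgb.DMatrix(features), pred_contribs=True)[:, :-1]  # drop bias term
    mean_abs = np.abs(contribs).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    X = features.to_numpy(float)
    direction = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if X[:, j].std() > 0 and contribs[:, j].std() > 0:
            direction[j] = np.sign(np.corrcoef(X[:, j], contribs[:, j])[0, 1])
    top = mean_abs[order[0]]
    relative = mean_abs / top if top > 0 else np.zeros_like(mean_abs)
    return AttributionReport(
        features=[features.columns[i] for i in order],
        mean_abs=mean_abs[order], relative=relative[order],
        direction=direction[order], values=contribs)
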