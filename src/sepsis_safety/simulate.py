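"""Synthetic ICU sepsis cohort generator.

Emulates the statistical structure of an ICU sepsis cohort observed on a
4-hour decision grid: hypotension episodes that respond to fluids and
vasopressors, fluid-balance accumulation driving central venous pressure,
severity-linked mortality, and a guideline-like behaviour policy that takes
each hazard scenario's unsafe action with a configurable propensity whenever
the patient is at risk. Every downstream stage (flagging, RL training,
off-policy evaluation) can therefore be tested against known ground truth
without any data download.

Determinism: all random draws are generated up front from a single seeded
``numpy.random.Generator``, so an identical :class:`SimConfig` always yields
a byte-identical cohort, and raising a mortality coefficient can only move
each stay's death earlier (states do not depend on mortality coefficients).

Severity is a latent driver and is *not* emitted in the feature table, so
state clustering faces realistic partial observability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .hazards import at_risk, default_scenarios, is_unsafe

__all__ = ["SimConfig", "GroundTruth", "generate_cohort", "ground_truth_summary"]

SCENARIO_IDS = ("A", "B", "C", "D")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Propensities default near the observed clinician unsafe-action rates of
    the four hazard scenarios (roughly 0.54 / 0.025 / 0.54 / 0.37); physiology
    and mortality coefficients are chosen to give a plausibly septic cohort:
    a few percent of steps hypotensive below 55 mm Hg, roughly a tenth
    hypertensive above 95 mm Hg, rare but present fluid-overload states, and
    double-digit percent mortality concentrated in severe, under-resuscitated
    stays.
    """

    n_stays: int = 500
    max_steps: int = 18            # 18 steps of 4 h = 72 h
    step_hours: float = 4.0
    seed: int = 0

    #: per-scenario probability that the behaviour policy takes the
    #: scenario's unsafe action when the patient is at risk
    unsafe_propensity: dict = field(
        default_factory=lambda: {"A": 0.5, "B": 0.03, "C": 0.5, "D": 0.35})

    # --- physiology coefficients -----------------------------------------
    map_baseline: float = 87.0       # mm Hg population homeostatic set point
    map_baseline_sd: float = 10.0    # per-stay set-point spread (chronic hyper/hypotension)
    map_severity_offset: float = 14.0  # initial MAP deficit per unit severity
    map_init_sd: float = 8.0
    fluid_map_gain: float = 5.0      # mm Hg per log1p(fluid mL / 250)
    vaso_map_gain: float = 22.0      # mm Hg per ug/kg/min
    # preload dependence of drug effect: fluid responsiveness is high on the
    # steep (low-CVP) part of the Starling curve and flat when overloaded;
    # vasopressors lose effect in frank hypovolaemia
    fluid_resp_floor: float = 0.6
    fluid_resp_gain: float = 0.8
    fluid_cvp_midpoint: float = 8.0
    vaso_resp_floor: float = 0.45
    vaso_resp_gain: float = 0.55
    vaso_cvp_midpoint: float = 4.0
    severity_map_drain: float = 4.8  # mm Hg lost per unit severity per step
    map_reversion: float = 0.12      # autoregulatory pull toward the set point
    map_noise_sd: float = 4.5
    cvp_baseline: float = 5.0        # mm Hg at zero balance
    cvp_balance_gain: float = 1.1    # mm Hg per litre of cumulative balance
    cvp_noise_sd: float = 1.5
    urine_base: float = 180.0        # mL per step when well perfused & healthy
    urine_noise_sd: float = 25.0
    lactate_noise_sd: float = 0.4
    maintenance_ml_per_step: float = 50.0
    severity_drift_sd: float = 0.04

    # --- per-step logistic death hazard ----------------------------------
    mort_intercept: float = -6.4
    mort_severity: float = 2.1          # per unit latent severity
    mort_hypotension: float = 0.18      # per accumulated step with MAP < 60
    mort_fluid_overload: float = 0.07   # per litre of balance above 5 L

    def validate(self) -> None:
        if self.n_stays <= 0 or self.max_steps <= 0:
            raise SimConfigError("n_stays and max_steps must be positive")
        if self.step_hours <= 0:
            raise SimConfigError("step_hours must be positive")
        for sid in SCENARIO_IDS:
            p = self.unsafe_propensity.get(sid, 0.0)
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"unsafe propensity for scenario {sid} not in [0, 1]")

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class GroundTruth:
    """Realized per-scenario risk/unsafe counts and mortality of one run."""

    unsafe_propensity: dict
    at_risk_counts: dict
    unsafe_counts: dict
    n_stays: int
    n_steps: int
    deaths: int

    @property
    def mortality(self) -> float:
        return self.deaths / self.n_stays

    def to_json(self) -> str:
        return json.dumps(asdict(self) | {"mortality": self.mortality}, indent=1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Simulate a cohort of ICU stays under the configured behaviour policy.

    Returns the cohort (one row per surviving 4-h step, features rounded to
    fixed decimals so files round-trip exactly) and the realized ground truth.
    """
    config.validate()
    n, T = config.n_stays, config.max_steps
    rng = np.random.default_rng(config.seed)
    scenarios = default_scenarios()
    prop = {sid: float(config.unsafe_propensity.get(sid, 0.0)) for sid in SCENARIO_IDS}

    # ---- all randomness drawn up front ----------------------------------
    sev = np.clip(rng.normal(0.55, 0.28, n), 0.05, 1.5)
    sev_drift = rng.normal(0.0, config.severity_drift_sd, (n, T))
    weight = np.round(np.clip(rng.normal(80.0, 15.0, n), 40.0, 140.0), 1)
    set_point = rng.normal(config.map_baseline, config.map_baseline_sd, n)
    map_now = np.clip(rng.normal(set_point - config.map_severity_offset * sev,
                                 config.map_init_sd), 35.0, 130.0)
    balance = np.round(rng.gamma(2.0, (800.0 + 3600.0 * sev) / 2.0))
    map_noise = rng.normal(0.0, config.map_noise_sd, (n, T))
    cvp_noise = rng.normal(0.0, config.cvp_noise_sd, (n, T))
    urine_noise = rng.normal(0.0, config.urine_noise_sd, (n, T))
    lact_noise = rng.normal(0.0, config.lactate_noise_sd, (n, T))
    sed_u = rng.uniform(size=(n, T))
    fluid_jit = np.exp(rng.normal(0.0, 0.35, (n, T)))   # bolus-size variability
    vaso_jit = rng.uniform(0.0, 0.10, (n, T))
    combo_u = rng.uniform(size=(n, T))                  # fluid+pressor combos
    combo_dose = rng.uniform(0.04, 0.24, (n, T))
    vonly_u = rng.uniform(size=(n, T))                  # pressor-only strategy
    vonly_dose = rng.uniform(0.06, 0.26, (n, T))
    unsafe_u = rng.uniform(size=(n, T, len(SCENARIO_IDS)))
    ov_fluid_u = rng.uniform(size=(n, T))
    ov_vaso_u = rng.uniform(size=(n, T))
    death_u = rng.uniform(size=(n, T))

    map_now = np.round(map_now, 1)
    hypo_steps = np.zeros(n)          # accumulated steps with MAP < 60
    active = np.ones(n, dtype=bool)
    died = np.zeros(n, dtype=bool)

    at_risk_counts = {sid: 0 for sid in SCENARIO_IDS}
    unsafe_counts = {sid: 0 for sid in SCENARIO_IDS}
    rows: list[dict] = []
    step_hours = float(config.step_hours)

    for t in range(T):
        if not active.any():
            break
        if t > 0:
            sev = np.clip(sev + sev_drift[:, t], 0.05, 1.5)

        cvp = np.round(np.clip(config.cvp_baseline
                               + config.cvp_balance_gain * balance / 1000.0
                               + cvp_noise[:, t], 0.0, 30.0), 1)
        perfusion = _sigmoid((map_now - 60.0) / 8.0)
        urine = np.round(np.clip(config.urine_base * (1.0 - 0.55 * sev / 1.5) * perfusion
                                 + urine_noise[:, t], 0.0, 600.0))
        lactate = np.round(np.clip(0.8 + 1.6 * sev + 0.35 * hypo_steps
                                   + lact_noise[:, t], 0.3, 25.0), 2)
        sofa = np.clip(np.rint(16.0 * sev / 1.5
                               + 3.0 * np.clip(65.0 - map_now, 0.0, 30.0) / 30.0
                               + 2.0 * (1.0 - np.clip(urine / 200.0, 0.0, 1.0))),
                       0, 24).astype(int)
        sedation = (sed_u[:, t] < 0.20 + 0.35 * sev / 1.5).astype(int)

        # ---- guideline-like behaviour: target MAP 65-90, with realistic
        # clinician heterogeneity (bolus-size spread, fluid+pressor combos,
        # a pressor-only strategy for moderate hypotension) ----------------
        bolus = np.where(map_now < 45.0, 1000.0,
                         np.where(map_now < 55.0, 600.0,
                                  np.where((map_now < 65.0) & (cvp < 12.0), 300.0, 0.0)))
        fluid = np.round(bolus * fluid_jit[:, t] / 10.0) * 10.0
        vaso = np.where(map_now < 55.0, 0.12 + 0.015 * (55.0 - map_now),
                        np.where(map_now < 60.0, 0.08, 0.0))
        vaso = np.where(vaso > 0, np.minimum(vaso + vaso_jit[:, t], 1.5), 0.0)
        combo = (map_now < 65.0) & (fluid > 0) & (combo_u[:, t] < 0.35)
        vaso = np.where(combo, np.maximum(vaso, combo_dose[:, t]), vaso)
        # pressor-only strategy only for volume-replete patients (CVP >= 8)
        vonly = (map_now > 55.0) & (map_now < 65.0) & (cvp >= 8.0) & (vonly_u[:, t] < 0.25)
        fluid = np.where(vonly, 0.0, fluid)
        vaso = np.where(vonly, vonly_dose[:, t], vaso)

        # ---- hazard overrides with configured propensities ---------------
        feats = {"map_mmhg": map_now, "cvp_mmhg": cvp, "cumulative_balance_ml": balance}
        risk = {sid: np.asarray(at_risk(feats, scenarios[sid])) for sid in SCENARIO_IDS}
        fire = {sid: risk[sid] & (unsafe_u[:, t, i] < prop[sid])
                for i, sid in enumerate(SCENARIO_IDS)}

        # A: withhold everything — no pressors, no fluids. (Scenario C is a
        # subset of scenario A's at-risk region, so A-type withholding at a
        # low-CVP step is counted as unsafe under both by the predicates.)
        fluid = np.where(fire["A"], 0.0, fluid)
        vaso = np.where(fire["A"], 0.0, vaso)
        # C: no fluids at all; keep a token pressor unless A also fired
        fluid = np.where(fire["C"], 0.0, fluid)
        vaso = np.where(fire["C"] & ~fire["A"], 0.10 + 0.10 * ov_vaso_u[:, t], vaso)
        # B: maximum-dose pressors despite high MAP
        vaso = np.where(fire["B"], 0.75 + 0.60 * ov_vaso_u[:, t], vaso)
        # D: maximum-dose fluids despite overload
        fluid = np.where(fire["D"], np.round(1040.0 + 560.0 * ov_fluid_u[:, t]), fluid)

        vaso = np.round(vaso, 4)
        total_input = fluid + config.maintenance_ml_per_step

        # realized counts use the hazard predicates on the final action, so
        # they are reproducible by re-flagging the emitted cohort
        fluid_rate = fluid / step_hours
        for sid in SCENARIO_IDS:
            unsafe_now = np.asarray(
                is_unsafe(feats, fluid_rate, vaso, scenarios[sid]))
            at_risk_counts[sid] += int((risk[sid] & active).sum())
            unsafe_counts[sid] += int((unsafe_now & active).sum())

        idx = np.flatnonzero(active)
        rows.append({
            "stay_id": idx, "step_index": t,
            "map_mmhg": map_now[idx], "cvp_mmhg": cvp[idx],
            "cumulative_balance_ml": balance[idx], "urine_output_ml": urine[idx],
            "sofa": sofa[idx], "lactate_mmol_l": lactate[idx],
            "sedation": sedation[idx], "total_fluid_input_ml": total_input[idx],
            "weight_kg": weight[idx], "action_fluid_ml": fluid[idx],
            "action_vaso_ug_kg_min": vaso[idx],
        })

        # ---- end-of-step death hazard ------------------------------------
        overload_l = np.clip((balance - 5000.0) / 1000.0, 0.0, None)
        p_death = _sigmoid(config.mort_intercept
                           + config.mort_severity * sev
                           + config.mort_hypotension * hypo_steps
                           + config.mort_fluid_overload * overload_l)
        new_death = active & (death_u[:, t] < p_death)
        died |= new_death
        active &= ~new_death

        # ---- dynamics to the next step -----------------------------------
        hypo_steps = hypo_steps + (map_now < 60.0)
        balance = balance + total_input - urine
        fluid_resp = (config.fluid_resp_floor + config.fluid_resp_gain
                      * _sigmoid((config.fluid_cvp_midpoint - cvp) / 2.0))
        vaso_resp = (config.vaso_resp_floor + config.vaso_resp_gain
                     * _sigmoid((cvp - config.vaso_cvp_midpoint) / 2.0))
        map_next = (map_now
                    + config.fluid_map_gain * np.log1p(fluid / 250.0) * fluid_resp
                    + config.vaso_map_gain * vaso * vaso_resp
                    - config.severity_map_drain * sev
                    + config.map_reversion * (set_point - map_now)
                    + map_noise[:, t])
        map_now = np.round(np.clip(map_next, 30.0, 140.0), 1)

    survived = ~died
    frames = []
    for r in rows:
        idx = r.pop("stay_id")
        t = r.pop("step_index")
        df = pd.DataFrame(r)
        df.insert(0, "stay_id", [f"stay{j:05d}" for j in idx])
        df.insert(1, "step_index", t)
        df["survived_90d"] = survived[idx].astype(int)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["stay_id", "step_index"], kind="stable").reset_index(drop=True)

    cohort = Cohort(table, provenance=f"synthetic:{config.config_hash()}")
    gt = GroundTruth(unsafe_propensity=dict(prop), at_risk_counts=at_risk_counts,
                     unsafe_counts=unsafe_counts, n_stays=n, n_steps=len(table),
                     deaths=int(died.sum()))
    return cohort, gt


def ground_truth_summary(gt: GroundTruth) -> pd.DataFrame:
    """Per-scenario at-risk count, unsafe count and unsafe rate.

    A scenario with zero at-risk steps gets a missing (NaN) rate.
    """
    rows = []
    for sid in SCENARIO_IDS:
        n = gt.at_risk_counts.get(sid, 0)
        x = gt.unsafe_counts.get(sid, 0)
        rows.append({"scenario": sid, "at_risk": n, "unsafe": x,
                     "rate": (x / n) if n > 0 else np.nan})
    return pd.DataFrame(rows)
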