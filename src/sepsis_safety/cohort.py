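"""Trajectory data model for ICU sepsis stays.

A cohort is a flat table with one row per 4-hour decision point, carrying the
clinical features a clinician (or policy) sees when dosing, the doses actually
given at that step, and the stay-level survival outcome repeated on every row.

This module also owns the two discretizations used by the offline-RL pipeline:

* :class:`ActionGrid` — the 5x5 dose grid (25 composed actions) built from
  per-drug dose quartiles, with bin 0 reserved for an exactly-zero dose;
* :class:`StateModel` — a k-means clustering of standardized observables into
  ``k`` patient states plus two absorbing terminals (survival, death).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "COLUMN_UNITS",
    "REQUIRED_COLUMNS",
    "CohortError",
    "CohortFormatError",
    "Stay",
    "Cohort",
    "write_cohort",
    "read_cohort",
    "DoseBins",
    "ActionGrid",
    "discretize_actions",
    "StateModel",
    "fit_state_clusters",
    "assign_states",
]

#: Canonical column names and their units. ``sedation`` and ``survived_90d``
#: are 0/1 indicators; everything else is a float.
COLUMN_UNITS: dict[str, str] = {
    "stay_id": "identifier",
    "step_index": "ordinal (0-based, consecutive within a stay)",
    "map_mmhg": "mm Hg (mean arterial pressure)",
    "cvp_mmhg": "mm Hg (central venous pressure)",
    "cumulative_balance_ml": "mL (running fluid inputs minus urine, at decision time)",
    "urine_output_ml": "mL over the step",
    "sofa": "integer 0-24",
    "lactate_mmol_l": "mmol/L",
    "sedation": "0/1",
    "total_fluid_input_ml": "mL over the step (treatment + maintenance)",
    "weight_kg": "kg",
    "action_fluid_ml": "mL of IV fluid given this step (treatment dose)",
    "action_vaso_ug_kg_min": "ug/kg/min vasopressor rate this step",
    "survived_90d": "0/1 (stay outcome, constant within a stay)",
}

REQUIRED_COLUMNS: tuple[str, ...] = tuple(COLUMN_UNITS)

NUMERIC_COLUMNS = tuple(c for c in REQUIRED_COLUMNS if c != "stay_id")

#: Default feature set for state clustering: the observables only. Latent
#: severity is deliberately absent so state construction faces the same
#: partial observability as it would on real EHR data.
DEFAULT_STATE_FEATURES: tuple[str, ...] = (
    "map_mmhg",
    "cvp_mmhg",
    "cumulative_balance_ml",
    "urine_output_ml",
    "sofa",
    "lactate_mmol_l",
    "sedation",
    "total_fluid_input_ml",
    "weight_kg",
)


class CohortError(ValueError):
    """Invalid cohort content (violated invariant)."""


class CohortFormatError(CohortError):
    """Malformed cohort file: names the offending column or row."""


@dataclass
class Stay:
    """One ICU stay: an ordered block of timesteps and its outcome."""

    stay_id: object
    table: pd.DataFrame
    survived_90d: bool

    def __len__(self) -> int:
        return len(self.table)


class Cohort:
    """A collection of stays stored as a single validated flat table.

    Parameters
    ----------
    table
        One row per timestep with the :data:`REQUIRED_COLUMNS` (extra numeric
        feature columns are allowed and kept).
    provenance
        Free-text origin tag (synthetic config hash or external source).
    """

    def __init__(self, table: pd.DataFrame, provenance: str = "unspecified"):
        self.table = _validate_table(table)
        self.provenance = provenance

    # -- basic accessors ---------------------------------------------------
    @property
    def n_steps(self) -> int:
        return len(self.table)

    @property
    def stay_ids(self) -> np.ndarray:
        return self.table["stay_id"].unique()

    @property
    def n_stays(self) -> int:
        return self.table["stay_id"].nunique()

    @property
    def extra_features(self) -> list[str]:
        return [c for c in self.table.columns if c not in REQUIRED_COLUMNS]

    def stays(self) -> Iterator[Stay]:
        for sid, block in self.table.groupby("stay_id", sort=False):
            yield Stay(sid, block, bool(block["survived_90d"].iloc[0]))

    def outcomes(self) -> pd.Series:
        """Per-stay survival indicator, indexed by stay_id (data order)."""
        return self.table.groupby("stay_id", sort=False)["survived_90d"].first().astype(bool)

    def fluid_rate_ml_h(self, step_hours: float = 4.0) -> np.ndarray:
        """Treatment fluid dose expressed as a rate in mL/hour."""
        return self.table["action_fluid_ml"].to_numpy(float) / float(step_hours)

    def content_hash(self) -> str:
        payload = self.table.to_csv(index=False, float_format="%.10g").encode()
        return hashlib.sha256(payload).hexdigest()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Cohort(n_stays={self.n_stays}, n_steps={self.n_steps}, provenance={self.provenance!r})"


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")
    table = table.reset_index(drop=True)
    for col in NUMERIC_COLUMNS:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortFormatError(f"non-numeric value in column '{col}' at row {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise CohortFormatError(f"missing value in column '{col}' at row {row}")
        table[col] = coerced.astype(np.float64)  # uniform dtype so files round-trip
    for col in ("map_mmhg", "cvp_mmhg", "action_fluid_ml", "action_vaso_ug_kg_min"):
        if (table[col] < 0).any():
            row = int(np.flatnonzero((table[col] < 0).to_numpy())[0])
            raise CohortError(f"negative {col} at row {row}")
    if ((table["sofa"] < 0) | (table["sofa"] > 24)).any():
        raise CohortError("SOFA out of range [0, 24]")
    for sid, block in table.groupby("stay_id", sort=False):
        steps = block["step_index"].to_numpy()
        if not np.array_equal(steps, np.arange(len(steps))):
            row = int(block.index[0])
            raise CohortFormatError(
                f"step_index not consecutive from 0 for stay {sid!r} (first row {row})"
            )
        if block["survived_90d"].nunique() != 1:
            raise CohortError(f"outcome not constant within stay {sid!r}")
    return table


# ---------------------------------------------------------------------------
# File I/O: comma-separated UTF-8 text with a header row; provenance is kept
# on a leading comment line so the file round-trips the full object.
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as delimited text (one row per timestep)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# provenance: {cohort.provenance}\n")
        cohort.table.to_csv(fh, index=False, float_format="%.10g")
    return path


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Raises :class:`CohortFormatError` naming the offending column/row on
    malformed input.
    """
    path = Path(path)
    provenance = "unspecified"
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# provenance:"):
        provenance = first.split(":", 1)[1].strip()
    try:
        table = pd.read_csv(path, comment="#", dtype={"stay_id": str})
    except pd.errors.ParserError as exc:  # pragma: no cover - rare malformed CSV
        raise CohortFormatError(f"unparseable cohort file {path}: {exc}") from exc
    if table.empty:
        raise CohortFormatError(f"cohort file {path} has no data rows")
    return Cohort(table, provenance=provenance)


# ---------------------------------------------------------------------------
# Action discretization: 5 bins per drug -> 25 composed actions
# ---------------------------------------------------------------------------

N_BINS_PER_DRUG = 5
N_ACTIONS = N_BINS_PER_DRUG * N_BINS_PER_DRUG


@dataclass
class DoseBins:
    """Dose binning for one drug.

    Bin 0 holds exactly-zero doses. Non-zero doses fall into up to four bins
    delimited by ``edges`` (empirical quantiles of the observed non-zero
    doses); bins are left-closed/right-open, the last bin right-closed.
    ``representative`` maps each bin to its within-bin median observed dose
    (exactly 0.0 for bin 0).
    """

    edges: np.ndarray
    representative: np.ndarray
    n_bins: int

    def assign(self, doses: np.ndarray) -> np.ndarray:
        doses = np.asarray(doses, dtype=float)
        if (doses < 0).any():
            raise CohortError("negative dose passed to DoseBins.assign")
        bins = np.zeros(doses.shape, dtype=np.int64)
        nz = doses > 0
        if self.n_bins > 1:
            # left-closed bins: a dose equal to an edge belongs to the upper bin
            bins[nz] = 1 + (doses[nz][:, None] >= self.edges[None, :]).sum(axis=1)
        return bins


def _fit_dose_bins(doses: np.ndarray, drug: str) -> DoseBins:
    doses = np.asarray(doses, dtype=float)
    nonzero = np.sort(doses[doses > 0])
    distinct = np.unique(nonzero)
    if distinct.size == 0:
        warnings.warn(f"all {drug} doses are zero; using a single bin", stacklevel=3)
        return DoseBins(edges=np.empty(0), representative=np.zeros(1), n_bins=1)
    n_nonzero_bins = min(4, distinct.size)
    if n_nonzero_bins < 4:
        warnings.warn(
            f"only {distinct.size} distinct non-zero {drug} doses; "
            f"reducing to {n_nonzero_bins} non-zero bin(s)",
            stacklevel=3,
        )
    probs = np.arange(1, n_nonzero_bins) / n_nonzero_bins
    edges = np.quantile(nonzero, probs) if probs.size else np.empty(0)
    n_bins = n_nonzero_bins + 1
    bins = DoseBins(edges=edges, representative=np.zeros(n_bins), n_bins=n_bins)
    assigned = bins.assign(doses)
    rep = np.zeros(n_bins)
    for b in range(1, n_bins):
        members = doses[(assigned == b) & (doses > 0)]
        if members.size:
            rep[b] = float(np.median(members))
        else:  # empty bin under heavy ties: fall back to the lower edge
            rep[b] = float(edges[b - 2]) if b >= 2 else float(distinct[0])
    bins.representative = rep
    return bins


@dataclass
class ActionGrid:
    """5x5 dose grid: composed action index ``a = 5 * fluid_bin + vaso_bin``.

    The composed index space is always 25 wide even when a drug collapses to
    fewer bins, so indices stay stable across cohorts.
    """

    fluid: DoseBins
    vaso: DoseBins
    step_hours: float = 4.0
    n_actions: int = N_ACTIONS

    def action_index(self, fluid_ml: np.ndarray, vaso: np.ndarray) -> np.ndarray:
        fb = self.fluid.assign(np.asarray(fluid_ml, float))
        vb = self.vaso.assign(np.asarray(vaso, float))
        return N_BINS_PER_DRUG * fb + vb

    def decompose(self, action: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        action = np.asarray(action)
        return action // N_BINS_PER_DRUG, action % N_BINS_PER_DRUG

    def representative_doses(self, action: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map composed action indices to (fluid mL/step, vaso ug/kg/min).

        Bin 0 maps to exactly 0.0, so "no fluids"/"no vasopressors" hazard
        conditions are exactly decidable for policy recommendations.
        """
        fb, vb = self.decompose(action)
        fb = np.minimum(fb, self.fluid.n_bins - 1)
        vb = np.minimum(vb, self.vaso.n_bins - 1)
        return self.fluid.representative[fb], self.vaso.representative[vb]

    def to_json(self) -> str:
        payload = {
            "step_hours": self.step_hours,
            "fluid": {"edges": self.fluid.edges.tolist(),
                      "representative": self.fluid.representative.tolist(),
                      "n_bins": self.fluid.n_bins},
            "vaso": {"edges": self.vaso.edges.tolist(),
                     "representative": self.vaso.representative.tolist(),
                     "n_bins": self.vaso.n_bins},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ActionGrid":
        d = json.loads(text)
        mk = lambda e: DoseBins(np.asarray(e["edges"], float),
                                np.asarray(e["representative"], float), int(e["n_bins"]))
        return cls(fluid=mk(d["fluid"]), vaso=mk(d["vaso"]), step_hours=float(d["step_hours"]))


def discretize_actions(cohort: Cohort, step_hours: float = 4.0) -> tuple[ActionGrid, np.ndarray]:
    """Fit the 5x5 action grid on a cohort and index every step's action."""
    fluid = _fit_dose_bins(cohort.table["action_fluid_ml"].to_numpy(), "fluid")
    vaso = _fit_dose_bins(cohort.table["action_vaso_ug_kg_min"].to_numpy(), "vasopressor")
    grid = ActionGrid(fluid=fluid, vaso=vaso, step_hours=step_hours)
    idx = grid.action_index(cohort.table["action_fluid_ml"].to_numpy(),
                            cohort.table["action_vaso_ug_kg_min"].to_numpy())
    return grid, idx


# ---------------------------------------------------------------------------
# Patient-state model: k-means on standardized observables + two terminals
# ---------------------------------------------------------------------------

@dataclass
class StateModel:
    """k-means patient states plus absorbing survival/death terminals.

    State ids 0..k-1 are cluster states; ``k`` is the survival terminal and
    ``k + 1`` the death terminal. Standardization statistics come from the
    fitting cohort only.
    """

    k: int
    features: tuple[str, ...]
    means: np.ndarray
    stds: np.ndarray
    centroids: np.ndarray
    seed: int

    @property
    def survival_state(self) -> int:
        return self.k

    @property
    def death_state(self) -> int:
        return self.k + 1

    @property
    def n_states(self) -> int:
        return self.k + 2

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k, "features": list(self.features), "seed": self.seed,
            "means": self.means.tolist(), "stds": self.stds.tolist(),
            "centroids": self.centroids.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "StateModel":
        d = json.loads(text)
        return cls(k=int(d["k"]), features=tuple(d["features"]), seed=int(d["seed"]),
                   means=np.asarray(d["means"], float), stds=np.asarray(d["stds"], float),
                   centroids=np.asarray(d["centroids"], float))


def _feature_matrix(cohort: Cohort, features: Sequence[str]) -> np.ndarray:
    missing = [f for f in features if f not in cohort.table.columns]
    if missing:
        raise CohortError(f"state features missing from cohort: {', '.join(missing)}")
    return cohort.table[list(features)].to_numpy(float)


def fit_state_clusters(
    cohort: Cohort,
    k: int,
    seed: int,
    features: Sequence[str] = DEFAULT_STATE_FEATURES,
) -> StateModel:
    """Fit the k-means patient-state model on a cohort's observables."""
    if k < 2:
        raise CohortError("state cluster count k must be >= 2")
    X = _feature_matrix(cohort, features)
    if k >= len(X):
        raise CohortError(f"k={k} must be smaller than the number of timesteps ({len(X)})")
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    stds[stds == 0] = 1.0  # constant feature: leave centred at 0
    Z = (X - means) / stds
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    km.fit(Z)
    return StateModel(k=k, features=tuple(features), means=means, stds=stds,
                      centroids=km.cluster_centers_.copy(), seed=seed)


def assign_states(model: StateModel, cohort: Cohort) -> np.ndarray:
    """Assign each timestep to its nearest centroid (ties -> lowest id)."""
    X = _feature_matrix(cohort, model.features)
    Z = (X - model.means) / model.stds
    # squared Euclidean distance to each centroid; argmin returns the first
    # (lowest-id) centroid on exact ties
    d2 = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2) if len(Z) * model.k < 2_000_000 else None
    if d2 is None:
        # chunked for large cohorts x large k
        out = np.empty(len(Z), dtype=np.int64)
        chunk = max(1, 2_000_000 // max(model.k, 1))
        for lo in range(0, len(Z), chunk):
            block = Z[lo:lo + chunk]
            dd = ((block[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
            out[lo:lo + chunk] = np.argmin(dd, axis=1)
        return out
    return np.argmin(d2, axis=1)
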