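"""Routing policy: saturation rule, per-state optimal labels, decision-tree
distillation, and the fixed published protocol.

The optimal routing policy is threshold-based and state-dependent: for each
calibrated ED state the queueing cost is minimized to obtain tau*(state), and
a patient stratum is VPP-eligible exactly when its predicted bed-need risk is
at or below that threshold. Because tau* varies with demand, staffing and
saturation, the resulting labels are distilled — together with patient
observations and model predictions — into a shallow (depth <= 4), clinically
interpretable decision tree over (ESI, chief-complaint category, saturation),
which is then checked for agreement with the theoretical optimum on held-out
states.

Saturation follows an institutional-threshold style rule: the ED is saturated
when the number of waiting patients strictly exceeds a configured fraction of
staffed capacity plus the currently free treatment capacity — i.e. waiting
demand cannot be absorbed even after filling every open space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, export_text

from .config import COMPLAINT_CATEGORIES
from .queueing import (
    CostSpec,
    InstabilityError,
    QueueParams,
    ScoreOC,
    optimal_threshold,
)

logger = logging.getLogger(__name__)

SUE_COMPLAINTS = ("skin", "urinary", "eye")


@dataclass(frozen=True)
class SaturationThresholds:
    """waiting_frac: tolerated waiting patients as a fraction of staffed
    capacity once the ED is full; free_weight: how much open capacity offsets
    the waiting count."""

    waiting_frac: float = 0.25
    free_weight: float = 1.0


def saturation_rule(
    n_waiting: int,
    n_in_treatment: int,
    capacity: int,
    thresholds: SaturationThresholds = SaturationThresholds(),
) -> bool:
    """True iff waiting demand strictly exceeds the institutional threshold:
    n_waiting > waiting_frac * capacity + free_weight * free_capacity."""
    if min(n_waiting, n_in_treatment, capacity) < 0:
        raise ValueError("counts must be non-negative")
    free = max(capacity - n_in_treatment, 0)
    return n_waiting > thresholds.waiting_frac * capacity + thresholds.free_weight * free


@dataclass
class EDState:
    n_waiting: int
    n_in_treatment: int
    physicians: int
    nurses: int
    shift: str
    n_beds: int = 56
    thresholds: SaturationThresholds = field(default_factory=SaturationThresholds)

    @property
    def staffed_capacity(self) -> int:
        return min(self.n_beds, 4 * self.nurses)

    @property
    def saturated(self) -> bool:
        return saturation_rule(self.n_waiting, self.n_in_treatment,
                               self.staffed_capacity, self.thresholds)


@dataclass
class StateGridConfig:
    """Axes of the calibrated ED-state grid and the state -> rate mapping.

    Demand is expressed as offered load relative to staffed main-ED capacity
    (so every grid point admits a stable routing split). Census states come
    as physically coherent (occupancy, waiting) congestion profiles — open
    beds coexist only with short queues, and a substantial waiting room only
    with a full ED — rather than an independent cross-product, mirroring how
    census and demand co-vary in practice. The waiting backlog inflates
    effective arrivals (those patients must still be worked through) and full
    occupancy throttles the effective main-ED service rate.
    """

    demand_loads: tuple[float, ...] = (0.50, 0.65, 0.78)
    # (occupancy fraction, waiting as fraction of staffed capacity)
    unsaturated_profiles: tuple[tuple[float, float], ...] = (
        (0.55, 0.03), (0.70, 0.06), (0.85, 0.10))
    saturated_profiles: tuple[tuple[float, float], ...] = (
        (1.00, 0.35), (1.00, 0.45), (1.00, 0.55))
    staffing: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "6-12": (6, 11), "12-18": (7, 12), "0-6": (3, 8),
    })
    n_beds: int = 56
    mean_occupancy_hours: float = 5.0
    occupancy_penalty: float = 0.15
    waiting_inflation: float = 1.00
    mu_vpp: float = 8.0
    theta: float = 2.0
    # during declared saturation the pathway is prioritized: vertical
    # assessments get more clinician time and fewer availability gaps
    mu_vpp_saturated: float = 16.0
    theta_saturated: float = 30.0
    prevalence: float = 0.65
    # saturation arises from sustained high demand: saturated census profiles
    # are only paired with demand loads at or above this level
    min_saturated_load: float = 0.6
    thresholds: SaturationThresholds = field(default_factory=SaturationThresholds)

    @classmethod
    def from_data(cls, encounters: pd.DataFrame, state_series: pd.DataFrame,
                  **overrides) -> "StateGridConfig":
        """Calibrate grid axes from synthetic encounter/state tables: demand
        levels from arrival-rate quantiles relative to capacity, occupancy and
        waiting axes from census quantiles."""
        if len(state_series) == 0:
            raise ValueError("empty calibration data")
        staffed = np.minimum(56, 4 * state_series["nurses_on_duty"].to_numpy())
        occ = state_series["n_in_treatment"].to_numpy() / np.maximum(staffed, 1)
        wait = state_series["n_waiting"].to_numpy() / np.maximum(staffed, 1)
        sat = state_series["saturated"].to_numpy(dtype=bool)
        unsat_profiles = tuple(
            (float(np.round(np.quantile(occ[~sat], q), 2)),
             float(np.round(max(np.quantile(wait[~sat], q), 0.02), 2)))
            for q in (0.25, 0.6, 0.9))
        if sat.any():
            sat_profiles = tuple(
                (1.0, float(np.round(max(np.quantile(wait[sat], q), 0.25), 2)))
                for q in (0.25, 0.5, 0.9))
        else:
            sat_profiles = StateGridConfig.saturated_profiles
        hours = encounters["arrival_time"].to_numpy() / 60.0
        span = max(hours.max() - hours.min(), 1.0)
        lam_mean = len(encounters) / span
        cap_rate = np.mean(staffed) / overrides.get("mean_occupancy_hours", 5.0)
        base_load = lam_mean / cap_rate
        loads = tuple(float(np.round(np.clip(base_load * f, 0.3, 0.85), 2))
                      for f in (0.8, 1.1, 1.35))
        return cls(demand_loads=loads, unsaturated_profiles=unsat_profiles,
                   saturated_profiles=sat_profiles, **overrides)


def enumerate_ed_states(grid: StateGridConfig) -> pd.DataFrame:
    """Finite grid of ED states (demand x occupancy x waiting x staffing)
    with per-state effective queue rates. One row per state."""
    rows = []
    sid = 0
    for shift, (phys, nurses) in grid.staffing.items():
        staffed = min(grid.n_beds, 4 * nurses)
        mu_base = staffed / grid.mean_occupancy_hours
        for load in grid.demand_loads:
            lam = load * mu_base
            profiles = grid.unsaturated_profiles + (
                grid.saturated_profiles if load >= grid.min_saturated_load else ())
            for occ, wfrac in profiles:
                n_treat = int(round(occ * staffed))
                n_wait = int(round(wfrac * staffed))
                sat = saturation_rule(n_wait, n_treat, staffed, grid.thresholds)
                lam_eff = lam * (1.0 + grid.waiting_inflation * n_wait / staffed)
                mu_eff = mu_base * (1.0 - grid.occupancy_penalty * min(occ, 1.0))
                rows.append({
                    "state_id": sid, "shift": shift,
                    "physicians": phys, "nurses": nurses,
                    "staffed_capacity": staffed,
                    "demand_load": load, "occupancy_frac": occ,
                    "n_in_treatment": n_treat, "n_waiting": n_wait,
                    "saturated": sat,
                    "lambda_eff": lam_eff, "mu_main_eff": mu_eff,
                    "mu_vpp": grid.mu_vpp_saturated if sat else grid.mu_vpp,
                    "theta": grid.theta_saturated if sat else grid.theta,
                    "prevalence": grid.prevalence,
                })
                sid += 1
    if not rows:
        raise ValueError("state grid is empty")
    return pd.DataFrame(rows)


def patient_strata(labeled: pd.DataFrame, scores: np.ndarray) -> pd.DataFrame:
    """Collapse encounters into (ESI, complaint) strata with empirical weights
    and mean predicted bed-need risk."""
    df = labeled[["esi", "complaint"]].copy()
    df["score"] = np.asarray(scores, dtype=float)
    g = df.groupby(["esi", "complaint"], observed=True).agg(
        weight=("score", "size"), score=("score", "mean")).reset_index()
    g["weight"] = g["weight"] / g["weight"].sum()
    return g


def optimal_labels_for_states(
    states: pd.DataFrame,
    strata: pd.DataFrame,
    cost: CostSpec,
    oc: ScoreOC,
    grid_step: float = 1e-3,
) -> pd.DataFrame:
    """Optimal routing label for every (state, patient stratum) pair.

    A stratum is ``vpp_eligible`` in a state iff its mean risk score is at or
    below the state's optimal threshold. States where no threshold stabilizes
    both streams are labeled all-main-ED with a logged note (tau = NaN).
    """
    frames = []
    for _, st in states.iterrows():
        params = QueueParams(
            lambda_total=float(st["lambda_eff"]), mu_vpp=float(st["mu_vpp"]),
            mu_main=float(st["mu_main_eff"]), theta=float(st["theta"]),
            prevalence=float(st["prevalence"]),
        )
        try:
            sol = optimal_threshold(params, cost.for_state(bool(st["saturated"])),
                                    oc, grid_step=grid_step)
            tau = sol.tau
        except InstabilityError:
            logger.warning("state %s infeasible: labeling all strata main_ed",
                           st["state_id"])
            tau = float("nan")
        f = strata.copy()
        f["state_id"] = st["state_id"]
        f["saturated"] = bool(st["saturated"])
        f["tau_state"] = tau
        f["label"] = np.where(
            np.isnan(tau), "main_ed",
            np.where(f["score"] <= tau, "vpp_eligible", "main_ed"),
        )
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


TREE_FEATURES = ["esi", "saturated", "complaint_sue"] + [
    f"complaint_{c}" for c in COMPLAINT_CATEGORIES
]


def _tree_design(examples: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({
        "esi": examples["esi"].astype(float),
        "saturated": examples["saturated"].astype(float),
        "complaint_sue": examples["complaint"].isin(SUE_COMPLAINTS).astype(float),
    })
    comp = pd.Categorical(examples["complaint"], categories=list(COMPLAINT_CATEGORIES))
    dummies = pd.get_dummies(comp, prefix="complaint").astype(float)
    dummies.index = X.index
    return pd.concat([X, dummies], axis=1)[TREE_FEATURES]


@dataclass
class ProtocolTree:
    """Interpretable routing protocol distilled from per-state optimal labels.

    Evaluates deterministically over (ESI, complaint, saturated); depth is
    capped at 4. Mixed leaves resolve by weighted majority with ties broken
    toward main-ED (conservative: fewer VPP routings)."""

    tree: DecisionTreeClassifier
    feature_names: list[str]
    max_depth: int
    training_agreement: float
    classes: list[str]

    def decide(self, examples: pd.DataFrame) -> np.ndarray:
        X = _tree_design(examples)
        proba = self.tree.predict_proba(X.to_numpy())
        # ties -> main_ed
        main_idx = self.classes.index("main_ed") if "main_ed" in self.classes else 0
        best = np.argmax(proba, axis=1)
        tied = np.isclose(proba.max(axis=1), proba[:, main_idx])
        best = np.where(tied, main_idx, best)
        return np.asarray(self.classes)[best]

    def render_text(self) -> str:
        return export_text(self.tree, feature_names=self.feature_names)

    def to_json(self) -> str:
        t = self.tree.tree_

        def node(i):
            if t.children_left[i] == -1:
                counts = t.value[i][0]
                label = self.classes[int(np.argmax(counts))]
                return {"leaf": label}
            return {
                "if": f"{self.feature_names[t.feature[i]]} <= {t.threshold[i]:.3f}",
                "then": node(t.children_left[i]),
                "else": node(t.children_right[i]),
            }

        return json.dumps(node(0), indent=2)


def distill_decision_tree(
    examples: pd.DataFrame, max_depth: int = 4, seed: int = 0
) -> ProtocolTree:
    """Fit a shallow tree mapping (ESI, complaint, saturated) to the optimal
    routing label, weighted by stratum prevalence. Deterministic per seed."""
    if len(examples) == 0:
        raise ValueError("no labeled examples to distill")
    y = examples["label"].to_numpy()
    if len(np.unique(y)) < 2:
        logger.warning("single-label examples: distilled tree is one leaf")
    X = _tree_design(examples)
    w = examples["weight"].to_numpy(dtype=float) if "weight" in examples else None
    clf = DecisionTreeClassifier(max_depth=max_depth, random_state=int(seed))
    clf.fit(X.to_numpy(), y, sample_weight=w)
    tree = ProtocolTree(
        tree=clf, feature_names=TREE_FEATURES, max_depth=max_depth,
        training_agreement=float("nan"), classes=[str(c) for c in clf.classes_],
    )
    tree.training_agreement = agreement_rate(tree, examples)
    return tree


def agreement_rate(tree: ProtocolTree, examples: pd.DataFrame) -> float:
    """Weighted fraction of examples where the tree matches the optimal
    label. Use examples from held-out states for an honest estimate."""
    if len(examples) == 0:
        raise ValueError("no examples to score")
    pred = tree.decide(examples)
    match = (pred == examples["label"].to_numpy()).astype(float)
    w = examples["weight"].to_numpy(dtype=float) if "weight" in examples else np.ones(len(examples))
    return float(np.average(match, weights=w))


def split_states(labels: pd.DataFrame, test_frac: float = 0.4, seed: int = 0):
    """Split labeled examples by state id into distillation and held-out sets,
    keeping both saturated and unsaturated states in each side."""
    rng = np.random.default_rng(seed)
    out = []
    for _, grp in labels.groupby("saturated"):
        ids = np.sort(grp["state_id"].unique())
        rng.shuffle(ids)
        n_test = max(int(round(test_frac * len(ids))), 1) if len(ids) > 1 else 0
        out.append((set(ids[n_test:]), set(ids[:n_test])))
    train_ids = set().union(*(t for t, _ in out))
    test_ids = set().union(*(t for _, t in out))
    return (labels[labels["state_id"].isin(train_ids)].reset_index(drop=True),
            labels[labels["state_id"].isin(test_ids)].reset_index(drop=True))


def protocol_decision(esi: int, complaint: str, saturated: bool) -> str:
    """The fixed published protocol (the deployed decision diagram):

    * any patient during ED saturation -> ``vpp_eligible``;
    * ESI 4 or 5 -> ``vpp_eligible``;
    * ESI 3 with a skin, urinary, or eye complaint -> ``vpp_eligible``;
    * otherwise -> ``main_ed``.
    """
    esi = int(esi)
    if not 1 <= esi <= 5:
        raise ValueError(f"ESI must be in 1..5, got {esi}")
    if saturated:
        return "vpp_eligible"
    if esi >= 4:
        return "vpp_eligible"
    if esi == 3 and complaint in SUE_COMPLAINTS:
        return "vpp_eligible"
    return "main_ed"
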