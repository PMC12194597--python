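"""Saturation rule, state grid, optimal labels, distillation, fixed protocol."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vppflow import policy
from vppflow.policy import (
    EDState,
    SaturationThresholds,
    StateGridConfig,
    agreement_rate,
    distill_decision_tree,
    enumerate_ed_states,
    optimal_labels_for_states,
    protocol_decision,
    saturation_rule,
    split_states,
)
from vppflow.queueing import CostSpec, ScoreOC


class TestSaturationRule:
    def test_empty_waiting_room_never_saturated(self):
        assert not saturation_rule(0, 56, 56)

    def test_overwhelming_queue_saturated(self):
        assert saturation_rule(500, 56, 56)

    def test_boundary_is_strict(self):
        thr = SaturationThresholds(waiting_frac=0.25, free_weight=1.0)
        # all beds full: threshold is exactly 0.25 * capacity
        assert not saturation_rule(14, 56, 56, thr)
        assert saturation_rule(15, 56, 56, thr)

    def test_free_capacity_offsets_waiting(self):
        thr = SaturationThresholds(waiting_frac=0.25, free_weight=1.0)
        assert not saturation_rule(20, 40, 56, thr)  # 16 free beds absorb
        assert saturation_rule(31, 40, 56, thr)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            saturation_rule(-1, 10, 56)

    @given(st.integers(0, 200), st.integers(0, 56))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pure_function_of_state(self, waiting, treating):
        a = saturation_rule(waiting, treating, 56)
        b = saturation_rule(waiting, treating, 56)
        assert a == b
        state = EDState(n_waiting=waiting, n_in_treatment=treating,
                        physicians=6, nurses=14, shift="6-12")
        assert state.saturated == saturation_rule(waiting, treating,
                                                  state.staffed_capacity)


class TestStateGrid:
    def test_grid_size_and_classes(self):
        grid = StateGridConfig()
        states = enumerate_ed_states(grid)
        n_sat_loads = sum(l >= grid.min_saturated_load for l in grid.demand_loads)
        expected = len(grid.staffing) * (
            len(grid.demand_loads) * len(grid.unsaturated_profiles)
            + n_sat_loads * len(grid.saturated_profiles))
        assert len(states) == expected
        assert states["saturated"].any() and (~states["saturated"]).any()
        assert (states["lambda_eff"] > 0).all() and (states["mu_main_eff"] > 0).all()

    def test_degenerate_single_state_grid(self):
        grid = StateGridConfig(
            demand_loads=(0.6,), unsaturated_profiles=((0.7, 0.05),),
            saturated_profiles=(), staffing={"6-12": (6, 11)})
        states = enumerate_ed_states(grid)
        assert len(states) == 1

    def test_calibration_from_data(self, encounters):
        from vppflow import synth
        from vppflow.config import GeneratorConfig
        series = synth.generate_ed_state_series(GeneratorConfig(seed=5), 30 * 1440.0)
        grid = StateGridConfig.from_data(encounters, series)
        states = enumerate_ed_states(grid)
        assert states["saturated"].any() and (~states["saturated"]).any()


def _toy_strata():
    return pd.DataFrame({
        "esi": [5, 4, 3, 3, 2],
        "complaint": ["skin", "other", "skin", "chest", "chest"],
        "weight": [0.1, 0.2, 0.1, 0.4, 0.2],
        "score": [0.05, 0.15, 0.55, 0.92, 0.99],
    })


class TestOptimalLabels:
    def test_infeasible_state_labels_all_main_ed(self):
        states = pd.DataFrame([{
            "state_id": 0, "saturated": True, "lambda_eff": 100.0,
            "mu_main_eff": 3.0, "mu_vpp": 3.0, "theta": 2.0, "prevalence": 0.8,
        }])
        labels = optimal_labels_for_states(states, _toy_strata(), CostSpec(),
                                           ScoreOC.beta())
        assert (labels["label"] == "main_ed").all()
        assert labels["tau_state"].isna().all()

    def test_labels_follow_threshold(self, distill_run):
        labels = distill_run["labels"]
        ok = labels.dropna(subset=["tau_state"])
        eligible = ok["score"] <= ok["tau_state"]
        assert (ok["label"] == np.where(eligible, "vpp_eligible", "main_ed")).all()

    def test_saturated_states_strictly_expand_eligibility(self, distill_run):
        labels, states = distill_run["labels"], distill_run["states"]
        taus = labels.groupby("state_id")["tau_state"].first()
        scores = np.sort(distill_run["strata"]["score"].to_numpy())

        def eligible_set(tau):
            return frozenset(np.flatnonzero(scores <= tau))

        st = states.set_index("state_id")
        n_pairs = 0
        for _, grp in st.groupby(["shift", "demand_load"]):
            for si in grp.index[grp["saturated"]]:
                for ui in grp.index[~grp["saturated"]]:
                    assert eligible_set(taus[si]) > eligible_set(taus[ui])
                    n_pairs += 1
        assert n_pairs > 0


class TestDistillation:
    def test_planted_esi_rule_recovered_at_root(self):
        rng = np.random.default_rng(0)
        rows = []
        for sid in range(30):
            esi = rng.integers(1, 6, size=40)
            complaints = rng.choice(["skin", "chest", "other"], size=40)
            for e, c in zip(esi, complaints):
                rows.append({"state_id": sid, "esi": int(e), "complaint": c,
                             "saturated": False, "weight": 1.0,
                             "label": "vpp_eligible" if e >= 4 else "main_ed"})
        examples = pd.DataFrame(rows)
        tree = distill_decision_tree(examples, max_depth=3, seed=0)
        root_feature = tree.feature_names[tree.tree.tree_.feature[0]]
        assert root_feature == "esi"
        assert agreement_rate(tree, examples) == 1.0

    def test_depth_capped_and_deterministic(self, distill_run):
        tree = distill_run["tree"]
        assert tree.tree.get_depth() <= 4
        train, _ = split_states(distill_run["labels"], seed=1)
        refit = distill_decision_tree(train, max_depth=4, seed=1)
        assert refit.to_json() == tree.to_json()

    def test_shallower_tree_no_better_than_deeper(self):
        rng = np.random.default_rng(1)
        rows = []
        for sid in range(20):
            for _ in range(30):
                e = int(rng.integers(1, 6))
                sat = bool(rng.random() < 0.5)
                label = "vpp_eligible" if (e >= 4 or sat) else "main_ed"
                rows.append({"state_id": sid, "esi": e, "complaint": "other",
                             "saturated": sat, "weight": 1.0, "label": label})
        examples = pd.DataFrame(rows)
        shallow = distill_decision_tree(examples, max_depth=1, seed=0)
        deep = distill_decision_tree(examples, max_depth=3, seed=0)
        assert agreement_rate(shallow, examples) < agreement_rate(deep, examples)

    def test_single_label_examples_one_leaf(self):
        examples = pd.DataFrame({
            "state_id": [0] * 4, "esi": [3, 4, 5, 2],
            "complaint": ["skin"] * 4, "saturated": [False] * 4,
            "weight": [1.0] * 4, "label": ["main_ed"] * 4,
        })
        tree = distill_decision_tree(examples, seed=0)
        assert tree.tree.get_depth() == 0
        assert agreement_rate(tree, examples) == 1.0

    def test_agreement_complement_for_inverted_labels(self, distill_run):
        _, test = split_states(distill_run["labels"], seed=1)
        tree = distill_run["tree"]
        a = agreement_rate(tree, test)
        flipped = test.copy()
        flipped["label"] = np.where(flipped["label"] == "vpp_eligible",
                                    "main_ed", "vpp_eligible")
        assert agreement_rate(tree, flipped) == pytest.approx(1.0 - a)

    def test_empty_examples_rejected(self, distill_run):
        with pytest.raises(ValueError):
            agreement_rate(distill_run["tree"], distill_run["labels"].iloc[:0])

    def test_tree_serializes_to_nested_json(self, distill_run):
        node = json.loads(distill_run["tree"].to_json())
        while "leaf" not in node:
            assert set(node) == {"if", "then", "else"}
            node = node["then"]
        assert node["leaf"] in ("vpp_eligible", "main_ed")


class TestPublishedProtocol:
    def test_saturation_never_revokes_eligibility(self):
        complaints = ["skin", "urinary", "eye", "chest", "abdominal", "other"]
        for esi in range(1, 6):
            for c in complaints:
                base = protocol_decision(esi, c, saturated=False)
                flipped = protocol_decision(esi, c, saturated=True)
                if base == "vpp_eligible":
                    assert flipped == "vpp_eligible"

    def test_invalid_esi_rejected(self):
        with pytest.raises(ValueError):
            protocol_decision(0, "skin", False)
        with pytest.raises(ValueError):
            protocol_decision(6, "skin", False)
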