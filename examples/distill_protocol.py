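"""Distill the interpretable routing protocol and measure its fidelity.

Runs the full chain — synthetic cohort, labels, risk model, per-state
optimal thresholds over the calibrated ED-state grid — then distills the
state-by-state optima into a depth-4 decision tree over (ESI, complaint,
saturation) and scores its agreement with the theoretical optimum on states
never seen during distillation. Also shows the fixed published protocol.
"""

from vppflow import protocol_decision
from vppflow.pipeline import distillation_experiment

res = distillation_experiment(seed=1)
print(f"held-out agreement with the optimal policy: "
      f"{res['held_out_agreement']:.1%} "
      f"(training: {res['training_agreement']:.1%}, "
      f"{res['n_test_states']} held-out states)")

labels = res["labels"]
sat_tau = labels[labels["saturated"]]["tau_state"]
unsat_tau = labels[~labels["saturated"]]["tau_state"]
print(f"optimal thresholds: unsaturated {unsat_tau.min():.2f}-{unsat_tau.max():.2f}, "
      f"saturated {sat_tau.min():.2f}-{sat_tau.max():.2f} "
      "(saturation expands vertical eligibility)")

print("\ndistilled tree:")
print(res["tree"].render_text())

print("fixed published protocol on three probes:")
for esi, complaint, saturated in ((4, "chest", False), (3, "urinary", False),
                                  (2, "chest", True)):
    got = protocol_decision(esi, complaint, saturated)
    print(f"  ESI {esi}, {complaint:8s} saturated={saturated!s:5s} -> {got}")
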