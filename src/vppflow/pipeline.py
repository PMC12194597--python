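"""End-to-end orchestration: generate -> label -> fit -> solve -> simulate ->
distill -> evaluate, with a provenance manifest.

One user seed governs every stage through per-stage derived seeds
(seed + stage index), so a single flag reproduces a full run. Each stage
writes its artifacts under the output directory and registers them, with
SHA-256 checksums, in the run manifest; deterministic stages reproduce
identical checksums on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bed_need_model, des, evaluation, labeling, policy, queueing, synth
from .config import GeneratorConfig

logger = logging.getLogger(__name__)

STAGES = ("synth", "label", "fit", "solve", "simulate", "distill", "evaluate")


def _stage_seed(seed: int, stage: str) -> int:
    return (int(seed) + STAGES.index(stage)) % (2**31 - 1)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def distillation_experiment(
    seed: int,
    config: GeneratorConfig | None = None,
    grid: policy.StateGridConfig | None = None,
    cost: queueing.CostSpec | None = None,
    n_train: int = 6000,
    test_frac: float = 0.4,
    max_depth: int = 4,
) -> dict:
    """Full policy-distillation run for one seed.

    Generates encounters, labels them, fits the risk model, computes per-state
    optimal thresholds over the calibrated ED-state grid, distills the
    depth-capped decision tree on a training split of states, and returns the
    held-out state agreement together with the fitted pieces.
    """
    cfg = config or GeneratorConfig()
    cfg = GeneratorConfig.from_dict({**cfg.to_dict(), "seed": int(seed),
                                     "n_encounters": n_train})
    enc = synth.generate_encounters(cfg)
    clean, _ = labeling.preprocess(enc)
    labeled = labeling.assign_bed_need_labels(clean)
    model = bed_need_model.fit_bed_need_model(labeled, seed=seed)
    scores = bed_need_model.predict_risk(model, labeled)
    strata = policy.patient_strata(labeled, scores)
    oc = queueing.ScoreOC.from_scores(
        scores[labeled["requires_bed"].to_numpy()],
        scores[~labeled["requires_bed"].to_numpy()],
    )
    grid_cfg = grid or policy.StateGridConfig()
    # the grid's bed-need mix follows the labeled prevalence of this cohort
    grid_cfg.prevalence = float(labeled["requires_bed"].mean())
    states = policy.enumerate_ed_states(grid_cfg)
    labels = policy.optimal_labels_for_states(
        states, strata, cost or queueing.CostSpec(), oc)
    train, test = policy.split_states(labels, test_frac=test_frac, seed=seed)
    tree = policy.distill_decision_tree(train, max_depth=max_depth, seed=seed)
    held_out = policy.agreement_rate(tree, test)
    return {
        "seed": int(seed),
        "held_out_agreement": held_out,
        "training_agreement": tree.training_agreement,
        "tree": tree,
        "labels": labels,
        "states": states,
        "model": model,
        "strata": strata,
        "n_test_states": int(test["state_id"].nunique()),
    }


def run_pipeline(
    config: GeneratorConfig | str | Path | None = None,
    stages: tuple[str, ...] = STAGES,
    seed: int = 0,
    outdir: str | Path = "vpp_run",
) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Raises a dependency error naming the stage when an upstream artifact is
    missing. The manifest (written as ``manifest.json``) records the config
    hash, per-stage seeds, artifact paths with checksums, and timestamps.
    """
    if isinstance(config, (str, Path)):
        cfg = GeneratorConfig.from_yaml(config)
    else:
        cfg = config or GeneratorConfig()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": int(seed),
        "stage_seeds": {s: _stage_seed(seed, s) for s in stages},
        "stages": {},
        "artifacts": {},
    }

    def register(stage: str, name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _checksum(path)}
        manifest["stages"][stage]["outputs"].append(name)

    def need(name: str, stage: str) -> Path:
        if name not in manifest["artifacts"]:
            p = out / name
            if p.exists():
                manifest["artifacts"][name] = {"path": str(p), "sha256": _checksum(p)}
            else:
                raise FileNotFoundError(
                    f"stage {stage!r} requires missing upstream artifact {name!r}; "
                    "run its producing stage first")
        return Path(manifest["artifacts"][name]["path"])

    for stage in stages:
        t0 = time.time()
        manifest["stages"][stage] = {"outputs": [], "started": t0}
        s_seed = manifest["stage_seeds"][stage]
        if stage == "synth":
            cfg_run = GeneratorConfig.from_dict({**cfg.to_dict(), "seed": s_seed})
            enc = synth.generate_encounters(cfg_run)
            synth.write_encounters_csv(enc, out / "encounters.csv")
            register(stage, "encounters.csv", out / "encounters.csv")
            cfg_run.to_yaml(out / "generator_config.yaml")
            register(stage, "generator_config.yaml", out / "generator_config.yaml")
        elif stage == "label":
            enc = synth.read_encounters_csv(need("encounters.csv", stage))
            clean, report = labeling.preprocess(enc)
            labeled = labeling.assign_bed_need_labels(clean)
            labeled.to_csv(out / "labeled.csv", index=False)
            register(stage, "labeled.csv", out / "labeled.csv")
            (out / "labeling_report.json").write_text(json.dumps({
                "preprocess": report.to_dict(),
                "labels": labeling.labeling_report(labeled),
            }, indent=2))
            register(stage, "labeling_report.json", out / "labeling_report.json")
        elif stage == "fit":
            labeled = synth.read_encounters_csv(need("labeled.csv", stage))
            labeled["requires_bed"] = labeled["bed_need_tier"] == "bed"
            model = bed_need_model.fit_bed_need_model(labeled, seed=s_seed)
            model.save(out / "risk_model.pkl")
            register(stage, "risk_model.pkl", out / "risk_model.pkl")
            gold = labeling.flag_gold_standard(labeled, seed=s_seed)
            auc = bed_need_model.evaluate_auc_bootstrap(labeled, gold, n_boot=5,
                                                        seed=s_seed)
            (out / "auc_report.json").write_text(json.dumps(auc.to_dict(), indent=2))
            register(stage, "auc_report.json", out / "auc_report.json")
        elif stage == "solve":
            labeled = synth.read_encounters_csv(need("labeled.csv", stage))
            labeled["requires_bed"] = labeled["bed_need_tier"] == "bed"
            model = bed_need_model.RiskModel.load(need("risk_model.pkl", stage))
            scores = bed_need_model.predict_risk(model, labeled)
            oc = queueing.ScoreOC.from_scores(
                scores[labeled["requires_bed"]], scores[~labeled["requires_bed"]])
            states = policy.enumerate_ed_states(policy.StateGridConfig())
            strata = policy.patient_strata(labeled, scores)
            labels = policy.optimal_labels_for_states(states, strata,
                                                      queueing.CostSpec(), oc)
            labels.to_csv(out / "optimal_labels.csv", index=False)
            register(stage, "optimal_labels.csv", out / "optimal_labels.csv")
        elif stage == "simulate":
            grid = des.default_validation_grid()
            report = des.validate_against_analytic(grid, n_patients=20_000,
                                                   n_replications=3,
                                                   base_seed=s_seed)
            report.to_csv(out / "des_validation.csv", index=False)
            register(stage, "des_validation.csv", out / "des_validation.csv")
        elif stage == "distill":
            labels = pd.read_csv(need("optimal_labels.csv", stage))
            labels["saturated"] = labels["saturated"].astype(bool)
            train, test = policy.split_states(labels, seed=s_seed)
            tree = policy.distill_decision_tree(train, seed=s_seed)
            agreement = policy.agreement_rate(tree, test)
            (out / "protocol_tree.json").write_text(tree.to_json())
            register(stage, "protocol_tree.json", out / "protocol_tree.json")
            (out / "protocol_tree.txt").write_text(tree.render_text())
            register(stage, "protocol_tree.txt", out / "protocol_tree.txt")
            (out / "agreement.json").write_text(json.dumps({
                "held_out_agreement": agreement,
                "training_agreement": tree.training_agreement,
            }, indent=2))
            register(stage, "agreement.json", out / "agreement.json")
            manifest["held_out_agreement"] = agreement
        elif stage == "evaluate":
            enc = synth.read_encounters_csv(need("encounters.csv", stage))
            pre = enc[enc["period"] == "pre"]
            post = enc[enc["period"] == "post"]
            t1 = evaluation.summarize_table1(pre, post)
            t1.to_csv(out / "table1.csv", index=False)
            register(stage, "table1.csv", out / "table1.csv")
            t2 = evaluation.vpp_routing_table2(pre, post)
            t2.to_csv(out / "table2.csv", index=False)
            register(stage, "table2.csv", out / "table2.csv")
            rob = evaluation.robustness_suite(enc)
            rob.to_csv(out / "effect_estimates.csv", index=False)
            register(stage, "effect_estimates.csv", out / "effect_estimates.csv")
        manifest["stages"][stage]["elapsed_s"] = round(time.time() - t0, 3)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d stages -> %s", len(stages), out)
    return manifest
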