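import warnings

import numpy as np
import pytest

from vppflow import bed_need_model, labeling, queueing, synth
from vppflow.config import GeneratorConfig
from vppflow.pipeline import distillation_experiment

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(n_encounters=4000, seed=7)


@pytest.fixture(scope="session")
def encounters(gen_config):
    return synth.generate_encounters(gen_config)


@pytest.fixture(scope="session")
def labeled(encounters):
    clean, _ = labeling.preprocess(encounters)
    return labeling.assign_bed_need_labels(clean)


@pytest.fixture(scope="session")
def risk_artifacts(labeled):
    """Fitted model, scores, empirical operating characteristic, prevalence."""
    model = bed_need_model.fit_bed_need_model(labeled, seed=7)
    scores = bed_need_model.predict_risk(model, labeled)
    bed = labeled["requires_bed"].to_numpy()
    oc = queueing.ScoreOC.from_scores(scores[bed], scores[~bed])
    return {"model": model, "scores": scores, "oc": oc,
            "prevalence": float(bed.mean())}


@pytest.fixture(scope="session")
def distill_run():
    """One full distillation experiment, shared across policy tests."""
    return distillation_experiment(seed=1)
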