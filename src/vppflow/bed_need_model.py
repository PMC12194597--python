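"""Bed-need risk model: a random-forest classifier on triage data.

Predictors are triage-time features only — ESI, age, chief-complaint
category, and standardized vital signs; post-hoc fields (procedures,
disposition, LOS) are never used as predictors. The model outputs a
personalized risk score in [0, 1]: the predicted probability that the
arriving patient will require an ED bed. Evaluation follows a bootstrap
protocol: resampled training sets, AUC measured on the fixed gold-standard
held-out subset only.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score

from .config import COMPLAINT_CATEGORIES, VITAL_NAMES

TRIAGE_FEATURES = ("esi", "age") + tuple(f"{v}_z" for v in VITAL_NAMES)


def build_design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix with a fixed column order: ESI, age, z-scored
    vitals, and one-hot complaint categories (all categories always present)."""
    missing = [c for c in TRIAGE_FEATURES + ("complaint",) if c not in df.columns]
    if missing:
        raise ValueError(f"feature columns missing from input: {missing}")
    X = df.loc[:, list(TRIAGE_FEATURES)].astype(float).copy()
    comp = pd.Categorical(df["complaint"], categories=list(COMPLAINT_CATEGORIES))
    dummies = pd.get_dummies(comp, prefix="complaint").astype(float)
    dummies.index = X.index
    return pd.concat([X, dummies], axis=1)


@dataclass
class RiskModel:
    clf: RandomForestClassifier
    feature_names: list[str]
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "RiskModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class AUCReport:
    aucs: list[float]
    mean_auc: float
    sd_auc: float
    n_bootstraps: int
    single_bootstrap: bool = False

    def to_dict(self) -> dict:
        return {"aucs": self.aucs, "mean_auc": self.mean_auc, "sd_auc": self.sd_auc,
                "n_bootstraps": self.n_bootstraps, "single_bootstrap": self.single_bootstrap}


def fit_bed_need_model(
    train: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int | None = None,
    min_samples_leaf: int = 2,
) -> RiskModel:
    """Fit the random forest on labeled training rows (needs `requires_bed`).

    Deterministic for a fixed seed: refitting reproduces identical scores.
    """
    y = train["requires_bed"].to_numpy(dtype=bool)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training labels are single-class (all {'bed' if classes[0] else 'no-bed'}); "
            "cannot fit a classifier"
        )
    X = build_design_matrix(train)
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X.to_numpy(), y)
    tiers = (train["bed_need_tier"].value_counts().to_dict()
             if "bed_need_tier" in train else {})
    return RiskModel(
        clf=clf,
        feature_names=list(X.columns),
        meta={"seed": int(seed), "n_train": int(len(train)), "tier_counts": tiers},
    )


def predict_risk(model: RiskModel, features: pd.DataFrame) -> np.ndarray:
    """Risk scores in [0, 1] — P(requires an ED bed) — for schema-conformant
    rows. Raises with the offending feature names on schema mismatch."""
    X = build_design_matrix(features)
    if list(X.columns) != model.feature_names:
        extra = set(X.columns) - set(model.feature_names)
        missing = set(model.feature_names) - set(X.columns)
        raise ValueError(f"feature schema mismatch: missing={sorted(missing)}, "
                         f"unexpected={sorted(extra)}")
    return model.clf.predict_proba(X.to_numpy())[:, 1]


def evaluate_auc_bootstrap(
    labeled: pd.DataFrame,
    gold_mask: pd.Series,
    n_boot: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> AUCReport:
    """Bootstrap evaluation: for each of `n_boot` iterations, resample the
    non-gold rows with replacement, fit, and score AUC on the fixed
    gold-standard test rows. Training rows never overlap the test subset."""
    gold_mask = gold_mask.reindex(labeled.index, fill_value=False)
    test = labeled[gold_mask]
    pool = labeled[~gold_mask]
    if len(test) == 0:
        raise ValueError("gold-standard test subset is empty")
    if test["requires_bed"].nunique() < 2:
        raise ValueError("gold-standard test subset contains a single class")
    assert not set(test["encounter_id"]) & set(pool["encounter_id"])
    rng = np.random.default_rng(seed)
    aucs = []
    for b in range(n_boot):
        idx = rng.integers(0, len(pool), size=len(pool))
        boot = pool.iloc[idx]
        model = fit_bed_need_model(boot, seed=int(rng.integers(0, 2**31 - 1)), **fit_kwargs)
        scores = predict_risk(model, test)
        aucs.append(float(roc_auc_score(test["requires_bed"].to_numpy(), scores)))
    single = len(aucs) == 1
    return AUCReport(
        aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        sd_auc=0.0 if single else float(np.std(aucs, ddof=1)),
        n_bootstraps=n_boot,
        single_bootstrap=single,
    )


def feature_importance(model: RiskModel, method: str = "impurity",
                       X: pd.DataFrame | None = None, y=None,
                       seed: int = 0) -> list[tuple[str, float]]:
    """Ranked (feature, importance) pairs, importances normalized to sum 1.

    ``impurity`` (default) uses the forest's mean decrease in impurity;
    ``permutation`` requires evaluation data (X as raw feature rows, y labels).
    """
    if not hasattr(model.clf, "feature_importances_"):
        raise ValueError("model is not fitted")
    if method == "impurity":
        imp = np.asarray(model.clf.feature_importances_, dtype=float)
    elif method == "permutation":
        if X is None or y is None:
            raise ValueError("permutation importance needs X and y")
        design = build_design_matrix(X)
        res = permutation_importance(model.clf, design.to_numpy(), np.asarray(y),
                                     n_repeats=5, random_state=seed)
        imp = np.clip(res.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance method {method!r}")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    ranked = sorted(zip(model.feature_names, imp.tolist()), key=lambda kv: -kv[1])
    return ranked
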