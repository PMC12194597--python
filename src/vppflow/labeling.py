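"""Preprocessing and tiered bed-need labeling.

The training label "requires an ED bed" is defined through a tiered scheme,
applied in order (first match wins):

1. ``gold_no_bed`` — patients seen in the vertical pathway and discharged
   without a bed (direct VPP discharge): the gold-standard no-bed cases.
2. ``synth_esi3_no_bed`` — ESI-3 patients discharged without any imaging
   (CT with/without contrast, X-ray, ultrasound) or IV therapy whose total
   LOS was under two hours (strictly less than 120 minutes).
3. ``synth_esi45_no_bed`` — ESI 4-5 patients who received no IV medications
   or fluids.
4. ``bed`` — everyone else.

The binary label is ``tier == 'bed'``. Preprocessing removes duplicate
encounter ids, drops rows missing triage or outcome data, z-standardizes
vitals with training-split statistics, and maps free-text-like complaint
values onto the fixed category set via an editable CSV table; unmappable
values route to "other" with a logged warning, never a crash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .config import COMPLAINT_CATEGORIES, VITAL_NAMES

logger = logging.getLogger(__name__)

TIERS = ("gold_no_bed", "synth_esi3_no_bed", "synth_esi45_no_bed", "bed")
IMAGING = ("proc_ct_con", "proc_ct_noncon", "proc_xray", "proc_us")
REQUIRED = ("encounter_id", "esi", "complaint", "disposition", "los") + VITAL_NAMES


def load_complaint_map(path=None) -> dict[str, str]:
    """Raw complaint value -> category, from the packaged (or a user) CSV."""
    if path is None:
        src = resources.files("vppflow").joinpath("data/complaint_map.csv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    mapping = dict(zip(table["raw_value"].str.strip().str.lower(), table["category"]))
    bad = set(mapping.values()) - set(COMPLAINT_CATEGORIES)
    if bad:
        raise ValueError(f"complaint map targets unknown categories: {sorted(bad)}")
    return mapping


@dataclass
class PreprocessReport:
    n_input: int = 0
    n_duplicates_removed: int = 0
    n_missing_dropped: int = 0
    n_unmapped_complaints: int = 0
    n_output: int = 0
    vital_stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_missing_dropped": self.n_missing_dropped,
            "n_unmapped_complaints": self.n_unmapped_complaints,
            "n_output": self.n_output,
            "vital_stats": self.vital_stats,
        }


def preprocess(
    raw: pd.DataFrame,
    complaint_map: dict[str, str] | None = None,
    vital_stats: dict[str, tuple[float, float]] | None = None,
    train_mask: pd.Series | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Clean a raw encounter table.

    Vitals are z-standardized into ``<vital>_z`` columns using statistics
    from ``train_mask`` rows (or supplied ``vital_stats``), so a held-out
    split never leaks into the scaling. A zero-variance vital standardizes
    to all zeros.
    """
    report = PreprocessReport(n_input=len(raw))
    missing_cols = [c for c in REQUIRED if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"raw table missing required columns: {missing_cols}")
    df = raw.copy()

    before = len(df)
    df = df.drop_duplicates(subset="encounter_id", keep="first")
    report.n_duplicates_removed = before - len(df)

    before = len(df)
    df = df.dropna(subset=list(REQUIRED))
    df = df[(df["esi"].isin([1, 2, 3, 4, 5])) & (df["los"] > 0)]
    report.n_missing_dropped = before - len(df)
    if report.n_missing_dropped:
        logger.info("dropped %d rows with missing/invalid triage or outcome data",
                    report.n_missing_dropped)

    mapping = complaint_map if complaint_map is not None else load_complaint_map()
    norm = df["complaint"].astype(str).str.strip().str.lower()
    mapped = norm.map(mapping)
    unmapped = mapped.isna()
    report.n_unmapped_complaints = int(unmapped.sum())
    if report.n_unmapped_complaints:
        logger.warning("%d complaint values not in the mapping table; routed to 'other'",
                       report.n_unmapped_complaints)
    df["complaint"] = mapped.fillna("other")

    if vital_stats is None:
        fit_rows = df[train_mask.reindex(df.index, fill_value=False)] if train_mask is not None else df
        vital_stats = {}
        for v in VITAL_NAMES:
            vital_stats[v] = (float(fit_rows[v].mean()), float(fit_rows[v].std(ddof=0)))
    for v in VITAL_NAMES:
        mean, sd = vital_stats[v]
        df[f"{v}_z"] = 0.0 if sd == 0 else (df[v] - mean) / sd
    report.vital_stats = {k: list(v) for k, v in vital_stats.items()}
    report.n_output = len(df)
    return df.reset_index(drop=True), report


def assign_bed_need_labels(clean: pd.DataFrame) -> pd.DataFrame:
    """Assign the tiered label and its binary collapse to every clean row."""
    df = clean.copy()
    esi = df["esi"].to_numpy()
    discharged = df["disposition"].to_numpy() == "discharged"
    any_imaging = np.zeros(len(df), dtype=bool)
    for col in IMAGING:
        any_imaging |= df[col].to_numpy(dtype=bool)
    iv = df["proc_iv"].to_numpy(dtype=bool)
    los = df["los"].to_numpy(dtype=float)
    in_vpp = df["seen_in_vpp"].to_numpy(dtype=bool) if "seen_in_vpp" in df else np.zeros(len(df), bool)

    gold = in_vpp & discharged
    rule1 = (esi == 3) & discharged & ~any_imaging & ~iv & (los < 120.0)
    rule2 = np.isin(esi, (4, 5)) & ~iv

    tier = np.full(len(df), "bed", dtype=object)
    tier[rule2] = "synth_esi45_no_bed"
    tier[rule1] = "synth_esi3_no_bed"
    tier[gold] = "gold_no_bed"  # highest precedence
    df["bed_need_tier"] = tier
    df["requires_bed"] = tier == "bed"
    return df


def flag_gold_standard(labeled: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Boolean mask of the gold-standard test subset: all direct-VPP-discharge
    no-bed cases plus an equal-size random sample of unambiguous bed cases
    (ESI <= 2 patients who were admitted). Reserved for held-out evaluation."""
    rng = np.random.default_rng(seed)
    gold_neg = labeled["bed_need_tier"] == "gold_no_bed"
    hard_pos = (labeled["esi"] <= 2) & (labeled["disposition"] == "admitted")
    n = int(gold_neg.sum())
    pos_idx = labeled.index[hard_pos].to_numpy()
    if n == 0 or len(pos_idx) == 0:
        raise ValueError("gold-standard subset is empty (no direct VPP discharges "
                         "or no unambiguous bed cases)")
    take = rng.choice(pos_idx, size=min(n, len(pos_idx)), replace=False)
    mask = pd.Series(False, index=labeled.index)
    mask[labeled.index[gold_neg]] = True
    mask[take] = True
    return mask


def labeling_report(labeled: pd.DataFrame) -> dict:
    counts = labeled["bed_need_tier"].value_counts().to_dict()
    return {
        "n_rows": int(len(labeled)),
        "tier_counts": {t: int(counts.get(t, 0)) for t in TIERS},
        "prevalence_requires_bed": float(labeled["requires_bed"].mean()) if len(labeled) else float("nan"),
    }
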