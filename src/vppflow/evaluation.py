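"""Before/after evaluation: descriptive tables, log-LOS regression, return
models, denominator reconstruction, and robustness specifications.

The primary effect model is an encounter-level OLS regression of log(LOS) on
a post-period indicator plus optional control groups: (1) patient-level —
age, ESI (categorical or continuous), chief-complaint category; (2)
operational — attending physician, disposition, diagnostic procedures; (3)
saturation/timing — on-duty physicians and nurses, patients in treatment or
waiting, and the arrival shift. A coefficient beta on the post indicator
implies a 100*(exp(beta)-1) percent LOS change and a minutes change of
pre-mean * (exp(beta)-1). Educational-period rows are excluded from primary
contrasts.

Descriptive comparisons use Welch's t-test for continuous variables and
Pearson's chi-square for proportions, switching to Fisher's exact test
whenever any cell of a 2x2 routing table falls below 10 (the small-cell
rule). Two-sided tests throughout; no multiplicity correction is applied and
reports flag this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

SPEC_COVARIATES = {
    "patient": ["age", "C(esi)", "C(complaint)"],
    "patient_continuous_esi": ["age", "esi", "C(complaint)"],
    "operational": ["C(physician_id)", "C(disposition)", "proc_iv",
                    "proc_ct_con", "proc_ct_noncon", "proc_xray", "proc_us"],
    "saturation": ["physicians_on_duty", "nurses_on_duty", "n_in_treatment",
                   "n_waiting", "C(shift)"],
}


@dataclass
class EffectEstimate:
    coef: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    pct_change: float
    minutes_change: float
    pre_mean_minutes: float
    spec_id: str
    n_obs: int
    outcome: str = "log_los"

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _covariates_for(groups: list[str], continuous_esi: bool = False) -> list[str]:
    out: list[str] = []
    for g in groups:
        key = "patient_continuous_esi" if (g == "patient" and continuous_esi) else g
        if key not in SPEC_COVARIATES:
            raise ValueError(f"unknown covariate group {g!r}")
        out.extend(SPEC_COVARIATES[key])
    return out


def _primary_frame(encounters: pd.DataFrame, include_edu: bool) -> pd.DataFrame:
    df = encounters.copy()
    if not include_edu:
        df = df[df["period"].isin(["pre", "post"])]
    if (df["period"] == "post").sum() == 0:
        raise ValueError("no post-period rows: cannot estimate the intervention effect")
    df["post"] = (df["period"] == "post").astype(int)
    return df


def fit_log_los_model(
    encounters: pd.DataFrame,
    covariate_groups: list[str] = (),
    continuous_esi: bool = False,
    include_edu: bool = False,
    spec_id: str | None = None,
) -> EffectEstimate:
    """OLS of log(LOS) on the post indicator plus the selected controls."""
    df = _primary_frame(encounters, include_edu)
    df = df[df["los"] > 0].copy()
    df["log_los"] = np.log(df["los"])
    terms = ["post"] + _covariates_for(list(covariate_groups), continuous_esi)
    if include_edu:
        df["edu"] = (df["period"] == "edu").astype(int)
        terms.append("edu")
    formula = "log_los ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    coef = float(fit.params["post"])
    se = float(fit.bse["post"])
    lo, hi = (float(x) for x in fit.conf_int().loc["post"])
    pre_mean = float(df.loc[df["period"] == "pre", "los"].mean())
    return EffectEstimate(
        coef=coef, se=se, ci_low=lo, ci_high=hi, pvalue=float(fit.pvalues["post"]),
        pct_change=100.0 * (np.exp(coef) - 1.0),
        minutes_change=pre_mean * (np.exp(coef) - 1.0),
        pre_mean_minutes=pre_mean,
        spec_id=spec_id or f"log_los|{'+'.join(covariate_groups) or 'unadjusted'}",
        n_obs=int(fit.nobs),
    )


def fit_return_models(
    encounters: pd.DataFrame,
    covariate_groups: list[str] = (),
    continuous_esi: bool = False,
) -> dict[str, EffectEstimate]:
    """Logistic regressions of the 72-hour return indicators on post +
    controls; the closest binary analogue of the log-LOS linear model."""
    df = _primary_frame(encounters, include_edu=False)
    out = {}
    for outcome in ("returned_72h", "returned_72h_admit"):
        y = df[outcome].astype(int)
        if y.nunique() < 2:
            raise ValueError(f"outcome {outcome!r} has zero variance")
        terms = ["post"] + _covariates_for(list(covariate_groups), continuous_esi)
        formula = f"I({outcome}.astype(int)) ~ " + " + ".join(terms)
        fit = smf.logit(formula, data=df).fit(disp=0)
        coef = float(fit.params["post"])
        lo, hi = (float(x) for x in fit.conf_int().loc["post"])
        out[outcome] = EffectEstimate(
            coef=coef, se=float(fit.bse["post"]), ci_low=lo, ci_high=hi,
            pvalue=float(fit.pvalues["post"]),
            pct_change=100.0 * (np.exp(coef) - 1.0),  # odds-ratio scale
            minutes_change=float("nan"), pre_mean_minutes=float("nan"),
            spec_id=f"{outcome}|{'+'.join(covariate_groups) or 'unadjusted'}",
            n_obs=int(fit.nobs), outcome=outcome,
        )
    return out


# -- descriptive tables -----------------------------------------------------

CONTINUOUS_VARS = [("los", "ED length of stay (min)"), ("age", "Age (years)"),
                   ("esi", "ESI")]
BINARY_VARS = [
    ("disposition", "Discharged (%)", lambda d: d["disposition"] == "discharged"),
    ("returned_72h", "ED return within 72 h (%)", lambda d: d["returned_72h"]),
    ("returned_72h_admit", "72 h return with admit (%)", lambda d: d["returned_72h_admit"]),
    ("sex", "Female (%)", lambda d: d["sex"] == "F"),
    ("race", "White (%)", lambda d: d["race"] == "white"),
    ("proc_iv", "IV (%)", lambda d: d["proc_iv"]),
    ("proc_ct_con", "CT with IV contrast (%)", lambda d: d["proc_ct_con"]),
    ("proc_ct_noncon", "CT without IV contrast (%)", lambda d: d["proc_ct_noncon"]),
    ("proc_xray", "X-ray (%)", lambda d: d["proc_xray"]),
    ("proc_us", "Ultrasound (%)", lambda d: d["proc_us"]),
]


def summarize_table1(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Pre/post descriptive comparison: mean (SD) with Welch's t-test for
    continuous variables, percentages with the chi-square test for binary
    ones. The LOS row carries the difference in minutes and as a percent of
    the pre-period mean (difference = pre mean - post mean exactly)."""
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("pre and post tables must both be non-empty")
    rows = []
    for col, label in CONTINUOUS_VARS:
        a, b = pre[col].astype(float), post[col].astype(float)
        if len(a) > 1 and len(b) > 1:
            _, p = stats.ttest_ind(a, b, equal_var=False)
            sd_a, sd_b = float(a.std(ddof=1)), float(b.std(ddof=1))
        else:
            p, sd_a, sd_b = float("nan"), float("nan"), float("nan")
        row = {"variable": label, "pre": float(a.mean()), "pre_sd": sd_a,
               "post": float(b.mean()), "post_sd": sd_b,
               "test": "welch_t", "pvalue": float(p)}
        if col == "los":
            diff = float(a.mean() - b.mean())
            row["difference_minutes"] = diff
            row["difference_pct_of_pre"] = 100.0 * diff / float(a.mean())
        rows.append(row)
    for col, label, fn in BINARY_VARS:
        if col not in pre.columns or col not in post.columns:
            continue
        x1, x2 = int(fn(pre).sum()), int(fn(post).sum())
        n1, n2 = len(pre), len(post)
        table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
        if table.min() >= 0 and table.sum(axis=1).min() > 0 and table.min() < 5:
            p = float(stats.fisher_exact(table)[1])
            test = "fisher"
        else:
            p = float(stats.chi2_contingency(table, correction=False)[1])
            test = "chi2"
        rows.append({"variable": label, "pre": 100.0 * x1 / n1, "pre_sd": float("nan"),
                     "post": 100.0 * x2 / n2, "post_sd": float("nan"),
                     "test": test, "pvalue": p})
    out = pd.DataFrame(rows)
    out.attrs["multiplicity_correction"] = "none"
    return out


def _select_test(table: np.ndarray, small_cell: int = 10) -> str:
    """The small-cell rule: Fisher's exact test whenever any cell of the 2x2
    is below the threshold (strictly), Pearson chi-square otherwise."""
    return "fisher" if int(table.min()) < small_cell else "chi2"


def vpp_routing_table2(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Per-ESI-stratum VPP routing comparison (ESI 3 split into
    skin/urinary/eye vs other). Counts and percentages of all stratum
    patients per period; test chosen by the small-cell rule."""
    def stratum(df):
        sue = df["complaint"].isin(["skin", "urinary", "eye"])
        return np.where(df["esi"] == 3,
                        np.where(sue, "3 - skin/urinary/eye", "3 - other"),
                        df["esi"].astype(str))

    pre = pre.assign(_s=stratum(pre))
    post = post.assign(_s=stratum(post))
    order = ["1", "2", "3 - other", "3 - skin/urinary/eye", "4", "5"]
    rows = []
    for s in order:
        a, b = pre[pre["_s"] == s], post[post["_s"] == s]
        x1, n1 = int(a["seen_in_vpp"].sum()), len(a)
        x2, n2 = int(b["seen_in_vpp"].sum()), len(b)
        row = {"esi_stratum": s, "pre_vpp": x1, "pre_total": n1,
               "pre_pct": 100.0 * x1 / n1 if n1 else float("nan"),
               "post_vpp": x2, "post_total": n2,
               "post_pct": 100.0 * x2 / n2 if n2 else float("nan")}
        if n1 == 0 or n2 == 0:
            row.update(test=None, pvalue=float("nan"))
        else:
            table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
            test = _select_test(table)
            if test == "fisher":
                p = float(stats.fisher_exact(table)[1])
            else:
                p = float(stats.chi2_contingency(table, correction=False)[1])
            row.update(test=test, pvalue=p)
        rows.append(row)
    return pd.DataFrame(rows)


def reconstruct_denominators(count: int, printed_pct: float,
                             search_max: int = 100_000) -> dict:
    """Smallest denominator n <= search_max whose percentage rounds (2 dp) to
    the printed value, plus whether n is unique within +/-10%."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if not 0.0 < printed_pct <= 100.0:
        raise ValueError("printed_pct must lie in (0, 100]")
    matches = []
    lo_needed = None
    for n in range(max(count, 1), search_max + 1):
        pct = 100.0 * count / n
        if abs(pct - printed_pct) <= 0.005 + 1e-12:
            matches.append(n)
            if lo_needed is None:
                lo_needed = n
        if lo_needed is not None and n > int(lo_needed * 1.1) + 1:
            break
    if not matches:
        raise ValueError(f"no denominator up to {search_max} prints "
                         f"{count} as {printed_pct:.2f}%")
    n0 = matches[0]
    within = [m for m in matches if m <= n0 * 1.1]
    return {"denominator": n0, "unique_within_10pct": len(within) == 1,
            "candidates": within}


def robustness_suite(
    encounters: pd.DataFrame,
    specs: list[dict] | None = None,
) -> pd.DataFrame:
    """One EffectEstimate per model specification, with the implied
    minutes-change range summarized in the frame's attrs."""
    if specs is None:
        specs = [
            {"covariate_groups": [], "spec_id": "unadjusted"},
            {"covariate_groups": ["patient"], "spec_id": "patient"},
            {"covariate_groups": ["patient"], "continuous_esi": True,
             "spec_id": "patient_continuous_esi"},
            {"covariate_groups": ["patient", "operational"], "spec_id": "patient+operational"},
            {"covariate_groups": ["patient", "operational", "saturation"],
             "spec_id": "full"},
        ]
    if len(specs) < 1:
        raise ValueError("need at least one specification")
    rows = [fit_log_los_model(encounters, **spec).to_dict() for spec in specs]
    out = pd.DataFrame(rows)
    out.attrs["minutes_change_range"] = (float(out["minutes_change"].min()),
                                         float(out["minutes_change"].max()))
    return out
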