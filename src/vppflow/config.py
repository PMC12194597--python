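"""Generator configuration for synthetic ED encounter data.

The defaults emulate a large tertiary emergency department: roughly 56,000
visits per year flowing through 56 treatment beds, an acuity mix centered on
ESI 3 (mean 2.88, SD ~0.66), a right-skewed length of stay with mean near
259 minutes, and procedure frequencies (IV access, CT with/without contrast,
X-ray, ultrasound) matching the published descriptive table. All probability
vectors are validated to sum to one; all rates must be strictly positive.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

# ESI 1..5 acuity mix: mean 2.88, SD 0.668 — tertiary-center case mix with
# very few ESI 1 and ESI 5 presentations.
DEFAULT_ESI_PROBS = (0.025, 0.205, 0.645, 0.115, 0.010)

COMPLAINT_CATEGORIES = (
    "abdominal",
    "chest",
    "respiratory",
    "neurological",
    "musculoskeletal",
    "skin",
    "urinary",
    "eye",
    "other",
)

DEFAULT_COMPLAINT_PROBS = {
    "abdominal": 0.20,
    "chest": 0.15,
    "respiratory": 0.10,
    "neurological": 0.10,
    "musculoskeletal": 0.14,
    "skin": 0.06,
    "urinary": 0.07,
    "eye": 0.03,
    "other": 0.15,
}

VITAL_NAMES = ("heart_rate", "systolic_bp", "resp_rate", "temperature", "spo2")

PROCEDURES = ("proc_iv", "proc_ct_con", "proc_ct_noncon", "proc_xray", "proc_us")

SHIFT_LABELS = ("0-6", "6-12", "12-18", "18-24")

PERIODS = ("pre", "edu", "post")


@dataclass(frozen=True)
class VitalSpec:
    """One vital sign: normal mean/SD, the shift (in SDs) applied when the
    vital is 'abnormal', and the probability of abnormality per ESI level."""

    mean: float
    sd: float
    abnormal_shift_sd: float
    abnormal_prob_by_esi: tuple[float, float, float, float, float]


DEFAULT_VITALS: dict[str, VitalSpec] = {
    "heart_rate": VitalSpec(80.0, 12.0, 2.5, (0.80, 0.50, 0.25, 0.10, 0.05)),
    "systolic_bp": VitalSpec(128.0, 15.0, -2.2, (0.70, 0.40, 0.18, 0.08, 0.04)),
    "resp_rate": VitalSpec(16.0, 2.5, 2.8, (0.75, 0.45, 0.20, 0.08, 0.03)),
    "temperature": VitalSpec(36.9, 0.35, 3.0, (0.40, 0.30, 0.18, 0.10, 0.06)),
    "spo2": VitalSpec(97.5, 1.2, -3.0, (0.65, 0.35, 0.12, 0.04, 0.02)),
}

# P(procedure | ESI); skin/urinary/eye complaints receive a multiplicative
# reduction (these presentations rarely need advanced imaging or continuous
# IV access — the mechanism that makes them safely VPP-dischargeable).
# Mixtures under the default ESI/complaint distributions land near the
# published marginals (IV 65%, CT+c 24.9%, CT-c 19.8%, X-ray 45.6%, US 11.8%).
DEFAULT_PROCEDURE_PROBS: dict[str, tuple[float, float, float, float, float]] = {
    "proc_iv": (0.95, 0.92, 0.76, 0.24, 0.045),
    "proc_ct_con": (0.48, 0.42, 0.28, 0.055, 0.011),
    "proc_ct_noncon": (0.43, 0.35, 0.21, 0.066, 0.011),
    "proc_xray": (0.58, 0.53, 0.48, 0.45, 0.27),
    "proc_us": (0.165, 0.145, 0.125, 0.073, 0.031),
}

# multiplicative reduction for skin/urinary/eye presentations
DEFAULT_PROCEDURE_SUE_MULTIPLIER = {
    "proc_iv": 0.30,
    "proc_ct_con": 0.15,
    "proc_ct_noncon": 0.20,
    "proc_xray": 0.55,
    "proc_us": 0.70,
}

# Arrivals per hour by shift block (0-6, 6-12, 12-18, 18-24); the daily total
# of ~154 arrivals annualizes to ~56,200 visits.
DEFAULT_ARRIVAL_RATES = {"0-6": 3.0, "6-12": 8.0, "12-18": 8.5, "18-24": 6.2}

DEFAULT_STAFFING = {
    # shift -> (physicians, nurses)
    "0-6": (3, 8),
    "6-12": (6, 11),
    "12-18": (7, 12),
    "18-24": (5, 10),
}

# Ground-truth bed need: logistic in acuity, complaint group and count of
# abnormal vitals. ESI 1-2 are forced to bed-need regardless.
DEFAULT_BED_NEED_COEF = {
    "intercept": 4.0,
    "esi": -1.6,  # per ESI level above 1
    "abnormal_vital": 1.2,  # per abnormal vital
    "complaint_skin_urinary_eye": -1.5,
}

# Observed VPP routing rates by (ESI stratum, period); post-period rates follow
# the published routing table, pre-period rates the legacy ad hoc pathway.
DEFAULT_VPP_ROUTING = {
    "pre": {"1": 0.0, "2": 0.0028, "3_other": 0.0155, "3_sue": 0.0123, "4": 0.1808, "5": 0.20},
    "edu": {"1": 0.0, "2": 0.004, "3_other": 0.034, "3_sue": 0.049, "4": 0.39, "5": 0.51},
    "post": {"1": 0.0, "2": 0.0053, "3_other": 0.0526, "3_sue": 0.0864, "4": 0.5997, "5": 0.8261},
}

# Log-normal LOS: meanlog = base(bed need) + procedure increments; the bases
# are calibrated so the marginal mixture has mean ~258.7 min, SD ~122 min.
DEFAULT_LOS_MODEL = {
    "sigma": 0.383,
    "base_no_bed": 4.7537,
    "base_bed": 5.4437,
    "esi_slope": 0.0,  # optional extra acuity gradient on meanlog
    "proc_increments": {
        "proc_iv": 0.10,
        "proc_ct_con": 0.12,
        "proc_ct_noncon": 0.10,
        "proc_xray": 0.05,
        "proc_us": 0.06,
    },
}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic ED encounter generator.

    Defaults reproduce the study conditions: a 13-week horizon split into
    pre / educational / post periods (33 / 21 / 35 days), a multiplicative
    post-period LOS effect of 0.9585 (a 4.15% reduction), 56 beds, and the
    acuity, complaint, vitals, procedure and LOS distributions documented in
    this module.
    """

    n_encounters: int = 13700
    arrival_rates_per_hour: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARRIVAL_RATES)
    )
    esi_probs: tuple[float, ...] = DEFAULT_ESI_PROBS
    complaint_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLAINT_PROBS)
    )
    age_mean_sd: tuple[float, float] = (58.9, 21.0)
    female_prob: float = 0.535
    white_prob: float = 0.885
    vitals_spec: dict[str, VitalSpec] = field(default_factory=lambda: dict(DEFAULT_VITALS))
    procedure_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PROCEDURE_PROBS)
    )
    procedure_sue_multiplier: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROCEDURE_SUE_MULTIPLIER)
    )
    bed_need_coef: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BED_NEED_COEF))
    los_model: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_LOS_MODEL)))
    vpp_routing: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_VPP_ROUTING)))
    admit_prob_given_bed_by_esi: tuple[float, ...] = (0.90, 0.55, 0.35, 0.20, 0.10)
    return_72h_prob: float = 0.039
    return_admit_frac: float = 0.60
    intervention_effect: float = 0.9585
    period_cutover_days: tuple[float, float] = (33.0, 54.0)
    horizon_days: float = 89.0
    n_beds: int = 56
    staffing_spec: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STAFFING)
    )
    n_physicians_pool: int = 20
    # Day-to-day demand heterogeneity (gamma multiplier on arrival rates) used
    # by the ED-state series so that genuine saturation episodes occur.
    demand_day_cv: float = 0.25
    mean_boarding_min: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_encounters < 0:
            raise ValueError("n_encounters must be non-negative")
        for name, vec in (
            ("esi_probs", list(self.esi_probs)),
            ("complaint_probs", list(self.complaint_probs.values())),
        ):
            if any(p < 0 for p in vec) or abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if len(self.esi_probs) != 5:
            raise ValueError("esi_probs must have 5 entries (ESI 1..5)")
        for shift, rate in self.arrival_rates_per_hour.items():
            if rate < 0:
                raise ValueError(f"arrival rate for shift {shift} must be >= 0")
        if not (0.0 < self.intervention_effect < 2.0):
            raise ValueError("intervention_effect must lie in (0, 2)")
        c1, c2 = self.period_cutover_days
        if not (0 < c1 < c2 < self.horizon_days):
            raise ValueError("period cutovers must be ordered within the horizon")
        if self.n_beds <= 0:
            raise ValueError("n_beds must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vitals_spec"] = {
            k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
            for k, v in self.vitals_spec.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "vitals_spec" in d:
            d["vitals_spec"] = {
                k: VitalSpec(
                    mean=v["mean"],
                    sd=v["sd"],
                    abnormal_shift_sd=v["abnormal_shift_sd"],
                    abnormal_prob_by_esi=tuple(v["abnormal_prob_by_esi"]),
                )
                if not isinstance(v, VitalSpec)
                else v
                for k, v in d["vitals_spec"].items()
            }
        for key in ("esi_probs", "age_mean_sd", "period_cutover_days",
                    "admit_prob_given_bed_by_esi"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "procedure_probs" in d:
            d["procedure_probs"] = {k: tuple(v) for k, v in d["procedure_probs"].items()}
        if "staffing_spec" in d:
            d["staffing_spec"] = {k: tuple(v) for k, v in d["staffing_spec"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
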