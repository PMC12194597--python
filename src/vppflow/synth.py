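"""Synthetic ED encounter and ED-state generators.

No public encounter-level ED dataset exists for this design problem, so the
package ships a generator whose defaults emulate a high-acuity tertiary ED:
Poisson arrivals with piecewise-constant shift rates, an ESI mix centered on
3, vitals whose abnormality probability rises with acuity, procedure use
conditional on ESI, a logistic ground-truth "requires an ED bed" mechanism
(so the learnable signal is known exactly), log-normal length of stay
conditional on bed need and procedures, and a configurable multiplicative
post-period LOS effect for parameter-recovery experiments.

The generator is deterministic given (seed, config): the same pair yields a
byte-identical table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import (
    COMPLAINT_CATEGORIES,
    PERIODS,
    PROCEDURES,
    SHIFT_LABELS,
    GeneratorConfig,
)

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440.0
SHIFT_STARTS = {"0-6": 0.0, "6-12": 360.0, "12-18": 720.0, "18-24": 1080.0}

ENCOUNTER_COLUMNS = [
    "encounter_id", "arrival_time", "age", "sex", "race", "esi", "complaint",
    "heart_rate", "systolic_bp", "resp_rate", "temperature", "spo2",
    "n_abnormal_vitals",
    "proc_iv", "proc_ct_con", "proc_ct_noncon", "proc_xray", "proc_us",
    "disposition", "los", "seen_in_vpp", "period", "physician_id",
    "returned_72h", "returned_72h_admit",
    "n_waiting", "n_in_treatment", "physicians_on_duty", "nurses_on_duty",
    "shift", "saturated", "true_bed_need",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def shift_of_minute(minute_of_day: np.ndarray) -> np.ndarray:
    """Map minute-of-day to the four staffing shift labels."""
    idx = (np.asarray(minute_of_day) // 360).astype(int) % 4
    return np.asarray(SHIFT_LABELS)[idx]


def _arrival_times(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """First n_encounters arrival times (minutes) of a piecewise-constant
    Poisson process over consecutive days."""
    n = config.n_encounters
    if n == 0:
        return np.empty(0)
    daily = 6.0 * sum(config.arrival_rates_per_hour[s] for s in SHIFT_LABELS)
    times: list[np.ndarray] = []
    total = 0
    day = 0
    while total < n:
        block_days = max(int(np.ceil((n - total) / max(daily, 1e-9) * 1.25)), 2)
        for shift in SHIFT_LABELS:
            rate = config.arrival_rates_per_hour[shift]
            counts = rng.poisson(rate * 6.0, size=block_days)
            k = int(counts.sum())
            if k == 0:
                continue
            day_idx = np.repeat(np.arange(day, day + block_days), counts)
            t = (day_idx * MINUTES_PER_DAY + SHIFT_STARTS[shift]
                 + rng.uniform(0.0, 360.0, size=k))
            times.append(t)
            total += k
        day += block_days
        if daily <= 0:
            raise ValueError("all arrival rates are zero; cannot generate encounters")
    all_t = np.sort(np.concatenate(times))
    return all_t[:n]


def periods_from_times(arrival_time: np.ndarray, cutover_minutes: tuple[float, float]) -> np.ndarray:
    c1, c2 = cutover_minutes
    if not c1 < c2:
        raise ValueError("cutover times must be strictly increasing")
    t = np.asarray(arrival_time, dtype=float)
    out = np.where(t < c1, "pre", np.where(t < c2, "edu", "post"))
    return out.astype(object)


def inject_intervention_effect(
    encounters: pd.DataFrame,
    effect: float,
    cutover_minutes: tuple[float, float],
) -> pd.DataFrame:
    """Assign pre/edu/post periods from arrival time and multiply post-period
    LOS by `effect`. Pre and educational rows are untouched."""
    if not (0.0 < effect < 2.0):
        raise ValueError("effect must lie in (0, 2)")
    out = encounters.copy()
    out["period"] = periods_from_times(out["arrival_time"].to_numpy(), cutover_minutes)
    post = out["period"].to_numpy() == "post"
    out.loc[post, "los"] = out.loc[post, "los"] * effect
    return out


def generate_encounters(config: GeneratorConfig, post_acuity_shift: float = 0.0) -> pd.DataFrame:
    """Generate the synthetic encounter table.

    Returns exactly ``config.n_encounters`` rows with the full schema, sorted
    by arrival time. ``post_acuity_shift`` > 0 plants a confounder: that
    fraction of post-period patients has its ESI bumped one level toward low
    acuity before all downstream variables are drawn.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_encounters
    cutovers_min = (config.period_cutover_days[0] * MINUTES_PER_DAY,
                    config.period_cutover_days[1] * MINUTES_PER_DAY)

    arrival = _arrival_times(config, rng)
    period = periods_from_times(arrival, cutovers_min) if n else np.empty(0, dtype=object)

    esi = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.esi_probs))
    if post_acuity_shift > 0.0 and n:
        bump = (period == "post") & (rng.random(n) < post_acuity_shift)
        esi = np.where(bump, np.minimum(esi + 1, 5), esi)

    cats = list(config.complaint_probs)
    complaint = rng.choice(cats, size=n, p=np.asarray([config.complaint_probs[c] for c in cats]))

    age_mu, age_sd = config.age_mean_sd
    age = np.clip(rng.normal(age_mu, age_sd, size=n), 0.0, 105.0)
    sex = np.where(rng.random(n) < config.female_prob, "F", "M")
    race = np.where(rng.random(n) < config.white_prob, "white", "non-white")

    vitals = {}
    n_abnormal = np.zeros(n)
    for name, vs in config.vitals_spec.items():
        p_abn = np.asarray(vs.abnormal_prob_by_esi)[esi - 1] if n else np.empty(0)
        abn = rng.random(n) < p_abn
        vitals[name] = vs.mean + vs.sd * rng.standard_normal(n) + abn * vs.abnormal_shift_sd * vs.sd
        n_abnormal += abn

    sue = np.isin(complaint, ["skin", "urinary", "eye"])
    procs = {}
    for pname in PROCEDURES:
        p = np.asarray(config.procedure_probs[pname])[esi - 1] if n else np.empty(0)
        mult = config.procedure_sue_multiplier.get(pname, 1.0)
        p = np.where(sue, p * mult, p)
        procs[pname] = rng.random(n) < p

    coef = config.bed_need_coef
    logit = (coef["intercept"] + coef["esi"] * (esi - 1)
             + coef["abnormal_vital"] * n_abnormal
             + coef["complaint_skin_urinary_eye"] * sue)
    true_bed_need = (rng.random(n) < _sigmoid(logit)) | (esi <= 2)

    admit_p = np.asarray(config.admit_prob_given_bed_by_esi)[esi - 1] if n else np.empty(0)
    admitted = true_bed_need & (rng.random(n) < admit_p)
    disposition = np.where(admitted, "admitted", "discharged")

    lm = config.los_model
    meanlog = np.where(true_bed_need, lm["base_bed"], lm["base_no_bed"]).astype(float)
    meanlog += lm.get("esi_slope", 0.0) * (3 - esi)
    for pname, inc in lm["proc_increments"].items():
        meanlog += inc * procs[pname]
    los_raw = np.exp(meanlog + lm["sigma"] * rng.standard_normal(n))

    stratum = np.where(
        esi == 3, np.where(sue, "3_sue", "3_other"), esi.astype(str)
    ) if n else np.empty(0, dtype=object)
    vpp_p = np.zeros(n)
    for per in PERIODS:
        mask = period == per
        if mask.any():
            rates = config.vpp_routing[per]
            vpp_p[mask] = np.asarray([rates[s] for s in stratum[mask]])
    seen_in_vpp = rng.random(n) < vpp_p

    returned = rng.random(n) < config.return_72h_prob
    returned_admit = returned & (rng.random(n) < config.return_admit_frac)

    physician = rng.integers(0, config.n_physicians_pool, size=n)

    df = pd.DataFrame({
        "encounter_id": np.arange(n, dtype=np.int64),
        "arrival_time": arrival,
        "age": age, "sex": sex, "race": race,
        "esi": esi.astype(np.int64) if n else np.array([], dtype=np.int64),
        "complaint": complaint,
        **{k: v for k, v in vitals.items()},
        "n_abnormal_vitals": n_abnormal.astype(np.int64) if n else np.array([], dtype=np.int64),
        **{k: v.astype(bool) for k, v in procs.items()},
        "disposition": disposition,
        "los": los_raw,
        "seen_in_vpp": seen_in_vpp,
        "period": period,
        "physician_id": physician,
        "returned_72h": returned,
        "returned_72h_admit": returned_admit,
    })
    if n == 0:
        for col in ENCOUNTER_COLUMNS:
            if col not in df.columns:
                df[col] = pd.Series(dtype=float)
        return df[ENCOUNTER_COLUMNS]

    # congestion / staffing covariates at arrival, from an ED-state series
    # driven by a sub-seed of the same generator seed
    horizon = float(np.ceil(arrival[-1] / MINUTES_PER_DAY) * MINUTES_PER_DAY)
    state_cfg = GeneratorConfig.from_dict({**config.to_dict(), "seed": config.seed + 1_000_003})
    states = generate_ed_state_series(state_cfg, horizon)
    idx = np.minimum((arrival // 10).astype(int), len(states) - 1)
    for col in ("n_waiting", "n_in_treatment", "physicians_on_duty",
                "nurses_on_duty", "shift", "saturated"):
        df[col] = states[col].to_numpy()[idx]

    df["true_bed_need"] = true_bed_need
    df = inject_intervention_effect(df, config.intervention_effect, cutovers_min)
    logger.info("generated %d encounters (seed=%d, config=%s)",
                n, config.seed, config.config_hash())
    return df[ENCOUNTER_COLUMNS]


def generate_ed_state_series(config: GeneratorConfig, horizon_minutes: float) -> pd.DataFrame:
    """Simulate the ED census on a 10-minute grid.

    A birth-death approximation: Poisson arrivals per step (with a gamma
    day-level demand multiplier producing realistic surge days), patients move
    from the waiting room into staffed treatment spaces as capacity frees, and
    occupants depart memorylessly with mean occupancy equal to mean LOS plus
    boarding time for admitted patients. The saturation flag is the package's
    saturation rule applied to each row.
    """
    from .policy import SaturationThresholds, saturation_rule

    if horizon_minutes < 0:
        raise ValueError("horizon must be non-negative")
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = 10.0
    n_steps = int(horizon_minutes // dt)
    cols = ["time", "n_waiting", "n_in_treatment", "physicians_on_duty",
            "nurses_on_duty", "shift", "saturated"]
    if n_steps == 0:
        return pd.DataFrame({c: pd.Series(dtype=("object" if c == "shift" else float))
                             for c in cols})

    mean_occupancy = (np.exp(config.los_model["base_bed"] + config.los_model["sigma"] ** 2 / 2)
                      + 0.33 * config.mean_boarding_min)
    p_depart = 1.0 - np.exp(-dt / mean_occupancy)

    times = np.arange(n_steps) * dt
    minute_of_day = times % MINUTES_PER_DAY
    shifts = shift_of_minute(minute_of_day)
    day_idx = (times // MINUTES_PER_DAY).astype(int)
    n_days = int(day_idx.max()) + 1
    cv = config.demand_day_cv
    if cv > 0:
        shape = 1.0 / cv**2
        day_mult = rng.gamma(shape, 1.0 / shape, size=n_days)
    else:
        day_mult = np.ones(n_days)

    rates = np.asarray([config.arrival_rates_per_hour[s] for s in shifts])
    lam_step = rates * day_mult[day_idx] * dt / 60.0
    arrivals = rng.poisson(lam_step)

    phys = np.asarray([config.staffing_spec[s][0] for s in shifts])
    nurse = np.asarray([config.staffing_spec[s][1] for s in shifts])
    staffed = np.minimum(config.n_beds, 4 * nurse)

    thresholds = SaturationThresholds()
    n_wait = np.zeros(n_steps, dtype=np.int64)
    n_treat = np.zeros(n_steps, dtype=np.int64)
    waiting, treating = 0, 0
    for i in range(n_steps):
        departures = rng.binomial(treating, p_depart) if treating else 0
        treating -= departures
        waiting += int(arrivals[i])
        free = max(int(staffed[i]) - treating, 0)
        moved = min(waiting, free)
        waiting -= moved
        treating += moved
        n_wait[i] = waiting
        n_treat[i] = treating

    saturated = np.fromiter(
        (saturation_rule(int(w), int(t), int(s), thresholds)
         for w, t, s in zip(n_wait, n_treat, staffed)),
        dtype=bool, count=n_steps,
    )
    return pd.DataFrame({
        "time": times,
        "n_waiting": n_wait,
        "n_in_treatment": n_treat,
        "physicians_on_duty": phys,
        "nurses_on_duty": nurse,
        "shift": shifts,
        "saturated": saturated,
    })


def write_encounters_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_encounters_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("proc_iv", "proc_ct_con", "proc_ct_noncon", "proc_xray", "proc_us",
                "seen_in_vpp", "returned_72h", "returned_72h_admit", "saturated",
                "true_bed_need"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
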