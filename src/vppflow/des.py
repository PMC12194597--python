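"""Discrete-event simulation of ED patient flow.

A heap-based event engine simulating the two-stream system: a main-ED
single-server queue and a vertical-pathway (VPP) server whose physician takes
successive exponential vacations whenever the VPP queue empties (multiple
vacations — at the end of a vacation the server resumes only if a patient is
waiting, otherwise takes another vacation). Patients carry a ground-truth
bed-need flag and a risk score; routing follows the scenario's design:

* ``vpp``: score <= tau routes to the VPP; bed-need patients seen in the VPP
  (type I errors) re-queue at the main ED after their vertical assessment.
* ``no_vpp``: everyone to the main ED (plain M/M/1 — also the analytic
  validation oracle).
* ``fast_track``: a dedicated always-available server restricted to
  low-acuity (no-bed-need) arrivals; mistriaged bed-need patients re-queue
  at the main ED.
* ``physician_in_triage``: an upfront triage service stage for all arrivals,
  after which everyone queues at the main ED; a configurable rework
  probability adds a second main-ED service draw (deviating management plan).

Events are ordered by (time, sequence number) so replications are exactly
reproducible per seed. All internal times are minutes; `QueueParams` rates
(per hour) are converted on entry.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .queueing import QueueParams, mm1_metrics, mm1_vacation_metrics

DESIGNS = ("vpp", "no_vpp", "fast_track", "physician_in_triage")


@dataclass
class SimScenario:
    design: str
    params: QueueParams
    tau: float = 0.5
    horizon: float = 20_000.0  # minutes
    warmup: float | None = None  # default 20% of horizon
    n_replications: int = 3
    seeds: tuple[int, ...] | None = None
    # optional design knobs
    score_dists: tuple[tuple[float, float], tuple[float, float]] = ((5.0, 2.0), (2.0, 5.0))
    rework_prob: float = 0.15  # physician-in-triage deviating-plan rework
    label: str | None = None

    def validate(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; one of {DESIGNS}")
        warm = self.warmup if self.warmup is not None else 0.2 * self.horizon
        if not 0 <= warm < self.horizon:
            raise ValueError("warmup must lie in [0, horizon)")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")


@dataclass
class SimResult:
    scenario: SimScenario
    patients: pd.DataFrame  # per-patient records of the last replication
    replications: pd.DataFrame  # one row per replication
    summary: dict  # across-replication means and 95% CIs

    def ci(self, metric: str) -> tuple[float, float]:
        return self.summary[f"{metric}_ci"]


class _Server:
    """Single server with FIFO queue and optional multiple vacations."""

    __slots__ = ("name", "rate", "vac_rate", "busy", "on_vacation", "queue")

    def __init__(self, name: str, rate_per_min: float, vac_rate_per_min: float | None):
        self.name = name
        self.rate = rate_per_min
        self.vac_rate = vac_rate_per_min
        self.busy = False
        self.on_vacation = False
        self.queue: deque = deque()


def _exp(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate)


def _simulate_once(scn: SimScenario, seed: int) -> tuple[pd.DataFrame, dict]:
    rng = np.random.default_rng(seed)
    p = scn.params
    lam = p.lambda_total / 60.0
    mu_main = p.mu_main / 60.0
    mu_vpp = p.mu_vpp / 60.0
    theta = p.theta / 60.0
    warm = scn.warmup if scn.warmup is not None else 0.2 * scn.horizon
    (a1, b1), (a0, b0) = scn.score_dists

    servers: dict[str, _Server] = {"main": _Server("main", mu_main, None)}
    if scn.design == "vpp":
        servers["vpp"] = _Server("vpp", mu_vpp, theta)
    elif scn.design == "fast_track":
        servers["ft"] = _Server("ft", mu_vpp, None)
    elif scn.design == "physician_in_triage":
        servers["triage"] = _Server("triage", mu_vpp, None)

    events: list = []
    seq = 0

    def push(t, kind, payload):
        nonlocal seq
        heapq.heappush(events, (t, seq, kind, payload))
        seq += 1

    patients: list[dict] = []
    n_in_system = 0
    area_n = 0.0
    area_n_first_half = 0.0
    half_t = scn.horizon / 2.0
    last_t = 0.0

    def bump_area(t):
        nonlocal area_n, area_n_first_half, last_t
        if last_t < half_t:
            area_n_first_half += n_in_system * (min(t, half_t) - last_t)
        area_n += n_in_system * (t - last_t)
        last_t = t

    def start_service(srv: _Server, t: float):
        pat = srv.queue.popleft()
        srv.busy = True
        pat[f"start_{srv.name}"] = t
        svc = _exp(rng, srv.rate)
        if srv.name == "main" and pat.get("requeued"):
            # vertical assessment already initiated part of the workup
            svc *= p.requeue_load_frac
        push(t + svc, "service_end", (srv.name, pat))

    def join(srv: _Server, pat: dict, t: float):
        pat[f"join_{srv.name}"] = t
        srv.queue.append(pat)
        if srv.vac_rate is not None:
            if not srv.busy and not srv.on_vacation:
                # only at t=0 before the first vacation is scheduled
                start_service(srv, t)
        elif not srv.busy:
            start_service(srv, t)

    def route(pat: dict) -> str:
        if scn.design == "no_vpp":
            return "main"
        if scn.design == "vpp":
            return "vpp" if pat["score"] <= scn.tau else "main"
        if scn.design == "fast_track":
            return "ft" if not pat["bed_need"] else "main"
        return "triage"  # physician_in_triage: everyone starts there

    if lam > 0:
        push(_exp(rng, lam), "arrival", None)
    if "vpp" in servers:
        servers["vpp"].on_vacation = True
        push(_exp(rng, theta), "vacation_end", "vpp")

    pid = 0
    while events:
        t, _, kind, payload = heapq.heappop(events)
        if t > scn.horizon:
            bump_area(scn.horizon)
            break
        if kind == "arrival":
            bump_area(t)
            bed = bool(rng.random() < p.prevalence)
            score = float(rng.beta(a1, b1) if bed else rng.beta(a0, b0))
            pat = {"id": pid, "arrival": t, "bed_need": bed, "score": score,
                   "departure": math.nan, "requeued": False}
            pid += 1
            n_in_system += 1
            pat["route"] = route(pat)
            patients.append(pat)
            join(servers[pat["route"]], pat, t)
            push(t + _exp(rng, lam), "arrival", None)
        elif kind == "service_end":
            bump_area(t)
            name, pat = payload
            srv = servers[name]
            srv.busy = False
            pat[f"end_{name}"] = t
            done = True
            if name in ("vpp", "ft") and pat["bed_need"]:
                pat["requeued"] = True  # type I / mistriage: re-queue at main
                join(servers["main"], pat, t)
                done = False
            elif name == "triage":
                if rng.random() < scn.rework_prob:
                    pat["rework"] = True
                join(servers["main"], pat, t)
                done = False
            elif name == "main" and pat.get("rework") and not pat.get("rework_done"):
                pat["rework_done"] = True
                srv.queue.appendleft(pat)  # redo work immediately
                start_service(srv, t)
                done = False
            if done:
                pat["departure"] = t
                n_in_system -= 1
            if not srv.busy:
                if srv.queue:
                    start_service(srv, t)
                elif srv.vac_rate is not None:
                    srv.on_vacation = True
                    push(t + _exp(rng, srv.vac_rate), "vacation_end", name)
        elif kind == "vacation_end":
            bump_area(t)
            srv = servers[payload]
            srv.on_vacation = False
            if srv.queue:
                start_service(srv, t)
            else:
                srv.on_vacation = True
                push(t + _exp(rng, srv.vac_rate), "vacation_end", payload)
    else:
        bump_area(min(last_t, scn.horizon))

    df = pd.DataFrame(patients)
    if df.empty:
        summary = {"n_arrivals": 0, "n_departed": 0, "n_in_system_end": 0,
                   "mean_wait": math.nan, "mean_time_in_system": math.nan,
                   "throughput_per_hour": 0.0, "avg_number_in_system": 0.0,
                   "unstable_flag": False}
        return df, summary

    df["wait_first"] = np.nan
    for name in servers:
        started = df.get(f"start_{name}")
        joined = df.get(f"join_{name}")
        if started is not None and joined is not None:
            first = df["route"] == (name if name != "triage" else "triage")
            df.loc[first, "wait_first"] = (started - joined)[first]
    df["time_in_system"] = df["departure"] - df["arrival"]

    departed = df["departure"].notna()
    post_warm = departed & (df["arrival"] >= warm)
    n_arr = len(df)
    n_dep = int(departed.sum())
    in_sys_end = n_arr - n_dep
    horizon_hours = (scn.horizon - warm) / 60.0
    # queue growth flag: time-average census in the second half of the run
    # far exceeds the first half (a stable queue fluctuates around one level)
    avg_n = area_n / max(scn.horizon, 1e-9)
    avg_first = area_n_first_half / max(half_t, 1e-9)
    avg_second = (area_n - area_n_first_half) / max(scn.horizon - half_t, 1e-9)
    unstable = avg_second > 2.0 * avg_first + 10.0
    summary = {
        "n_arrivals": n_arr,
        "n_departed": n_dep,
        "n_in_system_end": in_sys_end,
        "mean_wait": float(df.loc[post_warm, "wait_first"].mean()),
        "mean_time_in_system": float(df.loc[post_warm, "time_in_system"].mean()),
        "throughput_per_hour": float((df.loc[departed, "arrival"] >= warm).sum() / horizon_hours),
        "avg_number_in_system": float(avg_n),
        "unstable_flag": bool(unstable),
    }
    return df, summary


def simulate(scenario: SimScenario) -> SimResult:
    """Run the scenario for its configured replications and summarize.

    Per-replication means are combined into across-replication means with
    t-based 95% confidence intervals. Warmup arrivals are excluded from wait
    and LOS summaries; conservation (arrivals = departures + in-system) holds
    per replication by construction and is exposed in the summaries.
    """
    scenario.validate()
    scenario.params.validate()
    seeds = scenario.seeds or tuple(range(1, scenario.n_replications + 1))
    if len(seeds) < scenario.n_replications:
        raise ValueError("need one seed per replication")
    rows, last_df = [], pd.DataFrame()
    for r in range(scenario.n_replications):
        last_df, summ = _simulate_once(scenario, int(seeds[r]))
        summ["replication"] = r
        summ["seed"] = int(seeds[r])
        rows.append(summ)
    reps = pd.DataFrame(rows)
    summary: dict = {"design": scenario.design, "label": scenario.label or scenario.design}
    for metric in ("mean_wait", "mean_time_in_system", "throughput_per_hour"):
        vals = reps[metric].to_numpy(dtype=float)
        m = float(np.nanmean(vals)) if np.isfinite(vals).any() else math.nan
        summary[metric] = m
        if len(vals) > 1 and np.isfinite(vals).all():
            half = stats.t.ppf(0.975, len(vals) - 1) * np.std(vals, ddof=1) / math.sqrt(len(vals))
        else:
            half = math.nan
        summary[f"{metric}_ci"] = (m - half, m + half)
    summary["any_unstable"] = bool(reps["unstable_flag"].any())
    return SimResult(scenario=scenario, patients=last_df, replications=reps, summary=summary)


def validate_against_analytic(
    grid: list[dict],
    n_patients: int = 100_000,
    n_replications: int = 3,
    base_seed: int = 1,
) -> pd.DataFrame:
    """Compare closed-form mean queue waits with simulated 95% CIs.

    Each grid point is a dict with ``kind`` ('mm1' or 'vacation') and rates
    per hour (``lam``, ``mu`` and, for vacation queues, ``theta``). The
    simulation horizon is sized to the requested number of patients. Returns
    one row per point with the analytic value, the simulated CI, and a
    coverage flag; the run is considered a validation failure when more than
    one point is uncovered.
    """
    if not grid:
        raise ValueError("empty validation grid")
    rows = []
    for i, point in enumerate(grid):
        kind = point["kind"]
        lam, mu = point["lam"], point["mu"]
        theta = point.get("theta", 1e9)
        if kind == "mm1":
            analytic = mm1_metrics(lam, mu)["mean_wait_in_queue"] * 60.0
            params = QueueParams(lambda_total=lam, mu_vpp=mu, mu_main=mu,
                                 theta=max(theta, 1e-9), prevalence=0.0)
            scn = SimScenario(design="no_vpp", params=params)
        elif kind == "vacation":
            analytic = mm1_vacation_metrics(lam, mu, theta)["mean_wait_in_queue"] * 60.0
            params = QueueParams(lambda_total=lam, mu_vpp=mu, mu_main=mu,
                                 theta=theta, prevalence=0.0)
            scn = SimScenario(design="vpp", params=params, tau=1.0)
        else:
            raise ValueError(f"unknown grid kind {kind!r}")
        horizon = n_patients / (lam / 60.0)
        scn.horizon = horizon
        scn.warmup = 0.2 * horizon
        scn.n_replications = n_replications
        scn.seeds = tuple(base_seed + 1000 * i + r for r in range(n_replications))
        res = simulate(scn)
        lo, hi = res.ci("mean_wait")
        rows.append({
            "kind": kind, "lam": lam, "mu": mu,
            "theta": theta if kind == "vacation" else math.nan,
            "analytic_wait_min": analytic,
            "sim_wait_min": res.summary["mean_wait"],
            "ci_lo": lo, "ci_hi": hi,
            "covered": bool(lo <= analytic <= hi),
        })
    report = pd.DataFrame(rows)
    report.attrs["n_uncovered"] = int((~report["covered"]).sum())
    report.attrs["passed"] = bool(report.attrs["n_uncovered"] <= 1)
    return report


def default_validation_grid() -> list[dict]:
    """Twelve stable (rate) points: six plain M/M/1 and six vacation queues."""
    mm1 = [
        {"kind": "mm1", "lam": 3.0, "mu": 6.0},
        {"kind": "mm1", "lam": 4.0, "mu": 6.0},
        {"kind": "mm1", "lam": 6.0, "mu": 8.0},
        {"kind": "mm1", "lam": 2.0, "mu": 10.0},
        {"kind": "mm1", "lam": 8.0, "mu": 10.0},
        {"kind": "mm1", "lam": 5.0, "mu": 12.0},
    ]
    vac = [
        {"kind": "vacation", "lam": 3.0, "mu": 6.0, "theta": 2.0},
        {"kind": "vacation", "lam": 4.0, "mu": 6.0, "theta": 4.0},
        {"kind": "vacation", "lam": 2.0, "mu": 8.0, "theta": 1.0},
        {"kind": "vacation", "lam": 6.0, "mu": 10.0, "theta": 3.0},
        {"kind": "vacation", "lam": 5.0, "mu": 8.0, "theta": 6.0},
        {"kind": "vacation", "lam": 2.5, "mu": 5.0, "theta": 2.0},
    ]
    return mm1 + vac


def compare_flow_designs(scenarios: list[SimScenario]) -> pd.DataFrame:
    """Run a set of flow designs and tabulate mean waits / time-in-system.

    Scenarios should share the arrival process and total service capacity
    (a resource-neutral comparison); a capacity mismatch is recorded as a
    warning column, not an error. No winner is asserted a priori.
    """
    if not scenarios:
        raise ValueError("no scenarios supplied")
    caps = [s.params.mu_main + s.params.mu_vpp for s in scenarios]
    lam0 = scenarios[0].params.lambda_total
    rows = []
    for s, cap in zip(scenarios, caps):
        res = simulate(s)
        rows.append({
            "label": s.label or s.design,
            "design": s.design,
            "lambda_per_hour": s.params.lambda_total,
            "prevalence": s.params.prevalence,
            "mean_wait_min": res.summary["mean_wait"],
            "mean_wait_ci_lo": res.summary["mean_wait_ci"][0],
            "mean_wait_ci_hi": res.summary["mean_wait_ci"][1],
            "mean_time_in_system_min": res.summary["mean_time_in_system"],
            "throughput_per_hour": res.summary["throughput_per_hour"],
            "any_unstable": res.summary["any_unstable"],
            "capacity_per_hour": cap,
            "capacity_warning": not math.isclose(cap, caps[0], rel_tol=1e-9)
                                or not math.isclose(s.params.lambda_total, lam0, rel_tol=1e-9),
        })
    return pd.DataFrame(rows).sort_values("mean_time_in_system_min").reset_index(drop=True)
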