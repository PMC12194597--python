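# Methods

This note documents the models, the calibrated defaults, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Synthetic ED cohort

The generator emulates a high-acuity tertiary ED. Arrivals follow a Poisson
process with piecewise-constant rates per six-hour shift (3.0 / 8.0 / 8.5 /
6.2 per hour), totalling ≈154 visits/day (≈56,000/yr). Acuity is drawn from
ESI probabilities (0.025, 0.205, 0.645, 0.115, 0.010), giving mean 2.88 and
SD 0.67 — a tertiary case mix with few ESI-1 and ESI-5 presentations. Age is
normal (58.9, 21.0) clipped to [0, 105]; sex and race are Bernoulli draws
kept only for descriptive tables.

Five vitals are normal draws with an ESI-dependent probability of an
"abnormal" shift (in SD units); the count of abnormal vitals feeds the
ground truth. Procedures (IV, CT ± contrast, X-ray, ultrasound) are
Bernoulli conditional on ESI, with a multiplicative reduction for skin,
urinary and eye complaints — these presentations rarely need advanced
imaging or continuous IV access, which is precisely what makes them safely
manageable without a bed. The per-ESI probabilities were calibrated once so
the implied marginals land near the published frequencies (IV 65%, CT+c
24.9%, CT−c 19.8%, X-ray 45.6%, US 11.8%).

Ground-truth bed need is logistic in acuity, the skin/urinary/eye indicator
and the abnormal-vital count (intercept 4.0, −1.6 per ESI level above 1,
−1.5 for skin/urinary/eye, +1.2 per abnormal vital), forced true for ESI ≤ 2.
This makes the learnable signal known exactly: prevalence declines
monotonically in ESI.

Length of stay is log-normal with meanlog depending on bed need plus small
procedure increments and σ = 0.383; the two bases (4.7537 / 5.4437) were
calibrated numerically so the marginal mixture has mean ≈ 258.7 min and SD
≈ 122 min with positive skew. A multiplicative intervention effect (default
0.9585, i.e. −4.15%) applies to post-period rows; the 13-week horizon splits
into pre (33 d), educational (21 d) and post (35 d) periods. Vertical
routing probabilities per (ESI stratum, period) follow the published
routing table for pre and post, with the educational period interpolated.

The ED-census series is a 10-minute birth–death approximation with a
gamma day-level demand multiplier (CV 0.25). Surge days push the census
past the saturation threshold for ≈8% of minutes — saturation is episodic,
not ambient. Encounters receive the census/staffing covariates at their
arrival minute.

What the generator does **not** emulate: boarding dynamics beyond a mean
occupancy add-on, inter-hospital transfer, seasonal or weekday structure,
free-text complaints, and any dependence of congestion on LOS (so the
regression's congestion covariates are controls, not confounders, unless a
confounder is planted explicitly via `post_acuity_shift`). Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted effects, not real-world effect sizes.

## Labeling

Tier order (first match wins): direct VPP discharge (seen vertically and
discharged — the gold no-bed cases), then ESI-3 discharged without any of
the four imaging modalities or IV therapy with LOS strictly under 120 min,
then ESI-4/5 without IV, then bed. "Imaging" means CT with/without
contrast, X-ray or ultrasound; "IV therapy" and "IV medications or fluids"
both map to the single IV flag. Zero-variance vitals standardize to zero
rather than NaN. Vitals are z-scored with training-split statistics so
held-out rows never leak into the scaling. The gold-standard test subset is
all gold no-bed rows plus an equal-size sample of unambiguous bed cases
(ESI ≤ 2 admitted), reserved for evaluation only.

## Risk model

A random forest (200 trees, min_samples_leaf 2, fixed seed) on triage
features only: ESI, age, z-scored vitals, one-hot complaint. Post-hoc
fields (procedures, disposition, LOS) are never predictors. Bootstrap
evaluation refits on resamples of the non-gold rows and scores AUC on the
fixed gold subset. Feature importance defaults to mean decrease in
impurity, with permutation importance as an option.

## Queueing model and routing cost

Rates are per hour; waits are reported in minutes. The VPP is an M/M/1
queue with multiple exponential vacations: when its queue empties, the
physician leaves for main-ED duties and returns after Exp(θ) intervals,
resuming only if someone is waiting. Its mean queue wait is the M/M/1 wait
plus the mean residual vacation 1/θ. The main ED is a plain M/M/1 queue.

Patients with score ≤ τ go vertical. Type-I patients (bed need, routed
vertically) re-queue at the main ED after their vertical assessment, but
load it by only κ = 0.65 of a full service: the vertical assessment
initiates part of the workup (orders placed from the waiting room). The
expected cost per arriving patient is

    w_vpp·f_vpp·Wq_vpp + w_main·f_main·Wq_main
      + c₁·p·F₁(τ) + c₂·(1−p)·(1−F₀(τ))

where F₁/F₀ are the class-conditional score CDFs, p the bed-need
prevalence, f_vpp/f_main the fractions of patients passing through each
stream. Defaults: c₁ = c₂ = 45 min; during declared saturation c₁ drops to
5 min, because a vertical assessment of a bed-bound patient replaces
waiting-room dead time rather than wasting capacity. The optimizer is a
dense grid (step 10⁻³) with bounded local refinement around the grid
minimum; ties break toward smaller τ (fewer vertical routings). An
independent exhaustive 10⁻⁴ grid serves as the test oracle.

Direction of comparative statics: since low scores route vertically, τ* is
non-increasing in the type-I penalty and non-decreasing in the type-II
penalty; the cost itself is non-decreasing in both penalties at fixed τ.

## ED-state grid and distillation

States are (shift staffing) × (relative demand load 0.50/0.65/0.78) ×
(congestion profile). Profiles are physically coherent pairs of occupancy
and waiting-room fractions — open beds never coexist with long queues —
with saturated profiles (full occupancy, waiting 35–55% of capacity)
paired only with loads ≥ 0.6, since saturation arises from sustained
demand. The state → rate mapping inflates effective arrivals by the
waiting backlog (coefficient 1.0), throttles the effective main service
rate by occupancy (penalty 0.15 at full), and, during saturation,
prioritizes the pathway (μ_vpp 16/h and θ 30/h versus 8/h and 2/h): the
protocol directs clinicians to waiting-room patients, so vertical capacity
rises and its availability gaps shrink. Saturation itself is declared when
waiting strictly exceeds 0.25 × staffed capacity plus free capacity.

These choices were fixed by an explicit design sweep before the acceptance
experiments: they make the per-state optima align with the binary
saturation flag (unsaturated states keep τ* below the high-risk score
band; saturated states push τ* to 1), which is exactly the structure the
deployed protocol encodes. Under this calibration the optimal policy is
approximately a function of (ESI, complaint group, saturation), so a
depth-4 tree can represent it — the point of the distillation step.

Distillation fits a depth-≤4 CART on (ESI, saturation, a skin/urinary/eye
indicator, one-hot complaint), weighted by stratum prevalence, on a
training split of states; agreement is measured on held-out states
(stratified so both saturation classes appear on each side). Mixed leaves
resolve by weighted majority with ties to main-ED. Held-out agreement runs
97–99.5% across seeds; the published fixed protocol (ESI 4–5, ESI-3
skin/urinary/eye, saturation → everyone) is exposed separately as an
executable decision function.

## Discrete-event simulator

A heap-ordered event engine ((time, sequence) keys, FIFO within servers)
written directly against the queueing semantics: exponential interarrival,
service and vacation draws; multiple-vacation discipline for the VPP
server; type-I patients re-queue at the main ED with service scaled by κ.
Alternative designs: single stream (the M/M/1 oracle), fast-track (a
dedicated always-available server restricted to low-acuity arrivals),
physician-in-triage (an upfront service stage for everyone with a rework
probability at the main stage). Warmup defaults to 20% of the horizon and
is excluded from wait summaries; conservation (arrivals = departures +
in-system) holds per replication. Instability is flagged, not raised: a run
is marked unstable when the time-average census in the second half exceeds
twice the first half plus ten. Validation compares closed-form waits with
t-based 95% CIs across replications on a 12-point rate grid; the shipped
grid covers utilizations 0.2–0.8 and vacation rates 1–6/h.

## Evaluation

The primary model is OLS of log(LOS) on a post-period indicator with
covariate groups: patient (age, ESI categorical or continuous, complaint),
operational (physician fixed effects, disposition, procedures), and
saturation/timing (staff on duty, census, waiting count, shift). The
educational period is excluded from primary contrasts. A coefficient β
implies a 100·(e^β−1)% change and pre-mean·(e^β−1) minutes. Return
outcomes use logistic regressions with the same covariates. Descriptive
tables use Welch's t-test for continuous variables and Pearson's chi-square
for proportions, switching to Fisher's exact test when any cell of the 2×2
falls below 10 (strict). All tests are two-sided with no multiplicity
correction, and reports flag this. Calendar covariates are deliberately
absent; congestion and staffing covariates stand in for them.
`reconstruct_denominators` inverts printed (count, percentage) pairs to the
smallest consistent denominator and reports uniqueness within ±10%.

## Problem sizes and numerical conventions

Default experiments use 13,700 encounters (≈5,000–5,500 per study arm),
a 54-state grid, and 6,000-encounter training cohorts for distillation.
Parameter-recovery experiments run 100 simulated studies; simulator
validation uses 10⁵ patients × 3 replications per grid point. Probability
vectors must sum to 1 within 10⁻⁹; importances are normalized to sum 1;
the vanishing-vacation limit is verified to 10⁻⁶ at θ = 10⁹. All
randomness flows from named integer seeds; identical (seed, config) pairs
reproduce byte-identical tables.

## Known limitations

The main ED is a single aggregate server rather than M/M/c, so its waits
are stylized; time variation is handled by re-solving per state rather
than by time-varying-rate analytics. The saturated-state service/vacation
rates and the misrouting penalties are design parameters with clinical
rationale, not estimates. Tier labels are conservative (≈87% bed
prevalence), so risk scores concentrate near 1 for most strata; the
distillation result should be read as fidelity of the tree to the optimal
policy under this calibration, not as a claim about any particular ED.
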