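# Methods

## The decision problem

Gumarontinib and savolitinib are MET inhibitors for advanced NSCLC with
METex14 skipping alterations.  Both were approved on single-arm phase II
trials, so no randomised head-to-head evidence exists.  The package
implements the standard workflow for this situation: reconstruct
patient-level data from the comparator's published Kaplan-Meier figures,
reweight the index trial's patients to the comparator's baseline
characteristics (unanchored MAIC), extrapolate survival parametrically, and
feed both arms' OS/PFS curves into a partitioned survival model that
accounts costs and QALYs from the healthcare-system perspective.

## Kaplan-Meier reconstruction

`reconstruct_ipd` follows the published-curve reconstruction idea of
iterating over the intervals between number-at-risk times: within each
interval a censor count is proposed, censoring times are spread over the
interval, event counts at each digitized coordinate are derived from the
product-limit relation d_k = round(n_k (1 − S_k / KM_last)), and the censor
count is adjusted until the implied number at risk at the next tabulated
time equals the published count exactly.  Three numerical choices matter:

* **Risk-table convention.** An entry (t, n) is read as the count at risk
  immediately *after* t; events plotted exactly at a tabulated time belong
  to the preceding interval.  `synthetic_data.digitize` writes tables with
  the same convention, so round trips are exact at the tabulated times.
* **Censor placement.** Candidate allocations place censors either
  uniformly over the interval (drop-out censoring) or at the interval end
  (administrative censoring).  Among allocations that reproduce the
  published at-risk count, the one whose reconstructed product-limit value
  best matches the digitized survival level at the interval boundary is
  kept.  This matters mainly in the last follow-up interval, where most
  censoring is administrative; uniform-only placement systematically
  starves late events.
* **Integer parity.** Because event counts are rounded integers, the exact
  at-risk target is occasionally unreachable by varying censors alone; a
  residual of at most ±2 is absorbed into the event count at the interval's
  final coordinate.  Larger discrepancies raise an inconsistency error
  naming the interval.

With 200 patients, a 40-point digitization grid and risk tables every six
months, the sup-norm distance between the input curve and the KM curve of
the reconstruction is below 0.01 across 40 seeds (tested bound: 0.02).
Ties between events and censorings are resolved event-first.  An optional
reported total event count is honoured by re-balancing the final interval.

## MAIC weighting

`estimate_weights` solves the method-of-moments weight model: centring the
covariate matrix at the aggregate targets, the convex objective
Q(α) = Σ exp(x̃ᵢᵀα) is minimised by BFGS with analytic gradient
(Newton-CG polish if needed); at the optimum the weighted covariate means
equal the targets (enforced to 1e−8, else an error reporting the gradient
norm).  Weights are rescaled to sum to n — cosmetic, since every downstream
quantity is scale-invariant — and the Kish effective sample size
(Σw)²/Σw² is reported.  Targets outside the observed covariate range raise
an infeasibility error before optimisation.

Covariate screening mirrors the practice of selecting matching variables on
the index trial's OS: univariate Cox fits (lifelines, Efron ties) at
p < 0.05, followed by a joint multivariate fit whose p-values govern the
final selection; clinically mandated covariates can be forced in
regardless of significance (the analysis this package reproduces forced
prior-treatment history on expert advice).  Separated covariates are
excluded with a warning; constant covariates are a precondition error.
The default covariate set of the synthetic trials is the trio used for the
cross-trial match: gender, histological subtype (adenocarcinoma vs other)
and prior systemic treatment (any vs none).

## Parametric survival fitting

`fit_parametric` maximises the weighted censored-data log-likelihood
Σ wᵢ [eᵢ log f(tᵢ) + (1 − eᵢ) log S(tᵢ)] on a transformed parameter scale
(log for positivity-constrained parameters) with L-BFGS-B and a
Nelder-Mead fallback; the exponential rate uses its closed form
Σwe / Σwt.  Time is in months throughout.  The generalized gamma uses the
Prentice (μ, σ, Q) form, which contains the lognormal (Q = 0), Weibull
(Q = 1) and gamma (Q = σ) as interior or boundary special cases — this is
what makes the all-family distribution sweep numerically dependable.  BIC
uses the effective sample size of the weights as n.  Fits are cross-checked
against lifelines' univariate fitters in the test suite.

The shipped base case uses the published optimum fits: exponential OS
(monthly rates 0.04397 gumarontinib, 0.04427 savolitinib) and lognormal PFS
(meanlog/sdlog 2.029/1.321 and 1.945/1.222).  `hybrid_curve` grafts a
parametric tail onto a trial KM curve at a switch time (default: end of
follow-up) by ratio anchoring, S(t) = KM(s)·S_par(t)/S_par(s) for t > s,
which is continuous by construction.

## Partitioned survival model

Three states: progression-free (PFS), progressed (PD), dead.  Occupancy is
read directly off the curves at each cycle start (no half-cycle
correction; a mid-cycle convention is available behind a settings flag):
pfs_t = min(S_PFS, S_OS), pd_t = S_OS − pfs_t (lognormal PFS tails can
cross an exponential OS tail far out; the cap logs a warning), dead_t = 1
− S_OS.  Cycles are one month (1/12 year exactly); the horizon runs until
OS ≤ 1% in every arm (cap 480 cycles); both arms always share a horizon.
Discounting is (1.05)^(−t/12) applied per cycle to costs and outcomes
alike.

Accounting per cycle: PFS occupancy accrues the on-treatment drug cost
($2,921.90 gumarontinib / $3,132.03 savolitinib per cycle) and PD occupancy
the post-progression pemetrexed + cisplatin cost ($731.82 per cycle, read
as per model cycle); utilities 0.804 (PFS) and 0.321 (PD) weight the
occupancy into QALYs.  End-of-life care ($7,554.01) is charged once to the
incident deaths of each cycle at that cycle's discount factor.
Adverse-event management costs and QALY decrements
(Σ incidence × disutility × duration, duration defaulting to one cycle)
are charged once at model entry.  Disease-management costs comprise an
initial visit (outpatient consult + gene panel, $498.80) and quarterly
monitoring assumptions (routine tests/ECG in both alive states; bed,
nursing and CT while progressed) — the underlying visit frequencies are
not published, so these are package assumptions calibrated to give a
lifetime health-resource cost of the order of $600–700, a ≲0.2% slice of
total cost.  Grade ≥3 adverse-event incidences are likewise unpublished in
the main text; the shipped profiles (oedema/headache for gumarontinib,
transaminase elevations for savolitinib) are assumptions reproducing the
order of the reported per-arm AE costs ($0.08 and $6.76).

Internal validation properties asserted by the tests: occupancy sums to 1
at every cycle (1e−12); with the discount rate set to 0, discounted and
undiscounted accumulators coincide; PFS drug cost equals the cycle cost
times discounted PFS person-months identically; for exponential OS the
undiscounted life-years equal the closed-form geometric series.

## Uncertainty analysis

*DSA*: each parameter moves to its published low/high bound (discount rate
0–8%) with the rest at base; rows sort by |NMB_high − NMB_low|.  Logical
parameters shared by both arms (utilities, chemotherapy cost, terminal
cost, management costs) carry several config paths and move jointly.

*PSA*: costs draw from gamma and utilities/incidences (and disutility
magnitudes) from beta distributions, moment-matched to (mean, sd) with
sd = (high − low)/3.92 where a 95% CI is available and 10% of the mean
otherwise; infeasible beta moments raise an error naming the parameter.
Survival curves are not sampled, so state occupancy is computed once and
only cost/utility accumulation repeats across the (seeded, reproducible)
draws.  The CEAC is the fraction of draws with positive NMB on a WTP grid.
Both the mean of per-draw ICERs (excluding |ΔQALY| < 1e−6) and the ratio
of mean increments are reported; the former is the figure comparable to
published Monte-Carlo summaries.

*Scenarios*: (a) dose-mix price adjustment — cycle costs scale by the
patient-weighted mean delivered dose from the trials
(gumarontinib 300:200 mg = 84:8 → 0.9710; savolitinib 600:400 mg = 62:8 →
0.9619); (b) a 30-month restricted horizon using the KM curves without
extrapolation (applied to parametric curves, with a label, when no KM data
exist); (c) an exhaustive sweep over all 6⁴ = 1,296 family combinations
for {arm} × {OS, PFS}, reporting the fraction of ICERs below given
thresholds (dominant combinations count as cost-effective).

## Synthetic data and the stand-in figures

`simulate_trial` draws covariates, then survival times by inverse transform
from the proportional-hazards construction S(t|x) = S₀(t)^exp(xᵀβ), with
administrative cutoff and optional exponential drop-out.  One seed governs
the whole draw.  This emulates the *statistical* structure the pipeline
assumes — independent censoring, exact proportional hazards, perfectly
digitized curves unless jitter is requested — and none of the messiness of
real trials (assessment-schedule-induced ties, informative censoring,
digitization bias), so passing tests demonstrate correctness of the
machinery, not robustness to real-data pathologies.

The published base case kept the trial KM curves within follow-up and
extrapolated beyond; the underlying figures are not machine-readable here.
`hybrid_standin_config` therefore builds *synthetic* digitized curves:
three-piece-exponential survival on [0, 30] months calibrated to published
summary statistics only — median OS 17.3/12.5 and median PFS 8.5/6.8
months, the within-follow-up restricted life-years and discounted
progression-free drug costs of the 30-month restricted analysis, and tails
anchored to the fitted parametric models so the hybrid join is continuous.
They are stand-ins for manual figure digitization, not trial data, and the
comparative results computed from them (ΔQALY ≈ 0.098, ΔCost ≈ $1,893,
ICER ≈ $19,400/QALY) carry that caveat.

## Known limitations

* Unanchored MAIC adjusts observed covariates only; no adjustment for
  unobserved differences or trial-design effects is possible, and the
  package does not attempt anchored comparisons.
* The partitioned structure treats OS and PFS as independent inputs; it
  cannot enforce clinical coherence of the extrapolated tails beyond
  capping PFS at OS.
* Negative Gompertz shapes (decreasing hazard) imply a survival plateau;
  they are accepted for fitting (the horizon cap bounds their effect) but
  violate the S(∞) = 0 ideal.
* Cost inputs are 2023 USD entered directly; no currency or inflation
  machinery is included.
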