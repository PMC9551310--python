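# Methods

## Estimation model

Follow-up is divided into annual intervals `j = 1..k` on `[j−1, j)` years
since diagnosis (`k = 5` by default).  For a cohort and an analysis window
the engine tabulates, per interval: patients at risk at the interval start
`n_j`, late entrants `e_j` (period mode), deaths `d_j`, and withdrawals
`c_j`.  Conditional observed survival is the actuarial estimator
`p_j = 1 − d_j/n′_j` with effective denominator

    n′_j = n_j + e_j/2 − c_mid_j/2 ,

where `c_mid_j` are the withdrawals strictly inside the interval.  A
withdrawal at exactly the interval boundary (typically the `k`-year cap or
a month-aligned administrative cutoff) was exposed for the whole interval
and keeps full weight; it is still counted in `c_j` so the flow identity
`n_{j+1} = n_j + e_j − d_j − c_j` holds exactly.  Without this refinement,
truncating a fully followed cohort at `k` years would down-weight the last
interval's denominator and the estimate would no longer equal the directly
counted survivor fraction.

Expected survival uses the Ederer II estimator: `p*_j` is the weighted mean
of population life-table annual survival probabilities over the patients at
risk at the interval start — full weight for patients present for the whole
interval (including those who die), half weight for mid-interval entrants
and withdrawals, mirroring `n′_j`.  Attained age and attained calendar year
advance by whole years from diagnosis (ages floored, capped at 99; years
clamped to the life table's range; clamps are counted and logged).
Cumulative quantities are products, `R_j = S_j/S*_j` is never capped at 1,
and the Greenwood variance

    Var(S_k) = S_k² Σ_{j≤k} d_j / (n′_j (n′_j − d_j)) ,   se(R_k) = se(S_k)/S*_k

treats the expected curve as fixed.  Strata with an empty at-risk interval
propagate as flagged missing values, never as zeros.

## Time conventions

Diagnosis dates are mid-month: `dx_year + (month − 0.5)/12` (mid-year when
the month is unknown).  Survival times arrive as whole months.  A death
recorded in follow-up month `m` is dated mid-month, `(m − 0.5)/12` years —
always inside follow-up year `ceil(m/12)`, so a death at an exact year
boundary belongs to the earlier interval, and death dates compare
symmetrically against the continuous calendar edges of a period window.
(Dating deaths at `m/12` exactly would leak deaths occurring just before a
window opening into the window — a measurable downward bias in entrant-fed
period estimates.)  Censoring times are completed months, `m/12`.

A period window `[start, end]` covers calendar `[start-01-01,
(end+1)-01-01)`.  Person-time is intersected with the window: entry at
`max(0, start − dx)`, exit at `min(t, end+1 − dx, k)`; deaths count only if
the death date falls inside the window; records whose person-time misses
the window contribute nothing.  Cohort mode follows patients diagnosed
within `[start, end]` from diagnosis.  A period window that covers all
diagnoses and all follow-up reproduces cohort mode cell for cell.

## Eligibility and stratification

Filters keep adults over 15 at diagnosis (`age ≥ 16`), first-and-only
primaries (sequence 0 — a "first of two" already implies a second primary
exists), cases not known solely from autopsy or a death certificate,
complete records, and no alive cases without a survival time.  When several
criteria fire, the record is counted once under a fixed precedence
(autopsy/DCO > age ≤ 15 > multiple primary > incomplete > alive without
survival time), making the filter report deterministic; "incomplete" means
any missing required field, and the report names the reason per record.
Histology-to-subtype and nodal-site maps are shipped as editable
configuration data (`periodsurv/data/icdo3_maps.yaml`), not code, since
such groupings get revised; unmapped malignant codes fall into "other",
non-malignant behaviour codes are an error.  Age groups default to 15–44,
45–54, 55–64, 65–74, 75+.

## Age standardization

Age-specific estimates combine as `R_std = Σ w_a R_a` with
`se_std = sqrt(Σ w_a² se_a²)`.  The shipped default weight vector
(0.07, 0.12, 0.23, 0.29, 0.29) is the published ICSS standard 1 collapsed
to the five bands above — a stand-in: choose the standard appropriate to
the cancer studied.  If any positively weighted group is undefined the
standardized value is undefined.

## Projection model

Conditional failure probabilities `1 − r_{j,p}` are modelled by a binomial
GLM, `link(1 − r_{j,p}) = α_j + γ·p`, cells weighted by their effective
denominators `n′_{j,p}` and fitted by IRLS (statsmodels, tolerance 1e-12).
The default complementary log-log link makes `γ` a log-linear trend in the
annual excess hazard; logit is available and recorded in the output
metadata.  The period covariate is the numeric index `1..P` (a linear trend
is the minimal structure that can extrapolate to an unseen period);
follow-up year is categorical.  Conditional ratios at or above 1 — possible
in noisy cells — are clamped to `1 − 1e-6` before fitting and the clamp
count reported; flagged cells (zero weight or undefined) are dropped, and
fitting requires at least two usable periods at every follow-up year.
Predictions cap `r̂_j` at 1 and report `R̂_k = Π r̂_j`.  Point projections
only: no standard errors are attached to projected values.

## Synthetic registry generator

The generator exists so that every stage is testable without restricted
registry data.  Background mortality is Gompertz–Makeham,
`μ(age) = a + b·c^age` (defaults a = 0.001, b = 5e-5, c = 1.09), optionally
scaled per sex (defaults 1.15 male / 0.88 female) and race, with an
optional calendar drift (default none); the population life table stores
`exp(−μ)` on ages 0–99, and the simulator draws each patient's annual death
probability from that same table plus the excess hazard,
`1 − exp(−(μ + λ_{j,p}))`, so the null case (λ = 0) matches the estimator's
expected-survival lookup exactly, age caps included.  The excess hazard is
piecewise constant per follow-up year and *calendar* period — a follow-up
year straddling a period boundary integrates both hazards exactly — which
gives the closed-form truth `R_k(p) = Π_{j≤k} exp(−λ_{j,p})` for the
person-time of calendar period `p`, independent of the demographic mix.

Defaults emulate a 2000–2018 NHL-like registry: four diagnosis periods
(2000–2003, 2004–2008, 2009–2013, 2014–2018) at 2,000 diagnoses per
calendar year; an adult age mix concentrated in the older bands; 53.8%
male; a four-category race mix; subtype/nodal/rural mixes of similar
magnitude to published NHL registry tables; administrative censoring on
Jan 1 after the last period (optional uniform loss to follow-up, default
off); and an excess hazard declining ~19% per period, front-loaded over
follow-up years (shape 1.6, 1.2, 0.9, 0.7, 0.6 summing to 5), anchored so
the latest period's true 5-year relative survival is 73.3%.  The 2000–2003
stub period matters: period analysis presumes left-truncated entrants from
earlier diagnosis years, and a first window with no diagnosis history has
late intervals consisting almost entirely of window-close-censored
person-time, where the actuarial estimator carries an O(h²) upward bias.
Deaths record the fatal month (`ceil(12t)`), censorings completed months.

Randomness is counter-based: every draw is a splitmix64 hash of (seed,
period, patient index, draw index), so output is byte-identical for a fixed
seed and enlarging a cohort never reshuffles earlier patients.

What the generator does **not** emulate: incidence trends, age- or
subtype-dependent excess hazards, cure fractions, reporting delay, or
life-table misspecification.  Passing tests therefore demonstrate that the
estimators recover known net survival under correctly specified background
mortality — not robustness to the data problems of real registries.

## Problem sizes and numerical choices

The simulation-based test properties use cohorts of 1,000–20,000 patients
per period and up to 300 replicates — large enough that calibration checks
(null coverage of R₅ = 1, empirical-SD-to-Greenwood-se ratio, projection
recovery against closed forms at 2 Monte-Carlo-SE tolerances) are sharp,
while the whole suite runs in about a minute.  Exact checks (risk-set
oracle equivalence, cohort-mode exactness to 1e-12, GLM recovery to 1e-6 on
noise-free grids) do not depend on size.  IRLS tolerance is 1e-12 with 300
iterations; a zero deviance on a saturated grid is a legitimate outcome,
not an error.  Rendered percentages round half-even to one decimal; raw
values are always written alongside.

## Known limitations

* Ederer I / Hakulinen expected survival, hybrid analysis, and
  competing-risks estimands are out of scope.
* The actuarial estimator retains second-order (h²) bias in intervals
  dominated by partial exposure; with annual intervals and realistic
  hazards this is ≲0.3% and vanishes when windows have a diagnosis history.
* Projection assumes the calendar trend on the link scale is linear and
  shared across follow-up years' intercepts; joinpoint or age-period-cohort
  structures are not modelled.
* One GLM is fitted per stratum (matching how registry tables report
  independent rows), not a pooled model with stratum terms.
* Life tables must be single-age (0–99) and single-year; no interpolation
  between calendar years or abridged-table support.
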