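# Methods

This note documents the models, conventions and design choices behind
`agitad`: what the identification algorithm computes, what the synthetic
claims generator emulates (and does not), and the numerical conventions the
summaries rely on.

## Data model

Four tables — beneficiaries, enrollment spells, medical claims, pharmacy
claims — carried as pandas DataFrames inside a `ClaimsBundle` with
referential integrity and a study window bounding all claim dates.  Dates
are calendar days; every interval is inclusive of both endpoints, matching
the day-level resolution of claims.  Diagnosis codes are ICD-9-CM or
ICD-10-CM, normalized to uppercase dot-free strings; matching is
system-aware (an ICD-9 `2900` never matches an ICD-10 entry) and supports
exact and prefix entries.  Code sets, like the Charlson mapping, are
configuration files; the shipped YAML lists are deliberately labelled
illustrative — a production analysis must supply clinically vetted lists.

Enrollment rows are canonicalized on read: per beneficiary the medical and
pharmacy coverage timelines are unioned independently (spans that overlap or
abut merge), then re-partitioned at coverage-change boundaries into disjoint
rows with constant flags.  Canonicalization is order-independent and
idempotent; any day not covered afterwards is a gap.

## Identification algorithm

All temporal rules share one primitive: *two or more claims at least g days
apart*, evaluated on the distinct service dates of claims carrying a
matching code.  We read this as "some pair of matching dates is ≥ g days
apart", which is equivalent to span(dates) ≥ g; a strict consecutive-pair
reading would be stricter than the stated rule and is rejected.  Boundaries
are inclusive (gaps of exactly 30 or 14 days qualify; 29 and 13 do not) and
duplicate same-day claims count once.

Parameters and defaults (`IdentificationParams`):

| parameter | default | meaning |
|---|---|---|
| `ad_dementia_gap_days` | 30 | confirmation gap for AD and for dementia |
| `agitation_gap_days` | 14 | agitation persistence gap |
| `smi_gap_days` | 30 | per-illness severe-mental-illness gap |
| `pre_window_days` / `post_window_days` | 183 / 365 | enrollment window around the index (6 months / 12 months as exact day counts, since month arithmetic is otherwise ambiguous) |
| `dx_position_limit_confirmation` | 2 | AD/dementia must appear in the primary or secondary position |
| `dx_position_limit_agitation_smi` | none | agitation and SMI codes count in any position |
| `agitation_search_window` | full study period | `followup_only` offered for sensitivity analyses |
| `enrollment_gap_tolerance_days` | 0 | uncovered days tolerated per coverage type |

The index date is the first claim date of the later-appearing of the two
confirmed diagnoses; the confirming (second) claim is not required to
precede the index.  Step order is confirmation → enrollment → SMI exclusion
→ agitation split (configurable to run the SMI step first); a beneficiary
meeting both the agitation and SMI criteria is excluded, not classified.
Exactly one terminal status per beneficiary, so attrition counts telescope
by construction.  The severity ("excess disability") criterion of the
clinical agitation definition is intentionally not implemented: it is not
observable in claims.

## Utilization and cost conventions

* **Stays.** Claims of one beneficiary and setting merge into a stay when a
  claim starts no more than `merge_gap_days` (default 1) after the latest
  service end seen so far; admit = earliest start, discharge = latest end,
  LOS = discharge − admit + 1 (same-day stay = 1 day).  A re-admission on
  the day after discharge is therefore a transfer, merged into the same
  stay.
* **Follow-up window.** Events are attributed to `(index, index + 365]` by
  their admit/fill date; stays straddling the boundary keep their full LOS
  (truncation available via `truncate_los_at_followup`).
* **Rates.** Per-beneficiary counts are annualized (×365/follow-up days,
  an identity under the fixed window) and reported as mean (SD) × 100 —
  "per 100 members per year".
* **30-day readmission.** Denominator: acute discharges with ≥30 observable
  days before follow-up end; numerator: those followed by another acute
  admission 1–30 days later (inclusive).  Reported as an unadjusted
  percentage; undefined (NaN) when the denominator is empty.
* **ED conversions.** An emergency claim whose dates fall inside an acute
  stay is absorbed: not counted as an ED visit and costed as inpatient
  (configurable).
* **AD-specific hospitalization.** An acute stay whose *principal* (first-
  position) diagnosis falls in the combined AD + dementia set — the standard
  claims convention, since "condition-specific" is not otherwise defined.
* **Costs.** `paid_amount` as given, no inflation adjustment; each claim
  maps to exactly one of seven categories by care setting, with hospice
  grouped under post-acute care by default (a separate hospice category is
  configurable) so the categories partition all spend.  Per-patient totals
  equal the sum of category costs exactly; cohort means include zero-cost
  members.
* **Per-patient vs per-stay LOS.** Per-patient means include zero-stay
  members; per-stay means are over stays.  For every cohort and setting,
  members × mean per-patient LOS = stays × mean per-stay LOS (total
  stay-days), an identity the tests assert exactly.

Baseline characteristics are frequencies/percentages and mean (SD).
Percentages of a full categorical partition use largest-remainder rounding
at one decimal, so each variable's levels sum to exactly 100.0.  The
Charlson Comorbidity Index is computed over claims in `[index − 183 d,
index)`; one matching claim in any diagnosis position flags a condition,
hierarchy pairs let the severer form suppress the milder, and the score is
the sum of retained weights.  The CMS-HCC risk score is reported from the
input field only (computing it is out of scope); the mapping version of the
CCI is configuration because no single canonical mapping exists.

## Synthetic claims generator

The generator's purpose is adversarial coverage of the identification rules
plus statistical calibration of the downstream summaries.  Each beneficiary
receives exactly one planted pattern:

* `agitation_case`, `non_agitation_control` — included, with/without a
  qualifying agitation pair;
* `fail_ad_confirmation`, `fail_dementia_confirmation` — a single claim or a
  29-day pair for the failing diagnosis;
* `fail_enrollment` — a 1–30-day coverage gap (medical, pharmacy, or both)
  planted inside the required window;
* `smi_excluded` — a per-illness qualifying pair (sometimes two illnesses,
  sometimes with a qualifying agitation pair, which must still be excluded);
* `smi_near_miss`, `agitation_near_miss` — pairs violating their rule by
  exactly one day (29/13), plus a cross-illness single-claim trap for SMI.

The near-miss patterns make the inclusive-boundary semantics a tested
contract.  Identification claims are emitted as $0 physician-service claims
so they perturb neither counted utilization metrics nor planted costs;
filler diagnoses are drawn from a benign pool disjoint from every phenotype
and comorbidity code set.

The default pattern mix encodes the selection funnel the pipeline is meant
to reproduce: 4% of beneficiaries fail confirmation; of the confirmed mass,
55.3% fails enrollment; of the remainder, 35.8% carries a severe mental
illness; of the included mass, exactly 36.5% are agitation cases and 2%
each are the two near-miss patterns.  Follow-up utilization for included
beneficiaries is drawn from per-cohort parameters: Poisson counts
(hospitalizations 0.89/0.81 per patient-year, ED 1.15/0.96, outpatient
15.99/14.76, plus physician, DME and pharmacy-fill rates), shifted-geometric
LOS (support ≥1 day; acute means 8.96/8.69 days, post-acute per-setting
means up to ~152/163 days for hospice), Bernoulli post-acute use per setting
(e.g. SNF 0.354/0.286), and an AD-coded principal diagnosis on a small
fraction of acute stays (0.045/0.012).

**Readmissions.** Each discharge leaving ≥30 observable days chains an extra
admission 2–30 days later with probability `readmit_prob` (0.218/0.193), and
*unrelated* stays are kept >30 uncovered days apart by re-drawing, so the
measured readmission rate is the planted per-discharge probability without
contamination from chance successions.  The base Poisson rate is deflated by
an exactly computed chain multiplier (day-grid convolution over
generations), so the expected *total* stay count still equals the configured
hospitalization rate.  The ≥2-day minimum gap keeps the stay-builder from
fusing chained stays into transfers.

**Costs.** `cost_lognormal` gives the per-claim paid-amount distribution per
category (σ = 1 by default).  Per-claim semantics make every category mean
analytic — E[claims] × exp(μ + σ²/2) — so the default (μ, σ) are derived
from target category PPPY totals divided by expected claim counts; the
shipped targets sum to $32,322 (agitation) and $30,121 (comparator) exactly.
A per-beneficiary-year draw was rejected because attaching it to
beneficiaries with no claims in a category would require auxiliary claims
that distort the planted count metrics.

Demographics (sex, race, region, entitlement, dual eligibility 0.452, age
~N(83, 8²) clipped to [40, 104], lognormal CMS-HCC with mean 1.15/SD 1.52)
are population-wide distributions; baseline comorbidity claims are planted
per condition with fixed probabilities so the Charlson score is non-trivial.
Determinism comes from per-beneficiary substreams keyed by (seed, index):
identical configurations reproduce bundles byte for byte, and adding or
removing beneficiaries leaves the others' claims unchanged.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic coding noise and miscoding of
AD-related dementias, mortality and mid-window disenrollment, temporal
clustering of events (dates are uniform over the follow-up, post-acute
stays are not anchored to a preceding hospitalization and may overlap other
settings), realistic magnitudes of claim-level dollar dispersion, and the
true content of the diagnosis code lists.  Recovery of planted parameters
demonstrates the *pipeline's* correctness, not the phenotype's clinical
validity.

## Problem sizes and verification

The acceptance script and the cohort-level tests use n = 20,000
beneficiaries, large enough that every planted rate, proportion and cost
mean is recovered within three standard errors while a full pipeline run
stays around ten seconds; unit and property tests use populations of
300–2,000 plus exhaustive enumeration of claim-date configurations (all
≤4-claim subsets of a 0–60-day grid) against all-pairs brute-force oracles.
A planted prevalence of 36.5% among included patterns is checked against the
exact binomial 99% interval of the realized included-population size.

## Known limitations

* The enrollment check treats the two coverage types independently; a
  tolerance > 0 admits gaps anywhere in the window, not only at its edges.
* Per-stay post-acute LOS draws are capped at 1,095 days (truncation mass
  < 10⁻³ for the longest-stay settings) so stays fit the study window.
* The baseline comorbidity planting uses fixed marginal probabilities with
  no correlation structure and no cohort differences.
* `read_bundle` infers the study window from observed claim dates when no
  window file is present, which widens the window to the data's extent.
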