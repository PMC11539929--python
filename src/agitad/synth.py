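"""Seeded synthetic Medicare-style claims with planted ground truth.

Real Medicare Fee-for-Service data are restricted, so every downstream stage
of the pipeline is exercised against populations generated here.  Each
beneficiary is assigned exactly one *planted pattern* — the identification
branch it must exit through — and its claims are constructed so the
temporal rules resolve that branch unambiguously (near-miss patterns violate
each rule by exactly one day, pinning the inclusive-boundary semantics).
Included beneficiaries additionally receive 12 months of follow-up
utilization drawn from their cohort's parameters: Poisson event counts,
shifted-geometric lengths of stay (support >= 1 day), per-discharge
readmission chaining, Bernoulli post-acute care use per setting, and
lognormal per-claim paid amounts.

Default parameters encode the population structure the pipeline is meant to
summarize: a 36.5% agitation share among included beneficiaries, a 55.3%
enrollment exclusion and 35.8% severe-mental-illness exclusion, cohort
hospitalization/ED/outpatient rates of 0.89/1.15/15.99 (agitation) vs
0.81/0.96/14.76 (comparator) events per patient-year, post-acute use and
stay lengths by setting, and per-category costs whose expected totals are
$32,322 vs $30,121 per patient per year.

Determinism: every beneficiary draws from its own substream keyed by
``(seed, beneficiary index)``, so the same configuration and seed reproduce
the bundle byte for byte and inserting or removing one beneficiary leaves
all others untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .costs import (CAT_DME, CAT_DRUG, CAT_ED, CAT_INPATIENT, CAT_OUTPATIENT,
                    CAT_PAC, CAT_PHYSICIAN)
from .identify import (SMI_LABELS, STATUS_AGITATION, STATUS_ENROLLMENT,
                       STATUS_NO_AGITATION, STATUS_NOT_CONFIRMED, STATUS_SMI)
from .io import default_code_sets
from .model import (ACUTE, DME, EMERGENCY, ICD10, OUTPATIENT, PAC_SETTINGS,
                    PHYSICIAN, ClaimsBundle, Code, CodeSet, ValidationError,
                    pack_diagnoses)

# planted identification patterns
AGITATION_CASE = "agitation_case"
NON_AGITATION_CONTROL = "non_agitation_control"
FAIL_AD = "fail_ad_confirmation"
FAIL_DEMENTIA = "fail_dementia_confirmation"
FAIL_ENROLLMENT = "fail_enrollment"
SMI_EXCLUDED = "smi_excluded"
SMI_NEAR_MISS = "smi_near_miss"
AGITATION_NEAR_MISS = "agitation_near_miss"
PATTERNS = (AGITATION_CASE, NON_AGITATION_CONTROL, FAIL_AD, FAIL_DEMENTIA,
            FAIL_ENROLLMENT, SMI_EXCLUDED, SMI_NEAR_MISS, AGITATION_NEAR_MISS)

#: patterns that reach the final cohort split
INCLUDED_PATTERNS = (AGITATION_CASE, NON_AGITATION_CONTROL,
                     SMI_NEAR_MISS, AGITATION_NEAR_MISS)

PATTERN_STATUS = {
    AGITATION_CASE: STATUS_AGITATION,
    NON_AGITATION_CONTROL: STATUS_NO_AGITATION,
    SMI_NEAR_MISS: STATUS_NO_AGITATION,
    AGITATION_NEAR_MISS: STATUS_NO_AGITATION,
    FAIL_AD: STATUS_NOT_CONFIRMED,
    FAIL_DEMENTIA: STATUS_NOT_CONFIRMED,
    FAIL_ENROLLMENT: STATUS_ENROLLMENT,
    SMI_EXCLUDED: STATUS_SMI,
}

# benign filler diagnoses, disjoint from every phenotype and comorbidity set
_BENIGN = (Code(ICD10, "I10"), Code(ICD10, "E785"), Code(ICD10, "M545"),
           Code(ICD10, "K219"))


class GeneratorConfigError(ValidationError):
    """The generator configuration is invalid or infeasible."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Follow-up utilization and cost intensities for one cohort.

    Rates are events per patient-year; LOS means are days of
    shifted-geometric stays; ``readmit_prob`` is the per-eligible-discharge
    probability of an extra admission 2-30 days later; ``cost_lognormal``
    maps cost category -> (mu, sigma) of the per-claim paid amount.
    """

    hosp_rate: float = 0.89
    ed_rate: float = 1.15
    outpatient_rate: float = 15.99
    physician_rate: float = 20.0
    dme_rate: float = 2.0
    rx_rate: float = 12.0
    acute_los_mean: float = 8.96
    ad_principal_prob: float = 0.045
    readmit_prob: float = 0.218
    pac_use_prob: dict = field(default_factory=dict)
    pac_los_mean: dict = field(default_factory=dict)
    cost_lognormal: dict = field(default_factory=dict)

    def validate(self):
        for name in ("hosp_rate", "ed_rate", "outpatient_rate",
                     "physician_rate", "dme_rate", "rx_rate"):
            if getattr(self, name) < 0:
                raise GeneratorConfigError(f"{name} must be >= 0")
        for name in ("ad_principal_prob", "readmit_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise GeneratorConfigError(f"{name} must be in [0, 1]")
        if self.acute_los_mean < 1:
            raise GeneratorConfigError("acute_los_mean must be >= 1 day")
        for s in PAC_SETTINGS:
            p = self.pac_use_prob.get(s, 0.0)
            if not 0 <= p <= 1:
                raise GeneratorConfigError(f"pac_use_prob[{s}] must be in [0, 1]")
            if p > 0 and self.pac_los_mean.get(s, 0) < 1:
                raise GeneratorConfigError(f"pac_los_mean[{s}] must be >= 1 day")

    def expected_category_costs(self) -> dict[str, float]:
        """Analytic expected PPPY cost per category under these parameters."""
        counts = _expected_claim_counts(self)
        out = {}
        for cat, (mu, sigma) in self.cost_lognormal.items():
            out[cat] = counts.get(cat, 0.0) * math.exp(mu + sigma ** 2 / 2)
        return out


def _expected_claim_counts(cp: CohortParams) -> dict[str, float]:
    return {
        CAT_ED: cp.ed_rate,
        CAT_INPATIENT: cp.hosp_rate,
        CAT_OUTPATIENT: cp.outpatient_rate,
        CAT_PHYSICIAN: cp.physician_rate,
        CAT_DME: cp.dme_rate,
        CAT_DRUG: cp.rx_rate,
        CAT_PAC: sum(cp.pac_use_prob.get(s, 0.0) for s in PAC_SETTINGS),
    }


def lognormal_params_for_mean(mean: float, sigma: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and log-scale sigma."""
    if mean <= 0:
        raise GeneratorConfigError("lognormal mean must be positive")
    return math.log(mean) - sigma ** 2 / 2, sigma


def cost_lognormal_from_category_totals(cp: CohortParams,
                                        category_totals: dict[str, float],
                                        sigma: float = 1.0) -> dict:
    """Per-claim (mu, sigma) giving each category the target expected PPPY.

    The per-claim mean is the category's target PPPY total divided by the
    expected number of claims in that category under ``cp``.
    """
    counts = _expected_claim_counts(cp)
    out = {}
    for cat, target in category_totals.items():
        n = counts.get(cat, 0.0)
        if target > 0 and n <= 0:
            raise GeneratorConfigError(
                f"category {cat} has target cost but expected claim count 0")
        if target > 0:
            out[cat] = lognormal_params_for_mean(target / n, sigma)
    return out


@dataclass(frozen=True)
class Demography:
    """Baseline attribute distributions shared by all beneficiaries."""

    sex_probs: dict = field(default_factory=lambda: {
        "F": 0.705, "M": 0.29, "unknown": 0.005})
    race_probs: dict = field(default_factory=lambda: {
        "White": 0.820, "Black": 0.114, "Hispanic/Latino": 0.030,
        "Asian": 0.020, "North American Native": 0.003, "Unknown": 0.013})
    region_probs: dict = field(default_factory=lambda: {
        "South": 0.418, "Midwest": 0.233, "Northeast": 0.203,
        "West": 0.144, "Unknown": 0.002})
    entitlement_probs: dict = field(default_factory=lambda: {
        "aged": 0.900, "disability": 0.098, "ESRD": 0.001,
        "disability_and_ESRD": 0.001})
    dual_prob: float = 0.452
    age_mean: float = 83.0
    age_sd: float = 8.0
    cms_hcc_mean: float = 1.15
    cms_hcc_sd: float = 1.52
    #: probability of one baseline claim per comorbidity label (labels must
    #: exist in the comorbidity-index configuration used for reporting)
    comorbidity_probs: dict = field(default_factory=lambda: {
        "myocardial_infarction": 0.08, "congestive_heart_failure": 0.18,
        "peripheral_vascular_disease": 0.10, "cerebrovascular_disease": 0.15,
        "chronic_pulmonary_disease": 0.20, "diabetes": 0.25,
        "diabetes_with_complications": 0.08, "renal_disease": 0.12,
        "any_malignancy": 0.10, "metastatic_solid_tumor": 0.02})


def default_pattern_mix() -> dict[str, float]:
    """Pattern probabilities anchored to the published selection funnel.

    Of the confirmed mass, 55.3% fails continuous enrollment; of the
    remainder, 35.8% is excluded for severe mental illness; of the included
    mass, exactly 36.5% are agitation cases and 2% each are the two
    one-day near-miss patterns.  The two confirmation-failure patterns
    (upstream of the published funnel) take 2% each of the total.
    """
    confirmed = 0.96
    post_enroll = confirmed * (1 - 0.553)
    included = post_enroll * (1 - 0.358)
    mix = {
        FAIL_AD: 0.02,
        FAIL_DEMENTIA: 0.02,
        FAIL_ENROLLMENT: confirmed * 0.553,
        SMI_EXCLUDED: post_enroll * 0.358,
        AGITATION_CASE: included * 0.365,
        AGITATION_NEAR_MISS: included * 0.02,
        SMI_NEAR_MISS: included * 0.02,
        NON_AGITATION_CONTROL: included * (1 - 0.365 - 0.04),
    }
    return mix


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic study population."""

    n_beneficiaries: int = 1000
    seed: int = 0
    study_window: tuple = ("2009-07-01", "2016-12-31")
    pattern_mix: dict = field(default_factory=default_pattern_mix)
    cohort_params: dict = field(default_factory=lambda: {
        STATUS_AGITATION: agitation_cohort_params(),
        STATUS_NO_AGITATION: no_agitation_cohort_params()})
    demography: Demography = field(default_factory=Demography)
    pre_window_days: int = 183
    post_window_days: int = 365
    acute_los_cap: int = 365
    pac_los_cap: int = 1095
    #: widest span of identification-claim offsets from the anchor
    pattern_span_days: int = 150

    def window_timestamps(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (pd.Timestamp(self.study_window[0]),
                pd.Timestamp(self.study_window[1]))

    def validate(self) -> "GeneratorConfig":
        if self.n_beneficiaries <= 0:
            raise GeneratorConfigError("n_beneficiaries must be positive")
        total = sum(self.pattern_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise GeneratorConfigError(
                f"pattern_mix must sum to 1 (got {total!r})")
        unknown = set(self.pattern_mix) - set(PATTERNS)
        if unknown:
            raise GeneratorConfigError(f"unknown patterns {sorted(unknown)}")
        if any(p < 0 for p in self.pattern_mix.values()):
            raise GeneratorConfigError("pattern probabilities must be >= 0")
        for cohort in (STATUS_AGITATION, STATUS_NO_AGITATION):
            if cohort not in self.cohort_params:
                raise GeneratorConfigError(f"missing cohort_params[{cohort}]")
            self.cohort_params[cohort].validate()
        lo, hi = self.anchor_range()
        if hi < lo:
            start, end = self.window_timestamps()
            raise GeneratorConfigError(
                f"study window {start.date()}..{end.date()} too short: need "
                f"{self.pre_window_days} pre-index days plus the pattern span, "
                f"{self.post_window_days} follow-up days and room for the "
                f"longest post-acute stay ({self.pac_los_cap} days)")
        return self

    def anchor_range(self) -> tuple[int, int]:
        """Feasible anchor-day offsets (relative to window start)."""
        start, end = self.window_timestamps()
        n_days = (end - start).days + 1
        tail = 30 + self.post_window_days + max(self.pac_los_cap,
                                                self.acute_los_cap + 365) + 1
        return self.pre_window_days, n_days - 1 - max(tail,
                                                      self.pattern_span_days + 1)


def agitation_cohort_params() -> CohortParams:
    """Follow-up intensities of the agitation cohort (defaults)."""
    cp = CohortParams(
        hosp_rate=0.89, ed_rate=1.15, outpatient_rate=15.99,
        acute_los_mean=8.96, ad_principal_prob=0.045, readmit_prob=0.218,
        pac_use_prob={"snf": 0.354, "home_health": 0.366, "ltach": 0.010,
                      "irf": 0.019, "hospice": 0.096},
        pac_los_mean={"snf": 93.52, "home_health": 107.63, "ltach": 32.29,
                      "irf": 13.37, "hospice": 152.45})
    totals = {CAT_ED: 652.0, CAT_INPATIENT: 8062.0, CAT_OUTPATIENT: 2152.0,
              CAT_PHYSICIAN: 5149.0, CAT_DME: 324.0, CAT_DRUG: 4496.0,
              CAT_PAC: 11487.0}
    return replace(cp, cost_lognormal=cost_lognormal_from_category_totals(cp, totals))


def no_agitation_cohort_params() -> CohortParams:
    """Follow-up intensities of the non-agitation comparator (defaults)."""
    cp = CohortParams(
        hosp_rate=0.81, ed_rate=0.96, outpatient_rate=14.76,
        acute_los_mean=8.69, ad_principal_prob=0.012, readmit_prob=0.193,
        pac_use_prob={"snf": 0.286, "home_health": 0.382, "ltach": 0.009,
                      "irf": 0.026, "hospice": 0.095},
        pac_los_mean={"snf": 84.19, "home_health": 105.09, "ltach": 31.03,
                      "irf": 13.26, "hospice": 163.42})
    totals = {CAT_ED: 581.0, CAT_INPATIENT: 6970.0, CAT_OUTPATIENT: 2133.0,
              CAT_PHYSICIAN: 5080.0, CAT_DME: 420.0, CAT_DRUG: 4237.0,
              CAT_PAC: 10700.0}
    return replace(cp, cost_lognormal=cost_lognormal_from_category_totals(cp, totals))


def default_generator_config(n_beneficiaries: int = 20000,
                             seed: int = 0) -> GeneratorConfig:
    """The study-condition configuration with a chosen size and seed."""
    return GeneratorConfig(n_beneficiaries=n_beneficiaries, seed=seed).validate()


# ---------------------------------------------------------------------------
# distribution helpers
# ---------------------------------------------------------------------------

def _geometric_pmf(mean: float, cap: int) -> np.ndarray:
    """PMF of a geometric LOS on {1..cap} with the given (uncapped) mean."""
    p = 1.0 / mean
    k = np.arange(1, cap + 1)
    pmf = (1 - p) ** (k - 1) * p
    return pmf / pmf.sum()


def _draw_los(rng: np.random.Generator, mean: float, cap: int) -> int:
    return int(min(rng.geometric(1.0 / mean), cap))


def chain_multiplier(readmit_prob: float, los_pmf: np.ndarray,
                     followup_days: int = 365, margin_days: int = 30,
                     gap_lo: int = 2, gap_hi: int = 30) -> float:
    """Expected stays per base admission under per-discharge readmission.

    A stay admitted uniformly over the follow-up chains a readmission with
    probability ``readmit_prob`` whenever its discharge leaves at least
    ``margin_days`` observable days; the child is admitted ``gap_lo``..
    ``gap_hi`` days later.  Computed by propagating the admit-day
    distribution generation by generation (day-grid convolutions), this
    multiplier lets the generator deflate the base Poisson rate so the
    expected total stay count equals the configured hospitalization rate.
    """
    admit = np.full(followup_days, 1.0 / followup_days)
    kernel = np.full(gap_hi - gap_lo + 1, 1.0 / (gap_hi - gap_lo + 1))
    cutoff = followup_days - margin_days  # latest eligible discharge day
    total = 0.0
    for _ in range(30):
        mass = admit.sum()
        if mass < 1e-10:
            break
        total += mass
        disch = np.convolve(admit, los_pmf)      # index c -> day c + 1
        elig = disch[:cutoff]                    # discharge day <= cutoff
        child = readmit_prob * np.convolve(elig, kernel)
        admit = np.zeros(followup_days)
        upto = min(len(child), followup_days - gap_lo)
        admit[gap_lo:gap_lo + upto] = child[:upto]
    return total


# ---------------------------------------------------------------------------
# identification-pattern planting
# ---------------------------------------------------------------------------

def _pick_code(code_set: CodeSet, rng: np.random.Generator) -> Code:
    e = code_set.entries[int(rng.integers(len(code_set.entries)))]
    value = e.code.value + ("1" if e.prefix else "")
    return Code(e.code.system, value)


def _benign(rng: np.random.Generator) -> Code:
    return _BENIGN[int(rng.integers(len(_BENIGN)))]


def _pair_days(rng, start_lo, start_hi, gap, extra_hi):
    first = int(rng.integers(start_lo, start_hi + 1))
    second = first + gap + int(rng.integers(0, extra_hi + 1))
    return first, second


def plant_identification_claims(rng: np.random.Generator, pattern: str,
                                anchor: int, code_sets: dict[str, CodeSet]):
    """Identification claims (day offsets) realizing one planted pattern.

    Returns ``(claims, meta)`` where each claim is a tuple
    ``(day, codes)`` destined to become a $0 physician-service claim, and
    ``meta`` records ``ad_first``, ``dementia_first`` and ``index`` day
    offsets (``index`` None for confirmation failures).  Near-miss variants
    violate their temporal rule by exactly one day.
    """
    claims: list[tuple[int, list[Code]]] = []
    meta: dict = {}

    def emit(day: int, code: Code):
        claims.append((day, [code, _benign(rng)]))

    # AD and dementia confirmation (or its planted failure)
    ad_first = anchor
    dem_first = anchor + int(rng.integers(0, 31))
    if pattern == FAIL_AD:
        emit(ad_first, _pick_code(code_sets["AD"], rng))
        if rng.random() < 0.5:  # spacing failure rather than a single claim
            emit(ad_first + 29, _pick_code(code_sets["AD"], rng))
        d1, d2 = _pair_days(rng, dem_first, dem_first, 30, 60)
        emit(d1, _pick_code(code_sets["dementia"], rng))
        emit(d2, _pick_code(code_sets["dementia"], rng))
        meta.update(ad_first=ad_first, dementia_first=dem_first, index=None)
        return claims, meta
    if pattern == FAIL_DEMENTIA:
        a1, a2 = _pair_days(rng, ad_first, ad_first, 30, 60)
        emit(a1, _pick_code(code_sets["AD"], rng))
        emit(a2, _pick_code(code_sets["AD"], rng))
        emit(dem_first, _pick_code(code_sets["dementia"], rng))
        if rng.random() < 0.5:
            emit(dem_first + 29, _pick_code(code_sets["dementia"], rng))
        meta.update(ad_first=ad_first, dementia_first=dem_first, index=None)
        return claims, meta

    a1, a2 = _pair_days(rng, ad_first, ad_first, 30, 60)
    emit(a1, _pick_code(code_sets["AD"], rng))
    emit(a2, _pick_code(code_sets["AD"], rng))
    d1, d2 = _pair_days(rng, dem_first, dem_first, 30, 60)
    emit(d1, _pick_code(code_sets["dementia"], rng))
    emit(d2, _pick_code(code_sets["dementia"], rng))
    index = max(ad_first, dem_first)
    meta.update(ad_first=ad_first, dementia_first=dem_first, index=index)

    if pattern == AGITATION_CASE or (pattern == SMI_EXCLUDED and rng.random() < 0.5):
        g1, g2 = _pair_days(rng, anchor, anchor + 60, 14, 46)
        emit(g1, _pick_code(code_sets["agitation"], rng))
        emit(g2, _pick_code(code_sets["agitation"], rng))
    elif pattern == AGITATION_NEAR_MISS:
        g1 = anchor + int(rng.integers(0, 61))
        emit(g1, _pick_code(code_sets["agitation"], rng))
        emit(g1 + 13, _pick_code(code_sets["agitation"], rng))
    elif pattern == NON_AGITATION_CONTROL and rng.random() < 0.3:
        # a single agitation claim can never satisfy the two-claim rule
        emit(anchor + int(rng.integers(0, 61)),
             _pick_code(code_sets["agitation"], rng))

    if pattern == SMI_EXCLUDED:
        illness = SMI_LABELS[int(rng.integers(len(SMI_LABELS)))]
        s1, s2 = _pair_days(rng, anchor, anchor + 60, 30, 60)
        emit(s1, _pick_code(code_sets[illness], rng))
        emit(s2, _pick_code(code_sets[illness], rng))
        reasons = {illness}
        if rng.random() < 0.3:  # a second co-occurring severe mental illness
            other = SMI_LABELS[int(rng.integers(len(SMI_LABELS)))]
            if other != illness:
                s1, s2 = _pair_days(rng, anchor, anchor + 60, 30, 60)
                emit(s1, _pick_code(code_sets[other], rng))
                emit(s2, _pick_code(code_sets[other], rng))
                reasons.add(other)
        meta["smi_reasons"] = sorted(reasons)
    elif pattern == SMI_NEAR_MISS:
        # one illness spaced 29 days (one day short) plus a single claim of
        # another illness: pooling across illnesses must NOT exclude
        illness = SMI_LABELS[int(rng.integers(len(SMI_LABELS)))]
        other = SMI_LABELS[int(rng.integers(len(SMI_LABELS)))]
        s1 = anchor + int(rng.integers(0, 61))
        emit(s1, _pick_code(code_sets[illness], rng))
        emit(s1 + 29, _pick_code(code_sets[illness], rng))
        if other != illness:
            emit(anchor + int(rng.integers(0, 61)),
                 _pick_code(code_sets[other], rng))
    return claims, meta


# ---------------------------------------------------------------------------
# follow-up utilization
# ---------------------------------------------------------------------------

def generate_followup_utilization(rng: np.random.Generator, cp: CohortParams,
                                  base_hosp_rate: float, acute_los_cap: int,
                                  pac_los_cap: int, code_sets):
    """Draw one beneficiary's 12-month follow-up events and costs.

    Returns ``(medical, pharmacy, stats)`` where medical rows are
    ``(start_offset, end_offset, setting, codes, paid)`` with offsets in
    days after the index (1..), pharmacy rows are ``(offset, paid)``, and
    ``stats`` records the realized counts/costs for the ground truth.
    ``base_hosp_rate`` is the readmission-deflated Poisson rate computed
    once per cohort from :func:`chain_multiplier`.
    """
    ad_pool = code_sets["AD"].entries + code_sets["dementia"].entries
    ad_set = CodeSet("ad_dementia_pool", ad_pool)
    medical = []
    pharmacy = []
    cost = {cat: 0.0 for cat in cp.cost_lognormal}

    def paid(cat: str) -> float:
        mu, sigma = cp.cost_lognormal.get(cat, (None, None))
        if mu is None:
            return 0.0
        amount = round(float(rng.lognormal(mu, sigma)), 2)
        cost[cat] = round(cost[cat] + amount, 2)
        return amount

    # --- acute stays with readmission chaining -------------------------
    # Unrelated stays keep > 30 uncovered days between them, so the only
    # admissions within the 30-day readmission window of a discharge are
    # the deliberately chained ones and the measured readmission rate is
    # the planted per-discharge probability.  The >= 2-day minimum gap also
    # keeps the stay-builder (merge gap 1 day) from fusing stays.
    stays: list[tuple[int, int, bool]] = []  # (admit, discharge, is_readmit)

    def separated(a: int, d: int, skip: int | None = None,
                  margin: int = 30) -> bool:
        return all((a - od > margin) or (oa - d > margin)
                   for j, (oa, od, _) in enumerate(stays) if j != skip)

    n_base = rng.poisson(base_hosp_rate) if base_hosp_rate > 0 else 0
    queue: list[int] = []
    for _ in range(n_base):
        los = _draw_los(rng, cp.acute_los_mean, acute_los_cap)
        for _ in range(200):
            a = int(rng.integers(1, 366))
            d = a + los - 1
            if separated(a, d):
                queue.append(len(stays))
                stays.append((a, d, False))
                break
    n_readmit = 0
    while queue:
        parent = queue.pop(0)
        a, d = stays[parent][:2]
        if d <= 365 - 30 and rng.random() < cp.readmit_prob:
            los = _draw_los(rng, cp.acute_los_mean, acute_los_cap)
            for _ in range(100):
                ca = d + int(rng.integers(2, 31))
                cd = ca + los - 1
                if separated(ca, cd, skip=parent):
                    queue.append(len(stays))
                    stays.append((ca, cd, True))
                    n_readmit += 1
                    break
    stays.sort()
    for a, d, _ in stays:
        if rng.random() < cp.ad_principal_prob:
            e = ad_pool[int(rng.integers(len(ad_pool)))]
            principal = Code(e.code.system,
                             e.code.value + ("1" if e.prefix else ""))
        else:
            principal = _benign(rng)
        medical.append((a, d, ACUTE, [principal, _benign(rng)],
                        paid(CAT_INPATIENT)))

    # --- ED visits (placed outside acute stays) ------------------------
    n_ed = 0
    for _ in range(rng.poisson(cp.ed_rate) if cp.ed_rate > 0 else 0):
        for _ in range(200):
            day = int(rng.integers(1, 366))
            if all(not (a <= day <= d) for a, d, _ in stays):
                medical.append((day, day, EMERGENCY, [_benign(rng)],
                                paid(CAT_ED)))
                n_ed += 1
                break

    # --- outpatient / physician / DME point claims ----------------------
    n_outpatient = rng.poisson(cp.outpatient_rate) if cp.outpatient_rate > 0 else 0
    for _ in range(n_outpatient):
        day = int(rng.integers(1, 366))
        medical.append((day, day, OUTPATIENT, [_benign(rng)],
                        paid(CAT_OUTPATIENT)))
    for _ in range(rng.poisson(cp.physician_rate) if cp.physician_rate > 0 else 0):
        day = int(rng.integers(1, 366))
        medical.append((day, day, PHYSICIAN, [_benign(rng)],
                        paid(CAT_PHYSICIAN)))
    for _ in range(rng.poisson(cp.dme_rate) if cp.dme_rate > 0 else 0):
        day = int(rng.integers(1, 366))
        medical.append((day, day, DME, [], paid(CAT_DME)))

    # --- post-acute episodes, one per used setting ----------------------
    pac_stats = {}
    for setting in PAC_SETTINGS:
        use_p = cp.pac_use_prob.get(setting, 0.0)
        used = use_p > 0 and rng.random() < use_p
        los = 0
        if used:
            los = _draw_los(rng, cp.pac_los_mean[setting], pac_los_cap)
            a = int(rng.integers(1, 366))
            medical.append((a, a + los - 1, setting, [_benign(rng)],
                            paid(CAT_PAC)))
        pac_stats[setting] = (1 if used else 0, los)

    # --- pharmacy fills --------------------------------------------------
    n_rx = rng.poisson(cp.rx_rate) if cp.rx_rate > 0 else 0
    for _ in range(n_rx):
        pharmacy.append((int(rng.integers(1, 366)), paid(CAT_DRUG)))

    stats = {
        "n_acute_stays": len(stays),
        "n_readmissions": n_readmit,
        "acute_los_days": sum(d - a + 1 for a, d, _ in stays),
        "n_ed_visits": n_ed,
        "n_outpatient_visits": int(n_outpatient),
        "n_rx_fills": int(n_rx),
    }
    for setting in PAC_SETTINGS:
        used, los = pac_stats[setting]
        stats[f"pac_{setting}_stays"] = used
        stats[f"pac_{setting}_los_days"] = los
    for cat, amount in cost.items():
        stats[f"cost_{cat}"] = round(amount, 2)
    stats["cost_total"] = round(sum(cost.values()), 2)
    return medical, pharmacy, stats


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def _categorical(rng: np.random.Generator, probs: dict):
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return labels[int(rng.choice(len(labels), p=p))]


def generate_population(config: GeneratorConfig,
                        code_sets: dict[str, CodeSet] | None = None,
                        cci_code_sets: dict[str, CodeSet] | None = None,
                        ) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a synthetic claims bundle plus its ground-truth table.

    The ground truth holds, per beneficiary, the planted pattern, the
    intended identification status and index date, and the realized
    follow-up event counts and category costs used for generation.  The
    bundle validates against the data-model contract; identical
    ``(config, seed)`` reproduce it exactly.
    """
    config.validate()
    code_sets = code_sets or default_code_sets()
    if cci_code_sets is None:
        from .profile import default_cci_config
        cci_code_sets = {c.label: c.code_set
                         for c in default_cci_config().conditions}

    window_start, window_end = config.window_timestamps()
    anchor_lo, anchor_hi = config.anchor_range()
    patterns = list(PATTERNS)
    mix = np.asarray([config.pattern_mix.get(p, 0.0) for p in patterns])
    mix = mix / mix.sum()
    base_rates = {}
    for cohort, cp in config.cohort_params.items():
        pmf = _geometric_pmf(cp.acute_los_mean, config.acute_los_cap)
        mult = chain_multiplier(cp.readmit_prob, pmf,
                                followup_days=config.post_window_days)
        base_rates[cohort] = cp.hosp_rate / mult if mult > 0 else 0.0

    bene_rows, enr_rows, med_rows, pharm_rows, truth_rows = [], [], [], [], []
    window_days = (window_end - window_start).days

    for i in range(config.n_beneficiaries):
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, i])
        bid = f"B{i:06d}"
        pattern = patterns[int(rng.choice(len(patterns), p=mix))]
        anchor = int(rng.integers(anchor_lo, anchor_hi + 1))

        id_claims, meta = plant_identification_claims(rng, pattern, anchor,
                                                      code_sets)
        index_day = meta["index"]
        ref_day = index_day if index_day is not None else anchor

        claim_no = 0

        def add_medical(start, end, setting, codes, paid_amount):
            nonlocal claim_no
            claim_no += 1
            med_rows.append((f"M{i:06d}x{claim_no:03d}", bid, start, end,
                             setting, pack_diagnoses(codes), paid_amount))

        for day, codes in id_claims:
            add_medical(day, day, PHYSICIAN, codes, 0.0)

        # baseline comorbidity claims inside the 6-month lookback
        for label, prob in config.demography.comorbidity_probs.items():
            cs = cci_code_sets.get(label)
            if cs is not None and rng.random() < prob:
                day = ref_day - int(rng.integers(8, config.pre_window_days - 2))
                add_medical(day, day, PHYSICIAN, [_pick_code(cs, rng)], 0.0)

        # enrollment: full-window coverage, with a planted gap when required
        if pattern == FAIL_ENROLLMENT:
            gap_len = int(rng.integers(1, 31))
            win_lo = index_day - config.pre_window_days
            win_hi = index_day + config.post_window_days - gap_len + 1
            gs = int(rng.integers(win_lo, win_hi + 1))
            ge = gs + gap_len - 1
            gap_type = ("medical", "pharmacy", "both")[int(rng.integers(3))]
            if gs > 0:
                enr_rows.append((bid, 0, gs - 1, True, True))
            if gap_type != "both":
                enr_rows.append((bid, gs, ge, gap_type != "medical",
                                 gap_type != "pharmacy"))
            enr_rows.append((bid, ge + 1, window_days, True, True))
        else:
            enr_rows.append((bid, 0, window_days, True, True))

        # follow-up utilization for beneficiaries reaching the cohort split
        stats: dict = {}
        if pattern in INCLUDED_PATTERNS:
            cohort = PATTERN_STATUS[pattern]
            cp = config.cohort_params[cohort]
            med, pharm, stats = generate_followup_utilization(
                rng, cp, base_rates[cohort], config.acute_los_cap,
                config.pac_los_cap, code_sets)
            for start, end, setting, codes, paid_amount in med:
                add_medical(index_day + start, index_day + end, setting,
                            codes, paid_amount)
            for k, (day, paid_amount) in enumerate(pharm, start=1):
                pharm_rows.append((f"P{i:06d}x{k:03d}", bid,
                                   index_day + day, paid_amount))

        # demographics
        demo = config.demography
        age = float(np.clip(rng.normal(demo.age_mean, demo.age_sd), 40, 104))
        birth_day = ref_day - int(age * 365.25) - int(rng.integers(0, 365))
        hcc_mu, hcc_sigma = lognormal_params_for_mean(
            demo.cms_hcc_mean,
            math.sqrt(math.log(1 + (demo.cms_hcc_sd / demo.cms_hcc_mean) ** 2)))
        bene_rows.append((
            bid, birth_day, _categorical(rng, demo.sex_probs),
            _categorical(rng, demo.race_probs),
            _categorical(rng, demo.region_probs),
            bool(rng.random() < demo.dual_prob),
            _categorical(rng, demo.entitlement_probs),
            round(float(rng.lognormal(hcc_mu, hcc_sigma)), 4)))

        truth = {
            "beneficiary_id": bid,
            "pattern": pattern,
            "intended_status": PATTERN_STATUS[pattern],
            "intended_index_day": index_day if index_day is not None else -1,
            "intended_smi_reasons": "|".join(meta.get("smi_reasons", [])),
        }
        truth.update(stats)
        truth_rows.append(truth)

    day0 = window_start

    def to_date(col):
        return day0 + pd.to_timedelta(col, unit="D")

    beneficiaries = pd.DataFrame(bene_rows, columns=[
        "id", "birth_date", "sex", "race_ethnicity", "region",
        "dual_eligible", "entitlement_reason", "cms_hcc_score"])
    beneficiaries["birth_date"] = to_date(beneficiaries["birth_date"])
    enrollment = pd.DataFrame(enr_rows, columns=[
        "beneficiary_id", "start", "end", "medical", "pharmacy"])
    enrollment["start"] = to_date(enrollment["start"])
    enrollment["end"] = to_date(enrollment["end"])
    medical = pd.DataFrame(med_rows, columns=[
        "claim_id", "beneficiary_id", "service_start", "service_end",
        "setting", "diagnoses", "paid_amount"])
    medical["service_start"] = to_date(medical["service_start"])
    medical["service_end"] = to_date(medical["service_end"])
    pharmacy = pd.DataFrame(pharm_rows, columns=[
        "claim_id", "beneficiary_id", "fill_date", "paid_amount"])
    if len(pharmacy):
        pharmacy["fill_date"] = to_date(pharmacy["fill_date"])
    else:
        pharmacy["fill_date"] = pd.to_datetime(pharmacy["fill_date"])

    truth = pd.DataFrame(truth_rows)
    numeric_cols = [c for c in truth.columns if c.startswith(("n_", "cost_",
                                                              "pac_", "acute_"))]
    truth[numeric_cols] = truth[numeric_cols].fillna(0)
    truth["intended_index_date"] = pd.NaT
    has_idx = truth["intended_index_day"] >= 0
    truth.loc[has_idx, "intended_index_date"] = (
        day0 + pd.to_timedelta(truth.loc[has_idx, "intended_index_day"], unit="D"))
    truth = truth.drop(columns="intended_index_day")

    bundle = ClaimsBundle(
        beneficiaries=beneficiaries, enrollment=enrollment,
        medical_claims=medical, pharmacy_claims=pharmacy,
        study_window=(window_start, window_end))
    return bundle.validate(), truth
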