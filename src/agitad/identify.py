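"""Claims-based identification of agitation in Alzheimer dementia cohorts.

Implements the iterative computable-phenotype algorithm over a claims bundle:

1. **Diagnosis confirmation** — Alzheimer's disease and dementia each require
   two or more claims whose service dates span at least 30 days, with a
   qualifying code in the primary or secondary diagnosis position.
2. **Index date** — the first claim date of whichever of the two diagnoses
   appeared later, anchoring the 6-month baseline and 12-month follow-up.
3. **Continuous enrollment** — medical AND pharmacy coverage over the full
   window from 183 days before to 365 days after the index date.
4. **Severe-mental-illness exclusion** — beneficiaries with two or more
   claims at least 30 days apart for any single severe psychiatric illness
   (bipolar disorder, major depressive disorder, schizophrenia) are removed;
   the two-claim rule applies per illness, never pooled across illnesses.
5. **Agitation split** — remaining beneficiaries with two or more agitation
   claims at least 14 days apart form the agitation cohort; the rest are the
   non-agitation comparator.

All temporal thresholds are inclusive: gaps of exactly 30 (or 14) days
qualify.  Multiple claims on the same service date count once.  With more
than two matching claims, "two or more claims >= g days apart" holds iff the
span from earliest to latest distinct matching date is >= g, i.e. some pair
qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import coverage_intervals
from .model import ClaimsBundle, CodeSet, ValidationError

# terminal statuses of the identification algorithm
STATUS_AGITATION = "agitation"
STATUS_NO_AGITATION = "no_agitation"
STATUS_NOT_CONFIRMED = "excluded_not_confirmed"
STATUS_ENROLLMENT = "excluded_enrollment"
STATUS_SMI = "excluded_smi"
STATUSES = (STATUS_AGITATION, STATUS_NO_AGITATION, STATUS_NOT_CONFIRMED,
            STATUS_ENROLLMENT, STATUS_SMI)

SMI_LABELS = ("bipolar", "MDD", "schizophrenia")

FULL_STUDY_PERIOD = "full_study_period"
FOLLOWUP_ONLY = "followup_only"


@dataclass(frozen=True)
class IdentificationParams:
    """Tunable thresholds of the identification algorithm.

    Defaults encode the published rules: 30-day confirmation gap for
    AD/dementia and severe mental illness, 14-day gap for agitation,
    183-day (6-month) baseline and 365-day (12-month) follow-up enrollment
    windows, confirmation restricted to diagnosis positions 1-2 while
    agitation/SMI search every position, zero enrollment-gap tolerance.
    """

    ad_dementia_gap_days: int = 30
    agitation_gap_days: int = 14
    smi_gap_days: int = 30
    pre_window_days: int = 183
    post_window_days: int = 365
    dx_position_limit_confirmation: int | None = 2
    dx_position_limit_agitation_smi: int | None = None
    agitation_search_window: str = FULL_STUDY_PERIOD
    enrollment_gap_tolerance_days: int = 0
    smi_before_enrollment: bool = False

    def __post_init__(self):
        for name in ("ad_dementia_gap_days", "agitation_gap_days",
                     "smi_gap_days", "pre_window_days", "post_window_days"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.agitation_search_window not in (FULL_STUDY_PERIOD, FOLLOWUP_ONLY):
            raise ValidationError(
                f"unknown agitation_search_window {self.agitation_search_window!r}")


@dataclass(frozen=True)
class ConfirmationResult:
    """Outcome of a two-claim temporal confirmation rule."""

    confirmed: bool
    first_date: pd.Timestamp | None = None
    qualifying_second_date: pd.Timestamp | None = None


@dataclass
class AttritionReport:
    """Step-by-step sample-selection accounting.

    ``steps`` is an ordered list of ``(label, n_remaining, n_excluded)``
    rows; counts telescope (each n_remaining equals the previous minus the
    step's n_excluded).  The terminal split is carried in ``agitation_n`` /
    ``no_agitation_n``.
    """

    steps: list[tuple[str, int, int]] = field(default_factory=list)
    agitation_n: int = 0
    no_agitation_n: int = 0

    @property
    def agitation_share(self) -> float:
        total = self.agitation_n + self.no_agitation_n
        return self.agitation_n / total if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [(label, rem, exc) for label, rem, exc in self.steps]
        rows.append((STATUS_AGITATION, self.agitation_n, 0))
        rows.append((STATUS_NO_AGITATION, self.no_agitation_n, 0))
        return pd.DataFrame(rows, columns=["step", "n_remaining", "n_excluded"])


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def confirm_dates(dates, gap_days: int) -> ConfirmationResult:
    """Apply the two-claim gap rule to a collection of claim dates.

    Duplicates collapse to distinct dates.  Confirmed iff the span from the
    earliest to the latest distinct date is at least ``gap_days`` (boundary
    inclusive); the qualifying second date is the earliest date at least
    ``gap_days`` after the first.  Accepts Timestamps/dates or plain integer
    day offsets.
    """
    distinct = sorted(set(dates))
    if len(distinct) < 2:
        return ConfirmationResult(confirmed=False,
                                  first_date=distinct[0] if distinct else None)
    first, last = distinct[0], distinct[-1]
    span = last - first
    gap = (pd.Timedelta(days=gap_days)
           if isinstance(span, pd.Timedelta) else gap_days)
    if span < gap:
        return ConfirmationResult(confirmed=False, first_date=first)
    second = next(d for d in distinct if d - first >= gap)
    return ConfirmationResult(confirmed=True, first_date=first,
                              qualifying_second_date=second)


def matching_claim_dates(claims: pd.DataFrame, code_set: CodeSet,
                         position_limit: int | None = None) -> list:
    """Distinct service-start dates of claims carrying a matching code.

    ``claims`` is a medical-claims frame (packed ``diagnoses`` column);
    only diagnosis positions up to ``position_limit`` (1-based) are searched
    when a limit is given.
    """
    from .model import parse_diagnoses
    dates = set()
    for row in claims.itertuples(index=False):
        codes = parse_diagnoses(row.diagnoses)
        if position_limit is not None:
            codes = codes[:position_limit]
        if any(code_set.matches(c) for c in codes):
            dates.add(row.service_start)
    return sorted(dates)


def confirm_code_set(claims: pd.DataFrame, code_set: CodeSet, gap_days: int,
                     position_limit: int | None = None) -> ConfirmationResult:
    """Two-claim temporal confirmation of one code set for one beneficiary."""
    return confirm_dates(matching_claim_dates(claims, code_set, position_limit),
                         gap_days)


def determine_index(ad: ConfirmationResult,
                    dementia: ConfirmationResult) -> pd.Timestamp:
    """Index date: first claim date of the later-appearing diagnosis.

    Both confirmations must hold; the index is the later of the two
    first-occurrence dates, i.e. the date on which the second of the two
    diagnoses first appeared.
    """
    if not (ad.confirmed and dementia.confirmed):
        raise ValidationError("index date requires both AD and dementia confirmed")
    return max(ad.first_date, dementia.first_date)


def uncovered_days(intervals, window_start, window_end) -> int:
    """Days in the inclusive window not covered by the given merged intervals."""
    total = (window_end - window_start)
    total = total.days + 1 if hasattr(total, "days") else total + 1
    covered = 0
    for s, e in intervals:
        lo = max(s, window_start)
        hi = min(e, window_end)
        if lo <= hi:
            d = hi - lo
            covered += (d.days if hasattr(d, "days") else d) + 1
    return total - covered


def check_continuous_enrollment(enrollment: pd.DataFrame, index,
                                params: IdentificationParams) -> bool:
    """Continuous medical AND pharmacy coverage around the index date.

    True iff, for each coverage type separately, the total number of
    uncovered days in ``[index - pre_window_days, index + post_window_days]``
    does not exceed ``enrollment_gap_tolerance_days``.
    """
    index = pd.Timestamp(index)
    lo = index - pd.Timedelta(days=params.pre_window_days)
    hi = index + pd.Timedelta(days=params.post_window_days)
    cov = coverage_intervals(enrollment)
    if not cov:
        return False
    spans = next(iter(cov.values()))
    tol = params.enrollment_gap_tolerance_days
    return (uncovered_days(spans["medical"], lo, hi) <= tol
            and uncovered_days(spans["pharmacy"], lo, hi) <= tol)


def detect_agitation(claims: pd.DataFrame, agitation_set: CodeSet,
                     params: IdentificationParams) -> ConfirmationResult:
    """Agitation rule: two or more matching claims at least 14 days apart."""
    return confirm_code_set(claims, agitation_set, params.agitation_gap_days,
                            params.dx_position_limit_agitation_smi)


def detect_smi_exclusion(claims: pd.DataFrame, smi_sets: dict[str, CodeSet],
                         params: IdentificationParams) -> set[str]:
    """Severe mental illnesses meeting the per-illness two-claim/30-day rule.

    Each illness is evaluated against its own code set; a single claim for
    one illness plus a single claim for another never triggers exclusion.
    """
    hits = set()
    for label, cs in smi_sets.items():
        res = confirm_code_set(claims, cs, params.smi_gap_days,
                               params.dx_position_limit_agitation_smi)
        if res.confirmed:
            hits.add(label)
    return hits


# ---------------------------------------------------------------------------
# bulk pipeline
# ---------------------------------------------------------------------------

def _bulk_confirm(dx: pd.DataFrame, code_set: CodeSet, gap_days: int,
                  position_limit: int | None) -> pd.DataFrame:
    """Vectorized confirmation over every beneficiary in a dx-long frame.

    Returns a frame indexed by beneficiary_id with columns
    ``first, second, confirmed`` (only beneficiaries with >=1 matching claim
    appear).
    """
    mask = code_set.match_mask(dx)
    if position_limit is not None:
        mask &= (dx["position"] <= position_limit).to_numpy()
    sub = dx.loc[mask, ["beneficiary_id", "date"]].drop_duplicates()
    if not len(sub):
        return pd.DataFrame(columns=["first", "second", "confirmed"])
    g = sub.groupby("beneficiary_id")["date"]
    first = g.min()
    span_ok = (g.max() - first) >= pd.Timedelta(days=gap_days)
    merged = sub.merge(first.rename("first"), on="beneficiary_id")
    late = merged[merged["date"] - merged["first"] >= pd.Timedelta(days=gap_days)]
    second = late.groupby("beneficiary_id")["date"].min()
    out = first.to_frame("first")
    out["second"] = second
    out["confirmed"] = span_ok
    return out


def assign_cohorts(bundle: ClaimsBundle, code_sets: dict[str, CodeSet],
                   params: IdentificationParams | None = None,
                   ) -> tuple[pd.DataFrame, AttritionReport]:
    """Run the full identification algorithm over a claims bundle.

    ``code_sets`` must contain labels ``AD``, ``dementia``, ``agitation``
    and the three severe-mental-illness labels (``bipolar``, ``MDD``,
    ``schizophrenia``).  Returns the per-beneficiary assignment table
    (``beneficiary_id, status, index_date, smi_reasons``) and the attrition
    report.  Every beneficiary receives exactly one status.
    """
    params = params or IdentificationParams()
    for label in ("AD", "dementia", "agitation") + SMI_LABELS:
        if label not in code_sets:
            raise ValidationError(f"code_sets is missing the {label!r} set")

    bene_ids = bundle.beneficiaries["id"].tolist()
    n_total = len(bene_ids)
    dx = bundle.dx_long()

    ad = _bulk_confirm(dx, code_sets["AD"], params.ad_dementia_gap_days,
                       params.dx_position_limit_confirmation)
    dem = _bulk_confirm(dx, code_sets["dementia"], params.ad_dementia_gap_days,
                        params.dx_position_limit_confirmation)

    status = pd.Series(STATUS_NOT_CONFIRMED, index=pd.Index(bene_ids, name="beneficiary_id"))
    index_date = pd.Series(pd.NaT, index=status.index, dtype="datetime64[ns]")
    smi_reasons = pd.Series("", index=status.index)

    conf_set = (set(ad.index[ad["confirmed"]])
                & set(dem.index[dem["confirmed"]]))
    confirmed_ids = pd.Index([b for b in bene_ids if b in conf_set],
                             name="beneficiary_id")
    # index date = later of the two first-occurrence dates
    idx_dates = pd.concat([ad.loc[confirmed_ids, "first"],
                           dem.loc[confirmed_ids, "first"]], axis=1).max(axis=1)
    index_date.loc[confirmed_ids] = idx_dates

    steps = [("beneficiaries", n_total, 0),
             ("ad_dementia_confirmed", len(confirmed_ids),
              n_total - len(confirmed_ids))]
    remaining = confirmed_ids

    def _enrollment_step(remaining):
        enr = bundle.enrollment[bundle.enrollment["beneficiary_id"].isin(remaining)]
        cov = coverage_intervals(enr)
        tol = params.enrollment_gap_tolerance_days
        keep = []
        for bid in remaining:
            idx = index_date.loc[bid]
            lo = idx - pd.Timedelta(days=params.pre_window_days)
            hi = idx + pd.Timedelta(days=params.post_window_days)
            spans = cov.get(bid, {"medical": [], "pharmacy": []})
            if (uncovered_days(spans["medical"], lo, hi) <= tol
                    and uncovered_days(spans["pharmacy"], lo, hi) <= tol):
                keep.append(bid)
        return pd.Index(keep, name="beneficiary_id")

    def _smi_step(remaining):
        per_illness = {
            label: _bulk_confirm(dx, code_sets[label], params.smi_gap_days,
                                 params.dx_position_limit_agitation_smi)
            for label in SMI_LABELS}
        excluded: dict[str, list[str]] = {}
        for label, table in per_illness.items():
            for bid in table.index[table["confirmed"]]:
                excluded.setdefault(bid, []).append(label)
        keep = []
        for bid in remaining:
            if bid in excluded:
                smi_reasons.loc[bid] = "|".join(sorted(excluded[bid]))
                status.loc[bid] = STATUS_SMI
            else:
                keep.append(bid)
        return pd.Index(keep, name="beneficiary_id")

    if params.smi_before_enrollment:
        kept = _smi_step(remaining)
        steps.append(("no_severe_mental_illness", len(kept),
                      len(remaining) - len(kept)))
        remaining = kept
        kept = _enrollment_step(remaining)
        status.loc[remaining.difference(kept)] = STATUS_ENROLLMENT
        steps.append(("continuous_enrollment", len(kept),
                      len(remaining) - len(kept)))
        remaining = kept
    else:
        kept = _enrollment_step(remaining)
        status.loc[remaining.difference(kept)] = STATUS_ENROLLMENT
        steps.append(("continuous_enrollment", len(kept),
                      len(remaining) - len(kept)))
        remaining = kept
        kept = _smi_step(remaining)
        steps.append(("no_severe_mental_illness", len(kept),
                      len(remaining) - len(kept)))
        remaining = kept

    # agitation split
    dx_agit = dx
    if params.agitation_search_window == FOLLOWUP_ONLY:
        idx_map = index_date.reindex(dx["beneficiary_id"]).to_numpy()
        delta = dx["date"].to_numpy() - idx_map
        in_window = ((delta > np.timedelta64(0, "ns"))
                     & (delta <= np.timedelta64(params.post_window_days, "D")))
        dx_agit = dx.loc[in_window]
    agit = _bulk_confirm(dx_agit, code_sets["agitation"],
                         params.agitation_gap_days,
                         params.dx_position_limit_agitation_smi)
    agit_ids = set(agit.index[agit["confirmed"]])
    for bid in remaining:
        status.loc[bid] = (STATUS_AGITATION if bid in agit_ids
                           else STATUS_NO_AGITATION)

    report = AttritionReport(
        steps=steps,
        agitation_n=int((status == STATUS_AGITATION).sum()),
        no_agitation_n=int((status == STATUS_NO_AGITATION).sum()),
    )
    assignments = pd.DataFrame({
        "beneficiary_id": status.index,
        "status": status.to_numpy(),
        "index_date": index_date.to_numpy(),
        "smi_reasons": smi_reasons.to_numpy(),
    })
    return assignments, report
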