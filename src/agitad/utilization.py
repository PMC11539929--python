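"""Healthcare resource utilization over the 12-month follow-up window.

Claims from institutional settings are first merged into *stays* (episodes
with admit/discharge dates); utilization is then summarized per cohort as
annualized rates per 100 members per year, length of stay per patient and
per stay, 30-day readmissions, and post-acute care use by setting.

Conventions (all configurable through :class:`AnalysisParams`):

* follow-up window = ``(index, index + 365]``; a stay is attributed to the
  window iff its admit date lies inside, and its LOS is not truncated;
* LOS counts both endpoints, so a same-day stay has LOS 1;
* claims in one setting separated by at most ``merge_gap_days`` (default 1,
  i.e. abutting) belong to the same stay — an acute admission on the day
  after a discharge is a transfer, not a readmission;
* an emergency claim whose dates fall inside an acute stay is treated as
  part of the hospitalization, not as a distinct ED visit;
* the 30-day readmission boundary is inclusive, and only discharges with at
  least 30 observable follow-up days enter the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import (ACUTE, EMERGENCY, OUTPATIENT, PAC_SETTINGS, STAY_SETTINGS,
                    ClaimsBundle, CodeSet, ValidationError)
from .identify import STATUS_AGITATION, STATUS_NO_AGITATION

COHORTS = (STATUS_AGITATION, STATUS_NO_AGITATION)


@dataclass(frozen=True)
class AnalysisParams:
    """Windows and conventions for utilization and cost summarization."""

    followup_days: int = 365
    annualization_days: int = 365
    merge_gap_days: int = 1
    truncate_los_at_followup: bool = False
    absorb_ed_into_acute: bool = True
    readmission_window_days: int = 30
    hospice_in_pac: bool = True

    def __post_init__(self):
        if self.followup_days <= 0:
            raise ValidationError("followup_days must be positive")


class ReadmissionResult(NamedTuple):
    rate_pct: float            # nan when no eligible discharges
    n_readmissions: int
    n_eligible_discharges: int


# ---------------------------------------------------------------------------
# stay construction
# ---------------------------------------------------------------------------

def build_stays(claims: pd.DataFrame, merge_gap_days: int = 1) -> pd.DataFrame:
    """Merge institutional claims into stays per beneficiary and setting.

    Claims sorted by service start join the running stay whenever they begin
    no more than ``merge_gap_days`` after the latest service end seen so far;
    the stay's principal diagnosis comes from its earliest claim.  Returns a
    frame with columns ``beneficiary_id, setting, admit, discharge, los_days,
    principal_system, principal_value`` ('' when the claim had no diagnosis).
    """
    cols = ["beneficiary_id", "setting", "admit", "discharge", "los_days",
            "principal_system", "principal_value"]
    if not len(claims):
        return pd.DataFrame(columns=cols)
    mc = claims.sort_values(
        ["beneficiary_id", "setting", "service_start", "service_end", "claim_id"]
    ).reset_index(drop=True)
    grp_keys = ["beneficiary_id", "setting"]
    mc["_cummax_end"] = mc.groupby(grp_keys, sort=False)["service_end"].cummax()
    prev_end = mc.groupby(grp_keys, sort=False)["_cummax_end"].shift()
    gap = pd.Timedelta(days=merge_gap_days)
    new_stay = prev_end.isna() | (mc["service_start"] > prev_end + gap)
    mc["_stay"] = new_stay.cumsum()

    first = mc.drop_duplicates("_stay", keep="first")
    agg = mc.groupby("_stay").agg(
        beneficiary_id=("beneficiary_id", "first"),
        setting=("setting", "first"),
        admit=("service_start", "min"),
        discharge=("service_end", "max"),
    )
    principal = first.set_index("_stay")["diagnoses"].fillna("").str.split("|").str[0]
    sysval = principal.str.partition(":")
    agg["los_days"] = (agg["discharge"] - agg["admit"]).dt.days + 1
    agg["principal_system"] = sysval[0].where(principal != "", "")
    agg["principal_value"] = sysval[2].where(principal != "", "")
    return agg.reset_index(drop=True)[cols]


def ad_specific_stays(stays: pd.DataFrame, ad_dementia_set: CodeSet) -> pd.DataFrame:
    """Stays whose principal diagnosis falls in the AD/dementia code set."""
    if not len(stays):
        return stays.copy()
    dx = stays.rename(columns={"principal_system": "system",
                               "principal_value": "value"})[["system", "value"]]
    has_dx = (dx["value"] != "").to_numpy()
    mask = ad_dementia_set.match_mask(dx) & has_dx
    return stays.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# rates and summaries
# ---------------------------------------------------------------------------

def annualized_rate_per_100(event_counts, followup_days,
                            annualization_days: int = 365) -> tuple[float, float]:
    """Mean and SD of per-beneficiary annualized counts, per 100 members.

    Each beneficiary's count is scaled to a full year
    (``count * annualization_days / followup_days``); the returned mean/SD
    are over beneficiaries, multiplied by 100.  With everyone observed for a
    full year this is simply ``100 * mean(count)``.
    """
    counts = np.asarray(event_counts, dtype=float)
    fu = np.asarray(followup_days, dtype=float)
    if len(counts) == 0:
        return float("nan"), float("nan")
    if np.any(fu <= 0):
        raise ValidationError("followup_days must be positive for every member")
    annualized = counts * annualization_days / fu
    sd = float(annualized.std(ddof=1)) if len(annualized) > 1 else float("nan")
    return float(annualized.mean()) * 100.0, sd * 100.0


def readmission_rate_30d(stays: pd.DataFrame, followup_end,
                         window_days: int = 30) -> ReadmissionResult:
    """Unadjusted 30-day all-cause readmission rate over acute stays.

    ``followup_end`` maps beneficiary_id -> last observable date (Series or
    dict).  A discharge enters the denominator when at least ``window_days``
    days remain before the beneficiary's follow-up end; it counts as a
    readmission when another acute admission occurs 1..``window_days`` days
    (inclusive) after it.
    """
    if isinstance(followup_end, dict):
        followup_end = pd.Series(followup_end)
    numerator = 0
    denominator = 0
    for bid, grp in stays.groupby("beneficiary_id", sort=False):
        end = followup_end.get(bid, pd.NaT)
        if pd.isna(end):
            continue
        admits = grp["admit"].sort_values().to_numpy()
        discharges = np.sort(grp["discharge"].to_numpy())
        for d in discharges:
            if (end - d) / np.timedelta64(1, "D") < window_days:
                continue
            denominator += 1
            delta = (admits - d) / np.timedelta64(1, "D")
            if np.any((delta >= 1) & (delta <= window_days)):
                numerator += 1
    rate = 100.0 * numerator / denominator if denominator else float("nan")
    return ReadmissionResult(rate, numerator, denominator)


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if len(arr) == 0:
        return float("nan"), float("nan")
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    return float(arr.mean()), sd


def pac_summary(stays: pd.DataFrame, members) -> pd.DataFrame:
    """Post-acute-care LOS and use by setting plus an overall row.

    ``members`` lists every cohort member; beneficiaries with no stay in a
    setting contribute zero days to the per-patient LOS and to the use
    proportion.  Per-stay statistics are over stays only.  Returns rows
    ``setting ('overall' first), los_per_patient_mean/sd,
    los_per_stay_mean/sd, use_pct, n_members, n_stays``.
    """
    members = pd.Index(members)
    pac = stays[stays["setting"].isin(PAC_SETTINGS)]
    rows = []
    for setting in ("overall",) + PAC_SETTINGS:
        sub = pac if setting == "overall" else pac[pac["setting"] == setting]
        per_patient = (sub.groupby("beneficiary_id")["los_days"].sum()
                       .reindex(members, fill_value=0))
        pp_mean, pp_sd = _mean_sd(per_patient)
        ps_mean, ps_sd = _mean_sd(sub["los_days"])
        use = float((per_patient > 0).mean() * 100.0) if len(members) else float("nan")
        rows.append((setting, pp_mean, pp_sd, ps_mean, ps_sd, use,
                     len(members), len(sub)))
    return pd.DataFrame(rows, columns=[
        "setting", "los_per_patient_mean", "los_per_patient_sd",
        "los_per_stay_mean", "los_per_stay_sd", "use_pct",
        "n_members", "n_stays"])


# ---------------------------------------------------------------------------
# cohort-level summary
# ---------------------------------------------------------------------------

def followup_claims(bundle: ClaimsBundle, assignments: pd.DataFrame,
                    params: AnalysisParams) -> pd.DataFrame:
    """Medical claims of cohort members starting inside the follow-up window."""
    members = assignments[assignments["status"].isin(COHORTS)]
    mc = bundle.medical_claims.merge(
        members[["beneficiary_id", "status", "index_date"]], on="beneficiary_id")
    if not len(mc):
        return mc
    delta = (pd.to_datetime(mc["service_start"])
             - pd.to_datetime(mc["index_date"])).dt.days
    keep = (delta > 0) & (delta <= params.followup_days)
    return mc.loc[keep].reset_index(drop=True)


def absorbed_ed_mask(claims: pd.DataFrame, acute_stays: pd.DataFrame) -> np.ndarray:
    """Mark emergency claims whose service dates fall within an acute stay."""
    mask = np.zeros(len(claims), dtype=bool)
    if not len(claims) or not len(acute_stays):
        return mask
    ed = claims["setting"] == EMERGENCY
    if not ed.any():
        return mask
    stays_by_bene = {bid: list(zip(g["admit"], g["discharge"]))
                     for bid, g in acute_stays.groupby("beneficiary_id")}
    idx = np.flatnonzero(ed.to_numpy())
    for i in idx:
        row = claims.iloc[i]
        for a, d in stays_by_bene.get(row["beneficiary_id"], ()):
            if a <= row["service_start"] and row["service_end"] <= d:
                mask[i] = True
                break
    return mask


def summarize_utilization(bundle: ClaimsBundle, assignments: pd.DataFrame,
                          code_sets: dict[str, CodeSet],
                          params: AnalysisParams | None = None) -> pd.DataFrame:
    """Per-cohort utilization table (tidy: cohort, metric, mean, sd, n).

    Metrics mirror the standard claims burden panel: all-cause and
    AD-specific hospitalizations per 100 members per year with LOS per
    patient/per stay, ED and outpatient visits per 100 members per year,
    the 30-day readmission rate, and post-acute care LOS/use by setting.
    ``code_sets`` must provide ``AD`` and ``dementia`` (their union defines
    AD-specific hospitalization).
    """
    params = params or AnalysisParams()
    fu_claims = followup_claims(bundle, assignments, params)
    combined = CodeSet(label="ad_dementia", entries=tuple(
        code_sets["AD"].entries + code_sets["dementia"].entries))

    rows = []
    for cohort in COHORTS:
        members_df = assignments[assignments["status"] == cohort]
        members = pd.Index(members_df["beneficiary_id"])
        n = len(members)
        claims = fu_claims[fu_claims["status"] == cohort]
        stay_claims = claims[claims["setting"].isin(STAY_SETTINGS)]
        stays = build_stays(stay_claims, params.merge_gap_days)
        if params.truncate_los_at_followup and len(stays):
            end = members_df.set_index("beneficiary_id")["index_date"] + \
                pd.Timedelta(days=params.followup_days)
            cap = stays["beneficiary_id"].map(end)
            stays["discharge"] = np.minimum(stays["discharge"], cap)
            stays["los_days"] = (stays["discharge"] - stays["admit"]).dt.days + 1
        acute = stays[stays["setting"] == ACUTE]
        fu = np.full(n, params.followup_days)

        def _count_rate(event_frame):
            counts = (event_frame.groupby("beneficiary_id").size()
                      .reindex(members, fill_value=0))
            return annualized_rate_per_100(counts, fu, params.annualization_days)

        def add(metric, mean, sd, count=n):
            rows.append((cohort, metric, mean, sd, count))

        m, s = _count_rate(acute)
        add("hospitalizations_all_cause_per100py", m, s)
        pp = acute.groupby("beneficiary_id")["los_days"].sum().reindex(members, fill_value=0)
        add("acute_los_per_patient_days", *_mean_sd(pp))
        add("acute_los_per_stay_days", *_mean_sd(acute["los_days"]), count=len(acute))

        ad_acute = ad_specific_stays(acute, combined)
        m, s = _count_rate(ad_acute)
        add("hospitalizations_ad_specific_per100py", m, s)
        pp = ad_acute.groupby("beneficiary_id")["los_days"].sum().reindex(members, fill_value=0)
        add("ad_specific_los_per_patient_days", *_mean_sd(pp))
        add("ad_specific_los_per_stay_days", *_mean_sd(ad_acute["los_days"]),
            count=len(ad_acute))

        ed = claims[claims["setting"] == EMERGENCY]
        if params.absorb_ed_into_acute:
            ed = ed.loc[~absorbed_ed_mask(ed.reset_index(drop=True), acute)]
        m, s = _count_rate(ed)
        add("ed_visits_per100py", m, s)

        m, s = _count_rate(claims[claims["setting"] == OUTPATIENT])
        add("outpatient_visits_per100py", m, s)

        fu_end = (members_df.set_index("beneficiary_id")["index_date"]
                  + pd.Timedelta(days=params.followup_days))
        readm = readmission_rate_30d(acute, fu_end, params.readmission_window_days)
        add("readmission_rate_30d_pct", readm.rate_pct, float("nan"),
            count=readm.n_eligible_discharges)

        for r in pac_summary(stays, members).itertuples(index=False):
            prefix = f"pac_{r.setting}"
            add(f"{prefix}_los_per_patient_days", r.los_per_patient_mean,
                r.los_per_patient_sd)
            add(f"{prefix}_los_per_stay_days", r.los_per_stay_mean,
                r.los_per_stay_sd, count=r.n_stays)
            add(f"{prefix}_use_pct", r.use_pct, float("nan"))

    return pd.DataFrame(rows, columns=["cohort", "metric", "mean", "sd", "n"])
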