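"""Per-patient-per-year (PPPY) direct healthcare costs by category.

Every claim maps to exactly one of seven cost categories — emergency
department, inpatient, outpatient, physician services/tests, durable medical
equipment, prescription drug, and post-acute care — determined by its care
setting (pharmacy claims are always prescription drug).  Hospice is grouped
with post-acute care by default so the seven categories partition all paid
amounts; a separate ``hospice`` category is available via
``AnalysisParams(hospice_in_pac=False)``.  An emergency claim absorbed into
an acute stay is costed as inpatient, mirroring the utilization convention.

Costs are the ``paid_amount`` field as given, summed over the follow-up
window ``(index, index + 365]`` per beneficiary and category, annualized
(an identity under the fixed window), and averaged over all cohort members
including those with zero cost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (ACUTE, DME, EMERGENCY, HOSPICE, OUTPATIENT, PHYSICIAN,
                    ClaimsBundle, ValidationError)
from .model import SNF, HOME_HEALTH, LTACH, IRF
from .utilization import (AnalysisParams, COHORTS, absorbed_ed_mask,
                          build_stays, followup_claims)

CAT_ED = "emergency_department"
CAT_INPATIENT = "inpatient"
CAT_OUTPATIENT = "outpatient"
CAT_PHYSICIAN = "physician_services_tests"
CAT_DME = "durable_medical_equipment"
CAT_DRUG = "prescription_drug"
CAT_PAC = "post_acute_care"
CAT_HOSPICE = "hospice"

#: category order used in every report
CATEGORIES = (CAT_ED, CAT_INPATIENT, CAT_OUTPATIENT, CAT_PHYSICIAN,
              CAT_DME, CAT_DRUG, CAT_PAC)

_SETTING_CATEGORY = {
    ACUTE: CAT_INPATIENT,
    EMERGENCY: CAT_ED,
    OUTPATIENT: CAT_OUTPATIENT,
    PHYSICIAN: CAT_PHYSICIAN,
    DME: CAT_DME,
    SNF: CAT_PAC,
    HOME_HEALTH: CAT_PAC,
    LTACH: CAT_PAC,
    IRF: CAT_PAC,
    HOSPICE: CAT_PAC,  # configurable
}


def categorize_claim(setting: str, hospice_in_pac: bool = True) -> str:
    """Cost category of a medical claim's care setting."""
    if setting == HOSPICE and not hospice_in_pac:
        return CAT_HOSPICE
    try:
        return _SETTING_CATEGORY[setting]
    except KeyError:
        raise ValidationError(f"unknown care setting {setting!r}") from None


def active_categories(params: AnalysisParams) -> tuple[str, ...]:
    if params.hospice_in_pac:
        return CATEGORIES
    return CATEGORIES + (CAT_HOSPICE,)


def pppy_costs(bundle: ClaimsBundle, assignments: pd.DataFrame,
               params: AnalysisParams | None = None) -> pd.DataFrame:
    """Cohort mean (SD) PPPY costs per category plus a ``total`` row.

    Returns a tidy frame ``cohort, category, mean_pppy, sd_pppy, n`` with
    categories in the fixed report order and ``total`` last.  Per
    beneficiary the total equals the sum of category costs exactly, so the
    cohort total mean equals the sum of category means up to floating
    rounding.
    """
    params = params or AnalysisParams()
    cats = active_categories(params)
    fu_med = followup_claims(bundle, assignments, params)
    fu_med = fu_med.copy()
    fu_med["category"] = [categorize_claim(s, params.hospice_in_pac)
                          for s in fu_med["setting"]]
    if params.absorb_ed_into_acute and len(fu_med):
        acute = build_stays(fu_med[fu_med["setting"] == ACUTE],
                            params.merge_gap_days)
        absorbed = absorbed_ed_mask(fu_med.reset_index(drop=True), acute)
        fu_med.loc[absorbed, "category"] = CAT_INPATIENT

    members_all = assignments[assignments["status"].isin(COHORTS)]
    if members_all["index_date"].isna().any():
        bad = members_all.loc[members_all["index_date"].isna(),
                              "beneficiary_id"].tolist()[:10]
        raise ValidationError(f"cohort members without index date: {bad}")
    idx = members_all.set_index("beneficiary_id")["index_date"]
    pharm = bundle.pharmacy_claims.merge(
        members_all[["beneficiary_id", "status", "index_date"]],
        on="beneficiary_id")
    if len(pharm):
        delta = (pd.to_datetime(pharm["fill_date"])
                 - pd.to_datetime(pharm["index_date"])).dt.days
        pharm = pharm.loc[(delta > 0) & (delta <= params.followup_days)].copy()
    pharm["category"] = CAT_DRUG

    cols = ["beneficiary_id", "status", "category", "paid_amount"]
    parts = [df[cols] for df in (fu_med, pharm) if len(df)]
    spend = (pd.concat(parts, ignore_index=True) if parts
             else fu_med[cols])

    annualize = params.annualization_days / params.followup_days
    rows = []
    for cohort in COHORTS:
        members = pd.Index(
            members_all.loc[members_all["status"] == cohort, "beneficiary_id"])
        n = len(members)
        sub = spend[spend["status"] == cohort]
        table = (sub.pivot_table(index="beneficiary_id", columns="category",
                                 values="paid_amount", aggfunc="sum",
                                 fill_value=0.0)
                 .reindex(index=members, columns=list(cats), fill_value=0.0)
                 .astype(float) * annualize)
        total = table.sum(axis=1)
        for cat in cats:
            col = table[cat]
            sd = float(col.std(ddof=1)) if n > 1 else float("nan")
            rows.append((cohort, cat, float(col.mean()) if n else float("nan"),
                         sd, n))
        sd = float(total.std(ddof=1)) if n > 1 else float("nan")
        rows.append((cohort, "total", float(total.mean()) if n else float("nan"),
                     sd, n))
    return pd.DataFrame(rows, columns=["cohort", "category", "mean_pppy",
                                       "sd_pppy", "n"])
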