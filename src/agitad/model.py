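"""Administrative-claims data model: diagnosis codes, code sets, claim tables.

The package works on four longitudinal tables held as pandas DataFrames and
wrapped in a :class:`ClaimsBundle`:

``beneficiaries``
    one row per person: ``id, birth_date, sex, race_ethnicity, region,
    dual_eligible, entitlement_reason, cms_hcc_score``
``enrollment``
    coverage spells: ``beneficiary_id, start, end, medical, pharmacy``
    (dates inclusive on both ends)
``medical_claims``
    ``claim_id, beneficiary_id, service_start, service_end, setting,
    diagnoses, paid_amount`` where ``diagnoses`` packs an ordered list of
    codes as ``"SYS:CODE|SYS:CODE"`` (position 1 = principal diagnosis)
``pharmacy_claims``
    ``claim_id, beneficiary_id, fill_date, paid_amount``

All dates are calendar dates (stored as pandas Timestamps at midnight) and all
intervals are inclusive of both endpoints, matching the day-level resolution
of claims data.  Diagnosis codes are ICD-9-CM or ICD-10-CM, normalized to
uppercase dot-free strings; matching is system-aware, so an ICD-9 code never
matches an ICD-10 entry even when the strings coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

ICD9 = "ICD9"
ICD10 = "ICD10"
CODE_SYSTEMS = (ICD9, ICD10)

# care settings of medical claims
ACUTE = "inpatient_acute"
EMERGENCY = "emergency"
OUTPATIENT = "outpatient"
PHYSICIAN = "physician_service"
DME = "dme"
SNF = "snf"
HOME_HEALTH = "home_health"
LTACH = "ltach"
IRF = "irf"
HOSPICE = "hospice"

#: post-acute settings, in the report order used throughout
PAC_SETTINGS = (SNF, HOME_HEALTH, LTACH, IRF, HOSPICE)
#: settings whose claims describe institutional/episodic care (stay-forming)
STAY_SETTINGS = (ACUTE,) + PAC_SETTINGS
SETTINGS = (ACUTE, EMERGENCY, OUTPATIENT, PHYSICIAN, DME) + PAC_SETTINGS

SEXES = ("F", "M", "unknown")
RACES = ("White", "Black", "Hispanic/Latino", "Asian",
         "North American Native", "Unknown")
REGIONS = ("South", "Midwest", "Northeast", "West", "Unknown")
ENTITLEMENTS = ("aged", "disability", "ESRD", "disability_and_ESRD")

BENEFICIARY_COLUMNS = ("id", "birth_date", "sex", "race_ethnicity", "region",
                       "dual_eligible", "entitlement_reason", "cms_hcc_score")
ENROLLMENT_COLUMNS = ("beneficiary_id", "start", "end", "medical", "pharmacy")
MEDICAL_COLUMNS = ("claim_id", "beneficiary_id", "service_start",
                   "service_end", "setting", "diagnoses", "paid_amount")
PHARMACY_COLUMNS = ("claim_id", "beneficiary_id", "fill_date", "paid_amount")


class ValidationError(ValueError):
    """A table, code, or configuration violates the data-model contract."""


def _as_timestamp(d) -> pd.Timestamp:
    ts = pd.Timestamp(d)
    return ts.normalize()


@dataclass(frozen=True, order=True)
class Code:
    """A normalized diagnosis code: coding system plus dot-free value."""

    system: str
    value: str

    def __post_init__(self):
        if self.system not in CODE_SYSTEMS:
            raise ValidationError(
                f"unknown code system {self.system!r}; expected one of {CODE_SYSTEMS}")
        if not self.value or "." in self.value:
            raise ValidationError(f"malformed code value {self.value!r}")

    def __str__(self) -> str:  # "ICD10:G300"
        return f"{self.system}:{self.value}"


def normalize_code(raw: str, system: str) -> Code:
    """Normalize a raw diagnosis code string to a :class:`Code`.

    Uppercases, strips surrounding whitespace and removes dots, e.g.
    ``("G30.0", "ICD10") -> ICD10:G300``.  Idempotent.  Raises
    :class:`ValidationError` for empty or non-alphanumeric input.
    """
    cleaned = str(raw).strip().upper().replace(".", "")
    if not cleaned or not cleaned.isalnum():
        raise ValidationError(f"cannot normalize diagnosis code {raw!r}")
    return Code(system=system, value=cleaned)


@dataclass(frozen=True)
class CodeSetEntry:
    """One entry of a code set; ``prefix=True`` matches any code extending it."""

    code: Code
    prefix: bool = False


@dataclass(frozen=True)
class CodeSet:
    """A labelled set of diagnosis codes with exact/prefix matching semantics.

    Code sets are the unit of phenotype configuration: AD, dementia,
    agitation, the three severe-mental-illness sets and the comorbidity
    mappings are all expressed this way and loaded from configuration files.
    """

    label: str
    entries: tuple[CodeSetEntry, ...]

    def __post_init__(self):
        if not self.entries:
            raise ValidationError(f"code set {self.label!r} has no entries")
        seen = set()
        for e in self.entries:
            key = (e.code.system, e.code.value, e.prefix)
            if key in seen:
                raise ValidationError(
                    f"code set {self.label!r} duplicates entry {key}")
            seen.add(key)

    def matches(self, code: Code) -> bool:
        """True iff some entry matches ``code`` (same system; exact or prefix)."""
        for e in self.entries:
            if e.code.system != code.system:
                continue
            if e.prefix:
                if code.value.startswith(e.code.value):
                    return True
            elif code.value == e.code.value:
                return True
        return False

    def match_mask(self, dx: pd.DataFrame) -> np.ndarray:
        """Vectorized matching over a frame with ``system``/``value`` columns."""
        mask = np.zeros(len(dx), dtype=bool)
        if not len(dx):
            return mask
        system = dx["system"].to_numpy()
        value = dx["value"]
        for e in self.entries:
            sys_ok = system == e.code.system
            if not sys_ok.any():
                continue
            if e.prefix:
                hit = value.str.startswith(e.code.value).to_numpy()
            else:
                hit = (value == e.code.value).to_numpy()
            mask |= sys_ok & hit
        return mask


def pack_diagnoses(codes: Sequence[Code]) -> str:
    """Serialize an ordered diagnosis list to the packed column format."""
    return "|".join(str(c) for c in codes)


def parse_diagnoses(packed: str) -> list[Code]:
    """Parse a packed ``"SYS:CODE|SYS:CODE"`` diagnosis string."""
    if packed is None or packed == "" or (isinstance(packed, float) and np.isnan(packed)):
        return []
    out = []
    for part in str(packed).split("|"):
        system, _, value = part.partition(":")
        if system not in CODE_SYSTEMS or not value:
            raise ValidationError(f"malformed packed diagnosis {part!r}")
        out.append(normalize_code(value, system))
    return out


@dataclass(eq=False)
class ClaimsBundle:
    """The joined longitudinal claims tables for one study population.

    ``study_window`` bounds all claim dates (inclusive).  Construct via
    :func:`agitad.io.read_bundle`, :func:`agitad.synth.generate_population`
    or directly from conforming DataFrames, then call :meth:`validate`.
    """

    beneficiaries: pd.DataFrame
    enrollment: pd.DataFrame
    medical_claims: pd.DataFrame
    pharmacy_claims: pd.DataFrame
    study_window: tuple[pd.Timestamp, pd.Timestamp]

    def __post_init__(self):
        self.study_window = (_as_timestamp(self.study_window[0]),
                             _as_timestamp(self.study_window[1]))
        self._dx_cache: pd.DataFrame | None = None

    # -- basic views ----------------------------------------------------
    @property
    def n_beneficiaries(self) -> int:
        return len(self.beneficiaries)

    def dx_long(self) -> pd.DataFrame:
        """Exploded diagnosis table, one row per (claim, diagnosis position).

        Columns: ``claim_id, beneficiary_id, date (service_start), setting,
        position (1-based), system, value``.  Cached; invalidated only by
        rebuilding the bundle.
        """
        if self._dx_cache is not None:
            return self._dx_cache
        mc = self.medical_claims
        has_dx = mc["diagnoses"].fillna("") != ""
        base = mc.loc[has_dx, ["claim_id", "beneficiary_id", "service_start",
                               "setting", "diagnoses"]].copy()
        if not len(base):
            self._dx_cache = pd.DataFrame(columns=[
                "claim_id", "beneficiary_id", "date", "setting",
                "position", "system", "value"])
            return self._dx_cache
        split = base["diagnoses"].str.split("|")
        long = base.drop(columns="diagnoses").join(split.rename("dx")).explode("dx")
        long["position"] = long.groupby("claim_id").cumcount() + 1
        sysval = long["dx"].str.partition(":")
        long["system"] = sysval[0]
        long["value"] = sysval[2]
        long = long.rename(columns={"service_start": "date"}).drop(columns="dx")
        long = long.reset_index(drop=True)
        self._dx_cache = long
        return long

    # -- validation -----------------------------------------------------
    def validate(self) -> "ClaimsBundle":
        """Check all bundle invariants; raise ValidationError listing offenders."""
        errors: list[str] = []
        bene = self.beneficiaries
        for name, df, cols in (
                ("beneficiaries", bene, BENEFICIARY_COLUMNS),
                ("enrollment", self.enrollment, ENROLLMENT_COLUMNS),
                ("medical_claims", self.medical_claims, MEDICAL_COLUMNS),
                ("pharmacy_claims", self.pharmacy_claims, PHARMACY_COLUMNS)):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                errors.append(f"{name}: missing columns {missing}")
        if errors:
            raise ValidationError("; ".join(errors))

        if bene["id"].duplicated().any():
            dups = bene.loc[bene["id"].duplicated(), "id"].tolist()[:10]
            errors.append(f"duplicate beneficiary ids {dups}")
        known = set(bene["id"])
        for name, df, col, idcol in (
                ("enrollment", self.enrollment, "beneficiary_id", None),
                ("medical_claims", self.medical_claims, "beneficiary_id", "claim_id"),
                ("pharmacy_claims", self.pharmacy_claims, "beneficiary_id", "claim_id")):
            orphan = ~df[col].isin(known)
            if orphan.any():
                ids = (df.loc[orphan, idcol] if idcol else df.loc[orphan, col])
                errors.append(
                    f"{name}: rows reference unknown beneficiaries: "
                    f"{ids.tolist()[:10]}")

        start, end = self.study_window
        mc = self.medical_claims
        if len(mc):
            bad = (mc["service_start"] > mc["service_end"])
            if bad.any():
                errors.append(
                    f"medical_claims: service_start after service_end for "
                    f"{mc.loc[bad, 'claim_id'].tolist()[:10]}")
            out = (mc["service_start"] < start) | (mc["service_end"] > end)
            if out.any():
                errors.append(
                    f"medical_claims: outside study window: "
                    f"{mc.loc[out, 'claim_id'].tolist()[:10]}")
            bad_set = ~mc["setting"].isin(SETTINGS)
            if bad_set.any():
                errors.append(
                    f"medical_claims: unknown setting for "
                    f"{mc.loc[bad_set, 'claim_id'].tolist()[:10]}")
            no_dx = (mc["diagnoses"].fillna("") == "") & (mc["setting"] != DME)
            if no_dx.any():
                errors.append(
                    f"medical_claims: empty diagnoses outside dme for "
                    f"{mc.loc[no_dx, 'claim_id'].tolist()[:10]}")
            if (mc["paid_amount"] < 0).any():
                errors.append("medical_claims: negative paid_amount")
        pc = self.pharmacy_claims
        if len(pc):
            out = (pc["fill_date"] < start) | (pc["fill_date"] > end)
            if out.any():
                errors.append(
                    f"pharmacy_claims: outside study window: "
                    f"{pc.loc[out, 'claim_id'].tolist()[:10]}")
            if (pc["paid_amount"] < 0).any():
                errors.append("pharmacy_claims: negative paid_amount")
        en = self.enrollment
        if len(en):
            bad = en["start"] > en["end"]
            if bad.any():
                errors.append(
                    f"enrollment: start after end for beneficiaries "
                    f"{en.loc[bad, 'beneficiary_id'].tolist()[:10]}")

        # birth precedes every claim date
        if len(mc):
            first_claim = mc.groupby("beneficiary_id")["service_start"].min()
            birth = bene.set_index("id")["birth_date"]
            joined = first_claim.to_frame("first").join(birth.rename("birth"), how="left")
            late = joined["birth"] >= joined["first"]
            if late.any():
                errors.append(
                    f"beneficiaries born on/after their first claim: "
                    f"{joined.index[late].tolist()[:10]}")

        if errors:
            raise ValidationError("; ".join(errors))
        return self


def empty_bundle(study_window) -> ClaimsBundle:
    """A structurally valid bundle with zero beneficiaries."""
    return ClaimsBundle(
        beneficiaries=pd.DataFrame(columns=list(BENEFICIARY_COLUMNS)),
        enrollment=pd.DataFrame(columns=list(ENROLLMENT_COLUMNS)),
        medical_claims=pd.DataFrame(columns=list(MEDICAL_COLUMNS)),
        pharmacy_claims=pd.DataFrame(columns=list(PHARMACY_COLUMNS)),
        study_window=study_window,
    )
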