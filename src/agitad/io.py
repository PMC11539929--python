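"""Readers and writers for claims tables and code-set configuration files.

Bundles are stored as four UTF-8 comma-separated tables with header rows
(``beneficiaries.csv``, ``enrollment.csv``, ``medical_claims.csv``,
``pharmacy_claims.csv``) plus ``study_window.json`` recording the study
period.  Dates are ISO-8601 (YYYY-MM-DD).  Code sets and comorbidity-index
configurations are YAML; illustrative fixtures ship with the package (they
are NOT the source study's code lists, which are configuration, not code).
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (BENEFICIARY_COLUMNS, ENROLLMENT_COLUMNS, MEDICAL_COLUMNS,
                    PHARMACY_COLUMNS, CODE_SYSTEMS, ClaimsBundle, Code,
                    CodeSet, CodeSetEntry, ValidationError, normalize_code,
                    pack_diagnoses)

_TABLES = {
    "beneficiaries": BENEFICIARY_COLUMNS,
    "enrollment": ENROLLMENT_COLUMNS,
    "medical_claims": MEDICAL_COLUMNS,
    "pharmacy_claims": PHARMACY_COLUMNS,
}
_DATE_COLS = {
    "beneficiaries": ["birth_date"],
    "enrollment": ["start", "end"],
    "medical_claims": ["service_start", "service_end"],
    "pharmacy_claims": ["fill_date"],
}
_BOOL_COLS = {
    "beneficiaries": ["dual_eligible"],
    "enrollment": ["medical", "pharmacy"],
    "medical_claims": [],
    "pharmacy_claims": [],
}


# ---------------------------------------------------------------------------
# code-set configuration
# ---------------------------------------------------------------------------

def code_sets_from_dict(raw: dict) -> dict[str, CodeSet]:
    """Build labelled code sets from a parsed configuration mapping."""
    out: dict[str, CodeSet] = {}
    for label, entries in raw.items():
        if not entries:
            raise ValidationError(f"code set {label!r} has no entries")
        built = []
        for e in entries:
            system = e.get("system")
            if system not in CODE_SYSTEMS:
                raise ValidationError(
                    f"code set {label!r}: unknown system {system!r}")
            code = normalize_code(e["code"], system)
            built.append(CodeSetEntry(code=code, prefix=bool(e.get("prefix", False))))
        out[label] = CodeSet(label=label, entries=tuple(built))
    return out


def read_code_sets(path) -> dict[str, CodeSet]:
    """Read a YAML code-set configuration file (label -> entry list)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping of label -> entries")
    return code_sets_from_dict(raw)


def write_code_sets(code_sets: dict[str, CodeSet], path) -> None:
    raw = {
        label: [
            {"system": e.code.system, "code": e.code.value,
             **({"prefix": True} if e.prefix else {})}
            for e in cs.entries
        ]
        for label, cs in code_sets.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def default_code_sets() -> dict[str, CodeSet]:
    """Illustrative phenotype code sets shipped with the package.

    These are plausible ICD-9/ICD-10 choices for demonstration and testing;
    a real analysis must supply its own vetted lists via configuration.
    """
    ref = importlib.resources.files("agitad.data") / "codesets_illustrative.yaml"
    with importlib.resources.as_file(ref) as p:
        return read_code_sets(p)


# ---------------------------------------------------------------------------
# enrollment canonicalization
# ---------------------------------------------------------------------------

def merge_day_intervals(intervals, abut_gap: int = 1):
    """Union inclusive day intervals, merging overlaps and abutments.

    ``intervals`` is an iterable of (start, end) pairs of comparable
    day-valued endpoints (ints or Timestamps).  Two intervals merge when the
    next start is within ``abut_gap`` days of the current end (gap of zero
    uncovered days).  Returns sorted disjoint intervals.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    step = (pd.Timedelta(days=abut_gap)
            if isinstance(ivs[0][0], pd.Timestamp) else abut_gap)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + step:
            if e > out[-1][1]:
                out[-1][1] = e
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def coverage_intervals(enrollment: pd.DataFrame) -> dict:
    """Merged coverage intervals per beneficiary and coverage type.

    Returns ``{beneficiary_id: {"medical": [(start, end), ...],
    "pharmacy": [...]}}`` with overlapping/abutting spans unioned.
    """
    out: dict = {}
    if not len(enrollment):
        return out
    df = enrollment.sort_values("beneficiary_id", kind="stable")
    bids = df["beneficiary_id"].to_numpy()
    starts = pd.DatetimeIndex(df["start"])   # scalar access yields Timestamps
    ends = pd.DatetimeIndex(df["end"])
    med = df["medical"].to_numpy(dtype=bool)
    pharm = df["pharmacy"].to_numpy(dtype=bool)
    bounds = np.flatnonzero(np.r_[True, bids[1:] != bids[:-1], True])
    for i, j in zip(bounds[:-1], bounds[1:]):
        out[bids[i]] = {
            "medical": merge_day_intervals(
                [(starts[k], ends[k]) for k in range(i, j) if med[k]]),
            "pharmacy": merge_day_intervals(
                [(starts[k], ends[k]) for k in range(i, j) if pharm[k]]),
        }
    return out


def canonicalize_enrollment(enrollment: pd.DataFrame) -> pd.DataFrame:
    """Canonical enrollment rows: disjoint spans with constant coverage flags.

    Per beneficiary, the (medical, pharmacy) coverage profiles are unioned
    per type, the timeline is partitioned at coverage-change boundaries, and
    consecutive days with identical flags are emitted as one row.  The result
    is order-independent and idempotent; rows with no coverage are dropped.
    """
    day = pd.Timedelta(days=1)
    rows = []
    for bid, grp in enrollment.groupby("beneficiary_id", sort=True):
        med = merge_day_intervals(
            grp.loc[grp["medical"], ["start", "end"]].itertuples(index=False))
        pharm = merge_day_intervals(
            grp.loc[grp["pharmacy"], ["start", "end"]].itertuples(index=False))
        bounds = set()
        for s, e in med + pharm:
            bounds.add(s)
            bounds.add(e + day)
        cuts = sorted(bounds)
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            end = hi - day
            in_med = any(s <= lo and end <= e for s, e in med)
            in_pharm = any(s <= lo and end <= e for s, e in pharm)
            if in_med or in_pharm:
                rows.append((bid, lo, end, in_med, in_pharm))
    out = pd.DataFrame(rows, columns=list(ENROLLMENT_COLUMNS))
    if not len(out):
        out = pd.DataFrame(columns=list(ENROLLMENT_COLUMNS))
    return out


# ---------------------------------------------------------------------------
# bundle read/write
# ---------------------------------------------------------------------------

def _read_table(directory: Path, name: str) -> pd.DataFrame:
    path = directory / f"{name}.csv"
    if not path.exists():
        raise ValidationError(f"missing input table {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _TABLES[name]
    missing = [c for c in cols if c not in df.columns]
    dx_cols = [c for c in df.columns if c.startswith("dx")]
    if name == "medical_claims" and "diagnoses" in missing and dx_cols:
        # alternative wide layout dx1..dxK with SYS:CODE cells
        packed = df[dx_cols].apply(
            lambda r: "|".join(v for v in r if v), axis=1)
        df = df.drop(columns=dx_cols)
        df["diagnoses"] = packed
        missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df[list(cols)].copy()
    for c in _DATE_COLS[name]:
        parsed = pd.to_datetime(df[c].replace("", pd.NA), format="%Y-%m-%d",
                                errors="coerce")
        bad = parsed.isna() & (df[c] != "")
        if bad.any():
            raise ValidationError(
                f"{path}: unparseable {c} in rows {df.index[bad].tolist()[:10]}")
        df[c] = parsed
    for c in _BOOL_COLS[name]:
        lowered = df[c].str.lower()
        ok = lowered.isin(["true", "false"])
        if not ok.all():
            raise ValidationError(
                f"{path}: non-boolean {c} in rows {df.index[~ok].tolist()[:10]}")
        df[c] = lowered == "true"
    if "paid_amount" in cols:
        df["paid_amount"] = pd.to_numeric(df["paid_amount"], errors="raise")
    if "cms_hcc_score" in cols:
        df["cms_hcc_score"] = pd.to_numeric(
            df["cms_hcc_score"].replace("", np.nan), errors="raise")
    if name == "medical_claims":
        # normalize every packed diagnosis code
        def _norm(packed: str) -> str:
            if not packed:
                return ""
            return pack_diagnoses([
                normalize_code(part.partition(":")[2], part.partition(":")[0])
                for part in packed.split("|")])
        df["diagnoses"] = df["diagnoses"].map(_norm)
    return df


def read_bundle(directory, canonicalize: bool = True) -> ClaimsBundle:
    """Read, validate and canonicalize a claims bundle from ``directory``.

    Requires the four csv tables; ``study_window.json`` supplies the study
    period (falling back to the observed claim date range when absent).
    Raises :class:`ValidationError` naming offending rows on any schema,
    date, referential-integrity or window violation.
    """
    directory = Path(directory)
    tables = {name: _read_table(directory, name) for name in _TABLES}
    meta_path = directory / "study_window.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        window = (pd.Timestamp(meta["start"]), pd.Timestamp(meta["end"]))
    else:
        dates = pd.concat([
            tables["medical_claims"]["service_start"],
            tables["medical_claims"]["service_end"],
            tables["pharmacy_claims"]["fill_date"],
        ])
        if dates.dropna().empty:
            raise ValidationError(
                f"{directory}: no study_window.json and no claims to infer it")
        window = (dates.min(), dates.max())
    if canonicalize:
        tables["enrollment"] = canonicalize_enrollment(tables["enrollment"])
    bundle = ClaimsBundle(study_window=window, **tables)
    return bundle.validate()


def write_bundle(bundle: ClaimsBundle, directory) -> list[Path]:
    """Write a bundle's tables and study window; inverse of read_bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _TABLES:
        df = getattr(bundle, name).copy()
        for c in _DATE_COLS[name]:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        for c in _BOOL_COLS[name]:
            df[c] = np.where(df[c].astype(bool), "true", "false")
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    meta_path = directory / "study_window.json"
    meta_path.write_text(json.dumps({
        "start": bundle.study_window[0].strftime("%Y-%m-%d"),
        "end": bundle.study_window[1].strftime("%Y-%m-%d"),
    }, indent=2, sort_keys=True) + "\n")
    written.append(meta_path)
    return written
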