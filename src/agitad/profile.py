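"""Baseline cohort characteristics, the Charlson comorbidity score, reports.

Baseline characteristics are summarized per cohort as frequencies with
percentages (categorical variables) and mean (SD) (continuous variables):
age with bands <65 / 65-<80 / >=80 years, sex, race/ethnicity, census
region, Medicare entitlement reason, a disability indicator (original
entitlement due to disability, with or without ESRD), dual
Medicare/Medicaid eligibility as a low-income proxy, the precomputed
CMS-HCC risk score, and the Charlson Comorbidity Index (CCI) computed from
diagnosis codes in the 6-month pre-index baseline window.

The CCI mapping (condition code sets, weights, hierarchy pairs where a
severer condition suppresses its milder form) is configuration; an
illustrative Quan-style mapping ships with the package.  One matching claim
suffices to flag a condition.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .identify import AttritionReport
from .io import code_sets_from_dict
from .model import ClaimsBundle, CodeSet, ValidationError
from .utilization import COHORTS, AnalysisParams

AGE_BANDS = ("<65", "65-<80", ">=80")


def rounded_shares(counts, total, decimals: int = 1) -> list[float]:
    """Percentages rounded to ``decimals`` that still sum to exactly 100.

    Largest-remainder rounding: exact shares are floored at the target
    precision and the leftover tenths are given to the levels with the
    largest fractional parts, so a full partition of ``total`` never drifts
    from 100.0 by rounding.
    """
    if total <= 0:
        return [float("nan")] * len(counts)
    scale = 10 ** decimals
    exact = [c * 100.0 * scale / total for c in counts]
    floors = [int(np.floor(x)) for x in exact]
    leftover = int(round(100 * scale - sum(floors)))
    order = sorted(range(len(counts)), key=lambda i: exact[i] - floors[i],
                   reverse=True)
    for i in order[:max(leftover, 0)]:
        floors[i] += 1
    return [f / scale for f in floors]


# ---------------------------------------------------------------------------
# Charlson comorbidity index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CCICondition:
    label: str
    code_set: CodeSet
    weight: int


@dataclass(frozen=True)
class CCIConfig:
    """Condition mappings, weights and hierarchy overrides for the CCI."""

    conditions: tuple[CCICondition, ...]
    hierarchy: tuple[tuple[str, str], ...] = ()  # (milder, severer)

    def __post_init__(self):
        labels = {c.label for c in self.conditions}
        if len(labels) != len(self.conditions):
            raise ValidationError("duplicate CCI condition labels")
        for c in self.conditions:
            if c.weight < 1:
                raise ValidationError(f"CCI weight for {c.label} must be >= 1")
        for milder, severer in self.hierarchy:
            if milder not in labels or severer not in labels:
                raise ValidationError(
                    f"hierarchy pair ({milder}, {severer}) references "
                    f"undefined conditions")


def read_cci_config(path) -> CCIConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    conditions = []
    for c in raw.get("conditions", []):
        cs = code_sets_from_dict({c["label"]: c["codes"]})[c["label"]]
        conditions.append(CCICondition(label=c["label"], code_set=cs,
                                       weight=int(c["weight"])))
    hierarchy = tuple((h["milder"], h["severer"])
                      for h in raw.get("hierarchy", []))
    return CCIConfig(conditions=tuple(conditions), hierarchy=hierarchy)


def default_cci_config() -> CCIConfig:
    """The illustrative Quan-style mapping shipped with the package."""
    ref = importlib.resources.files("agitad.data") / "cci_illustrative.yaml"
    with importlib.resources.as_file(ref) as p:
        return read_cci_config(p)


def charlson_score(claims: pd.DataFrame, config: CCIConfig) -> int:
    """CCI for one beneficiary from (already baseline-filtered) claims.

    A condition is present when at least one claim carries a matching code
    in any diagnosis position; hierarchy pairs then suppress the milder
    condition; the score is the sum of retained weights.
    """
    from .model import parse_diagnoses
    present = set()
    codes = [c for packed in claims["diagnoses"]
             for c in parse_diagnoses(packed)]
    for cond in config.conditions:
        if any(cond.code_set.matches(c) for c in codes):
            present.add(cond.label)
    for milder, severer in config.hierarchy:
        if severer in present:
            present.discard(milder)
    weights = {c.label: c.weight for c in config.conditions}
    return sum(weights[label] for label in present)


def charlson_scores(bundle: ClaimsBundle, assignments: pd.DataFrame,
                    config: CCIConfig,
                    params: AnalysisParams | None = None,
                    pre_window_days: int = 183) -> pd.Series:
    """Vectorized CCI over cohort members, baseline window [index-183, index)."""
    members = assignments[assignments["status"].isin(COHORTS)]
    idx = members.set_index("beneficiary_id")["index_date"]
    dx = bundle.dx_long()
    dx = dx[dx["beneficiary_id"].isin(idx.index)]
    mapped = dx["beneficiary_id"].map(idx)
    delta = (dx["date"] - mapped).dt.days
    base = dx[(delta >= -pre_window_days) & (delta < 0)]

    present: dict[str, set] = {}
    for cond in config.conditions:
        mask = cond.code_set.match_mask(base)
        present[cond.label] = set(base.loc[mask, "beneficiary_id"])
    for milder, severer in config.hierarchy:
        present[milder] = present[milder] - present[severer]
    scores = pd.Series(0, index=pd.Index(idx.index, name="beneficiary_id"),
                       dtype=int)
    for cond in config.conditions:
        hit = scores.index.isin(present[cond.label])
        scores[hit] += cond.weight
    return scores


# ---------------------------------------------------------------------------
# age helpers
# ---------------------------------------------------------------------------

def age_at_index(birth_date, index_date) -> int:
    """Completed years of age at the index date (birthday-adjusted)."""
    birth = pd.Timestamp(birth_date)
    index = pd.Timestamp(index_date)
    if birth >= index:
        raise ValidationError("birth_date must precede index_date")
    years = index.year - birth.year
    if (index.month, index.day) < (birth.month, birth.day):
        years -= 1
    return years


def age_band(age: int) -> str:
    """Age band as reported: <65, 65-<80, >=80 (half-open boundaries)."""
    if age < 0:
        raise ValidationError("age must be non-negative")
    if age < 65:
        return AGE_BANDS[0]
    if age < 80:
        return AGE_BANDS[1]
    return AGE_BANDS[2]


# ---------------------------------------------------------------------------
# baseline table
# ---------------------------------------------------------------------------

def baseline_table(bundle: ClaimsBundle, assignments: pd.DataFrame,
                   cci_config: CCIConfig | None = None,
                   params: AnalysisParams | None = None,
                   pre_window_days: int = 183) -> pd.DataFrame:
    """Per-cohort baseline characteristics, tidy rows in report order.

    Columns: ``cohort, variable, level, n, pct, mean, sd``.  Counts carry
    ``n``/``pct`` (percentages of the cohort size, 'Unknown' levels
    included); continuous variables carry ``mean``/``sd``.  The CMS-HCC row
    is omitted when the score is missing for every member of both cohorts.
    """
    cci_config = cci_config or default_cci_config()
    members = assignments[assignments["status"].isin(COHORTS)]
    bene = bundle.beneficiaries.set_index("id")
    cci = charlson_scores(bundle, assignments, cci_config, params,
                          pre_window_days)

    rows = []
    for cohort in COHORTS:
        sub = members[members["status"] == cohort]
        ids = sub["beneficiary_id"]
        n = len(ids)
        info = bene.reindex(ids)

        def add_count(variable, level, count):
            pct = round(100.0 * count / n, 1) if n else float("nan")
            rows.append((cohort, variable, level, int(count), pct,
                         float("nan"), float("nan")))

        def add_partition(variable, level_counts):
            # full partitions of the cohort use sum-preserving rounding
            pcts = rounded_shares([c for _, c in level_counts], n)
            for (level, count), pct in zip(level_counts, pcts):
                rows.append((cohort, variable, level, int(count), pct,
                             float("nan"), float("nan")))

        def add_cont(variable, values):
            values = pd.Series(values).dropna().astype(float)
            if not len(values):
                rows.append((cohort, variable, "", 0, float("nan"),
                             float("nan"), float("nan")))
                return
            sd = float(values.std(ddof=1)) if len(values) > 1 else float("nan")
            rows.append((cohort, variable, "", int(len(values)), float("nan"),
                         float(values.mean()), sd))

        rows.append((cohort, "n", "", n, 100.0 if n else float("nan"),
                     float("nan"), float("nan")))
        if n:
            ages = [age_at_index(b, x) for b, x in
                    zip(info["birth_date"], sub["index_date"])]
            add_cont("age_years", ages)
            bands = pd.Series([age_band(a) for a in ages])
            add_partition("age_band", [
                (band, (bands == band).sum())
                for band in (AGE_BANDS[2], AGE_BANDS[1], AGE_BANDS[0])])
            add_partition("sex", [(level, (info["sex"] == level).sum())
                                  for level in ("F", "M", "unknown")])
            add_partition("race_ethnicity", [
                (level, (info["race_ethnicity"] == level).sum())
                for level in info["race_ethnicity"].value_counts().index])
            add_partition("region", [
                (level, (info["region"] == level).sum())
                for level in info["region"].value_counts().index])
            add_partition("entitlement", [
                (level, (info["entitlement_reason"] == level).sum())
                for level in ("aged", "disability", "ESRD",
                              "disability_and_ESRD")])
            add_count("disability_proxy", "disabled",
                      info["entitlement_reason"].isin(
                          ["disability", "disability_and_ESRD"]).sum())
            add_count("dual_eligible", "yes",
                      info["dual_eligible"].astype(bool).sum())
            if info["cms_hcc_score"].notna().any():
                add_cont("cms_hcc_score", info["cms_hcc_score"])
            add_cont("cci_score", cci.reindex(ids))
    return pd.DataFrame(rows, columns=["cohort", "variable", "level",
                                       "n", "pct", "mean", "sd"])


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_reports(out_dir, attrition: AttritionReport,
                   assignments: pd.DataFrame, baseline: pd.DataFrame,
                   utilization: pd.DataFrame, costs: pd.DataFrame,
                   manifest: dict | None = None) -> list[Path]:
    """Write deterministic delimited-text report tables plus a manifest.

    Identical inputs produce byte-identical files.  The manifest records the
    final cohort sizes and agitation share alongside any caller-supplied
    run metadata (seed, configuration hash).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    tables = {
        "attrition.csv": attrition.to_frame(),
        "assignments.csv": assignments.assign(
            index_date=pd.to_datetime(assignments["index_date"])
            .dt.strftime("%Y-%m-%d").fillna("")),
        "baseline.csv": baseline,
        "utilization.csv": utilization,
        "costs.csv": costs,
    }
    for name, df in tables.items():
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)

    summary = {
        "agitation_n": attrition.agitation_n,
        "no_agitation_n": attrition.no_agitation_n,
        "agitation_share": round(attrition.agitation_share, 6)
        if attrition.agitation_n + attrition.no_agitation_n else None,
        "steps": [list(s) for s in attrition.steps],
    }
    if manifest:
        summary["run"] = manifest
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written


def config_digest(obj) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
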