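"""Shared fixtures: code sets, claim-frame builders, small synthetic runs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from agitad.io import default_code_sets
from agitad.model import (BENEFICIARY_COLUMNS, ENROLLMENT_COLUMNS,
                          MEDICAL_COLUMNS, PHARMACY_COLUMNS, PHYSICIAN,
                          ClaimsBundle)

settings.register_profile(
    "agitad", deadline=None, derandomize=True,
    suppress_health_check=list(HealthCheck))
settings.load_profile("agitad")

BASE = pd.Timestamp("2012-01-01")


@pytest.fixture(scope="session")
def code_sets():
    return default_code_sets()


@pytest.fixture(scope="session")
def claims_frame():
    """Factory: medical-claims frame from (day, packed_dx[, setting]) tuples."""

    def build(day_codes, beneficiary_id="B0", setting=PHYSICIAN, base=BASE):
        rows = []
        for k, item in enumerate(day_codes):
            day, packed = item[0], item[1]
            stg = item[2] if len(item) > 2 else setting
            date = base + pd.Timedelta(days=int(day))
            rows.append((f"C{k:03d}", beneficiary_id, date, date, stg,
                         packed, 0.0))
        return pd.DataFrame(rows, columns=list(MEDICAL_COLUMNS))

    return build


@pytest.fixture(scope="session")
def bundle_builder():
    """Factory: a small validated bundle from per-table row lists.

    ``medical`` rows: (claim_id, bene, start_day, end_day, setting, dxs, paid)
    with day offsets from ``base``; ``enrollment`` rows: (bene, start_day,
    end_day, medical, pharmacy); ``pharmacy`` rows: (claim_id, bene, day,
    paid).  Beneficiary attributes get sensible defaults.
    """

    def build(bene_ids, medical=(), enrollment=None, pharmacy=(),
              base=BASE, window_days=3000, bene_overrides=None):
        bene_overrides = bene_overrides or {}
        brows = []
        for bid in bene_ids:
            row = {"id": bid, "birth_date": base - pd.Timedelta(days=30000),
                   "sex": "F", "race_ethnicity": "White", "region": "South",
                   "dual_eligible": False, "entitlement_reason": "aged",
                   "cms_hcc_score": 1.0}
            row.update(bene_overrides.get(bid, {}))
            brows.append(row)
        beneficiaries = pd.DataFrame(brows, columns=list(BENEFICIARY_COLUMNS))
        if enrollment is None:
            enrollment = [(bid, 0, window_days, True, True) for bid in bene_ids]
        enr = pd.DataFrame(
            [(b, base + pd.Timedelta(days=s), base + pd.Timedelta(days=e),
              m, p) for b, s, e, m, p in enrollment],
            columns=list(ENROLLMENT_COLUMNS))
        med = pd.DataFrame(
            [(cid, b, base + pd.Timedelta(days=s), base + pd.Timedelta(days=e),
              stg, dxs, paid) for cid, b, s, e, stg, dxs, paid in medical],
            columns=list(MEDICAL_COLUMNS))
        pharm = pd.DataFrame(
            [(cid, b, base + pd.Timedelta(days=d), paid)
             for cid, b, d, paid in pharmacy],
            columns=list(PHARMACY_COLUMNS))
        bundle = ClaimsBundle(
            beneficiaries=beneficiaries, enrollment=enr, medical_claims=med,
            pharmacy_claims=pharm,
            study_window=(base - pd.Timedelta(days=400),
                          base + pd.Timedelta(days=window_days)))
        return bundle.validate()

    return build


@pytest.fixture(scope="session")
def small_population():
    """One seeded synthetic population (n=600) shared by non-acceptance tests."""
    from agitad.synth import default_generator_config, generate_population
    config = default_generator_config(n_beneficiaries=600, seed=42)
    bundle, truth = generate_population(config)
    return config, bundle, truth


@pytest.fixture(scope="session")
def small_results(small_population, code_sets):
    from agitad.identify import assign_cohorts
    _, bundle, truth = small_population
    assignments, attrition = assign_cohorts(bundle, code_sets)
    return bundle, truth, assignments, attrition
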