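"""Temporal confirmation rules, index dating, enrollment, cohort assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from agitad.identify import (IdentificationParams, assign_cohorts,
                             check_continuous_enrollment, confirm_code_set,
                             confirm_dates, detect_agitation,
                             detect_smi_exclusion, determine_index,
                             STATUS_AGITATION, STATUS_NO_AGITATION,
                             STATUS_SMI, uncovered_days)
from agitad.model import (ENROLLMENT_COLUMNS, Code, CodeSet, CodeSetEntry,
                          ICD10, ValidationError)

BASE = pd.Timestamp("2012-01-01")


def _days(*offsets):
    return [BASE + pd.Timedelta(days=d) for d in offsets]


def _oracle_confirm(days, gap):
    """All-pairs brute force of the 'two claims >= gap days apart' rule."""
    distinct = sorted(set(days))
    return any(b - a >= gap for a, b in itertools.combinations(distinct, 2))


class TestConfirmDates:
    def test_boundary_inclusive(self):
        assert confirm_dates(_days(0, 30), 30).confirmed
        assert not confirm_dates(_days(0, 29), 30).confirmed
        assert confirm_dates(_days(0, 14), 14).confirmed
        assert not confirm_dates(_days(0, 13), 14).confirmed

    def test_single_and_duplicate_dates(self):
        assert not confirm_dates(_days(5), 30).confirmed
        # same-day claims collapse to one distinct date
        assert not confirm_dates(_days(5, 5, 5), 30).confirmed

    def test_first_and_second_dates(self):
        res = confirm_dates(_days(0, 10, 41), 30)
        assert res.confirmed
        assert res.first_date == _days(0)[0]
        assert res.qualifying_second_date == _days(41)[0]
        assert not confirm_dates(_days(0, 10, 25), 30).confirmed

    def test_exhaustive_grid_matches_all_pairs_oracle(self):
        """Every <=3-claim configuration on a 0-60 day grid, both rules."""
        for gap in (30, 14):
            for size in (1, 2, 3):
                for combo in itertools.combinations(range(61), size):
                    got = confirm_dates(list(combo), gap).confirmed
                    assert got == _oracle_confirm(combo, gap), (combo, gap)

    def test_randomized_fuzz_matches_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(2000):
            days = rng.integers(0, 200, size=rng.integers(1, 7)).tolist()
            gap = int(rng.integers(1, 60))
            got = confirm_dates(_days(*days), gap)
            assert got.confirmed == _oracle_confirm(days, gap)
            if got.confirmed:
                first = min(set(days))
                second = min(d for d in set(days) if d - first >= gap)
                assert got.first_date == _days(first)[0]
                assert got.qualifying_second_date == _days(second)[0]

    def test_monotone_in_gap_and_dates(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            days = rng.integers(0, 120, size=4).tolist()
            gap = int(rng.integers(2, 50))
            if confirm_dates(_days(*days), gap).confirmed:
                # shrinking the gap can never un-confirm
                assert confirm_dates(_days(*days), gap - 1).confirmed
                # adding a claim date can never un-confirm
                extra = days + [int(rng.integers(0, 120))]
                assert confirm_dates(_days(*extra), gap).confirmed


class TestConfirmCodeSet:
    def test_position_limit(self, claims_frame, code_sets):
        # AD code only in third position: outside the primary/secondary limit
        claims = claims_frame([(0, "ICD10:I10|ICD10:E785|ICD10:G300"),
                               (40, "ICD10:G300|ICD10:I10")])
        res = confirm_code_set(claims, code_sets["AD"], 30, position_limit=2)
        assert not res.confirmed
        res = confirm_code_set(claims, code_sets["AD"], 30, position_limit=None)
        assert res.confirmed

    def test_larger_code_set_never_unconfirms(self, claims_frame, code_sets):
        claims = claims_frame([(0, "ICD10:G300"), (31, "ICD10:G300")])
        small = code_sets["AD"]
        bigger = CodeSet("AD+", small.entries + (
            CodeSetEntry(Code(ICD10, "ZZZ"), prefix=True),))
        assert confirm_code_set(claims, small, 30).confirmed
        assert confirm_code_set(claims, bigger, 30).confirmed


class TestIndexDate:
    def test_later_first_occurrence_wins(self):
        ad = confirm_dates(_days(0, 40), 30)
        dem = confirm_dates(_days(60, 95), 30)
        assert determine_index(ad, dem) == _days(60)[0]
        assert determine_index(dem, ad) == _days(60)[0]

    def test_tie_same_date(self):
        ad = confirm_dates(_days(10, 45), 30)
        dem = confirm_dates(_days(10, 50), 30)
        assert determine_index(ad, dem) == _days(10)[0]

    def test_requires_both_confirmed(self):
        ad = confirm_dates(_days(0, 40), 30)
        bad = confirm_dates(_days(0), 30)
        with pytest.raises(ValidationError):
            determine_index(ad, bad)

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a0, d0 = int(rng.integers(0, 500)), int(rng.integers(0, 500))
            ad = confirm_dates(_days(a0, a0 + 30 + int(rng.integers(0, 60))), 30)
            dem = confirm_dates(_days(d0, d0 + 30 + int(rng.integers(0, 60))), 30)
            assert determine_index(ad, dem) == max(ad.first_date, dem.first_date)


def _enr(rows):
    return pd.DataFrame(
        [("B0", BASE + pd.Timedelta(days=s), BASE + pd.Timedelta(days=e), m, p)
         for s, e, m, p in rows], columns=list(ENROLLMENT_COLUMNS))


class TestEnrollment:
    params = IdentificationParams()
    index = BASE + pd.Timedelta(days=400)

    def test_full_cover(self):
        enr = _enr([(400 - 183, 400 + 365, True, True)])
        assert check_continuous_enrollment(enr, self.index, self.params)

    def test_one_missing_day_fails_at_zero_tolerance(self):
        enr = _enr([(400 - 183, 400 + 364, True, True)])  # last day uncovered
        assert not check_continuous_enrollment(enr, self.index, self.params)
        tol = IdentificationParams(enrollment_gap_tolerance_days=1)
        assert check_continuous_enrollment(enr, self.index, tol)

    def test_pharmacy_gap_alone_fails(self):
        enr = _enr([(0, 1000, True, False), (0, 399, False, True),
                    (401, 1000, False, True)])
        assert not check_continuous_enrollment(enr, self.index, self.params)

    def test_randomized_spans_match_daily_scan(self):
        rng = np.random.default_rng(17)
        lo, hi = 400 - 183, 400 + 365
        for _ in range(200):
            rows = []
            for _ in range(rng.integers(1, 5)):
                s = int(rng.integers(150, 800))
                e = s + int(rng.integers(0, 400))
                rows.append((s, e, bool(rng.integers(2)), bool(rng.integers(2))))
            tol = int(rng.integers(0, 3))
            params = IdentificationParams(enrollment_gap_tolerance_days=tol)
            got = check_continuous_enrollment(_enr(rows), self.index, params)
            # day-by-day brute force over the 549-day window
            med = np.zeros(hi - lo + 1, bool)
            pharm = np.zeros(hi - lo + 1, bool)
            for s, e, m, p in rows:
                a, b = max(s, lo) - lo, min(e, hi) - lo
                if a <= b:
                    if m:
                        med[a:b + 1] = True
                    if p:
                        pharm[a:b + 1] = True
            expected = ((~med).sum() <= tol) and ((~pharm).sum() <= tol)
            assert got == expected

    def test_uncovered_days_int_and_timestamp(self):
        assert uncovered_days([(0, 9)], 0, 19) == 10
        assert uncovered_days([(BASE, BASE + pd.Timedelta(days=9))],
                              BASE, BASE + pd.Timedelta(days=19)) == 10


class TestSMI:
    def test_single_claims_of_two_illnesses_do_not_exclude(
            self, claims_frame, code_sets):
        claims = claims_frame([(0, "ICD10:F311"), (60, "ICD10:F321")])
        smi = {k: code_sets[k] for k in ("bipolar", "MDD", "schizophrenia")}
        assert detect_smi_exclusion(claims, smi, IdentificationParams()) == set()

    def test_single_illness_boundary(self, claims_frame, code_sets):
        smi = {k: code_sets[k] for k in ("bipolar", "MDD", "schizophrenia")}
        claims = claims_frame([(0, "ICD10:F201"), (30, "ICD10:F201")])
        assert detect_smi_exclusion(claims, smi, IdentificationParams()) == {
            "schizophrenia"}
        claims = claims_frame([(0, "ICD10:F201"), (29, "ICD10:F201")])
        assert detect_smi_exclusion(claims, smi, IdentificationParams()) == set()

    def test_randomized_mixture_matches_per_illness_oracle(
            self, claims_frame, code_sets):
        rng = np.random.default_rng(23)
        smi = {k: code_sets[k] for k in ("bipolar", "MDD", "schizophrenia")}
        codes = {"bipolar": "ICD10:F311", "MDD": "ICD10:F321",
                 "schizophrenia": "ICD10:F201"}
        for _ in range(300):
            rows, truth_days = [], {k: [] for k in codes}
            for _ in range(rng.integers(0, 8)):
                illness = list(codes)[rng.integers(3)]
                day = int(rng.integers(0, 120))
                rows.append((day, codes[illness]))
                truth_days[illness].append(day)
            claims = claims_frame(rows) if rows else claims_frame([])
            got = detect_smi_exclusion(claims, smi, IdentificationParams())
            expected = {k for k, days in truth_days.items()
                        if _oracle_confirm(days, 30)}
            assert got == expected


class TestAssignCohorts:
    def test_empty_bundle(self, code_sets):
        from agitad.model import empty_bundle
        bundle = empty_bundle(("2010-01-01", "2016-12-31"))
        assignments, report = assign_cohorts(bundle, code_sets)
        assert len(assignments) == 0
        assert report.steps[0] == ("beneficiaries", 0, 0)

    def test_agitation_detection_14_day_rule(self, claims_frame, code_sets,
                                             bundle_builder):
        claims = claims_frame([(0, "ICD10:R4511"), (14, "ICD10:R4511")])
        res = detect_agitation(claims, code_sets["agitation"],
                               IdentificationParams())
        assert res.confirmed
        claims = claims_frame([(0, "ICD10:R4511"), (13, "ICD10:R4511")])
        assert not detect_agitation(claims, code_sets["agitation"],
                                    IdentificationParams()).confirmed

    def test_smi_exclusion_precedes_agitation_split(self, bundle_builder,
                                                    code_sets):
        # beneficiary meets BOTH the agitation and the SMI criteria
        medical = [
            ("M1", "B0", 300, 300, "physician_service", "ICD10:G301", 0.0),
            ("M2", "B0", 335, 335, "physician_service", "ICD10:G301", 0.0),
            ("M3", "B0", 300, 300, "physician_service", "ICD10:F031", 0.0),
            ("M4", "B0", 340, 340, "physician_service", "ICD10:F031", 0.0),
            ("M5", "B0", 310, 310, "physician_service", "ICD10:R4511", 0.0),
            ("M6", "B0", 330, 330, "physician_service", "ICD10:R4511", 0.0),
            ("M7", "B0", 305, 305, "physician_service", "ICD10:F311", 0.0),
            ("M8", "B0", 350, 350, "physician_service", "ICD10:F311", 0.0),
        ]
        bundle = bundle_builder(["B0"], medical=medical)
        assignments, report = assign_cohorts(bundle, code_sets)
        assert assignments.loc[0, "status"] == STATUS_SMI
        assert assignments.loc[0, "smi_reasons"] == "bipolar"

    def test_statuses_partition_and_attrition_telescopes(self, small_results):
        _, truth, assignments, report = small_results
        assert len(assignments) == len(truth)
        assert assignments["status"].notna().all()
        prev = None
        for label, remaining, excluded in report.steps:
            if prev is not None:
                assert remaining == prev - excluded
            prev = remaining
        assert report.agitation_n + report.no_agitation_n == prev

    def test_planted_branches_recovered(self, small_results):
        _, truth, assignments, _ = small_results
        merged = assignments.merge(truth, on="beneficiary_id")
        assert (merged["status"] == merged["intended_status"]).all()
        conf = merged[merged["intended_index_date"].notna()]
        assert (pd.to_datetime(conf["index_date"])
                == pd.to_datetime(conf["intended_index_date"])).all()
        smi = merged[merged["status"] == STATUS_SMI]
        assert (smi["smi_reasons"] == smi["intended_smi_reasons"]).all()

    def test_cohort_members_have_index_and_no_smi_reason(self, small_results):
        _, _, assignments, _ = small_results
        cohorts = assignments[assignments["status"].isin(
            [STATUS_AGITATION, STATUS_NO_AGITATION])]
        assert cohorts["index_date"].notna().all()
        assert (cohorts["smi_reasons"] == "").all()
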