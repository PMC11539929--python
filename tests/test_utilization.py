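"""Stay construction, annualized rates, readmissions, post-acute summaries."""

import numpy as np
import pandas as pd
import pytest

from agitad.model import ACUTE, MEDICAL_COLUMNS, Code, CodeSet, CodeSetEntry, ICD10
from agitad.utilization import (AnalysisParams, ad_specific_stays,
                                annualized_rate_per_100, build_stays,
                                pac_summary, readmission_rate_30d,
                                summarize_utilization)

BASE = pd.Timestamp("2013-01-01")


def _claims(rows, bene="B0", setting=ACUTE):
    out = []
    for k, item in enumerate(rows):
        s, e = item[0], item[1]
        dx = item[2] if len(item) > 2 else "ICD10:I10"
        out.append((f"C{k}", bene, BASE + pd.Timedelta(days=s),
                    BASE + pd.Timedelta(days=e), setting, dx, 0.0))
    return pd.DataFrame(out, columns=list(MEDICAL_COLUMNS))


class TestBuildStays:
    def test_abutting_claims_merge_into_one_stay(self):
        stays = build_stays(_claims([(0, 3), (4, 6)]), merge_gap_days=1)
        assert len(stays) == 1
        assert stays.loc[0, "los_days"] == 7

    def test_two_day_gap_splits(self):
        stays = build_stays(_claims([(0, 3), (6, 7)]), merge_gap_days=1)
        assert len(stays) == 2
        assert stays["los_days"].tolist() == [4, 2]

    def test_same_day_stay_has_los_one(self):
        stays = build_stays(_claims([(5, 5)]))
        assert stays.loc[0, "los_days"] == 1

    def test_principal_dx_from_earliest_claim(self):
        stays = build_stays(_claims([(2, 4, "ICD10:E785|ICD10:I10"),
                                     (0, 1, "ICD10:G300|ICD10:I10")]))
        assert len(stays) == 1
        assert stays.loc[0, "principal_value"] == "G300"

    def test_empty_input(self):
        assert len(build_stays(_claims([]))) == 0

    def test_randomized_intervals_match_day_grid_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(150):
            n = int(rng.integers(1, 10))
            gap = int(rng.integers(0, 4))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 80))
                ivs.append((s, s + int(rng.integers(0, 10))))
            stays = build_stays(_claims(ivs), merge_gap_days=gap)
            # oracle: cluster sorted intervals, joining when the next start
            # is within gap days of the running maximum end
            clusters = []
            for s, e in sorted(ivs):
                if clusters and s <= clusters[-1][1] + gap:
                    clusters[-1][1] = max(clusters[-1][1], e)
                else:
                    clusters.append([s, e])
            got = [(r.admit - BASE).days for r in stays.itertuples()]
            assert got == [c[0] for c in clusters]
            assert stays["los_days"].tolist() == [
                c[1] - c[0] + 1 for c in clusters]

    def test_merging_never_increases_stay_count(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            ivs = [(int(s), int(s) + int(rng.integers(0, 6)))
                   for s in rng.integers(0, 60, size=6)]
            n1 = len(build_stays(_claims(ivs), merge_gap_days=0))
            n2 = len(build_stays(_claims(ivs), merge_gap_days=3))
            assert n2 <= n1


class TestAnnualizedRate:
    def test_direct_formula(self):
        counts = [1, 1, 1, 1, 1, 1, 1, 1, 1, 0]  # 9 events over 10 members
        mean, sd = annualized_rate_per_100(counts, [365] * 10)
        assert mean == pytest.approx(90.0)

    def test_all_zero(self):
        mean, sd = annualized_rate_per_100([0, 0, 0], [365] * 3)
        assert mean == 0.0 and sd == 0.0

    def test_partial_followup_scales(self):
        mean, _ = annualized_rate_per_100([1], [73])  # a fifth of a year
        assert mean == pytest.approx(500.0)

    def test_zero_followup_rejected(self):
        from agitad.model import ValidationError
        with pytest.raises(ValidationError):
            annualized_rate_per_100([1], [0])


class TestReadmission:
    end = {"B0": BASE + pd.Timedelta(days=365)}

    def _stays(self, spans):
        df = _claims(spans)
        return build_stays(df)

    def test_thirty_day_boundary_inclusive(self):
        stays = self._stays([(100, 102), (132, 134)])  # gap 30 after discharge
        res = readmission_rate_30d(stays, self.end)
        assert res.rate_pct == pytest.approx(50.0)  # second discharge: no successor
        stays = self._stays([(100, 102), (133, 134)])  # gap 31
        assert readmission_rate_30d(stays, self.end).n_readmissions == 0

    def test_single_stay_rate_zero(self):
        res = readmission_rate_30d(self._stays([(100, 105)]), self.end)
        assert res == (0.0, 0, 1)

    def test_transfer_merged_not_counted(self):
        # admission the day after discharge merges into one stay
        stays = self._stays([(100, 102), (103, 110)])
        assert len(stays) == 1
        assert readmission_rate_30d(stays, self.end).n_readmissions == 0

    def test_late_discharge_excluded_from_denominator(self):
        stays = self._stays([(350, 355)])  # only 10 observable days remain
        res = readmission_rate_30d(stays, self.end)
        assert res.n_eligible_discharges == 0
        assert np.isnan(res.rate_pct)

    def test_no_stays(self):
        res = readmission_rate_30d(self._stays([]), self.end)
        assert res.n_eligible_discharges == 0


class TestAdSpecific:
    ad_set = CodeSet("ad", (CodeSetEntry(Code(ICD10, "G30"), prefix=True),))

    def test_filter_by_principal_membership(self):
        stays = build_stays(_claims([(0, 2, "ICD10:G300|ICD10:I10"),
                                     (10, 12, "ICD10:I10|ICD10:G300")]))
        kept = ad_specific_stays(stays, self.ad_set)
        assert len(kept) == 1
        assert (kept["admit"] == BASE).all()

    def test_missing_principal_dropped(self):
        stays = build_stays(_claims([(0, 2)]))
        stays.loc[0, ["principal_system", "principal_value"]] = ["", ""]
        assert len(ad_specific_stays(stays, self.ad_set)) == 0


class TestPacSummary:
    def test_hand_example(self):
        stays = build_stays(_claims([(0, 9)], setting="snf"))
        out = pac_summary(stays, ["B0", "B1"]).set_index("setting")
        snf = out.loc["snf"]
        assert snf["los_per_patient_mean"] == pytest.approx(5.0)
        assert snf["los_per_stay_mean"] == pytest.approx(10.0)
        assert snf["use_pct"] == pytest.approx(50.0)
        overall = out.loc["overall"]
        assert overall["los_per_patient_mean"] == pytest.approx(5.0)

    def test_no_stays_degenerate(self):
        out = pac_summary(build_stays(_claims([])), ["B0"]).set_index("setting")
        assert out.loc["snf", "los_per_patient_mean"] == 0.0
        assert np.isnan(out.loc["snf", "los_per_stay_mean"])
        assert out.loc["snf", "use_pct"] == 0.0

    def test_accounting_identity(self):
        rng = np.random.default_rng(8)
        rows = []
        for k in range(30):
            s = int(rng.integers(0, 200))
            rows.append((f"C{k}", f"B{rng.integers(10)}",
                         BASE + pd.Timedelta(days=s),
                         BASE + pd.Timedelta(days=s + int(rng.integers(0, 40))),
                         str(rng.choice(["snf", "home_health", "hospice"])),
                         "ICD10:I10", 0.0))
        stays = build_stays(pd.DataFrame(rows, columns=list(MEDICAL_COLUMNS)))
        members = [f"B{i}" for i in range(10)]
        out = pac_summary(stays, members).set_index("setting")
        for setting in out.index:
            r = out.loc[setting]
            pp_total = r["los_per_patient_mean"] * r["n_members"]
            ps_total = (0.0 if r["n_stays"] == 0
                        else r["los_per_stay_mean"] * r["n_stays"])
            assert pp_total == pytest.approx(ps_total)


class TestSummarize:
    def test_ed_visit_inside_acute_stay_absorbed(self, bundle_builder,
                                                 code_sets):
        medical = [
            ("M1", "B0", 400, 400, "physician_service", "ICD10:G301", 0.0),
            ("M2", "B0", 435, 435, "physician_service", "ICD10:G301", 0.0),
            ("M3", "B0", 400, 400, "physician_service", "ICD10:F031", 0.0),
            ("M4", "B0", 440, 440, "physician_service", "ICD10:F031", 0.0),
            # follow-up: one acute stay with an ED claim inside it, one outside
            ("M5", "B0", 500, 510, "inpatient_acute", "ICD10:I10", 100.0),
            ("M6", "B0", 505, 505, "emergency", "ICD10:I10", 10.0),
            ("M7", "B0", 600, 600, "emergency", "ICD10:I10", 10.0),
        ]
        bundle = bundle_builder(["B0"], medical=medical)
        from agitad.identify import assign_cohorts
        assignments, _ = assign_cohorts(bundle, code_sets)
        out = summarize_utilization(bundle, assignments, code_sets)
        no_agit = out[out["cohort"] == "no_agitation"].set_index("metric")
        assert no_agit.loc["ed_visits_per100py", "mean"] == pytest.approx(100.0)
        off = summarize_utilization(bundle, assignments, code_sets,
                                    AnalysisParams(absorb_ed_into_acute=False))
        no_agit = off[off["cohort"] == "no_agitation"].set_index("metric")
        assert no_agit.loc["ed_visits_per100py", "mean"] == pytest.approx(200.0)

    def test_stay_admitted_after_window_excluded(self, bundle_builder,
                                                 code_sets):
        medical = [
            ("M1", "B0", 400, 400, "physician_service", "ICD10:G301", 0.0),
            ("M2", "B0", 435, 435, "physician_service", "ICD10:G301", 0.0),
            ("M3", "B0", 440, 440, "physician_service", "ICD10:F031", 0.0),
            ("M4", "B0", 475, 475, "physician_service", "ICD10:F031", 0.0),
            # index = day 440 (dementia appears later); window ends day 805
            ("M5", "B0", 805, 810, "inpatient_acute", "ICD10:I10", 0.0),
            ("M6", "B0", 806, 812, "snf", "ICD10:I10", 0.0),
        ]
        bundle = bundle_builder(["B0"], medical=medical)
        from agitad.identify import assign_cohorts
        assignments, _ = assign_cohorts(bundle, code_sets)
        out = summarize_utilization(bundle, assignments, code_sets)
        sub = out[out["cohort"] == "no_agitation"].set_index("metric")
        # admitted on the boundary day counts; LOS is not truncated
        assert sub.loc["hospitalizations_all_cause_per100py", "mean"] == 100.0
        assert sub.loc["acute_los_per_patient_days", "mean"] == 6.0
        assert sub.loc["pac_snf_use_pct", "mean"] == 0.0  # admit day 806 > 805

    def test_synthetic_identity_per_cohort(self, small_results, code_sets):
        bundle, _, assignments, _ = small_results
        out = summarize_utilization(bundle, assignments, code_sets)
        for cohort in ("agitation", "no_agitation"):
            sub = out[out["cohort"] == cohort].set_index("metric")
            n = sub.loc["hospitalizations_all_cause_per100py", "n"]
            pp = sub.loc["acute_los_per_patient_days"]
            ps = sub.loc["acute_los_per_stay_days"]
            total_pp = pp["mean"] * n
            total_ps = (ps["mean"] * ps["n"]) if ps["n"] else 0.0
            assert total_pp == pytest.approx(total_ps)
            assert 0.0 <= sub.loc["readmission_rate_30d_pct", "mean"] <= 100.0
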