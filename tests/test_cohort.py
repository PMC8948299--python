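"""Cohort construction: index admissions, exclusions, lookback, summaries."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import mmclust as m


class TestHandwrittenFixture:
    """Hand-traced expectations for every exclusion path (see conftest)."""

    def test_index_set_and_drop_counts(self, handwritten_episodes):
        idx = m.find_index_admissions(handwritten_episodes, 2014)
        assert list(idx.table["patient_id"]) == ["A", "C", "F"]
        assert idx.table.set_index("patient_id")["index_date"].to_dict() == {
            "A": dt.date(2014, 3, 10),
            "C": dt.date(2014, 3, 20),
            "F": dt.date(2014, 6, 1),
        }
        # equal-date tie for F resolved by file order -> routine admission
        assert (
            idx.table.set_index("patient_id").loc["F", "admission_type_at_index"]
            == "routine"
        )
        assert idx.drop_counts == {
            "episodes_input": 14,
            "episodes_missing_id": 1,
            "episodes_outside_study_year": 4,
            "episodes_excluded_record_type": 1,
            "episodes_excluded_admission_type": 3,
            "episodes_index_candidates": 5,
            "patients_with_candidates": 4,
            "patients_under_18": 1,
            "patients_index": 3,
        }

    def test_condition_matrix(self, handwritten_episodes, catalog):
        idx = m.find_index_admissions(handwritten_episodes, 2014)
        mat = m.ascertain_conditions(handwritten_episodes, idx, 5, catalog)
        expected = {
            "A": {"Asthma", "Diabetes"},       # day case + 2011 admission
            "C": {"Depression"},               # psychiatric prior counts
            "F": {"Asthma", "Diabetes"},       # one multi-slot prior
        }
        for pid, conds in expected.items():
            flagged = set(mat.columns[mat.loc[pid] == 1])
            assert flagged == conds, pid
        # hypertension appears only on index-day admissions -> never flagged
        assert mat["Hypertension"].sum() == 0

    def test_include_index_admission_flag(self, handwritten_episodes, catalog):
        idx = m.find_index_admissions(handwritten_episodes, 2014)
        mat = m.ascertain_conditions(
            handwritten_episodes, idx, 5, catalog, include_index_admission=True
        )
        assert mat.loc["A", "Hypertension"] == 1
        assert mat.loc["C", "Diabetes"] == 1  # same-day day case now inside

    def test_ages_and_bands(self, handwritten_episodes):
        idx = m.find_index_admissions(handwritten_episodes, 2014).table
        ages = idx.set_index("patient_id")["age_at_index"].to_dict()
        assert ages == {"A": 64, "C": 73, "F": 23}
        bands = idx.set_index("patient_id")["age_group"].to_dict()
        assert bands == {"A": "60-74", "C": "60-74", "F": "18-29"}


class TestWindowBoundaries:
    def _episodes(self, prior_date):
        rows = []
        for pid, date, diags, typ in [
            ("X", "2014-06-15", ["R104"], "emergency"),
            ("X", prior_date, ["I10"], "routine"),
        ]:
            rows.append(
                dict(
                    patient_id=pid, record_type="general_acute",
                    admission_date=date, discharge_date=date, admission_type=typ,
                    diag_main=diags[0], diag_1="", diag_2="", diag_3="",
                    diag_4="", diag_5="", sex="male", birth_date="1950-01-01",
                    simd_quintile="1", urban_rural="1",
                )
            )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "prior_date,flagged",
        [
            ("2009-06-15", True),   # exactly 5 years before: window start included
            ("2009-07-15", True),   # 4 years 11 months before
            ("2009-06-14", False),  # one day outside
            ("2008-06-15", False),  # 6 years before
            ("2014-06-15", False),  # index day itself (half-open window)
        ],
    )
    def test_half_open_window(self, prior_date, flagged, catalog):
        eps = self._episodes(prior_date)
        idx = m.find_index_admissions(eps, 2014)
        mat = m.ascertain_conditions(eps, idx, 5, catalog)
        assert bool(mat.loc["X", "Hypertension"]) is flagged


class TestFilterMultimorbid:
    def test_threshold(self):
        mat = pd.DataFrame(
            [[0] * 5, [1, 0, 0, 0, 0], [1, 1, 0, 0, 0], [1, 1, 1, 1, 1]],
            index=["p0", "p1", "p2", "p3"],
        )
        out = m.filter_multimorbid(mat)
        assert list(out.index) == ["p2", "p3"]
        assert list(m.filter_multimorbid(mat, 1).index) == ["p1", "p2", "p3"]

    def test_idempotent_and_degenerate(self):
        mat = pd.DataFrame(np.zeros((3, 4), dtype=int))
        assert m.filter_multimorbid(mat).empty
        rng = np.random.default_rng(0)
        M = pd.DataFrame((rng.random((30, 6)) < 0.4).astype(int))
        once = m.filter_multimorbid(M)
        assert once.equals(m.filter_multimorbid(once))


class TestRoundTrip:
    def test_recovered_matrix_equals_planted_truth(self, planted_population, catalog):
        """Generator -> cohort round trip is exact without missingness."""
        eps = planted_population["episodes"]
        truth = planted_population["truth"]
        idx = m.find_index_admissions(eps, 2014)
        mat = m.ascertain_conditions(eps, idx, 5, catalog)
        planted = truth.set_index("patient_id").loc[mat.index].drop(columns="group")
        assert (mat.to_numpy() == planted.to_numpy()).all()

    def test_episode_conservation(self, planted_population):
        idx = m.find_index_admissions(planted_population["episodes"], 2014)
        c = idx.drop_counts
        assert (
            c["episodes_missing_id"]
            + c["episodes_outside_study_year"]
            + c["episodes_excluded_record_type"]
            + c["episodes_excluded_admission_type"]
            + c["episodes_index_candidates"]
            == c["episodes_input"]
        )


class TestSummariseBaseline:
    def test_hand_tally(self, handwritten_episodes, catalog):
        idx = m.find_index_admissions(handwritten_episodes, 2014)
        mat = m.ascertain_conditions(handwritten_episodes, idx, 5, catalog)
        cohort = m.assemble_cohort(idx, mat)
        summary = m.summarise_baseline(cohort)
        mm = summary[summary["stratum"] == ">=2 conditions"]
        total = mm[(mm["block"] == "n")]["n"].iloc[0]
        assert total == 2  # A and F
        female = mm[(mm["block"] == "sex") & (mm["category"] == "female")]
        assert female["n"].iloc[0] == 1 and female["pct"].iloc[0] == 50.0
        not_mm = summary[summary["stratum"] == "<2 conditions"]
        assert not_mm[not_mm["block"] == "n"]["n"].iloc[0] == 1  # C only

    def test_single_patient_degenerate_iqr(self, handwritten_episodes, catalog):
        idx = m.find_index_admissions(handwritten_episodes, 2014)
        mat = m.ascertain_conditions(handwritten_episodes, idx, 5, catalog)
        cohort = m.assemble_cohort(idx, mat)
        summary = m.summarise_baseline(cohort)
        row = summary[
            (summary["stratum"] == "<2 conditions") & (summary["block"] == "age")
        ]
        assert row["value"].iloc[0] == "73 (73-73)"  # C alone
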