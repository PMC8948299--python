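"""Shared fixtures: catalogs and synthetic populations reused across tests."""

import numpy as np
import pandas as pd
import pytest

import mmclust as m


@pytest.fixture(scope="session")
def catalog():
    return m.load_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """Two-condition catalog used by the worked mapping examples."""
    return m.ConditionCatalog(
        (
            m.ConditionDef("A", ("I10",)),
            m.ConditionDef("B", ("E11",)),
        ),
        version="toy",
    )


@pytest.fixture(scope="session")
def default_demographics():
    return m.default_profiles()[2]


@pytest.fixture(scope="session")
def planted_population(default_demographics):
    """n=1000 patients from 10 well-separated groups (0.9/0.05 profiles).

    All patients multimorbid, no missingness; used for clusterability,
    recovery and sensitivity checks.
    """
    weights, profiles = m.well_separated_profiles()
    cfg = m.SimulationConfig(
        n_patients=1000,
        group_weights=weights,
        condition_profiles=profiles,
        demographics=default_demographics,
        multimorbid_fraction=1.0,
        missing_id_rate=0.0,
        missing_postcode_rate=0.0,
        seed=1,
    )
    episodes, truth = m.generate_population(cfg)
    matrix = truth.drop(columns=["patient_id", "group"]).set_index(truth["patient_id"])
    return {"episodes": episodes, "truth": truth, "matrix": matrix}


@pytest.fixture(scope="session")
def planted_baseline(planted_population):
    """Jaccard k-selection baseline on the planted population."""
    D = m.jaccard_matrix(planted_population["matrix"])
    return m.select_k(D, range(2, 16))


def _episode(pid, rec, adm, dis, typ, diags, sex="male", birth="1950-01-01",
             simd="1", ur="1"):
    diags = list(diags) + [""] * (6 - len(diags))
    return dict(
        patient_id=pid, record_type=rec, admission_date=adm, discharge_date=dis,
        admission_type=typ, diag_main=diags[0], diag_1=diags[1], diag_2=diags[2],
        diag_3=diags[3], diag_4=diags[4], diag_5=diags[5], sex=sex,
        birth_date=birth, simd_quintile=simd, urban_rural=ur,
    )


@pytest.fixture(scope="session")
def handwritten_episodes():
    """Hand-traced episode fixture exercising every cohort exclusion.

    Expected outcome (study year 2014, 5-year lookback, default catalog):

    - A: index 2014-03-10 (emergency). Conditions {Diabetes (day case
      2014-01-05), Asthma (2011)}; the 2008 depression code is outside the
      window and the index-day hypertension code never counts.
    - B: only a psychiatric admission in 2014 -> absent.
    - C: obstetric admission skipped; index 2014-03-20. Conditions
      {Depression} via a psychiatric prior; the same-day day case and the
      index diagnosis are excluded.
    - D (blank id): episode dropped.
    - E: aged 14 at index -> excluded.
    - F: two general admissions on 2014-06-01; file order keeps the routine
      one. Conditions {Asthma, Diabetes} from one multi-slot prior.
    """
    rows = [
        _episode("A", "general_acute", "2014-03-10", "2014-03-12", "emergency", ["I10"]),
        _episode("A", "general_acute", "2014-01-05", "2014-01-05", "day_case", ["E11"]),
        _episode("A", "general_acute", "2011-06-01", "2011-06-03", "routine", ["J45"]),
        _episode("A", "general_acute", "2008-02-01", "2008-02-02", "routine", ["F32"]),
        _episode("B", "psychiatric", "2014-02-01", "2014-02-20", "emergency", ["F20"]),
        _episode("C", "general_acute", "2014-01-15", "2014-01-16", "obstetric", ["O800"],
                 sex="female", birth="1940-07-01", simd="3", ur="2"),
        _episode("C", "general_acute", "2014-03-20", "2014-03-25", "emergency", ["I10"],
                 sex="female", birth="1940-07-01", simd="3", ur="2"),
        _episode("C", "psychiatric", "2012-05-01", "2012-06-01", "routine", ["F32"],
                 sex="female", birth="1940-07-01", simd="3", ur="2"),
        _episode("C", "general_acute", "2014-03-20", "2014-03-20", "day_case", ["E11"],
                 sex="female", birth="1940-07-01", simd="3", ur="2"),
        _episode("", "general_acute", "2014-04-01", "2014-04-02", "emergency", ["I10"]),
        _episode("E", "general_acute", "2014-05-01", "2014-05-02", "emergency", ["R104"],
                 birth="1999-06-01"),
        _episode("F", "general_acute", "2014-06-01", "2014-06-02", "routine", ["I10"],
                 sex="female", birth="1990-12-31", simd="5", ur="6"),
        _episode("F", "general_acute", "2014-06-01", "2014-06-03", "emergency", ["E11"],
                 sex="female", birth="1990-12-31", simd="5", ur="6"),
        _episode("F", "general_acute", "2013-01-01", "2013-01-04", "routine", ["J45", "E11"],
                 sex="female", birth="1990-12-31", simd="5", ur="6"),
    ]
    return pd.DataFrame(rows)
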