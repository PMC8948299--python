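"""Cohort construction from raw episode records.

Identifies each patient's index admission in the study year, applies the
exclusions (missing identifier, day-case / obstetric / psychiatric
admissions, age under 18), ascertains the 30 chronic conditions over a
half-open lookback window strictly before the index date, and flags
multimorbidity (>= 2 conditions).

Index identification uses general/acute admissions only, but condition
ascertainment scans *all* record and admission types inside the window —
psychiatric stays are excluded as index events yet still contribute
diagnoses.  The index admission's own diagnoses are excluded from
ascertainment by default (conditions first coded on the index date are
unobservable under a strictly-prior convention); pass
``include_index_admission=True`` for the alternative reading.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .catalog import ConditionCatalog, flag_episode
from .errors import InputFormatError
from .simulate import EPISODE_COLUMNS, _years_before

logger = logging.getLogger(__name__)

DIAG_COLUMNS = ["diag_main", "diag_1", "diag_2", "diag_3", "diag_4", "diag_5"]

AGE_BANDS = [(18, 29), (30, 44), (45, 59), (60, 74), (75, 89), (90, 200)]
AGE_BAND_LABELS = ["18-29", "30-44", "45-59", "60-74", "75-89", ">=90"]

INDEX_ADMISSION_TYPES = {"routine", "emergency"}
EXCLUDED_ADMISSION_TYPES = {"day_case", "obstetric"}


@dataclass
class IndexAdmissions:
    """Index-admission table plus episode/patient drop accounting."""

    table: pd.DataFrame  # one row per index patient
    drop_counts: dict


def read_episodes(path) -> pd.DataFrame:
    """Read the documented flat episode CSV; empty string means missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EPISODE_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"episode file missing columns: {missing}")
    return df[EPISODE_COLUMNS]


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def _age_completed_years(birth: dt.date, on: dt.date) -> int:
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def age_band(age: int) -> str:
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} below adult range")


def find_index_admissions(episodes: pd.DataFrame, study_year: int = 2014) -> IndexAdmissions:
    """Locate each patient's first eligible admission in the study year.

    Eligible index events are general/acute admissions of type routine or
    emergency.  Episodes with a blank patient id are dropped first; patients
    younger than 18 at their index date are excluded.  Equal index dates are
    broken by file order.  All drops are counted for conservation checks.
    """
    df = episodes.copy()
    n_input = len(df)
    has_id = df["patient_id"].astype(str).str.strip() != ""
    n_missing_id = int((~has_id).sum())
    df = df[has_id]

    adm_dates = df["admission_date"].map(_parse_date)
    in_year = adm_dates.map(lambda d: d.year) == study_year
    n_outside_year = int((~in_year).sum())
    df, adm_dates = df[in_year], adm_dates[in_year]

    ok_record = df["record_type"] == "general_acute"
    n_bad_record = int((~ok_record).sum())
    df, adm_dates = df[ok_record], adm_dates[ok_record]

    ok_type = df["admission_type"].isin(INDEX_ADMISSION_TYPES)
    n_bad_type = int((~ok_type).sum())
    df, adm_dates = df[ok_type], adm_dates[ok_type]

    df = df.reset_index(drop=True)
    dates = list(adm_dates)
    # earliest admission per patient; strict < keeps the first file occurrence
    # on equal dates, and output order is the patient's first appearance
    best: dict[str, int] = {}
    order: list[str] = []
    for i, p in enumerate(df["patient_id"]):
        if p not in best:
            best[p] = i
            order.append(p)
        elif dates[i] < dates[best[p]]:
            best[p] = i

    rows = []
    n_under_18 = 0
    for p in order:
        row = df.iloc[best[p]]
        index_date = dates[best[p]]
        birth = _parse_date(row["birth_date"])
        age = _age_completed_years(birth, index_date)
        if age < 18:
            n_under_18 += 1
            continue
        rows.append(
            {
                "patient_id": row["patient_id"],
                "index_date": index_date,
                "age_at_index": age,
                "age_group": age_band(age),
                "sex": row["sex"],
                "admission_type_at_index": row["admission_type"],
                "simd_quintile": row["simd_quintile"],
                "urban_rural": row["urban_rural"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "index_date",
            "age_at_index",
            "age_group",
            "sex",
            "admission_type_at_index",
            "simd_quintile",
            "urban_rural",
        ],
    )
    drop_counts = {
        "episodes_input": n_input,
        "episodes_missing_id": n_missing_id,
        "episodes_outside_study_year": n_outside_year,
        "episodes_excluded_record_type": n_bad_record,
        "episodes_excluded_admission_type": n_bad_type,
        "episodes_index_candidates": int(len(df)),
        "patients_with_candidates": len(order),
        "patients_under_18": n_under_18,
        "patients_index": int(len(table)),
    }
    assert (
        n_missing_id + n_outside_year + n_bad_record + n_bad_type + len(df) == n_input
    ), "episode conservation violated"
    logger.info("index admissions: %s", drop_counts)
    return IndexAdmissions(table, drop_counts)


def ascertain_conditions(
    episodes: pd.DataFrame,
    index: Union[IndexAdmissions, pd.DataFrame],
    lookback_years: int,
    catalog: ConditionCatalog,
    include_index_admission: bool = False,
) -> pd.DataFrame:
    """Binary patient x condition matrix over the lookback window.

    For each index patient, conditions are the union of `flag_episode` over
    every episode of any record/admission type with an admission date in the
    half-open window [index_date - lookback_years, index_date).  With
    ``include_index_admission`` the window closes at the end of the index
    date instead, pulling in same-day and index-admission diagnoses.
    """
    table = index.table if isinstance(index, IndexAdmissions) else index
    df = episodes[episodes["patient_id"].astype(str).str.strip() != ""]
    # flag each episode once; windowing is per patient below
    flags = [
        flag_episode([row[c] for c in DIAG_COLUMNS], catalog)
        for row in df[DIAG_COLUMNS].to_dict("records")
    ]
    adm_dates = df["admission_date"].map(_parse_date).to_numpy()
    pid = df["patient_id"].to_numpy()
    by_patient: dict[str, list[int]] = {}
    for i, p in enumerate(pid):
        by_patient.setdefault(p, []).append(i)

    names = catalog.names
    col_of = {name: j for j, name in enumerate(names)}
    out = np.zeros((len(table), len(names)), dtype=np.int8)
    for r, (_, row) in enumerate(table.iterrows()):
        index_date = row["index_date"]
        start = _years_before(index_date, lookback_years)
        for i in by_patient.get(row["patient_id"], []):
            d = adm_dates[i]
            if include_index_admission:
                inside = start <= d <= index_date
            else:
                inside = start <= d < index_date
            if inside:
                for cond in flags[i]:
                    out[r, col_of[cond]] = 1
    return pd.DataFrame(out, index=pd.Index(table["patient_id"], name="patient_id"), columns=names)


def filter_multimorbid(matrix: pd.DataFrame, min_conditions: int = 2) -> pd.DataFrame:
    """Keep rows with at least ``min_conditions`` conditions, order preserved."""
    kept = matrix[matrix.sum(axis=1) >= min_conditions]
    if kept.empty:
        logger.warning("multimorbidity filter left an empty cohort")
    return kept


def assemble_cohort(index: Union[IndexAdmissions, pd.DataFrame], matrix: pd.DataFrame) -> pd.DataFrame:
    """One row per index patient: demographics + condition flags + count."""
    table = (index.table if isinstance(index, IndexAdmissions) else index).set_index("patient_id")
    table = table.loc[matrix.index]
    cohort = table.copy()
    cohort["condition_count"] = matrix.sum(axis=1).astype(int)
    return pd.concat([cohort, matrix], axis=1)


def _pct_block(series: pd.Series, categories, denominator: Optional[int] = None) -> list[dict]:
    n_total = denominator if denominator is not None else len(series)
    rows = []
    for cat in categories:
        n = int((series == cat).sum())
        rows.append({"category": str(cat), "n": n, "pct": 100.0 * n / n_total if n_total else np.nan})
    return rows


def summarise_baseline(cohort: pd.DataFrame, min_conditions: int = 2) -> pd.DataFrame:
    """Baseline characteristics by multimorbidity status, long format.

    Percentages for sex, age group, admission type and condition counts use
    the stratum total; deprivation and urban-rural percentages use the
    non-missing total, with missing counts reported as their own rows.
    """
    out = []
    strata = {
        f"<{min_conditions} conditions": cohort[cohort["condition_count"] < min_conditions],
        f">={min_conditions} conditions": cohort[cohort["condition_count"] >= min_conditions],
    }
    for stratum, sub in strata.items():
        if sub.empty:
            continue
        ages = sub["age_at_index"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(ages, [25, 50, 75], method="linear")
        out.append({"stratum": stratum, "block": "n", "category": "total", "n": len(sub), "pct": 100.0})
        out.append(
            {"stratum": stratum, "block": "age", "category": "median (IQR)",
             "n": len(sub), "pct": np.nan, "value": f"{med:g} ({q1:g}-{q3:g})"}
        )
        blocks = [
            ("sex", sub["sex"], ["male", "female"], None),
            ("age_group", sub["age_group"], AGE_BAND_LABELS, None),
            ("admission_type", sub["admission_type_at_index"], ["routine", "emergency"], None),
        ]
        for name, series, cats, denom in blocks:
            for row in _pct_block(series, cats, denom):
                out.append({"stratum": stratum, "block": name, **row})
        for name, series, cats in [
            ("simd_quintile", sub["simd_quintile"], ["1", "2", "3", "4", "5"]),
            ("urban_rural", sub["urban_rural"], ["1", "2", "3", "4", "5", "6"]),
        ]:
            non_missing = series[series.astype(str).str.strip() != ""]
            for row in _pct_block(non_missing, cats, len(non_missing)):
                out.append({"stratum": stratum, "block": name, **row})
            out.append(
                {"stratum": stratum, "block": name, "category": "missing",
                 "n": int(len(series) - len(non_missing)), "pct": np.nan}
            )
        counts = sub["condition_count"]
        for c in range(0, int(counts.max()) + 1):
            n = int((counts == c).sum())
            out.append(
                {"stratum": stratum, "block": "condition_count", "category": str(c),
                 "n": n, "pct": 100.0 * n / len(sub)}
            )
    return pd.DataFrame(out)
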