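"""Synthetic hospital-episode generator with planted multimorbidity structure.

Real Scottish Morbidity Record extracts are held in a data safe haven and
cannot be shipped, so every downstream stage of the pipeline is exercised on
synthetic episodes instead.  Patients are drawn from a finite mixture: a
multimorbid fraction belongs to one of K latent groups, each with its own
Bernoulli condition profile over the 30 catalog conditions (resampled until
at least two conditions are present), while background patients carry zero
or one condition so the multimorbidity filter has something to reject.

The planted chronic conditions are written only into admissions *before* the
index admission: each present condition generates a 1-plus-Poisson number of
prior admissions, uniformly dated inside the lookback window, carrying an
ICD-10 code drawn from that condition's catalog prefixes.  The index
admission itself carries a neutral acute code that maps to no catalog
condition, which makes the lookback convention of the cohort builder
directly testable: a condition seen only on the index date must not be
ascertained.

The default mixture (``default_profiles``) encodes the prevalence and
demographic structure of a large Scottish hospital multimorbidity cohort of
11,389 multimorbid inpatients partitioned into ten patient groups: group
weights proportional to the published group sizes, condition profiles equal
to the published per-group prevalences, and per-group age, sex, deprivation,
urban-rural and emergency-admission distributions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ConditionCatalog, load_catalog, match_code
from .errors import ParameterError, SimulationError

#: Acute, non-chronic ICD-10 codes used for index admissions; none of them
#: matches any prefix of the default condition catalog (tested).
NEUTRAL_INDEX_CODES = ("R074", "R104", "J189", "A099", "N390", "M179", "S720", "K359")

#: Retry budget for the >=2-condition rejection loop, per patient.
REJECTION_BUDGET = 1000

#: Sentinel group index for non-multimorbid background patients.
BACKGROUND_GROUP = -1

EPISODE_COLUMNS = [
    "patient_id",
    "record_type",
    "admission_date",
    "discharge_date",
    "admission_type",
    "diag_main",
    "diag_1",
    "diag_2",
    "diag_3",
    "diag_4",
    "diag_5",
    "sex",
    "birth_date",
    "simd_quintile",
    "urban_rural",
]


@dataclass(frozen=True)
class Demographics:
    """Demographic parameters for one latent patient group.

    Ages are drawn from a normal with location ``age_median`` and scale
    ``(q3 - q1)/1.349``, truncated to [18, 105]; categorical weights are
    normalised before sampling.
    """

    age_median: float
    age_iqr: tuple[float, float]
    male_prop: float
    simd_weights: tuple[float, ...]       # 5 deprivation quintiles, 1 = most deprived
    urban_rural_weights: tuple[float, ...]  # sixfold urban-rural classes
    emergency_prop: float

    def __post_init__(self) -> None:
        if len(self.simd_weights) != 5 or len(self.urban_rural_weights) != 6:
            raise ParameterError("need 5 SIMD weights and 6 urban-rural weights")
        if not (0.0 <= self.male_prop <= 1.0 and 0.0 <= self.emergency_prop <= 1.0):
            raise ParameterError("proportions must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic population."""

    n_patients: int
    group_weights: np.ndarray
    condition_profiles: pd.DataFrame  # K x n_conditions Bernoulli probabilities
    demographics: dict  # {"groups": [Demographics]*K, "background": Demographics}
    multimorbid_fraction: float = 0.274
    study_year: int = 2014
    lookback_years: int = 5
    admissions_per_condition: float = 1.5
    background_single_condition_rate: float = 0.241
    missing_id_rate: float = 0.01
    missing_postcode_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_weights = np.asarray(self.group_weights, dtype=float)
        if self.n_patients <= 0:
            raise ParameterError("n_patients must be positive")
        if self.group_weights.ndim != 1 or len(self.group_weights) < 2:
            raise ParameterError("need K >= 2 group weights")
        if abs(self.group_weights.sum() - 1.0) > 1e-9:
            raise ParameterError("group_weights must sum to 1")
        if (self.group_weights < 0).any():
            raise ParameterError("group_weights must be non-negative")
        profiles = np.asarray(self.condition_profiles, dtype=float)
        if profiles.shape[0] != len(self.group_weights):
            raise ParameterError("one profile row per group required")
        if ((profiles < 0) | (profiles > 1)).any():
            raise ParameterError("condition profiles must be probabilities in [0, 1]")
        for rate_name in (
            "multimorbid_fraction",
            "background_single_condition_rate",
            "missing_id_rate",
            "missing_postcode_rate",
        ):
            rate = getattr(self, rate_name)
            if not (0.0 <= rate <= 1.0):
                raise ParameterError(f"{rate_name} must lie in [0, 1]")
        if self.lookback_years <= 0:
            raise ParameterError("lookback_years must be positive")
        if self.admissions_per_condition < 1.0:
            raise ParameterError("admissions_per_condition must be >= 1")
        if len(self.demographics.get("groups", [])) != len(self.group_weights):
            raise ParameterError("one Demographics entry per group required")
        if "background" not in self.demographics:
            raise ParameterError("background Demographics entry required")

    @property
    def n_groups(self) -> int:
        return len(self.group_weights)


def _load_reference_csv(name: str) -> pd.DataFrame:
    ref = resources.files("mmclust.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def default_profiles() -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Reference mixture: weights, condition profiles and demographics.

    Returns K=10 group weights proportional to the reference group sizes
    (2590, 1290, 931, 878, 1396, 834, 654, 694, 1614, 508 of 11,389), a
    10 x 30 profile matrix equal to the reference per-group prevalences
    divided by 100, and per-group plus background demographics.
    """
    prev = _load_reference_csv("group_condition_prevalence.csv")
    demo = _load_reference_csv("group_demographics.csv")
    group_cols = [c for c in prev.columns if c.startswith("g")]
    demo = demo.set_index("group")
    sizes = demo.loc[group_cols, "n"].to_numpy(dtype=float)
    weights = sizes / sizes.sum()
    profiles = pd.DataFrame(
        prev[group_cols].to_numpy().T / 100.0,
        index=group_cols,
        columns=prev["condition"],
    )
    demographics = {
        "groups": [_demographics_from_row(demo.loc[g]) for g in group_cols],
        "background": _demographics_from_row(demo.loc["background"]),
    }
    return weights, profiles, demographics


def _demographics_from_row(row: pd.Series) -> Demographics:
    return Demographics(
        age_median=float(row["age_median"]),
        age_iqr=(float(row["age_q1"]), float(row["age_q3"])),
        male_prop=float(row["male_pct"]) / 100.0,
        simd_weights=tuple(float(row[f"simd{i}"]) for i in range(1, 6)),
        urban_rural_weights=tuple(float(row[f"ur{i}"]) for i in range(1, 7)),
        emergency_prop=float(row["emergency_pct"]) / 100.0,
    )


def reference_prevalence_table() -> pd.DataFrame:
    """Published-style per-group prevalence matrix (%), conditions x groups.

    Used as the fixture for the cluster-labelling rule and as the source of
    the default generator profiles.
    """
    prev = _load_reference_csv("group_condition_prevalence.csv")
    group_cols = [c for c in prev.columns if c.startswith("g")]
    table = prev.set_index("condition")[["overall_pct"] + group_cols]
    return table


def reference_group_sizes() -> pd.Series:
    demo = _load_reference_csv("group_demographics.csv").set_index("group")
    return demo.loc[[g for g in demo.index if g != "background"], "n"]


def well_separated_profiles(
    n_groups: int = 10,
    condition_names: Optional[Sequence[str]] = None,
    within: float = 0.9,
    background: float = 0.05,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Equal-weight mixture with block-structured profiles for recovery tests.

    Conditions are dealt round-robin to groups; a group's own conditions have
    probability ``within``, all others ``background``.
    """
    if condition_names is None:
        condition_names = load_catalog().names
    p = len(condition_names)
    if n_groups < 2 or n_groups > p:
        raise ParameterError("need 2 <= n_groups <= number of conditions")
    profiles = np.full((n_groups, p), background)
    for j in range(p):
        profiles[j % n_groups, j] = within
    weights = np.full(n_groups, 1.0 / n_groups)
    return weights, pd.DataFrame(profiles, columns=list(condition_names))


def default_config(n_patients: int, seed: int = 0, **overrides) -> SimulationConfig:
    """SimulationConfig using the reference mixture as study conditions."""
    weights, profiles, demographics = default_profiles()
    kwargs = dict(
        n_patients=n_patients,
        group_weights=weights,
        condition_profiles=profiles,
        demographics=demographics,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _years_before(d: dt.date, years: int) -> dt.date:
    try:
        return d.replace(year=d.year - years)
    except ValueError:  # Feb 29 anchored to Feb 28
        return d.replace(year=d.year - years, day=28)


def _draw_age(rng: np.random.Generator, demo: Demographics) -> int:
    q1, q3 = demo.age_iqr
    scale = max((q3 - q1) / 1.349, 1.0)
    loc = demo.age_median
    a, b = (18.0 - loc) / scale, (105.0 - loc) / scale
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng)
    return int(np.floor(age))


def _weighted_choice(rng: np.random.Generator, weights: Sequence[float]) -> int:
    w = np.asarray(weights, dtype=float)
    return int(rng.choice(len(w), p=w / w.sum()))


def generate_population(
    config: SimulationConfig, catalog: Optional[ConditionCatalog] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate synthetic episodes and the planted truth labels.

    Returns ``(episodes, truth)``: episodes is one row per admission in the
    documented flat format, truth is one row per patient with the planted
    group (``-1`` for background) and condition flags.  Fully reproducible
    from ``config.seed``.
    """
    catalog = catalog if catalog is not None else load_catalog()
    cond_names = catalog.names
    profiles = np.asarray(config.condition_profiles, dtype=float)
    profile_cols = list(config.condition_profiles.columns)
    if profile_cols != cond_names:
        raise ParameterError(
            "condition_profiles columns must match catalog conditions in order"
        )
    # sanity: the neutral index codes must not flag any catalog condition
    for code in NEUTRAL_INDEX_CODES:
        if match_code(code, catalog) is not None:
            raise SimulationError(f"neutral index code {code} matches the catalog")

    rng = np.random.default_rng(config.seed)
    n_cond = len(cond_names)
    overall = config.group_weights @ profiles
    if overall.sum() <= 0:
        overall = np.full(n_cond, 1.0 / n_cond)

    year_start = dt.date(config.study_year, 1, 1)
    days_in_year = (dt.date(config.study_year + 1, 1, 1) - year_start).days

    episodes: list[tuple] = []
    truth_rows: list[tuple] = []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        is_mm = rng.random() < config.multimorbid_fraction
        if is_mm:
            g = _weighted_choice(rng, config.group_weights)
            for _ in range(REJECTION_BUDGET):
                vec = (rng.random(n_cond) < profiles[g]).astype(np.int8)
                if vec.sum() >= 2:
                    break
            else:
                raise SimulationError(
                    f"group {g}: could not draw >=2 conditions within "
                    f"{REJECTION_BUDGET} attempts (profile too sparse)"
                )
            demo = config.demographics["groups"][g]
        else:
            g = BACKGROUND_GROUP
            vec = np.zeros(n_cond, dtype=np.int8)
            if rng.random() < config.background_single_condition_rate:
                vec[_weighted_choice(rng, overall)] = 1
            demo = config.demographics["background"]

        age = _draw_age(rng, demo)
        sex = "male" if rng.random() < demo.male_prop else "female"
        if rng.random() < config.missing_postcode_rate:
            simd, ur = "", ""
        else:
            simd = str(_weighted_choice(rng, demo.simd_weights) + 1)
            ur = str(_weighted_choice(rng, demo.urban_rural_weights) + 1)

        index_date = year_start + dt.timedelta(days=int(rng.integers(0, days_in_year)))
        # birth date back-dated so completed years at index equal the drawn age
        birth_date = _years_before(index_date, age) - dt.timedelta(
            days=int(rng.integers(0, 365))
        )
        adm_type = "emergency" if rng.random() < demo.emergency_prop else "routine"

        def emit(date, rec_type, a_type, diags):
            diags = list(diags)[:6]
            diags += [""] * (6 - len(diags))
            blank = rng.random() < config.missing_id_rate
            episodes.append(
                (
                    "" if blank else pid,
                    rec_type,
                    date.isoformat(),
                    (date + dt.timedelta(days=int(rng.integers(0, 15)))).isoformat(),
                    a_type,
                    *diags,
                    sex,
                    birth_date.isoformat(),
                    simd,
                    ur,
                )
            )

        # index admission: neutral acute code only, never a planted condition
        emit(
            index_date,
            "general_acute",
            adm_type,
            [NEUTRAL_INDEX_CODES[int(rng.integers(0, len(NEUTRAL_INDEX_CODES)))]],
        )

        present = np.flatnonzero(vec)
        window_start = _years_before(index_date, config.lookback_years)
        window_days = (index_date - window_start).days
        for ci in present:
            cond = catalog.conditions[ci]
            n_adm = 1 + int(rng.poisson(config.admissions_per_condition - 1.0))
            for _ in range(n_adm):
                date = window_start + dt.timedelta(days=int(rng.integers(0, window_days)))
                codes = [_code_for(rng, cond)]
                # occasionally co-code other present conditions in the 5 extra slots
                others = [c for c in present if c != ci]
                if others and rng.random() < 0.3:
                    extra = rng.choice(
                        others, size=min(len(others), int(rng.integers(1, 3))), replace=False
                    )
                    codes += [_code_for(rng, catalog.conditions[e]) for e in extra]
                rec_type = (
                    "psychiatric"
                    if codes[0].startswith("F") and rng.random() < 0.5
                    else "general_acute"
                )
                a_type = "emergency" if rng.random() < 0.5 else "routine"
                # prior admissions inside the study year must not displace the
                # planted index admission, so they are emitted as day cases
                # (never index-eligible, still scanned during ascertainment)
                if date >= year_start and rec_type == "general_acute":
                    a_type = "day_case"
                emit(date, rec_type, a_type, codes)

        truth_rows.append((pid, g, *vec.tolist()))

    episodes_df = pd.DataFrame(episodes, columns=EPISODE_COLUMNS)
    truth_df = pd.DataFrame(truth_rows, columns=["patient_id", "group"] + cond_names)
    return episodes_df, truth_df


def _code_for(rng: np.random.Generator, cond) -> str:
    prefix = cond.icd10_prefixes[int(rng.integers(0, len(cond.icd10_prefixes)))]
    if len(prefix) == 3:
        return prefix + str(int(rng.integers(0, 10)))
    return prefix


def write_episodes(episodes: pd.DataFrame, path) -> None:
    episodes.to_csv(path, index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
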