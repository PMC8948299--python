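"""Characterisation of the patient groups found by the clustering.

Three views: per-group condition prevalence (the analogue of a published
prevalence-by-group table), automatic cluster labelling, and per-group
demographic summaries.

Labelling follows a deterministic rule that reproduces the published
annotation scheme: conditions with prevalence >= 50% within a group are the
group's *cluster conditions* (the "bold" set); the group label is the
highest-prevalence condition's base name, with conditions tied at the
maximum joined by "/" (hence "Chronic kidney disease/diabetes" next to a
plain "Chronic kidney disease" group).  *Feature conditions* (the "italic"
set) are a stated approximation of the original clinical review: a
condition features in the group where it attains its highest prevalence
among groups where it is not a cluster condition, provided it is at least
``feature_min_ratio`` times more prevalent there than overall.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .cohort import AGE_BAND_LABELS
from .errors import ParameterError

COUNT_BANDS = ["2", "3", "4", "5+"]


@dataclass
class PrevalenceTable:
    """Per-group and overall condition prevalence, in percent."""

    table: pd.DataFrame      # conditions x groups, percent
    group_sizes: pd.Series   # per-group n
    overall: pd.Series = None  # conditions, percent; derived if omitted

    def __post_init__(self) -> None:
        weighted = (self.table * self.group_sizes).sum(axis=1) / self.group_sizes.sum()
        if self.overall is None:
            self.overall = weighted
        elif np.abs(weighted - self.overall).max() > 1e-9:
            raise ParameterError(
                "overall prevalence must equal the size-weighted group mean"
            )


@dataclass
class ClusterLabelSet:
    labels: dict            # group -> label string
    cluster_conditions: dict  # group -> list of condition names, by prevalence desc
    feature_conditions: dict  # group -> list of condition names


def prevalence_by_group(
    M: pd.DataFrame, assignment: Sequence[int]
) -> PrevalenceTable:
    """Percentage of each group carrying each condition, plus overall."""
    labels = np.asarray(assignment)
    if labels.shape[0] != len(M):
        raise ParameterError("assignment must cover every matrix row")
    groups = np.unique(labels)
    sizes = pd.Series({g: int((labels == g).sum()) for g in groups})
    if (sizes == 0).any():
        raise ParameterError("empty group in assignment")
    cols = {}
    for g in groups:
        cols[g] = 100.0 * M[labels == g].mean(axis=0)
    table = pd.DataFrame(cols)
    overall = 100.0 * M.mean(axis=0)
    return PrevalenceTable(table=table, overall=overall, group_sizes=sizes)


def condition_base_name(name: str) -> str:
    """Display name for labels: drop parentheticals and comma qualifiers.

    "Cancer, non-metastatic (breast, ...)" -> "Cancer";
    "Cirrhosis (and hepatic decompensation)" -> "Cirrhosis".
    """
    name = re.sub(r"\s*\(.*\)", "", name)
    return name.split(",")[0].strip()


def _join_label(parts: list[str]) -> str:
    parts = [parts[0]] + [p[0].lower() + p[1:] for p in parts[1:]]
    return "/".join(parts)


def label_clusters(
    P: PrevalenceTable, bold_threshold: float = 50.0, feature_min_ratio: float = 1.25
) -> ClusterLabelSet:
    """Derive cluster/feature condition sets and a label per group.

    Cluster conditions: prevalence >= ``bold_threshold`` within the group
    (falling back to the single most prevalent condition if none reaches
    the threshold, so a label always exists).  The label joins all
    conditions tied at the group's maximum prevalence; if two groups still
    share a label, each appends its next-highest cluster condition.
    """
    table = P.table
    bold: dict = {}
    for g in table.columns:
        col = table[g]
        members = col[col >= bold_threshold]
        if members.empty:
            members = col.loc[[col.idxmax()]]
        # order by prevalence descending, ties by table order (stable sort)
        bold[g] = list(members.iloc[np.argsort(-members.to_numpy(), kind="stable")].index)

    labels: dict = {}
    for g in table.columns:
        col = table[g]
        top = col.max()
        tied = [c for c in table.index if col[c] == top]
        labels[g] = _join_label([condition_base_name(c) for c in tied])

    # disambiguate residual collisions with the next-highest cluster condition
    counts = pd.Series(labels).value_counts()
    for g in table.columns:
        if counts[labels[g]] > 1:
            col = table[g]
            used = {condition_base_name(c) for c in table.index if col[c] == col.max()}
            extra = next(
                (c for c in bold[g] if condition_base_name(c) not in used), None
            )
            if extra is not None:
                labels[g] = _join_label(
                    [labels[g], condition_base_name(extra)]
                )

    features: dict = {g: [] for g in table.columns}
    for cond in table.index:
        row = table.loc[cond]
        non_bold_groups = [g for g in table.columns if cond not in bold[g]]
        if not non_bold_groups:
            continue
        best = max(row[g] for g in non_bold_groups)
        for g in non_bold_groups:
            if (
                row[g] == best
                and row[g] > 0
                and row[g] >= feature_min_ratio * P.overall[cond]
            ):
                features[g].append(cond)

    return ClusterLabelSet(
        labels=labels, cluster_conditions=bold, feature_conditions=features
    )


@dataclass
class GroupCharacteristics:
    """Per-group demographic and condition-count summaries."""

    summary: pd.DataFrame      # long: group, block, category, n, pct
    age: pd.DataFrame          # group, median, q1, q3
    condition_count: pd.DataFrame  # group, median, q1, q3
    missing: pd.DataFrame      # group, simd_missing, urban_rural_missing


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def characterise_groups(
    cohort: pd.DataFrame, assignment: Sequence[int]
) -> GroupCharacteristics:
    """Demographics per group: age, sex, deprivation, urban-rural,
    condition-count bands {2,3,4,5+} and admission type.

    Deprivation and urban-rural percentages are over patients with
    non-missing values; missing counts are reported separately.
    """
    labels = np.asarray(assignment)
    if labels.shape[0] != len(cohort):
        raise ParameterError("assignment must align with cohort rows")
    rows, age_rows, count_rows, missing_rows = [], [], [], []
    for g in np.unique(labels):
        sub = cohort[labels == g]
        n = len(sub)
        med, q1, q3 = _quartiles(sub["age_at_index"].to_numpy(dtype=float))
        age_rows.append({"group": g, "n": n, "median": med, "q1": q1, "q3": q3})
        cmed, cq1, cq3 = _quartiles(sub["condition_count"].to_numpy(dtype=float))
        count_rows.append({"group": g, "median": cmed, "q1": cq1, "q3": cq3})

        def add_block(block, series, cats, denominator):
            for cat in cats:
                cnt = int((series == cat).sum())
                rows.append(
                    {
                        "group": g,
                        "block": block,
                        "category": str(cat),
                        "n": cnt,
                        "pct": 100.0 * cnt / denominator if denominator else np.nan,
                    }
                )

        add_block("sex", sub["sex"], ["male", "female"], n)
        add_block("age_group", sub["age_group"], AGE_BAND_LABELS, n)
        add_block(
            "admission_type", sub["admission_type_at_index"], ["routine", "emergency"], n
        )
        simd = sub["simd_quintile"].astype(str).str.strip()
        ur = sub["urban_rural"].astype(str).str.strip()
        add_block("simd_quintile", simd[simd != ""], list("12345"), int((simd != "").sum()))
        add_block("urban_rural", ur[ur != ""], list("123456"), int((ur != "").sum()))
        missing_rows.append(
            {
                "group": g,
                "simd_missing": int((simd == "").sum()),
                "urban_rural_missing": int((ur == "").sum()),
            }
        )
        counts = sub["condition_count"]
        banded = counts.map(lambda c: str(c) if c <= 4 else "5+")
        add_block("condition_count", banded, COUNT_BANDS, n)
    return GroupCharacteristics(
        summary=pd.DataFrame(rows),
        age=pd.DataFrame(age_rows),
        condition_count=pd.DataFrame(count_rows),
        missing=pd.DataFrame(missing_rows),
    )
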