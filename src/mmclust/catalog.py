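"""ICD-10 → chronic-condition mapping.

Conditions are ascertained from hospital diagnosis codes by leading-prefix
match against a catalog of 30 chronic conditions (a Tonelli-style coding
scheme for administrative data).  The packaged default catalog is an
implementer-curated approximation and can be replaced by any CSV with the
same two-column layout (``condition,icd10_prefix``).

Cross-condition prefix nesting (one condition's prefix being a leading
substring of another condition's prefix) is rejected at load time so that
every code maps to at most one condition without longest-match rules.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import CatalogError, InputFormatError

#: Maximum number of diagnosis positions on one episode (main + 5 others).
MAX_DIAGNOSES = 6

_PREFIX_RE = re.compile(r"^[A-Z][A-Z0-9]{2,4}$")


@dataclass(frozen=True)
class ConditionDef:
    """One chronic condition and the ICD-10 prefixes that flag it."""

    name: str
    icd10_prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.icd10_prefixes:
            raise CatalogError(f"condition {self.name!r} has no prefixes")
        for p in self.icd10_prefixes:
            if not _PREFIX_RE.match(p):
                raise CatalogError(
                    f"condition {self.name!r}: invalid prefix {p!r} "
                    "(need 3-5 uppercase alphanumerics, letter first, no dots)"
                )


@dataclass(frozen=True)
class ConditionCatalog:
    """Ordered collection of condition definitions."""

    conditions: tuple[ConditionDef, ...]
    version: str = "custom"
    _prefix_index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CatalogError(f"duplicate condition names: {dupes}")
        index: dict[str, str] = {}
        for cond in self.conditions:
            for p in cond.icd10_prefixes:
                if p in index and index[p] != cond.name:
                    raise CatalogError(
                        f"prefix {p!r} claimed by both {index[p]!r} and {cond.name!r}"
                    )
                index[p] = cond.name
        # reject cross-condition nesting, e.g. "I1" under one condition and
        # "I10" under another would make matching ambiguous
        prefixes = sorted(index)
        for i, a in enumerate(prefixes):
            for b in prefixes[i + 1 :]:
                if not b.startswith(a):
                    break  # lexicographic order: later strings cannot start with a
                if index[a] != index[b]:
                    raise CatalogError(
                        f"prefix nesting across conditions: {a!r} ({index[a]!r}) "
                        f"is a prefix of {b!r} ({index[b]!r})"
                    )
        object.__setattr__(self, "_prefix_index", index)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.conditions]

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)


def normalise_code(raw: Optional[str]) -> str:
    """Normalise a raw diagnosis string to dot-free uppercase ICD-10 form.

    Returns the empty string when no usable code remains (the "no code"
    sentinel); never raises.
    """
    if raw is None:
        return ""
    return str(raw).replace(".", "").replace(" ", "").strip().upper()


def match_code(code: str, catalog: ConditionCatalog) -> Optional[str]:
    """Return the condition name whose prefix leads ``code``, or None.

    ``code`` is expected to be normalised already.  Deterministic because
    prefix nesting across conditions is excluded at load time.
    """
    index = catalog._prefix_index
    # prefixes are 3-5 characters long
    for ln in (3, 4, 5):
        hit = index.get(code[:ln])
        if hit is not None:
            return hit
    return None


def flag_episode(diagnoses: Iterable[str], catalog: ConditionCatalog) -> set[str]:
    """Map one episode's ordered diagnosis codes to the set of conditions.

    Main vs other diagnosis position carries no weight; duplicate codes
    collapse under set semantics.  Empty/no-code slots are dropped before
    the 1-6 position limit is enforced.
    """
    codes = [c for c in (normalise_code(d) for d in diagnoses) if c]
    if len(codes) > MAX_DIAGNOSES:
        raise InputFormatError(
            f"episode carries {len(codes)} diagnosis codes; at most {MAX_DIAGNOSES} allowed"
        )
    out: set[str] = set()
    for code in codes:
        cond = match_code(code, catalog)
        if cond is not None:
            out.add(cond)
    return out


def _parse_rows(rows: Iterable[tuple[int, list[str]]], version: str) -> ConditionCatalog:
    by_condition: dict[str, list[str]] = {}
    for lineno, row in rows:
        if len(row) != 2:
            raise CatalogError(
                f"line {lineno}: expected 2 columns (condition,icd10_prefix), got {len(row)}"
            )
        name, prefix = row[0].strip(), row[1].strip().upper()
        if not name:
            raise CatalogError(f"line {lineno}: empty condition name")
        by_condition.setdefault(name, [])
        if prefix in by_condition[name]:
            raise CatalogError(f"line {lineno}: duplicate prefix {prefix!r} for {name!r}")
        by_condition[name].append(prefix)
    if not by_condition:
        raise CatalogError("catalog file contains no condition rows")
    conds = tuple(
        ConditionDef(name, tuple(prefixes)) for name, prefixes in by_condition.items()
    )
    return ConditionCatalog(conds, version=version)


def load_catalog(path: Union[str, Path, None] = None) -> ConditionCatalog:
    """Load a condition catalog from CSV, or the packaged default.

    The CSV dialect is two columns ``condition,icd10_prefix``, UTF-8, one
    prefix per row, ``#`` comment lines ignored.  The default catalog has
    exactly 30 conditions and its version string flags it as an
    approximation of the validated Tonelli code list.
    """
    if path is None:
        ref = resources.files("mmclust.data").joinpath("condition_catalog.csv")
        with ref.open("r", encoding="utf-8") as fh:
            catalog = _read_catalog_stream(fh, version="default-approx-tonelli-v1")
        if len(catalog) != 30:
            raise CatalogError(
                f"packaged default catalog has {len(catalog)} conditions, expected 30"
            )
        return catalog
    p = Path(path)
    with p.open("r", encoding="utf-8", newline="") as fh:
        return _read_catalog_stream(fh, version=f"file:{p.name}")


def _read_catalog_stream(fh, version: str) -> ConditionCatalog:
    reader = csv.reader(fh)
    rows = []
    header_skipped = False
    for lineno, row in enumerate(reader, start=1):
        if not row or (row[0].lstrip().startswith("#")):
            continue
        if not header_skipped and [c.strip().lower() for c in row[:2]] == [
            "condition",
            "icd10_prefix",
        ]:
            header_skipped = True
            continue
        rows.append((lineno, row))
    return _parse_rows(rows, version)
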