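"""Data model and validated I/O for registry-style joint replacement records.

A procedure record is one row of a national arthroplasty registry extract:
who (opaque patient id, age, sex), when (calendar year), which joint
(knee/hip), the procedure class (primary/revision), the recorded diagnosis,
and where it was done (public/private sector, metropolitan/regional
setting, left/right side).  The module provides

* CSV reading with row-level diagnostics and a configurable column mapping,
* the osteoarthritis/primary inclusion filter,
* age-group binning into <40, 40-69 and 70+ years,
* the bilateral-collapsing rule used for costing: two (or more) same-joint
  procedures for one patient in one year within one hospital sector are
  treated as a single simultaneous bilateral admission, and
* stratified count tabulation with zero-filled cells.

Incidence analyses always count procedures; admissions exist only so that
bilateral surgeries can be costed once at the bilateral rate.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "JOINTS",
    "PROCEDURE_CLASSES",
    "DIAGNOSES",
    "SECTORS",
    "SETTINGS",
    "SIDES",
    "DEFAULT_STUDY_WINDOW",
    "ProcedureRecord",
    "Admission",
    "StratumCountTable",
    "RowDiagnostic",
    "LoadResult",
    "age_group_of",
    "load_registry",
    "write_registry",
    "filter_primary_oa",
    "collapse_bilateral",
    "tabulate_counts",
]

AGE_GROUPS: tuple[str, ...] = ("<40", "40-69", "70+")
SEXES: tuple[str, ...] = ("female", "male")
JOINTS: tuple[str, ...] = ("knee", "hip")
PROCEDURE_CLASSES: tuple[str, ...] = ("primary", "revision")
DIAGNOSES: tuple[str, ...] = ("osteoarthritis", "other")
SECTORS: tuple[str, ...] = ("public", "private")
SETTINGS: tuple[str, ...] = ("metropolitan", "regional")
SIDES: tuple[str, ...] = ("left", "right", "unspecified")

#: Default study window (inclusive) for registry record validation.
DEFAULT_STUDY_WINDOW: tuple[int, int] = (2003, 2013)

# Canonical CSV column names; a dialect maps these onto a file's own headers.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "age_group",
    "sex",
    "year",
    "joint",
    "procedure_class",
    "diagnosis",
    "sector",
    "setting",
    "side",
)
_REQUIRED_COLUMNS = (
    "patient_id",
    "sex",
    "year",
    "joint",
    "procedure_class",
    "diagnosis",
    "sector",
    "setting",
)

# Accepted spellings -> canonical vocabulary, per field.
_VOCAB: dict[str, dict[str, str]] = {
    "sex": {"f": "female", "female": "female", "m": "male", "male": "male"},
    "joint": {"knee": "knee", "tkr": "knee", "hip": "hip", "thr": "hip"},
    "procedure_class": {"primary": "primary", "revision": "revision"},
    "diagnosis": {
        "osteoarthritis": "osteoarthritis",
        "oa": "osteoarthritis",
        "other": "other",
    },
    "sector": {"public": "public", "private": "private"},
    "setting": {
        "metropolitan": "metropolitan",
        "metro": "metropolitan",
        "regional": "regional",
        "rural": "regional",
        "regional/rural": "regional",
    },
    "side": {
        "left": "left",
        "l": "left",
        "right": "right",
        "r": "right",
        "unspecified": "unspecified",
        "": "unspecified",
    },
}

_AGE_GROUP_ALIASES = {
    "<40": "<40",
    "under 40": "<40",
    "40-69": "40-69",
    "40–69": "40-69",
    "70+": "70+",
    ">=70": "70+",
    "≥70": "70+",
}


def age_group_of(age_years: int) -> str:
    """Bin an age at procedure into the half-open bins [0,40), [40,70), [70,inf)."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    if age_years < 40:
        return "<40"
    if age_years < 70:
        return "40-69"
    return "70+"


@dataclass(frozen=True)
class ProcedureRecord:
    """One registry row, vocabulary already canonical."""

    patient_id: str
    sex: str
    year: int
    joint: str
    procedure_class: str
    diagnosis: str
    hospital_sector: str
    hospital_setting: str
    side: str = "unspecified"
    age_years: int | None = None
    age_group: str | None = None

    def __post_init__(self) -> None:
        if self.age_years is None and self.age_group is None:
            raise ValueError("either age_years or age_group is required")
        if self.age_years is not None and self.age_group is not None:
            if age_group_of(self.age_years) != self.age_group:
                raise ValueError(
                    f"age {self.age_years} inconsistent with age group "
                    f"{self.age_group!r}"
                )
        for fname, allowed in (
            ("sex", SEXES),
            ("joint", JOINTS),
            ("procedure_class", PROCEDURE_CLASSES),
            ("diagnosis", DIAGNOSES),
            ("hospital_sector", SECTORS),
            ("hospital_setting", SETTINGS),
            ("side", SIDES),
        ):
            value = getattr(self, fname)
            if value not in allowed:
                raise ValueError(f"{fname}={value!r} not in {allowed}")
        if self.age_group is not None and self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group={self.age_group!r} not in {AGE_GROUPS}")

    @property
    def resolved_age_group(self) -> str:
        """The explicit age group, or the bin of age_years."""
        if self.age_group is not None:
            return self.age_group
        return age_group_of(self.age_years)  # type: ignore[arg-type]


@dataclass(frozen=True)
class Admission:
    """A hospital admission: one unilateral procedure or one simultaneous
    bilateral pair collapsed from same-patient/year/joint/sector records."""

    patient_id: str
    year: int
    joint: str
    hospital_sector: str
    laterality: str  # "unilateral" | "bilateral_simultaneous"
    n_procedures: int
    age_group: str
    sex: str

    def __post_init__(self) -> None:
        if self.n_procedures < 1:
            raise ValueError("n_procedures must be >= 1")
        expected = "bilateral_simultaneous" if self.n_procedures >= 2 else "unilateral"
        if self.laterality != expected:
            raise ValueError(
                f"laterality {self.laterality!r} inconsistent with "
                f"n_procedures={self.n_procedures}"
            )


@dataclass(frozen=True)
class RowDiagnostic:
    """A rejected input row and why it was rejected."""

    row_number: int  # 1-based data row number (header excluded)
    reason: str
    raw: Mapping[str, str]


@dataclass
class LoadResult:
    """Parsed records plus row-level diagnostics for rejected rows."""

    records: list[ProcedureRecord]
    errors: list[RowDiagnostic] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)

    def write_error_report(self, path: str | Path) -> None:
        """Machine-readable CSV of rejected rows (row number, reason, raw row)."""
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["row_number", "reason", "raw_row"])
            for diag in self.errors:
                raw = ";".join(f"{k}={v}" for k, v in diag.raw.items())
                writer.writerow([diag.row_number, diag.reason, raw])


def _normalise(fieldname: str, value: str) -> str:
    key = value.strip().lower()
    vocab = _VOCAB[fieldname]
    if key not in vocab:
        raise ValueError(f"unrecognised {fieldname} value {value!r}")
    return vocab[key]


def _parse_row(
    row: Mapping[str, str], study_window: tuple[int, int] | None
) -> ProcedureRecord:
    patient_id = (row.get("patient_id") or "").strip()
    if not patient_id:
        raise ValueError("blank patient_id")

    year_raw = (row.get("year") or "").strip()
    try:
        year = int(year_raw)
    except ValueError:
        raise ValueError(f"unparseable year {year_raw!r}") from None
    if study_window is not None and not study_window[0] <= year <= study_window[1]:
        raise ValueError(
            f"year {year} outside study window {study_window[0]}-{study_window[1]}"
        )

    age_raw = (row.get("age") or "").strip()
    group_raw = (row.get("age_group") or "").strip()
    age_years: int | None = None
    age_group: str | None = None
    if age_raw:
        try:
            age_years = int(age_raw)
        except ValueError:
            raise ValueError(f"unparseable age {age_raw!r}") from None
        if age_years < 0:
            raise ValueError(f"negative age {age_years}")
    if group_raw:
        key = group_raw.lower()
        if key not in _AGE_GROUP_ALIASES:
            raise ValueError(f"unrecognised age_group value {group_raw!r}")
        age_group = _AGE_GROUP_ALIASES[key]
    if age_years is None and age_group is None:
        raise ValueError("missing both age and age_group")

    return ProcedureRecord(
        patient_id=patient_id,
        age_years=age_years,
        age_group=age_group,
        sex=_normalise("sex", row.get("sex") or ""),
        year=year,
        joint=_normalise("joint", row.get("joint") or ""),
        procedure_class=_normalise("procedure_class", row.get("procedure_class") or ""),
        diagnosis=_normalise("diagnosis", row.get("diagnosis") or ""),
        hospital_sector=_normalise("sector", row.get("sector") or ""),
        hospital_setting=_normalise("setting", row.get("setting") or ""),
        side=_normalise("side", row.get("side") or ""),
    )


def load_registry(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    study_window: tuple[int, int] | None = DEFAULT_STUDY_WINDOW,
) -> LoadResult:
    """Read a registry CSV, normalising vocabulary and collecting diagnostics.

    Parameters
    ----------
    path
        UTF-8, comma-delimited file with a header row, one procedure per row.
    dialect
        Optional mapping of canonical column names (``patient_id``, ``age``,
        ``sex``, ...) to the file's own headers, for non-canonical layouts.
    study_window
        Inclusive (first, last) admissible procedure years; ``None`` disables
        the window check.

    A missing required column is fatal (:class:`ValueError`).  Rows that fail
    to parse are skipped and reported in :attr:`LoadResult.errors`.
    """
    mapping = {name: name for name in CANONICAL_COLUMNS}
    if dialect:
        mapping.update(dialect)

    records: list[ProcedureRecord] = []
    errors: list[RowDiagnostic] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [
            canon for canon in _REQUIRED_COLUMNS if mapping[canon] not in header
        ]
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) "
                + ", ".join(mapping[c] for c in missing)
            )
        has_age = mapping["age"] in header
        has_group = mapping["age_group"] in header
        if not has_age and not has_group:
            raise ValueError(f"{path}: need an age or age_group column")
        for row_number, raw in enumerate(reader, start=1):
            canon_row = {
                name: raw.get(mapping[name], "") or "" for name in CANONICAL_COLUMNS
            }
            try:
                records.append(_parse_row(canon_row, study_window))
            except ValueError as exc:
                errors.append(RowDiagnostic(row_number, str(exc), dict(raw)))
    return LoadResult(records=records, errors=errors)


def write_registry(records: Iterable[ProcedureRecord], path: str | Path) -> None:
    """Write records in the canonical CSV dialect (round-trips with load_registry)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CANONICAL_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    "" if rec.age_years is None else rec.age_years,
                    rec.age_group or "",
                    rec.sex,
                    rec.year,
                    rec.joint,
                    rec.procedure_class,
                    rec.diagnosis,
                    rec.hospital_sector,
                    rec.hospital_setting,
                    rec.side,
                ]
            )


def filter_primary_oa(records: Iterable[ProcedureRecord]) -> list[ProcedureRecord]:
    """Keep primary procedures with an osteoarthritis diagnosis, order preserved."""
    return [
        rec
        for rec in records
        if rec.procedure_class == "primary" and rec.diagnosis == "osteoarthritis"
    ]


def collapse_bilateral(records: Iterable[ProcedureRecord]) -> list[Admission]:
    """Collapse same-patient/year/joint/sector record groups into admissions.

    Groups of two or more become one ``bilateral_simultaneous`` admission
    carrying the group's procedure count, so total procedures are conserved.
    Groups larger than two are collapsed the same way with a warning, since
    the rule is stated for pairs.  Output is sorted by the grouping key.
    """
    groups: dict[tuple[str, int, str, str], list[ProcedureRecord]] = {}
    for rec in records:
        key = (rec.patient_id, rec.year, rec.joint, rec.hospital_sector)
        groups.setdefault(key, []).append(rec)

    admissions: list[Admission] = []
    for key in sorted(groups):
        group = groups[key]
        n = len(group)
        if n > 2:
            warnings.warn(
                f"{n} same-joint procedures for patient {key[0]!r} in {key[1]} "
                f"({key[3]} sector); collapsing to one bilateral admission",
                stacklevel=2,
            )
        first = group[0]
        admissions.append(
            Admission(
                patient_id=first.patient_id,
                year=first.year,
                joint=first.joint,
                hospital_sector=first.hospital_sector,
                laterality="bilateral_simultaneous" if n >= 2 else "unilateral",
                n_procedures=n,
                age_group=first.resolved_age_group,
                sex=first.sex,
            )
        )
    return admissions


@dataclass
class StratumCountTable:
    """Procedure counts per (joint, age group, sex, year), zero-filled.

    Backed by a tidy DataFrame with columns ``joint, age_group, sex, year,
    count`` covering the full cross product of its strata and years.
    """

    df: pd.DataFrame

    COLUMNS = ("joint", "age_group", "sex", "year", "count")

    def __post_init__(self) -> None:
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if (self.df["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Sequence[ProcedureRecord],
        *,
        joints: Sequence[str] = JOINTS,
        age_groups: Sequence[str] = AGE_GROUPS,
        sexes: Sequence[str] = SEXES,
        years: Sequence[int] | None = None,
    ) -> "StratumCountTable":
        """Tabulate records over exhaustive, mutually exclusive strata.

        Records carrying a stratum value outside the given spec raise a
        ValueError listing the offending values.  Cells with no records are
        zero-filled.  ``years`` defaults to the span of the records' years.
        """
        bad: set[str] = set()
        keyed: dict[tuple[str, str, str, int], int] = {}
        rec_years: set[int] = set()
        for rec in records:
            group = rec.resolved_age_group
            if rec.joint not in joints:
                bad.add(f"joint={rec.joint}")
            if group not in age_groups:
                bad.add(f"age_group={group}")
            if rec.sex not in sexes:
                bad.add(f"sex={rec.sex}")
            if years is not None and rec.year not in years:
                bad.add(f"year={rec.year}")
            rec_years.add(rec.year)
            key = (rec.joint, group, rec.sex, rec.year)
            keyed[key] = keyed.get(key, 0) + 1
        if bad:
            raise ValueError(
                "records outside the stratum spec: " + ", ".join(sorted(bad))
            )
        if years is None:
            years = (
                list(range(min(rec_years), max(rec_years) + 1)) if rec_years else []
            )
        grid = [
            (j, g, s, y, keyed.get((j, g, s, y), 0))
            for j in joints
            for g in age_groups
            for s in sexes
            for y in years
        ]
        return cls(pd.DataFrame(grid, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StratumCountTable":
        df = pd.read_csv(path)
        return cls(df)

    # -- accessors ---------------------------------------------------------
    def total(self) -> int:
        return int(self.df["count"].sum())

    def get(self, joint: str, age_group: str, sex: str, year: int) -> int:
        mask = (
            (self.df["joint"] == joint)
            & (self.df["age_group"] == age_group)
            & (self.df["sex"] == sex)
            & (self.df["year"] == year)
        )
        sub = self.df.loc[mask, "count"]
        if sub.empty:
            raise KeyError((joint, age_group, sex, year))
        return int(sub.iloc[0])

    def for_joint(self, joint: str) -> "StratumCountTable":
        return StratumCountTable(self.df[self.df["joint"] == joint].copy())

    def year_totals(self, joint: str | None = None) -> pd.Series:
        df = self.df if joint is None else self.df[self.df["joint"] == joint]
        return df.groupby("year")["count"].sum()

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique().tolist())

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def tabulate_counts(
    records: Sequence[ProcedureRecord],
    *,
    joints: Sequence[str] = JOINTS,
    age_groups: Sequence[str] = AGE_GROUPS,
    sexes: Sequence[str] = SEXES,
    years: Sequence[int] | None = None,
) -> StratumCountTable:
    """Stratified procedure counts; see :meth:`StratumCountTable.from_records`."""
    return StratumCountTable.from_records(
        records, joints=joints, age_groups=age_groups, sexes=sexes, years=years
    )
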