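"""Case-listing data model: patient records, factor-level cohorts, and I/O.

The unit of analysis downstream is the *combination*: the cohort of all
patients sharing one level of each active prognostic factor (e.g. every
patient with T1b, N1, M0, age < 70, squamous histology forms the cohort
"T1bN1M0A0H1").  This module reads flat case listings, recodes 7th-edition
primary-tumor (T) categories to the 8th edition using collaborative-stage
tumor size, partitions cases into combinations, and applies the
minimum-cohort-size filter that guards the stability of the survival
estimates computed later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Factor-level enumerations (8th-edition T after recoding).
T_LEVELS = ("T1a", "T1b", "T1c", "T2a", "T2b", "T3", "T4")
T7_LEVELS = ("T1a", "T1b", "T2a", "T2b", "T3", "T4")
N_LEVELS = ("N0", "N1", "N2", "N3")
M_LEVELS = ("M0", "M1")
A_LEVELS = ("A0", "A1")  # A0: age < 70 y, A1: age >= 70 y
H_LEVELS = ("H1", "H2", "H3", "H4")  # squamous, small cell, adeno, large cell

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "T": T_LEVELS,
    "N": N_LEVELS,
    "M": M_LEVELS,
    "A": A_LEVELS,
    "H": H_LEVELS,
}
FACTORS = ("T", "N", "M", "A", "H")

AGE_CUTOFF_YEARS = 70

_RECODED8_COLUMNS = ["case_id", "T", "N", "M", "A", "H", "survival_months", "event"]
_RAW7_COLUMNS = ["case_id", "T7", "N", "M", "H", "survival_months", "event",
                 "cs_tumor_size_mm", "age_years"]


class CaseListingError(ValueError):
    """Malformed case listing: missing column or unparseable level code."""


class RecodeError(ValueError):
    """T recoding rule needs a tumor size that is missing."""


@dataclass(frozen=True)
class CaseRecord:
    """One patient: factor levels, follow-up in whole months, event flag.

    ``event`` is 1 for death from the studied cancer, 0 for censoring
    (alive at last contact or death from another cause).
    """

    case_id: str
    t: str
    n: str
    m: str
    age_group: str
    histology: str
    survival_months: int
    event: int

    def __post_init__(self) -> None:
        if self.t not in T_LEVELS:
            raise ValueError(f"invalid T level {self.t!r}")
        if self.n not in N_LEVELS:
            raise ValueError(f"invalid N level {self.n!r}")
        if self.m not in M_LEVELS:
            raise ValueError(f"invalid M level {self.m!r}")
        if self.age_group not in A_LEVELS:
            raise ValueError(f"invalid A level {self.age_group!r}")
        if self.histology not in H_LEVELS:
            raise ValueError(f"invalid H level {self.histology!r}")
        if self.survival_months < 0:
            raise ValueError("survival_months must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")

    def level(self, factor: str) -> str:
        return {"T": self.t, "N": self.n, "M": self.m,
                "A": self.age_group, "H": self.histology}[factor]


@dataclass(frozen=True)
class RawCaseRecord:
    """A patient as extracted with 7th-edition T, tumor size and age in years."""

    case_id: str
    t7: str
    n: str
    m: str
    histology: str
    survival_months: int
    event: int
    cs_tumor_size_mm: float | None = None
    age_years: int | None = None


@dataclass
class CombinationCohort:
    """All patients sharing one level of each active factor.

    The clustering operates on these cohorts, not on individual patients.
    ``times``/``events`` carry the members' survival data as arrays so that
    downstream survival estimation does not re-scan the case table.
    """

    label: str
    levels: Mapping[str, str]
    member_ids: list[str]
    times: np.ndarray = field(repr=False)
    events: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def recode_t_7to8(t7: str, size_mm: float | None) -> str:
    """Map a 7th-edition T category to the 8th edition.

    The reclassification splits/merges categories on collaborative-stage
    tumor size (mm).  Size intervals are half-open ``(lo, hi]``, anchored by
    the closed upper bounds of the <=10 mm and <=70 mm rules:

    * 7th T1a: <=10 mm -> T1a; (10, 20] -> T1b
    * 7th T1b -> T1c (size not consulted)
    * 7th T2a: (30, 40] -> T2a; (40, 50] -> T2b
    * 7th T2b -> T3 (size not consulted)
    * 7th T3: <=70 mm -> T3; >70 mm -> T4
    * 7th T4 -> T4 (size not consulted)

    A 7th-edition T2a with size outside (30, 50] can occur under registry
    size-coding conventions; it is mapped to the nearest covered bin
    (<=30 -> T2a, >50 -> T2b) and logged as anomalous.
    """
    if t7 not in T7_LEVELS:
        raise ValueError(f"invalid 7th-edition T level {t7!r}")
    if t7 == "T1b":
        return "T1c"
    if t7 == "T2b":
        return "T3"
    if t7 == "T4":
        return "T4"
    if size_mm is None or (isinstance(size_mm, float) and np.isnan(size_mm)):
        raise RecodeError(f"tumor size required to recode 7th-edition {t7}")
    if t7 == "T1a":
        if size_mm <= 10:
            return "T1a"
        if size_mm <= 20:
            return "T1b"
        logger.warning("anomalous 7th T1a with size %.1f mm > 20; mapped to T1b", size_mm)
        return "T1b"
    if t7 == "T2a":
        if size_mm <= 30:
            logger.warning("anomalous 7th T2a with size %.1f mm <= 30; mapped to T2a", size_mm)
            return "T2a"
        if size_mm <= 40:
            return "T2a"
        if size_mm <= 50:
            return "T2b"
        logger.warning("anomalous 7th T2a with size %.1f mm > 50; mapped to T2b", size_mm)
        return "T2b"
    # t7 == "T3"
    return "T3" if size_mm <= 70 else "T4"


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CaseListingError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )


def _check_levels(df: pd.DataFrame, col: str, allowed: tuple[str, ...]) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CaseListingError(
            f"unparseable {col} level {df[col].iloc[row]!r} at data row {row + 1}"
        )


def read_cases(path, dialect: str = "recoded8") -> tuple[list, int]:
    """Read a case-listing CSV; returns ``(records, n_dropped)``.

    Rows with any missing required field are dropped (complete-case
    selection) and counted in ``n_dropped``.  ``dialect='recoded8'`` expects
    8th-edition T directly; ``dialect='raw7'`` expects 7th-edition T plus
    tumor size and age in years, and performs the T recode and the
    age-at-70 dichotomization here.
    """
    if dialect not in ("recoded8", "raw7"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype={"case_id": str})
    required = _RECODED8_COLUMNS if dialect == "recoded8" else _RAW7_COLUMNS
    # size may be legitimately missing for size-independent T rules
    hard_required = [c for c in required if c != "cs_tumor_size_mm"]
    _require_columns(df, hard_required, str(path))

    n0 = len(df)
    df = df.dropna(subset=hard_required)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("dropped %d incomplete row(s) of %d", n_dropped, n0)

    _check_levels(df, "N", N_LEVELS)
    _check_levels(df, "M", M_LEVELS)
    _check_levels(df, "H", H_LEVELS)

    records: list = []
    if dialect == "recoded8":
        _check_levels(df, "T", T_LEVELS)
        _check_levels(df, "A", A_LEVELS)
        for row in df.itertuples(index=False):
            records.append(CaseRecord(
                case_id=str(row.case_id), t=row.T, n=row.N, m=row.M,
                age_group=row.A, histology=row.H,
                survival_months=int(row.survival_months), event=int(row.event),
            ))
    else:
        _check_levels(df, "T7", T7_LEVELS)
        size_col = df["cs_tumor_size_mm"] if "cs_tumor_size_mm" in df.columns \
            else pd.Series(np.nan, index=df.index)
        for (row, size) in zip(df.itertuples(index=False), size_col):
            t8 = recode_t_7to8(row.T7, None if pd.isna(size) else float(size))
            age_group = "A0" if int(row.age_years) < AGE_CUTOFF_YEARS else "A1"
            records.append(CaseRecord(
                case_id=str(row.case_id), t=t8, n=row.N, m=row.M,
                age_group=age_group, histology=row.H,
                survival_months=int(row.survival_months), event=int(row.event),
            ))
    return records, n_dropped


def write_cases(records: Iterable[CaseRecord], path) -> None:
    """Write records in the ``recoded8`` CSV dialect."""
    cases_to_frame(list(records)).to_csv(path, index=False)


def cases_to_frame(cases) -> pd.DataFrame:
    """Normalize a list of :class:`CaseRecord` (or a DataFrame) to a DataFrame."""
    if isinstance(cases, pd.DataFrame):
        missing = [c for c in _RECODED8_COLUMNS if c not in cases.columns]
        if missing:
            raise CaseListingError(f"case frame missing column(s) {', '.join(missing)}")
        return cases
    return pd.DataFrame({
        "case_id": [c.case_id for c in cases],
        "T": [c.t for c in cases],
        "N": [c.n for c in cases],
        "M": [c.m for c in cases],
        "A": [c.age_group for c in cases],
        "H": [c.histology for c in cases],
        "survival_months": [c.survival_months for c in cases],
        "event": [c.event for c in cases],
    })


def combination_label(levels: Mapping[str, str], active_factors: Sequence[str]) -> str:
    return "".join(levels[f] for f in active_factors)


def group_into_combinations(cases, active_factors: Sequence[str]) -> list[CombinationCohort]:
    """Partition cases into cohorts, one per observed combination of levels.

    Cohorts come back sorted lexicographically by the level *order* of each
    active factor (T1a < T1b < ... within T, etc.), which fixes a
    deterministic cohort ordering for everything downstream.
    """
    active_factors = list(active_factors)
    if not active_factors:
        raise ValueError("active_factors must be non-empty")
    unknown = [f for f in active_factors if f not in FACTORS]
    if unknown:
        raise ValueError(f"unknown factor(s) {unknown}")
    df = cases_to_frame(cases)
    if df.empty:
        return []
    cohorts: list[CombinationCohort] = []
    for key, sub in df.groupby(active_factors, sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        levels = dict(zip(active_factors, key))
        cohorts.append(CombinationCohort(
            label=combination_label(levels, active_factors),
            levels=levels,
            member_ids=[str(x) for x in sub["case_id"]],
            times=sub["survival_months"].to_numpy(dtype=float),
            events=sub["event"].to_numpy(dtype=int),
        ))
    order = {f: {lvl: i for i, lvl in enumerate(FACTOR_LEVELS[f])} for f in active_factors}
    cohorts.sort(key=lambda c: tuple(order[f][c.levels[f]] for f in active_factors))
    return cohorts


def filter_min_cases(cohorts: Sequence[CombinationCohort], min_n: int = 50) -> list[CombinationCohort]:
    """Keep cohorts with at least ``min_n`` members (order preserved).

    Small cohorts yield unstable Kaplan-Meier and Mann-Whitney estimates;
    the default 50 trades coverage of rare combinations for robustness.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    kept = [c for c in cohorts if c.size >= min_n]
    n_excl = len(cohorts) - len(kept)
    logger.info(
        "min-cases filter (n >= %d): retained %d cohort(s) / %d case(s); "
        "excluded %d cohort(s) / %d case(s)",
        min_n, len(kept), sum(c.size for c in kept),
        n_excl, sum(c.size for c in cohorts) - sum(c.size for c in kept),
    )
    return kept


def cohort_table(cohorts: Sequence[CombinationCohort]) -> pd.DataFrame:
    """Cohort summary table: label, size, one column per active factor."""
    if not cohorts:
        return pd.DataFrame(columns=["label", "size"])
    factors = list(cohorts[0].levels)
    rows = [{"label": c.label, "size": c.size, **dict(c.levels)} for c in cohorts]
    return pd.DataFrame(rows, columns=["label", "size", *factors])
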