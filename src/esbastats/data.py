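"""Domain types and data plumbing for repeated Frankl-scale ratings.

The Frankl behavior rating scale has four ordered categories used in
pediatric dentistry:

====  ======  =====================
code  symbol  meaning
====  ======  =====================
1     ``--``  definitely negative
2     ``-``   negative
3     ``+``   positive
4     ``++``  definitely positive
====  ======  =====================

A study cohort consists of children rated at a first visit (baseline) and
again at the end of each of three program phases.  Children rated negative
or definitely negative at baseline form the *uncooperative* cohort
(``Init.Rating = 0``); children rated positive form the *cooperative*
cohort (``Init.Rating = 1``).  No child is rated definitely positive at a
first visit, by construction of the cohorts.

This module provides:

* conversion between Frankl symbols and integer levels,
* the :class:`ChildRecord` / long-format ("one row per child-phase")
  representations and CSV I/O,
* :class:`PhaseCountTable` marginal count tables and the built-in count
  fixture reconstructing the published cohort distributions
  (45 uncooperative + 40 cooperative children, 255 phase-level rows),
* simple descriptive summaries (mean 1-4 score).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FRANKL_LEVELS",
    "FRANKL_SYMBOLS",
    "frankl_to_level",
    "level_to_symbol",
    "encode_init_rating",
    "ChildRecord",
    "records_to_frame",
    "frame_to_records",
    "to_long",
    "PhaseCountTable",
    "table4_fixture",
    "counts_to_long",
    "mean_score",
    "read_children_csv",
    "write_long_csv",
    "UNCOOPERATIVE",
    "COOPERATIVE",
]

FRANKL_LEVELS = (1, 2, 3, 4)
FRANKL_SYMBOLS = {"--": 1, "-": 2, "+": 3, "++": 4}
_LEVEL_TO_SYMBOL = {v: k for k, v in FRANKL_SYMBOLS.items()}

UNCOOPERATIVE = "uncooperative"
COOPERATIVE = "cooperative"

#: column order of the child-level CSV dialect
CHILD_COLUMNS = [
    "child_id",
    "age",
    "gender",
    "nationality",
    "natural_birth",
    "vaccination",
    "medication",
    "previous_anesthesia",
    "plaque_index",
    "gingival_status",
    "dmft",
    "frankl_t0",
    "frankl_p1",
    "frankl_p2",
    "frankl_p3",
]

#: covariate columns carried along into long format
COVARIATE_COLUMNS = [
    "age",
    "gender",
    "nationality",
    "natural_birth",
    "vaccination",
    "medication",
    "previous_anesthesia",
    "plaque_index",
    "gingival_status",
    "dmft",
]


def frankl_to_level(value) -> int:
    """Coerce a Frankl rating given as 1-4 or as ``--/-/+/++`` to its level."""
    if isinstance(value, str):
        value = value.strip()
        if value in FRANKL_SYMBOLS:
            return FRANKL_SYMBOLS[value]
        try:
            value = int(value)
        except ValueError as exc:
            raise ValueError(f"unrecognized Frankl rating {value!r}") from exc
    level = int(value)
    if level not in FRANKL_LEVELS:
        raise ValueError(f"Frankl level must be in 1..4, got {level}")
    return level


def level_to_symbol(level: int) -> str:
    """Inverse of :func:`frankl_to_level` for the symbolic codes."""
    return _LEVEL_TO_SYMBOL[int(level)]


def encode_init_rating(rating_first_visit) -> int:
    """Binary baseline-cohort indicator from the first-visit Frankl rating.

    0 for initially uncooperative children (first visit negative or
    definitely negative), 1 for initially cooperative children (first visit
    positive).  A first-visit rating of definitely positive contradicts the
    cohort definition and raises ``ValueError``.
    """
    level = frankl_to_level(rating_first_visit)
    if level == 4:
        raise ValueError(
            "first-visit rating 'definitely positive' (level 4) is outside "
            "the study population; Init.Rating is undefined"
        )
    return 0 if level in (1, 2) else 1


@dataclass
class ChildRecord:
    """One child: baseline covariates plus Frankl ratings at the first
    visit and at the end of phases I-III.

    Binary covariates are lower-case strings (``"male"/"female"``,
    ``"yes"/"no"``, ``"italian"/"other"``) or ``None`` when missing.
    """

    child_id: str
    rating_first_visit: int
    rating_phase1: int
    rating_phase2: int
    rating_phase3: int
    age: Optional[float] = None
    gender: Optional[str] = None
    nationality: Optional[str] = None
    natural_birth: Optional[str] = None
    vaccination: Optional[str] = None
    medication: Optional[str] = None
    previous_anesthesia: Optional[str] = None
    plaque_index: Optional[int] = None
    gingival_status: Optional[int] = None
    dmft: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("rating_first_visit", "rating_phase1", "rating_phase2",
                     "rating_phase3"):
            setattr(self, name, frankl_to_level(getattr(self, name)))
        if self.rating_first_visit == 4:
            raise ValueError(
                f"child {self.child_id!r}: first-visit rating may not be "
                "'definitely positive'"
            )
        if self.age is not None and not (7 <= self.age <= 12):
            raise ValueError(f"child {self.child_id!r}: age must be in 7..12")
        if self.dmft is not None and self.dmft < 0:
            raise ValueError(f"child {self.child_id!r}: dmft must be >= 0")

    @property
    def init_rating(self) -> int:
        return encode_init_rating(self.rating_first_visit)


def records_to_frame(records: Iterable[ChildRecord]) -> pd.DataFrame:
    """Child-level DataFrame (one row per child) in the CSV column order."""
    rows = []
    for r in records:
        rows.append({
            "child_id": r.child_id,
            "age": r.age,
            "gender": r.gender,
            "nationality": r.nationality,
            "natural_birth": r.natural_birth,
            "vaccination": r.vaccination,
            "medication": r.medication,
            "previous_anesthesia": r.previous_anesthesia,
            "plaque_index": r.plaque_index,
            "gingival_status": r.gingival_status,
            "dmft": r.dmft,
            "frankl_t0": r.rating_first_visit,
            "frankl_p1": r.rating_phase1,
            "frankl_p2": r.rating_phase2,
            "frankl_p3": r.rating_phase3,
        })
    return pd.DataFrame(rows, columns=CHILD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[ChildRecord]:
    records = []
    for _, row in df.iterrows():
        def get(col):
            v = row.get(col)
            return None if pd.isna(v) else v
        records.append(ChildRecord(
            child_id=str(row["child_id"]),
            rating_first_visit=row["frankl_t0"],
            rating_phase1=row["frankl_p1"],
            rating_phase2=row["frankl_p2"],
            rating_phase3=row["frankl_p3"],
            age=get("age"),
            gender=get("gender"),
            nationality=get("nationality"),
            natural_birth=get("natural_birth"),
            vaccination=get("vaccination"),
            medication=get("medication"),
            previous_anesthesia=get("previous_anesthesia"),
            plaque_index=None if get("plaque_index") is None else int(row["plaque_index"]),
            gingival_status=None if get("gingival_status") is None else int(row["gingival_status"]),
            dmft=get("dmft"),
        ))
    return records


def to_long(records) -> pd.DataFrame:
    """Expand child records to the modelling long format.

    Each child contributes exactly three rows (phases 1-3) with columns
    ``child_id, phase, init_rating, rating`` plus the baseline covariates.
    Baseline (first-visit) ratings enter only through ``init_rating``.
    """
    if isinstance(records, pd.DataFrame):
        records = frame_to_records(records)
    rows = []
    for r in records:
        for phase, rating in ((1, r.rating_phase1), (2, r.rating_phase2),
                              (3, r.rating_phase3)):
            if rating is None:
                raise ValueError(
                    f"child {r.child_id!r} is missing the phase {phase} rating"
                )
            rows.append({
                "child_id": r.child_id,
                "phase": phase,
                "init_rating": r.init_rating,
                "rating": rating,
                "age": r.age,
                "gender": r.gender,
                "nationality": r.nationality,
                "natural_birth": r.natural_birth,
                "vaccination": r.vaccination,
                "medication": r.medication,
                "previous_anesthesia": r.previous_anesthesia,
                "plaque_index": r.plaque_index,
                "gingival_status": r.gingival_status,
                "dmft": r.dmft,
            })
    columns = ["child_id", "phase", "init_rating", "rating"] + COVARIATE_COLUMNS
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class PhaseCountTable:
    """Marginal Frankl category counts for one cohort.

    ``counts[phase]`` is a 4-tuple of counts over the Frankl levels 1-4;
    phase 0 denotes the first visit.  Every phase row must sum to the
    cohort size.
    """

    cohort: str
    counts: Mapping[int, tuple[int, int, int, int]]
    n: int

    def __post_init__(self) -> None:
        if self.cohort not in (UNCOOPERATIVE, COOPERATIVE):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        for phase, row in self.counts.items():
            if phase not in (0, 1, 2, 3):
                raise ValueError(f"phase must be in 0..3, got {phase}")
            if len(row) != 4:
                raise ValueError("each count row must have 4 categories")
            if any((c < 0 or int(c) != c) for c in row):
                raise ValueError(f"counts must be non-negative integers: {row}")
            if sum(row) != self.n:
                raise ValueError(
                    f"{self.cohort} phase {phase}: counts {row} sum to "
                    f"{sum(row)}, expected cohort size {self.n}"
                )

    @property
    def init_rating(self) -> int:
        return 0 if self.cohort == UNCOOPERATIVE else 1

    def phases(self) -> list[int]:
        return sorted(self.counts)


def _counts_from_percent(percents: Sequence[float], n: int) -> tuple[int, ...]:
    counts = tuple(int(round(p * n / 100.0)) for p in percents)
    if sum(counts) != n:
        raise AssertionError(
            f"percent row {percents} does not reconstruct to integer counts "
            f"summing to {n} (got {counts})"
        )
    return counts


def table4_fixture() -> tuple[PhaseCountTable, PhaseCountTable]:
    """Published per-phase Frankl category distributions as integer counts.

    Counts are reconstructed from the printed cohort percentages by
    nearest-integer rounding of ``percent x n / 100``; every row is checked
    to sum exactly to its cohort size (45 uncooperative, 40 cooperative).
    Returns ``(uncooperative, cooperative)``.
    """
    uncoop = PhaseCountTable(
        cohort=UNCOOPERATIVE,
        n=45,
        counts={
            0: _counts_from_percent((13.3, 86.7, 0.0, 0.0), 45),
            1: _counts_from_percent((11.1, 53.3, 35.6, 0.0), 45),
            2: _counts_from_percent((2.2, 37.8, 57.8, 2.2), 45),
            3: _counts_from_percent((0.0, 15.6, 80.0, 4.4), 45),
        },
    )
    coop = PhaseCountTable(
        cohort=COOPERATIVE,
        n=40,
        counts={
            0: _counts_from_percent((0.0, 0.0, 100.0, 0.0), 40),
            1: _counts_from_percent((0.0, 0.0, 97.5, 2.5), 40),
            2: _counts_from_percent((0.0, 10.0, 87.5, 2.5), 40),
            3: _counts_from_percent((0.0, 2.5, 90.0, 7.5), 40),
        },
    )
    return uncoop, coop


def counts_to_long(tables, include_baseline: bool = False) -> pd.DataFrame:
    """Expand marginal count tables into pseudo-child long-format rows.

    Each count unit becomes one row ``(child_id, phase, init_rating,
    rating)``.  Pseudo-children carry no baseline covariates; because the
    joint distribution across phases is not identified by marginal counts,
    each row receives its own synthetic ``child_id``.  Baseline (phase 0)
    rows are excluded unless ``include_baseline`` is set, in which case
    they appear with ``phase = 0``.
    """
    if isinstance(tables, PhaseCountTable):
        tables = [tables]
    rows = []
    serial = 0
    for table in tables:
        for phase in table.phases():
            if phase == 0 and not include_baseline:
                continue
            for level, count in zip(FRANKL_LEVELS, table.counts[phase]):
                for _ in range(int(count)):
                    serial += 1
                    rows.append({
                        "child_id": f"{table.cohort[:2]}{serial:04d}",
                        "phase": phase,
                        "init_rating": table.init_rating,
                        "rating": level,
                    })
    return pd.DataFrame(rows, columns=["child_id", "phase", "init_rating", "rating"])


def regroup_long(long_df: pd.DataFrame) -> dict[tuple[int, int], tuple[int, ...]]:
    """Category counts per (init_rating, phase) from long-format rows.

    Inverse of :func:`counts_to_long` up to pseudo-child labels; used for
    round-trip validation.
    """
    out: dict[tuple[int, int], list[int]] = {}
    for (init, phase), grp in long_df.groupby(["init_rating", "phase"]):
        counts = [int((grp["rating"] == lev).sum()) for lev in FRANKL_LEVELS]
        out[(int(init), int(phase))] = tuple(counts)
    return out


def mean_score(counts: Sequence[float]) -> float:
    """Mean 1-4 Frankl score of a category count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("mean_score requires a positive total count")
    return float(np.dot(FRANKL_LEVELS, counts) / total)


def read_children_csv(path) -> pd.DataFrame:
    """Read a child-level CSV, coercing Frankl columns to integer levels.

    Frankl ratings are accepted as 1-4 or as the symbols ``--``, ``-``,
    ``+``, ``++``.
    """
    df = pd.read_csv(path, dtype={"child_id": str})
    missing = [c for c in ("child_id", "frankl_t0", "frankl_p1", "frankl_p2",
                           "frankl_p3") if c not in df.columns]
    if missing:
        raise ValueError(f"child CSV is missing required columns: {missing}")
    for col in ("frankl_t0", "frankl_p1", "frankl_p2", "frankl_p3"):
        df[col] = df[col].map(frankl_to_level)
    return df


def write_long_csv(long_df: pd.DataFrame, path) -> None:
    long_df.to_csv(path, index=False)
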