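"""Data model for the inpatient EHR substrate and the ADR reference dataset.

The pipeline operates on four delimited tables in an OMOP-CDM-like layout
(person, visit, drug_exposure, measurement) plus a reference-pairs file that
labels drug--laboratory-event pairs as known ADRs (1) or unknown (0).

Tables are held as pandas DataFrames inside a :class:`Cohort`; all dates are
at day resolution (ISO-8601 in the CSV files).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "DrugLabEvent",
    "ReferencePair",
    "Cohort",
    "read_ehr",
    "write_ehr",
    "read_reference_pairs",
    "write_reference_pairs",
    "build_pair_universe",
    "build_reference_dataset",
    "split_train_test",
]

#: Valid event directions. "increased" means abnormal = value > normal_high,
#: "decreased" means abnormal = value < normal_low.
DIRECTIONS = ("increased", "decreased")

PERSON_COLUMNS = ["person_id", "sex", "birth_year"]
VISIT_COLUMNS = ["person_id", "visit_id", "admit_date", "discharge_date"]
DRUG_COLUMNS = ["person_id", "visit_id", "drug_code", "date"]
MEASUREMENT_COLUMNS = [
    "person_id",
    "visit_id",
    "lab_code",
    "date",
    "value",
    "normal_low",
    "normal_high",
]
REFERENCE_COLUMNS = ["drug_code", "lab_code", "direction", "label"]


@dataclass(frozen=True, order=True)
class DrugLabEvent:
    """A (drug, laboratory test, direction) pair -- the unit of signal detection."""

    drug_code: str
    lab_code: str
    direction: str  # "increased" | "decreased"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )

    def is_abnormal(self, value, normal_low, normal_high):
        """Abnormality indicator in this event's direction (vectorized)."""
        if self.direction == "increased":
            return np.asarray(value) > np.asarray(normal_high)
        return np.asarray(value) < np.asarray(normal_low)


@dataclass(frozen=True)
class ReferencePair:
    pair: DrugLabEvent
    label: int  # 1 = known/positive, 0 = unknown/nonpositive

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class Cohort:
    """In-memory EHR cohort: the four validated tables."""

    person: pd.DataFrame
    visit: pd.DataFrame
    drug_exposure: pd.DataFrame
    measurement: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def drug_codes(self) -> list[str]:
        return sorted(self.drug_exposure["drug_code"].unique())

    @property
    def lab_codes(self) -> list[str]:
        return sorted(self.measurement["lab_code"].unique())

    def first_exposures(self) -> pd.DataFrame:
        """First prescribed day per (visit_id, drug_code), cached."""
        if "first_exposures" not in self._cache:
            fe = (
                self.drug_exposure.groupby(["visit_id", "drug_code"], as_index=False)[
                    "date"
                ]
                .min()
                .rename(columns={"date": "first_date"})
            )
            self._cache["first_exposures"] = fe
        return self._cache["first_exposures"]


class SchemaError(ValueError):
    """A table is missing a required column or contains an unparseable value."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"table {name!r} is missing required column(s): {missing}")


def _parse_dates(df: pd.DataFrame, cols: Iterable[str], name: str) -> pd.DataFrame:
    for col in cols:
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"table {name!r}, column {col!r}: unparseable date "
                f"{df[col].iloc[row]!r} at row {row}"
            )
        df[col] = parsed.dt.normalize()
    return df


def _read_table(path: Path, name: str, columns: Sequence[str]) -> pd.DataFrame:
    fp = path / f"{name}.csv"
    if not fp.exists():
        raise FileNotFoundError(f"expected table file {fp}")
    df = pd.read_csv(fp, dtype=str)
    if df.empty and list(df.columns) != columns and len(df.columns) <= 1:
        # a headerless empty file: treat as an empty table with the schema
        df = pd.DataFrame(columns=columns)
    _check_columns(df, columns, name)
    return df[list(columns)].copy()


def read_ehr(tables_dir: str | Path) -> Cohort:
    """Read and validate the four cohort tables from ``tables_dir``.

    Raises :class:`SchemaError` naming the offending column/row on any
    violation of the documented schema (missing column, unparseable date,
    inverted normal range, visit or value inconsistencies).
    """
    tables_dir = Path(tables_dir)

    person = _read_table(tables_dir, "person", PERSON_COLUMNS)
    person["birth_year"] = person["birth_year"].astype(int)

    visit = _read_table(tables_dir, "visit", VISIT_COLUMNS)
    visit = _parse_dates(visit, ["admit_date", "discharge_date"], "visit")
    bad = visit["admit_date"] > visit["discharge_date"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"table 'visit': admit_date > discharge_date at row {row}")

    drug = _read_table(tables_dir, "drug_exposure", DRUG_COLUMNS)
    drug = _parse_dates(drug, ["date"], "drug_exposure")

    meas = _read_table(tables_dir, "measurement", MEASUREMENT_COLUMNS)
    meas = _parse_dates(meas, ["date"], "measurement")
    for col in ("value", "normal_low", "normal_high"):
        meas[col] = pd.to_numeric(meas[col], errors="coerce")
    if len(meas):
        bad = ~np.isfinite(meas["value"].to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(f"table 'measurement': non-finite value at row {row}")
        bad = meas["normal_low"].to_numpy() >= meas["normal_high"].to_numpy()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"table 'measurement': normal_low >= normal_high at row {row}"
            )

    cohort = Cohort(person=person, visit=visit, drug_exposure=drug, measurement=meas)
    logger.info(
        "read cohort: %d persons, %d visits, %d drug-exposure days, %d lab results",
        len(person),
        len(visit),
        len(drug),
        len(meas),
    )
    return cohort


def write_ehr(cohort: Cohort, tables_dir: str | Path) -> None:
    """Write the four tables as CSV (ISO dates, UTF-8, header row)."""
    tables_dir = Path(tables_dir)
    tables_dir.mkdir(parents=True, exist_ok=True)
    cohort.person.to_csv(tables_dir / "person.csv", index=False)
    for name, df, date_cols in (
        ("visit", cohort.visit, ["admit_date", "discharge_date"]),
        ("drug_exposure", cohort.drug_exposure, ["date"]),
        ("measurement", cohort.measurement, ["date"]),
    ):
        out = df.copy()
        for col in date_cols:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(tables_dir / f"{name}.csv", index=False)


def read_reference_pairs(path: str | Path) -> list[ReferencePair]:
    df = pd.read_csv(path, dtype={"drug_code": str, "lab_code": str})
    _check_columns(df, REFERENCE_COLUMNS, "reference_pairs")
    out = []
    seen = set()
    for rec in df.itertuples(index=False):
        pair = DrugLabEvent(rec.drug_code, rec.lab_code, rec.direction)
        if pair in seen:
            raise SchemaError(f"duplicate reference pair: {pair}")
        seen.add(pair)
        out.append(ReferencePair(pair=pair, label=int(rec.label)))
    return out


def write_reference_pairs(pairs: Iterable[ReferencePair], path: str | Path) -> None:
    rows = [
        (rp.pair.drug_code, rp.pair.lab_code, rp.pair.direction, rp.label)
        for rp in pairs
    ]
    pd.DataFrame(rows, columns=REFERENCE_COLUMNS).to_csv(path, index=False)


def build_pair_universe(
    drugs: Iterable[str], lab_events: Iterable[tuple[str, str]]
) -> list[DrugLabEvent]:
    """Cartesian product of drugs and directional laboratory events.

    ``lab_events`` are (lab_code, direction) tuples. The result is sorted by
    (drug_code, lab_code, direction) so downstream sampling is deterministic.
    """
    drugs = set(drugs)
    lab_events = set(lab_events)
    if not drugs or not lab_events:
        raise ValueError("drugs and lab_events must be nonempty")
    return sorted(
        DrugLabEvent(d, lab, direction)
        for d in drugs
        for (lab, direction) in lab_events
    )


def build_reference_dataset(
    universe: Sequence[DrugLabEvent],
    known_pairs: Iterable[DrugLabEvent],
    cohort: Cohort | None = None,
    min_records: int = 5,
    neg_ratio: float = 2.0,
    seed: int | None = None,
    record_counts: dict[DrugLabEvent, int] | None = None,
) -> list[ReferencePair]:
    """Label known pairs positive, sample ~``neg_ratio``x nonpositives, then
    drop pairs with fewer than ``min_records`` usable records.

    A pair's record count is the number of patients contributing a usable
    pre/post extreme pair for that drug--lab combination (the paired-extremes
    denominator); pass precomputed ``record_counts`` to avoid recomputing, or
    a ``cohort`` to count on the fly. With neither, the filter is skipped.

    Sampling happens *before* the record filter, so the final nonpositive:
    positive ratio can drift below ``neg_ratio``.
    """
    known = set(known_pairs)
    extra = known - set(universe)
    if extra:
        raise ValueError(f"{len(extra)} known pairs are not in the universe")

    rng = np.random.default_rng(seed)
    nonpositive_pool = [p for p in universe if p not in known]
    n_want = int(round(neg_ratio * len(known)))
    if n_want > len(nonpositive_pool):
        warnings.warn(
            f"requested {n_want} nonpositive pairs but only "
            f"{len(nonpositive_pool)} available; taking all",
            stacklevel=2,
        )
        sampled = list(nonpositive_pool)
    else:
        idx = rng.choice(len(nonpositive_pool), size=n_want, replace=False)
        sampled = [nonpositive_pool[i] for i in sorted(idx)]

    labeled = [ReferencePair(p, 1) for p in sorted(known)] + [
        ReferencePair(p, 0) for p in sampled
    ]

    if record_counts is None and cohort is not None:
        from .cert import count_usable_records

        record_counts = count_usable_records(
            [rp.pair for rp in labeled], cohort
        )
    if record_counts is not None:
        before = len(labeled)
        labeled = [
            rp for rp in labeled if record_counts.get(rp.pair, 0) >= min_records
        ]
        logger.info(
            "record filter (>=%d): kept %d of %d pairs", min_records, len(labeled), before
        )
    return labeled


def split_train_test(
    pairs: Sequence[ReferencePair], frac: float = 0.7, seed: int | None = None
) -> tuple[list[ReferencePair], list[ReferencePair]]:
    """Stratified (by label) split into development and test sets."""
    by_label: dict[int, list[ReferencePair]] = {0: [], 1: []}
    for rp in pairs:
        by_label[rp.label].append(rp)
    for lab, members in by_label.items():
        if len(members) < 2:
            raise ValueError(
                f"class {lab} has {len(members)} member(s); need at least 2 to split"
            )
    rng = np.random.default_rng(seed)
    dev: list[ReferencePair] = []
    test: list[ReferencePair] = []
    for lab in (1, 0):
        members = by_label[lab]
        order = rng.permutation(len(members))
        n_dev = int(round(frac * len(members)))
        n_dev = min(max(n_dev, 1), len(members) - 1)  # both sides nonempty
        dev.extend(members[i] for i in order[:n_dev])
        test.extend(members[i] for i in order[n_dev:])
    return dev, test
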