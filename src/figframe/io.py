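"""Data model, validation and I/O for pointing records.

A pointing dataset has two tables linked by ``subject_id``:

* the *record* table — one row per pointing response, with the paradigm,
  the target label of the 3x3 matrix and the recorded azimuth/polar angles
  in decimal degrees (azimuth positive rightward, polar positive upward);
* the *subject* table — demographics and group labels (sex, age,
  cognition, optional MoCA score, handedness).

CSV storage uses two sibling files (``cohort.csv`` + ``cohort.meta.csv``);
JSON storage keeps both tables in one document.  Angles are written with
Python's shortest round-trip float representation, so a write/read cycle
reproduces every value bit-identically.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TargetLabel",
    "Paradigm",
    "PointingRecord",
    "SubjectMeta",
    "PERIMETER_ORDER",
    "SchemaError",
    "DuplicateRecordError",
    "IncompleteBlockError",
    "read_pointing_table",
    "write_pointing_table",
    "validate_dataset",
    "meta_table",
    "records_table",
]


class SchemaError(ValueError):
    """A field failed validation against the documented schema."""


class DuplicateRecordError(ValueError):
    """The same (subject, paradigm, target) appears more than once."""


class IncompleteBlockError(ValueError):
    """A (subject, paradigm) block does not contain all nine targets."""


class TargetLabel(str, Enum):
    """One of the nine positions of the 3x3 wall target matrix."""

    TOP_LEFT = "top_left"
    TOP_MID = "top_mid"
    TOP_RIGHT = "top_right"
    MID_LEFT = "mid_left"
    CENTER = "center"
    MID_RIGHT = "mid_right"
    BOTTOM_LEFT = "bottom_left"
    BOTTOM_MID = "bottom_mid"
    BOTTOM_RIGHT = "bottom_right"

    @property
    def grid(self) -> tuple[int, int]:
        """(column, row) position, column positive rightward, row positive up."""
        return _GRID[self]

    @property
    def is_perimeter(self) -> bool:
        return self is not TargetLabel.CENTER


_GRID: dict[TargetLabel, tuple[int, int]] = {
    TargetLabel.TOP_LEFT: (-1, 1),
    TargetLabel.TOP_MID: (0, 1),
    TargetLabel.TOP_RIGHT: (1, 1),
    TargetLabel.MID_LEFT: (-1, 0),
    TargetLabel.CENTER: (0, 0),
    TargetLabel.MID_RIGHT: (1, 0),
    TargetLabel.BOTTOM_LEFT: (-1, -1),
    TargetLabel.BOTTOM_MID: (0, -1),
    TargetLabel.BOTTOM_RIGHT: (1, -1),
}

#: Fixed clockwise perimeter walk used to order figure-frame vertices.
#: Frames are always assembled in this label order, never re-sorted by
#: geometry, so pathological (self-crossing) frames are preserved.
PERIMETER_ORDER: tuple[TargetLabel, ...] = (
    TargetLabel.TOP_LEFT,
    TargetLabel.TOP_MID,
    TargetLabel.TOP_RIGHT,
    TargetLabel.MID_RIGHT,
    TargetLabel.BOTTOM_RIGHT,
    TargetLabel.BOTTOM_MID,
    TargetLabel.BOTTOM_LEFT,
    TargetLabel.MID_LEFT,
)


class Paradigm(str, Enum):
    """The seven test conditions: two calibrations then five pointing tasks.

    The two calibrations are performed with visual feedback; the five tasks
    are performed with closed eyes, interleaved with passive 90-degree
    whole-body yaw rotations toward the non-dominant and dominant side.
    """

    WORLD_CALIBRATION = "world_calibration"
    RETINOTOPIC_CALIBRATION = "retinotopic_calibration"
    REPRODUCTION = "reproduction"
    TRANSFORMATION_NONDOMINANT = "transformation_nondominant"
    POSTROTATION_NONDOMINANT = "postrotation_nondominant"
    TRANSFORMATION_DOMINANT = "transformation_dominant"
    POSTROTATION_DOMINANT = "postrotation_dominant"

    @property
    def order_index(self) -> int:
        """Position 1-7 in the administration order."""
        return _ORDER[self]

    @property
    def is_calibration(self) -> bool:
        return self in CALIBRATION_PARADIGMS


_ORDER = {p: i + 1 for i, p in enumerate(Paradigm)}

CALIBRATION_PARADIGMS: tuple[Paradigm, ...] = (
    Paradigm.WORLD_CALIBRATION,
    Paradigm.RETINOTOPIC_CALIBRATION,
)

TASK_PARADIGMS: tuple[Paradigm, ...] = (
    Paradigm.REPRODUCTION,
    Paradigm.TRANSFORMATION_NONDOMINANT,
    Paradigm.POSTROTATION_NONDOMINANT,
    Paradigm.TRANSFORMATION_DOMINANT,
    Paradigm.POSTROTATION_DOMINANT,
)

_MAX_ANGLE_DEG = 90.0


@dataclass(frozen=True)
class PointingRecord:
    """One pointing response: where a subject pointed for one target."""

    subject_id: str
    paradigm: Paradigm
    target: TargetLabel
    azimuth_deg: float
    polar_deg: float

    def __post_init__(self) -> None:
        for name in ("azimuth_deg", "polar_deg"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise SchemaError(f"{name} must be numeric, got {v!r}")
            if not math.isfinite(v):
                raise SchemaError(f"{name} must be finite, got {v!r}")
            if abs(v) >= _MAX_ANGLE_DEG:
                raise SchemaError(
                    f"{name}={v} out of the forward hemisphere (|angle| < 90)"
                )


_SEXES = ("female", "male")
_COGNITION = ("normal", "impaired")
_HANDEDNESS = ("right", "left")


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics and grouping variables for one subject."""

    subject_id: str
    sex: str
    age_years: float
    cognition: str
    moca_points: int | None = None
    handedness: str = "right"

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise SchemaError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.cognition not in _COGNITION:
            raise SchemaError(
                f"cognition must be one of {_COGNITION}, got {self.cognition!r}"
            )
        if self.handedness not in _HANDEDNESS:
            raise SchemaError(
                f"handedness must be one of {_HANDEDNESS}, got {self.handedness!r}"
            )
        if not (self.age_years >= 0):
            raise SchemaError(f"age_years must be >= 0, got {self.age_years!r}")
        if self.moca_points is not None and not (0 <= self.moca_points <= 30):
            raise SchemaError(
                f"moca_points must be within 0-30, got {self.moca_points!r}"
            )


RECORD_COLUMNS = ["subject_id", "paradigm", "target", "azimuth_deg", "polar_deg"]
META_COLUMNS = [
    "subject_id",
    "sex",
    "age_years",
    "cognition",
    "moca_points",
    "handedness",
]


def _meta_csv_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.csv")


def _parse_record(row: dict, where: str) -> PointingRecord:
    try:
        paradigm = Paradigm(str(row["paradigm"]))
    except ValueError:
        raise SchemaError(f"{where}: unknown paradigm {row['paradigm']!r}") from None
    try:
        target = TargetLabel(str(row["target"]))
    except ValueError:
        raise SchemaError(f"{where}: unknown target {row['target']!r}") from None
    angles = {}
    for name in ("azimuth_deg", "polar_deg"):
        try:
            angles[name] = float(row[name])
        except (TypeError, ValueError):
            raise SchemaError(
                f"{where}: non-numeric {name} {row[name]!r}"
            ) from None
    try:
        return PointingRecord(
            subject_id=str(row["subject_id"]),
            paradigm=paradigm,
            target=target,
            **angles,
        )
    except SchemaError as exc:
        raise SchemaError(f"{where}: {exc}") from None


def _parse_meta(row: dict, where: str) -> SubjectMeta:
    moca = row.get("moca_points")
    if moca is None or (isinstance(moca, float) and math.isnan(moca)) or moca == "":
        moca_val = None
    else:
        try:
            moca_val = int(float(moca))
        except (TypeError, ValueError):
            raise SchemaError(f"{where}: non-numeric moca_points {moca!r}") from None
    try:
        age = float(row["age_years"])
    except (TypeError, ValueError):
        raise SchemaError(
            f"{where}: non-numeric age_years {row['age_years']!r}"
        ) from None
    try:
        return SubjectMeta(
            subject_id=str(row["subject_id"]),
            sex=str(row["sex"]),
            age_years=age,
            cognition=str(row["cognition"]),
            moca_points=moca_val,
            handedness=str(row.get("handedness", "right")),
        )
    except SchemaError as exc:
        raise SchemaError(f"{where}: {exc}") from None


def _check_duplicates(records: Sequence[PointingRecord]) -> None:
    counts = Counter((r.subject_id, r.paradigm, r.target) for r in records)
    dups = [k for k, c in counts.items() if c > 1]
    if dups:
        s, p, t = dups[0]
        raise DuplicateRecordError(
            f"duplicate record for subject {s!r}, paradigm {p.value},"
            f" target {t.value} ({len(dups)} duplicated keys total)"
        )


def validate_dataset(
    records: Sequence[PointingRecord],
    meta: Sequence[SubjectMeta] | None = None,
    strict: bool = True,
) -> None:
    """Cross-record validation of a pointing dataset.

    Always rejects duplicated (subject, paradigm, target) keys.  In strict
    mode every (subject, paradigm) block present must contain all nine
    targets; lenient mode permits partial blocks (frames built from them
    are flagged downstream).
    """
    _check_duplicates(records)
    if meta is not None:
        ids = [m.subject_id for m in meta]
        if len(ids) != len(set(ids)):
            raise DuplicateRecordError("duplicate subject_id in metadata table")
    if strict:
        blocks: dict[tuple[str, Paradigm], set[TargetLabel]] = {}
        for r in records:
            blocks.setdefault((r.subject_id, r.paradigm), set()).add(r.target)
        for (s, p), targets in blocks.items():
            if len(targets) != 9:
                missing = sorted(t.value for t in TargetLabel if t not in targets)
                raise IncompleteBlockError(
                    f"subject {s!r}, paradigm {p.value}: {len(targets)}/9 targets"
                    f" (missing: {', '.join(missing)})"
                )


def records_table(records: Iterable[PointingRecord]) -> pd.DataFrame:
    """Record collection as a DataFrame in the canonical column order."""
    rows = [
        {
            "subject_id": r.subject_id,
            "paradigm": r.paradigm.value,
            "target": r.target.value,
            "azimuth_deg": r.azimuth_deg,
            "polar_deg": r.polar_deg,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def meta_table(meta: Iterable[SubjectMeta]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": m.subject_id,
            "sex": m.sex,
            "age_years": m.age_years,
            "cognition": m.cognition,
            "moca_points": m.moca_points,
            "handedness": m.handedness,
        }
        for m in meta
    ]
    return pd.DataFrame(rows, columns=META_COLUMNS)


def read_pointing_table(
    path: str | Path,
    format: str | None = None,
    strict: bool = False,
) -> tuple[list[PointingRecord], list[SubjectMeta]]:
    """Read a pointing dataset from CSV (+ sibling ``.meta.csv``) or JSON.

    Parameters
    ----------
    path
        For CSV, the record table; subject metadata is read from the
        sibling ``<stem>.meta.csv`` when present.  For JSON, one document
        with ``records`` and ``subjects`` arrays.
    format
        ``"csv"`` or ``"json"``; inferred from the suffix when omitted.
    strict
        When true, additionally require every (subject, paradigm) block to
        contain all nine targets.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        # read as strings and convert in Python: float() is exactly
        # round-trip for repr-serialized values, pandas' fast parser is not
        df = pd.read_csv(path, dtype=str)
        missing_cols = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"{path}: missing columns {missing_cols}")
        records = [
            _parse_record(row, f"{path.name} row {i + 2}")
            for i, row in enumerate(df.to_dict("records"))
        ]
        meta: list[SubjectMeta] = []
        mpath = _meta_csv_path(path)
        if mpath.exists():
            mdf = pd.read_csv(mpath, dtype=str)
            meta = [
                _parse_meta(row, f"{mpath.name} row {i + 2}")
                for i, row in enumerate(mdf.to_dict("records"))
            ]
    elif fmt == "json":
        doc = json.loads(Path(path).read_text())
        records = [
            _parse_record(row, f"{path.name} records[{i}]")
            for i, row in enumerate(doc.get("records", []))
        ]
        meta = [
            _parse_meta(row, f"{path.name} subjects[{i}]")
            for i, row in enumerate(doc.get("subjects", []))
        ]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    validate_dataset(records, meta, strict=strict)
    return records, meta


def write_pointing_table(
    records: Sequence[PointingRecord],
    meta: Sequence[SubjectMeta],
    path: str | Path,
    format: str | None = None,
) -> Path:
    """Write a dataset readable by :func:`read_pointing_table`.

    Floats are serialized with the shortest round-trip representation, so
    reading the file back reproduces the records exactly.  I/O is lossless:
    center-target records are written like any other (the center is only
    excluded later, when frames are assembled).
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(",".join(RECORD_COLUMNS) + "\n")
            for r in records:
                fh.write(
                    f"{r.subject_id},{r.paradigm.value},{r.target.value},"
                    f"{r.azimuth_deg!r},{r.polar_deg!r}\n"
                )
        with open(_meta_csv_path(path), "w", newline="") as fh:
            fh.write(",".join(META_COLUMNS) + "\n")
            for m in meta:
                moca = "" if m.moca_points is None else str(m.moca_points)
                fh.write(
                    f"{m.subject_id},{m.sex},{m.age_years!r},{m.cognition},"
                    f"{moca},{m.handedness}\n"
                )
    elif fmt == "json":
        doc = {
            "records": records_table(records).to_dict("records"),
            "subjects": [
                {
                    "subject_id": m.subject_id,
                    "sex": m.sex,
                    "age_years": m.age_years,
                    "cognition": m.cognition,
                    "moca_points": m.moca_points,
                    "handedness": m.handedness,
                }
                for m in meta
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
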