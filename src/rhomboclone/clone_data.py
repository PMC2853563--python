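"""Clone measurement records, normalization, and three-way boundary classification.

A clone is measured in a rhombomere by three lengths sharing one arbitrary
unit (see :class:`CloneRecord`): ``a``, centre-to-anterior-boundary distance;
``b``, the rhombomere's anteroposterior (AP) length at the level of the clone
centre; and ``c``, the clone's own AP extent.  Normalization maps the clone
into an idealised unit rhombomere, the interval [0, 1] with 0 anterior:
position ``x = a/b`` and radius ``r = (c/2)/b``.

A normalized clone is classified against the nearest boundary (distance
``d = min(x, 1 - x)``): it *crosses* if ``r > d``, *respects* (abuts without
crossing) if ``d - delta < r <= d`` where ``delta`` is the measurement-error
margin, and is a *middle* clone otherwise.  Ties at ``r == d`` count as
respecting (a clone abutting the boundary).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CROSS",
    "RESPECT",
    "MIDDLE",
    "UNBOUNDED",
    "CATEGORIES",
    "CloneRecord",
    "NormalizedClone",
    "CategoryCounts",
    "CloneValidationError",
    "TableValidationError",
    "normalize_clone",
    "classify_clone",
    "classify_positions_radii",
    "count_categories",
    "read_clone_table",
    "write_clone_table",
]

CROSS = "cross"
RESPECT = "respect"
MIDDLE = "middle"
UNBOUNDED = "unbounded"
CATEGORIES = (CROSS, RESPECT, MIDDLE)

#: Columns a clone table must contain; the rest are optional.
REQUIRED_COLUMNS = ("embryo_id", "rhombomere", "a", "b", "c")
OPTIONAL_COLUMNS = ("observed_category", "stage_induced", "stage_observed")


class CloneValidationError(ValueError):
    """A clone record or normalized clone violates an invariant.

    Carries the name of the offending field in :attr:`field`.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(message)


class TableValidationError(ValueError):
    """A clone table failed validation; per-row messages in :attr:`row_errors`."""

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        self.row_errors = row_errors or []
        super().__init__(message)


@dataclass(frozen=True)
class CloneRecord:
    """One measured clone: raw lengths plus metadata.

    Parameters
    ----------
    embryo_id : str
        Opaque identifier of the embryo the clone was observed in.
    rhombomere : str
        Rhombomere label (e.g. ``"r3"``) or ``"pooled"`` when all clones are
        placed in a single idealised rhombomere.
    a : float
        Distance from clone centre to its immediately anterior rhombomeric
        boundary, arbitrary units.
    b : float
        Rhombomere AP length at the level of the clone centre, same units.
    c : float
        Clone AP length, same units.
    observed_category : str, optional
        Eye-scored category, one of ``cross``/``respect``/``middle``/
        ``unbounded``.  When present it takes precedence over threshold
        classification.  ``unbounded`` marks clones not lying between two
        recognizable boundaries; they are excluded from category counts.
    stage_induced, stage_observed : float, optional
        Embryonic stage in days post coitum at labelling induction and at
        observation.
    """

    embryo_id: str
    rhombomere: str
    a: float
    b: float
    c: float
    observed_category: str | None = None
    stage_induced: float | None = None
    stage_observed: float | None = None

    def __post_init__(self):
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise CloneValidationError(name, f"{name} must be finite, got {v!r}")
        if self.a < 0:
            raise CloneValidationError("a", f"a must be >= 0, got {self.a}")
        if self.b <= 0:
            raise CloneValidationError("b", f"b must be > 0, got {self.b}")
        if self.c <= 0:
            raise CloneValidationError("c", f"c must be > 0, got {self.c}")
        if self.a > self.b:
            raise CloneValidationError(
                "a", f"a must not exceed b (centre beyond posterior boundary): a={self.a}, b={self.b}"
            )
        if self.observed_category is not None and self.observed_category not in (
            CROSS,
            RESPECT,
            MIDDLE,
            UNBOUNDED,
        ):
            raise CloneValidationError(
                "observed_category",
                f"observed_category must be one of {CATEGORIES + (UNBOUNDED,)}, "
                f"got {self.observed_category!r}",
            )


@dataclass(frozen=True)
class NormalizedClone:
    """A clone in the idealised unit rhombomere.

    ``x`` is the centre position as a fraction of the rhombomere AP length
    (0 = anterior boundary, 1 = posterior); ``r`` the radius on the same
    scale.  Both endpoints of [0, 1] are legal positions (centre exactly on
    a boundary).
    """

    x: float
    r: float

    def __post_init__(self):
        if not (0.0 <= self.x <= 1.0):
            raise CloneValidationError("x", f"x must lie in [0, 1], got {self.x}")
        if not (self.r > 0.0):
            raise CloneValidationError("r", f"r must be > 0, got {self.r}")

    @property
    def boundary_distance(self) -> float:
        """Distance to the nearest boundary, ``min(x, 1 - x)``."""
        return min(self.x, 1.0 - self.x)


@dataclass(frozen=True)
class CategoryCounts:
    """Observed (cross, respect, middle) tallies, plus excluded unbounded clones."""

    n_cross: int
    n_respect: int
    n_middle: int
    n_unbounded: int = 0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    @property
    def n_total(self) -> int:
        """Number of bounded clones (excludes unbounded)."""
        return self.n_cross + self.n_respect + self.n_middle

    def as_array(self) -> np.ndarray:
        """Counts in canonical (cross, respect, middle) order."""
        return np.array([self.n_cross, self.n_respect, self.n_middle], dtype=float)


def normalize_clone(record: CloneRecord) -> NormalizedClone:
    """Map raw measurements to the unit rhombomere: ``x = a/b``, ``r = (c/2)/b``.

    Scale-invariant: multiplying a, b, c by a common factor leaves the result
    unchanged.  Raises :class:`CloneValidationError` naming the offending
    field on invalid input (validation happens at record construction).
    """
    return NormalizedClone(x=record.a / record.b, r=(record.c / 2.0) / record.b)


def classify_clone(clone: NormalizedClone, delta: float) -> str:
    """Classify a clone as ``cross``, ``respect`` or ``middle``.

    With ``d = min(x, 1-x)`` the nearest-boundary distance: *cross* if
    ``r > d``; *respect* if ``d - delta < r <= d``; *middle* if
    ``r <= d - delta``.  ``delta`` is the measurement-error margin in
    rhombomere fractions, ``0 <= delta < 0.5``.
    """
    if not (0.0 <= delta < 0.5):
        raise ValueError(f"delta must lie in [0, 0.5), got {delta}")
    d = clone.boundary_distance
    if clone.r > d:
        return CROSS
    if clone.r > d - delta:
        return RESPECT
    return MIDDLE


def classify_positions_radii(
    x: np.ndarray, r: np.ndarray, delta: float
) -> np.ndarray:
    """Vectorized :func:`classify_clone` over position/radius arrays.

    Returns an object array of category strings aligned with the inputs.
    """
    if not (0.0 <= delta < 0.5):
        raise ValueError(f"delta must lie in [0, 0.5), got {delta}")
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    d = np.minimum(x, 1.0 - x)
    out = np.where(r > d, CROSS, np.where(r > d - delta, RESPECT, MIDDLE))
    return out.astype(object)


def count_categories(
    clones: Sequence[CloneRecord | NormalizedClone], delta: float
) -> CategoryCounts:
    """Tally (cross, respect, middle) over clones at error margin ``delta``.

    Accepts raw records (normalized on the fly) or pre-normalized clones.
    A record's ``observed_category``, when present, wins over threshold
    classification; records flagged ``unbounded`` are excluded from the
    trinomial counts and tallied separately.
    """
    if len(clones) == 0:
        raise ValueError("count_categories requires at least one clone")
    tally = {CROSS: 0, RESPECT: 0, MIDDLE: 0, UNBOUNDED: 0}
    for item in clones:
        if isinstance(item, CloneRecord):
            if item.observed_category is not None:
                tally[item.observed_category] += 1
                continue
            item = normalize_clone(item)
        tally[classify_clone(item, delta)] += 1
    return CategoryCounts(
        n_cross=tally[CROSS],
        n_respect=tally[RESPECT],
        n_middle=tally[MIDDLE],
        n_unbounded=tally[UNBOUNDED],
    )


def _record_from_row(row: pd.Series) -> CloneRecord:
    def _opt_float(v):
        return None if pd.isna(v) else float(v)

    cat = row.get("observed_category")
    if cat is not None and (pd.isna(cat) or cat == ""):
        cat = None
    return CloneRecord(
        embryo_id=str(row["embryo_id"]),
        rhombomere=str(row["rhombomere"]),
        a=float(row["a"]),
        b=float(row["b"]),
        c=float(row["c"]),
        observed_category=cat,
        stage_induced=_opt_float(row.get("stage_induced")),
        stage_observed=_opt_float(row.get("stage_observed")),
    )


def read_clone_table(
    path: str | Path, delimiter: str | None = None, strict: bool = True
) -> list[CloneRecord]:
    """Read a clone table (TSV/CSV with a header row) into records.

    The delimiter is auto-detected between tab and comma unless given.
    Rows failing validation are reported with their 1-based data row number;
    in strict mode any bad row is fatal (:class:`TableValidationError`),
    otherwise bad rows are skipped with a warning.
    """
    path = Path(path)
    if delimiter is None:
        header = path.open().readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, dtype={"embryo_id": str, "rhombomere": str})
    missing = [col for col in REQUIRED_COLUMNS if col not in df.columns]
    if missing:
        raise TableValidationError(
            f"clone table {path} is missing required columns: {missing} "
            f"(required: {list(REQUIRED_COLUMNS)})"
        )
    records: list[CloneRecord] = []
    row_errors: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(_record_from_row(row))
        except (CloneValidationError, ValueError, TypeError) as exc:
            row_errors.append((i, str(exc)))
    if row_errors:
        summary = "; ".join(f"row {i}: {msg}" for i, msg in row_errors)
        if strict:
            raise TableValidationError(
                f"{len(row_errors)} invalid row(s) in {path}: {summary}", row_errors
            )
        warnings.warn(f"skipped {len(row_errors)} invalid row(s) in {path}: {summary}")
    return records


def write_clone_table(
    records: Iterable[CloneRecord], path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write records as a delimited table; inverse of :func:`read_clone_table`.

    Numeric fields are written with repr-level precision so that
    write-then-read round-trips exactly.
    """
    path = Path(path)
    rows = []
    for rec in records:
        rows.append(
            {
                "embryo_id": rec.embryo_id,
                "rhombomere": rec.rhombomere,
                "a": rec.a,
                "b": rec.b,
                "c": rec.c,
                "observed_category": rec.observed_category or "",
                "stage_induced": "" if rec.stage_induced is None else rec.stage_induced,
                "stage_observed": "" if rec.stage_observed is None else rec.stage_observed,
            }
        )
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    return path


def records_to_frame(records: Sequence[CloneRecord], delta: float | None = None) -> pd.DataFrame:
    """Records as a DataFrame with appended normalized ``x``, ``r`` (fractions),
    ``x_percent`` (the a/b x 100 reporting convention, 1 decimal), and, when
    ``delta`` is given, a ``category`` column (observed category wins)."""
    rows = []
    for rec in records:
        nc = normalize_clone(rec)
        row = {
            "embryo_id": rec.embryo_id,
            "rhombomere": rec.rhombomere,
            "a": rec.a,
            "b": rec.b,
            "c": rec.c,
            "x": nc.x,
            "r": nc.r,
            "x_percent": round(nc.x * 100.0, 1),
        }
        if delta is not None:
            if rec.observed_category is not None:
                row["category"] = rec.observed_category
            else:
                row["category"] = classify_clone(nc, delta)
        rows.append(row)
    return pd.DataFrame(rows)
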