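"""Reading, validation and consolidation of bone and occurrence tables.

Two table types flow through the package:

* **bone tables** — radiocarbon-dated, surface-collected bones, each with the
  mean annual temperature (MAT) of its locality and a burial-history class;
  the raw material for the persistence-vs-temperature regression.
* **occurrence tables** — dated occurrences (body fossils or sedimentary
  eDNA) of a focal taxon, the input to extinction-date estimation.

Ages are calibrated years before present (cal yr BP, present = 1950 CE);
larger values are older.  Dating errors are stored as 2-sigma ranges, the
convention in which they are reported; any Gaussian sampling downstream uses
``sigma = age_2sigma / 2``.  Ages are kept in years internally; reports print
kyr where noted.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InsufficientDataError, RowError, SchemaError

__all__ = [
    "BurialClass",
    "Source",
    "BoneRecord",
    "OccurrenceRecord",
    "read_bone_table",
    "write_bone_table",
    "read_occurrence_table",
    "write_occurrence_table",
    "consolidate_oldest_per_region",
    "to_json",
]


class BurialClass(str, enum.Enum):
    """Burial-history class of a surface-collected bone.

    ``never_buried`` bones are confidently surface-exposed for their whole
    post-mortem history; ``potentially_never_buried`` bones were found
    exposed but exhumation cannot be excluded.
    """

    NEVER_BURIED = "never_buried"
    POTENTIALLY_NEVER_BURIED = "potentially_never_buried"


class Source(str, enum.Enum):
    """Provenance of a dated occurrence: identifiable body fossil or eDNA."""

    FOSSIL = "fossil"
    EDNA = "edna"


@dataclass(frozen=True)
class BoneRecord:
    """One dated surface bone with locality temperature and burial class."""

    record_id: str
    region: str
    taxon: str
    age: float  # cal yr BP; here the bone's persistence duration
    age_2sigma: float  # 2-sigma dating error, years
    mat: float  # mean annual temperature at the locality, degrees C
    burial_class: BurialClass

    def __post_init__(self) -> None:
        if not (self.age > 0):
            raise ValueError(f"age must be > 0, got {self.age}")
        if not (self.age_2sigma >= 0):
            raise ValueError(f"age_2sigma must be >= 0, got {self.age_2sigma}")
        if not math.isfinite(self.mat):
            raise ValueError(f"mat must be finite, got {self.mat}")
        if not isinstance(self.burial_class, BurialClass):
            object.__setattr__(
                self, "burial_class", BurialClass(self.burial_class)
            )


@dataclass(frozen=True)
class OccurrenceRecord:
    """One dated fossil or eDNA occurrence of the focal taxon."""

    record_id: str
    region: str
    source: Source
    age: float  # cal yr BP
    age_2sigma: float  # 2-sigma dating error, years

    def __post_init__(self) -> None:
        if not (self.age >= 0):
            raise ValueError(f"age must be >= 0, got {self.age}")
        if not (self.age_2sigma >= 0):
            raise ValueError(f"age_2sigma must be >= 0, got {self.age_2sigma}")
        if not isinstance(self.source, Source):
            object.__setattr__(self, "source", Source(self.source))


#: default CSV-header-to-field mapping; override via ``columns=`` when the
#: source file uses different headers.
BONE_COLUMNS = {
    "record_id": "record_id",
    "region": "region",
    "taxon": "taxon",
    "age": "age",
    "age_2sigma": "age_2sigma",
    "mat": "mat",
    "burial_class": "burial_class",
}

OCCURRENCE_COLUMNS = {
    "record_id": "record_id",
    "region": "region",
    "source": "source",
    "age": "age",
    "age_2sigma": "age_2sigma",
}


def _load_frame(
    path: str | Path, fields: Mapping[str, str], columns: Mapping[str, str] | None
) -> pd.DataFrame:
    mapping = dict(fields)
    if columns:
        mapping.update(columns)
    df = pd.read_csv(path, dtype=str)
    missing = [col for col in mapping.values() if col not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    frame = df[[mapping[f] for f in mapping]].copy()
    frame.columns = list(mapping)
    return frame


def _parse_float(value: str, field: str, idx: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise RowError(idx, f"non-numeric {field}: {value!r}") from None
    if not math.isfinite(out):
        raise RowError(idx, f"non-finite {field}: {value!r}")
    return out


def read_bone_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[BoneRecord]:
    """Read and validate a bone table CSV; row order is preserved.

    Parameters
    ----------
    path
        CSV file with a header row.
    columns
        Optional mapping from :class:`BoneRecord` field names to the CSV
        headers actually used in the file.
    """
    frame = _load_frame(path, BONE_COLUMNS, columns)
    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        label = str(row.burial_class).strip()
        try:
            burial = BurialClass(label)
        except ValueError:
            raise RowError(idx, f"unknown burial_class label: {label!r}") from None
        try:
            records.append(
                BoneRecord(
                    record_id=str(row.record_id),
                    region=str(row.region),
                    taxon=str(row.taxon),
                    age=_parse_float(row.age, "age", idx),
                    age_2sigma=_parse_float(row.age_2sigma, "age_2sigma", idx),
                    mat=_parse_float(row.mat, "mat", idx),
                    burial_class=burial,
                )
            )
        except ValueError as exc:
            raise RowError(idx, str(exc)) from None
    return records


def read_occurrence_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[OccurrenceRecord]:
    """Read and validate an occurrence table CSV; row order is preserved."""
    frame = _load_frame(path, OCCURRENCE_COLUMNS, columns)
    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        label = str(row.source).strip()
        try:
            source = Source(label)
        except ValueError:
            raise RowError(idx, f"unknown source label: {label!r}") from None
        try:
            records.append(
                OccurrenceRecord(
                    record_id=str(row.record_id),
                    region=str(row.region),
                    source=source,
                    age=_parse_float(row.age, "age", idx),
                    age_2sigma=_parse_float(row.age_2sigma, "age_2sigma", idx),
                )
            )
        except ValueError as exc:
            raise RowError(idx, str(exc)) from None
    return records


def _records_to_frame(records: Iterable) -> pd.DataFrame:
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec)
        for key, val in d.items():
            if isinstance(val, enum.Enum):
                d[key] = val.value
        rows.append(d)
    return pd.DataFrame(rows)


def write_bone_table(records: Sequence[BoneRecord], path: str | Path) -> None:
    """Write bone records to CSV with the canonical headers."""
    _records_to_frame(records).to_csv(path, index=False)


def write_occurrence_table(
    records: Sequence[OccurrenceRecord], path: str | Path
) -> None:
    """Write occurrence records to CSV with the canonical headers."""
    _records_to_frame(records).to_csv(path, index=False)


def consolidate_oldest_per_region(
    records: Sequence[BoneRecord],
) -> list[BoneRecord]:
    """Keep only the oldest bone from each region.

    The persistence regression treats the oldest surviving surface bone per
    region as that region's realised persistence duration.  Ties on maximal
    age are broken by smaller dating error (2-sigma), then lexicographically
    by ``record_id``, so the output is deterministic.  Output order follows
    first appearance of each region in the input.
    """
    if not records:
        raise InsufficientDataError("cannot consolidate an empty record list")
    best: dict[str, BoneRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.region not in best:
            best[rec.region] = rec
            order.append(rec.region)
            continue
        cur = best[rec.region]
        key_new = (-rec.age, rec.age_2sigma, rec.record_id)
        key_cur = (-cur.age, cur.age_2sigma, cur.record_id)
        if key_new < key_cur:
            best[rec.region] = rec
    return [best[region] for region in order]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def to_json(obj, path: str | Path | None = None) -> str:
    """Serialize any result dataclass (or nested structure) to JSON.

    Returns the JSON string; also writes it to ``path`` when given.
    """
    text = json.dumps(_jsonable(obj), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
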