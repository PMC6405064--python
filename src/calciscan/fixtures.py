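"""Per-specimen measurement tables: readers, writers, and paired arithmetic.

Two tables ship with the package under ``calciscan/data``:

* ``table1.csv`` — paired micro-CT measurements for 20 specimens: calcite
  CT number (CCN) and mean wall thickness before DNA extraction (pre),
  after extraction scanned three-at-a-time (post1), and after extraction
  scanned individually (post2).
* ``table2.csv`` — individual stable-isotope measurements for 49
  specimens: treatment group (A = untreated control, B = standard
  40-minute extraction, C = 120-minute extraction), genetic type where
  sequencing succeeded, d13C and d18O (permil VPDB), and shell weight (ug).

Specimen IDs in table 2 are unique only within a treatment group (the
same ID can occur in B and C); records are keyed by ``(group, id)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path

import pandas as pd

from calciscan.errors import SchemaError, TableParseError, ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("A", "B", "C")
GENETIC_TYPES = ("Ia", "Ib", "IIa", "untyped")

CT_COLUMNS = ("pre_ccn", "pre_thick", "post1_ccn", "post1_thick",
              "post2_ccn", "post2_thick")


@dataclass(frozen=True)
class CTRecord:
    """One specimen's paired CCN + wall-thickness measurements."""

    specimen_id: int
    pre_ccn: float
    pre_thick: float
    post1_ccn: float
    post1_thick: float
    post2_ccn: float
    post2_thick: float

    def __post_init__(self) -> None:
        if self.specimen_id <= 0:
            raise ValidationError(f"specimen_id must be positive: {self.specimen_id}")
        for name in ("pre_ccn", "post1_ccn", "post2_ccn"):
            v = getattr(self, name)
            if not 0 < v < 1200:
                raise ValidationError(f"{name}={v} outside (0, 1200)")
        for name in ("pre_thick", "post1_thick", "post2_thick"):
            v = getattr(self, name)
            if not 0 < v < 20:
                raise ValidationError(f"{name}={v} outside (0, 20) um")


@dataclass(frozen=True)
class IsotopeRecord:
    """One specimen's isotope measurement with treatment and genotype labels."""

    specimen_id: str
    group: str
    genetic_type: str
    d13c: float
    d18o: float
    weight: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group {self.group!r} not in {GROUPS}")
        if self.genetic_type not in GENETIC_TYPES:
            raise ValidationError(
                f"genetic_type {self.genetic_type!r} not in {GENETIC_TYPES}")
        if self.weight <= 0:
            raise ValidationError(f"weight must be positive: {self.weight}")
        if self.group == "A" and self.genetic_type != "untyped":
            raise ValidationError(
                "group-A records are never sequenced and must be untyped")


@dataclass(frozen=True)
class PairedDiffSummary:
    """Signed per-specimen differences (first minus second) and summaries."""

    first: str
    second: str
    diffs: tuple[float, ...]
    mean_diff: float
    min_diff: float
    max_diff: float

    @property
    def n(self) -> int:
        return len(self.diffs)


def _normalize_minus(text: str) -> str:
    # U+2212 minus and U+2013 en-dash both appear in published tables
    return text.replace("−", "-").replace("–", "-")


def _read_csv(path: str | Path) -> pd.DataFrame:
    raw = Path(path).read_text(encoding="utf-8")
    import io

    return pd.read_csv(io.StringIO(_normalize_minus(raw)), dtype=str,
                       skip_blank_lines=True)


def _parse_float(df_value: str, row: int, column: str) -> float:
    try:
        return float(df_value)
    except (TypeError, ValueError):
        raise TableParseError(
            f"row {row}, column {column!r}: cannot parse {df_value!r}") from None


def load_ct_table(path: str | Path) -> list[CTRecord]:
    """Load a paired CT measurement table (CSV, one row per specimen).

    Row order is preserved.  Raises :class:`SchemaError` if a measurement
    column is missing and :class:`TableParseError` for non-numeric cells.
    """
    df = _read_csv(path)
    required = ("specimen_id",) + CT_COLUMNS
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if df.empty:
        logger.warning("CT table %s has a header but no data rows", path)
        return []
    records = []
    seen: set[int] = set()
    for i, row in df.iterrows():
        sid = int(_parse_float(row["specimen_id"], i, "specimen_id"))
        if sid in seen:
            raise ValidationError(f"duplicate specimen_id {sid}")
        seen.add(sid)
        records.append(CTRecord(
            specimen_id=sid,
            **{c: _parse_float(row[c], i, c) for c in CT_COLUMNS}))
    return records


def load_isotope_table(path: str | Path) -> list[IsotopeRecord]:
    """Load an isotope table (CSV).  Empty genotype cells become 'untyped'."""
    df = _read_csv(path)
    required = ("group", "specimen_id", "genetic_type", "d13c", "d18o", "weight")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if df.empty:
        logger.warning("isotope table %s has a header but no data rows", path)
        return []
    records = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        gtype = row["genetic_type"]
        gtype = "untyped" if (pd.isna(gtype) or not str(gtype).strip()) else str(gtype).strip()
        rec = IsotopeRecord(
            specimen_id=str(row["specimen_id"]).strip(),
            group=str(row["group"]).strip(),
            genetic_type=gtype,
            d13c=_parse_float(row["d13c"], i, "d13c"),
            d18o=_parse_float(row["d18o"], i, "d18o"),
            weight=_parse_float(row["weight"], i, "weight"),
        )
        key = (rec.group, rec.specimen_id)
        if key in seen:
            raise ValidationError(f"duplicate (group, specimen_id) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_ct_table(records: list[CTRecord], path: str | Path) -> None:
    cols = ("specimen_id",) + CT_COLUMNS
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                      columns=cols)
    df.to_csv(path, index=False)


def write_isotope_table(records: list[IsotopeRecord], path: str | Path) -> None:
    cols = ("group", "specimen_id", "genetic_type", "d13c", "d18o", "weight")
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in cols}
        if d["genetic_type"] == "untyped":
            d["genetic_type"] = ""
        rows.append(d)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def paired_differences(records: list[CTRecord], first: str,
                       second: str) -> PairedDiffSummary:
    """Signed per-specimen differences ``first - second`` over a CT table."""
    valid = {f.name for f in dc_fields(CTRecord)} - {"specimen_id"}
    for col in (first, second):
        if col not in valid:
            raise KeyError(f"unknown CT column {col!r}; valid: {sorted(valid)}")
    if not records:
        raise ValidationError("no records")
    diffs = tuple(getattr(r, first) - getattr(r, second) for r in records)
    return PairedDiffSummary(
        first=first, second=second, diffs=diffs,
        mean_diff=sum(diffs) / len(diffs),
        min_diff=min(diffs), max_diff=max(diffs))


def packaged_table_path(name: str) -> Path:
    """Path to a packaged fixture table: 'ct' (table1) or 'isotope' (table2)."""
    fname = {"ct": "table1.csv", "isotope": "table2.csv"}.get(name)
    if fname is None:
        raise KeyError(f"unknown table {name!r}; expected 'ct' or 'isotope'")
    return Path(resources.files("calciscan") / "data" / fname)


def load_packaged_ct_table() -> list[CTRecord]:
    return load_ct_table(packaged_table_path("ct"))


def load_packaged_isotope_table() -> list[IsotopeRecord]:
    return load_isotope_table(packaged_table_path("isotope"))
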