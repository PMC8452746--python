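"""Reading and writing the tabular interchange formats.

The central input is the *segment file*: one row per detected genetic
alteration with its genomic location, alteration type and one mutated
clone fraction (MCF) column per biopsy, MCF expressed as a percentage in
[0, 100].  This is the u x v matrix the deconvolution operates on.  The
module also reads the optional two-column *rules* table of illicit
mother -> daughter event orderings, and writes event matrices,
subclone-fraction tables and Newick trees.

Dialect: tab-separated, UTF-8, one header row.  Metadata columns are
``event_id`` (optional), ``chrom``, ``start``, ``end``, ``type``,
``label``, ``source``; every remaining column is interpreted as a biopsy
MCF column unless an explicit list or prefix is configured.  Coordinates
are 1-based closed intervals.  Missing MCF cells (empty or NA) are
preserved as missing, never silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALT_TYPES",
    "SOURCES",
    "AlterationRecord",
    "McfMatrix",
    "RulesMatrix",
    "SegmentDialect",
    "SegmentFormatError",
    "read_segment_table",
    "write_segment_table",
    "read_rules",
    "write_newick",
    "read_newick",
    "write_event_matrix",
    "write_fractions",
]

ALT_TYPES = ("gain", "loss", "cnni", "amplification", "snv", "sv", "other")
SOURCES = ("snp_array", "wes", "wgs", "tds")

_META_COLUMNS = ("chrom", "start", "end", "type", "label", "source")


class SegmentFormatError(ValueError):
    """Raised on malformed segment / rules tables; carries the row number."""


@dataclass
class SegmentDialect:
    """How to map table columns onto records.

    ``mcf_columns`` pins the biopsy columns explicitly; otherwise every
    column that is not a metadata column is a biopsy, optionally
    filtered by ``mcf_prefix``.
    """

    sep: str = "\t"
    mcf_columns: Sequence[str] | None = None
    mcf_prefix: str | None = None


@dataclass
class AlterationRecord:
    """One detected genetic alteration with its per-biopsy MCFs."""

    event_id: str
    chrom: str
    start_bp: int
    end_bp: int
    alt_type: str
    label: str = ""
    source: str = "snp_array"
    mcf: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"event {self.event_id}: start_bp {self.start_bp} > end_bp {self.end_bp}"
            )
        if self.alt_type == "snv" and self.start_bp != self.end_bp:
            raise ValueError(f"event {self.event_id}: snv must have start_bp == end_bp")
        if self.alt_type not in ALT_TYPES:
            raise ValueError(f"event {self.event_id}: unknown alteration type {self.alt_type!r}")

    def mcf_in(self, biopsy: str) -> float | None:
        return self.mcf.get(biopsy)


class McfMatrix:
    """Events x biopsies matrix of MCF percentages (NaN = missing)."""

    def __init__(self, events: Sequence[str], biopsies: Sequence[str], values):
        self.events = list(events)
        self.biopsies = list(biopsies)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.events), len(self.biopsies)):
            raise ValueError("values shape does not match event/biopsy labels")
        if len(set(self.events)) != len(self.events):
            raise ValueError("duplicate event ids in McfMatrix")
        if len(set(self.biopsies)) != len(self.biopsies):
            raise ValueError("duplicate biopsy names in McfMatrix")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("MCF values must lie in [0, 100]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, event_id: str) -> np.ndarray:
        return self.values[self.events.index(event_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.events, columns=self.biopsies)

    def subset(self, event_ids: Sequence[str]) -> "McfMatrix":
        idx = [self.events.index(e) for e in event_ids]
        return McfMatrix(list(event_ids), self.biopsies, self.values[idx])


@dataclass
class RulesMatrix:
    """Pairs (mother, daughter): the daughter event must not descend from the mother."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def forbids(self, mother: str, daughter: str) -> bool:
        return (mother, daughter) in self._pair_set

    @property
    def _pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)


def _parse_mcf_cell(value, row_no: int, column: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text == "" or text.upper() in {"NA", "NAN", "NULL"}:
        return None
    try:
        mcf = float(text)
    except ValueError as exc:
        raise SegmentFormatError(
            f"row {row_no}: MCF cell {column!r} is not numeric: {value!r}"
        ) from exc
    if not 0.0 <= mcf <= 100.0:
        raise SegmentFormatError(
            f"row {row_no}: MCF {mcf} in column {column!r} outside [0, 100]"
        )
    return mcf


def read_segment_table(
    path: str | Path, dialect: SegmentDialect | None = None
) -> tuple[list[AlterationRecord], McfMatrix]:
    """Parse a segment file into records plus the assembled MCF matrix.

    Records are returned in file order.  Row numbers in error messages
    are 1-based data rows (the header is row 0).
    """
    dialect = dialect or SegmentDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    missing = [c for c in ("chrom", "start", "end", "type") if c not in df.columns]
    if missing:
        raise SegmentFormatError(f"segment table missing required columns: {missing}")

    if dialect.mcf_columns is not None:
        biopsies = list(dialect.mcf_columns)
        unknown = [b for b in biopsies if b not in df.columns]
        if unknown:
            raise SegmentFormatError(f"configured MCF columns not in table: {unknown}")
    else:
        skip = set(_META_COLUMNS) | {"event_id"}
        biopsies = [c for c in df.columns if c not in skip]
        if dialect.mcf_prefix is not None:
            biopsies = [c for c in biopsies if c.startswith(dialect.mcf_prefix)]
    if not biopsies:
        raise SegmentFormatError("no MCF (biopsy) columns found")

    records: list[AlterationRecord] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            start = int(str(row["start"]).replace(",", ""))
            end = int(str(row["end"]).replace(",", ""))
        except ValueError as exc:
            raise SegmentFormatError(f"row {i}: malformed coordinates "
                                     f"({row['start']!r}, {row['end']!r})") from exc
        mcf = {b: _parse_mcf_cell(row[b], i, b) for b in biopsies}
        event_id = str(row.get("event_id", "") or "").strip() or f"e{i}"
        try:
            rec = AlterationRecord(
                event_id=event_id,
                chrom=str(row["chrom"]).strip(),
                start_bp=start,
                end_bp=end,
                alt_type=str(row["type"]).strip(),
                label=str(row.get("label", "") or ""),
                source=str(row.get("source", "") or "snp_array") or "snp_array",
                mcf=mcf,
            )
        except ValueError as exc:
            raise SegmentFormatError(f"row {i}: {exc}") from exc
        for b in biopsies:
            if mcf[b] is None:
                continue
            key = (rec.chrom, rec.start_bp, rec.end_bp, rec.alt_type, b)
            if key in seen:
                raise SegmentFormatError(
                    f"row {i}: duplicate of row {seen[key]} "
                    f"for (chrom={rec.chrom}, start={rec.start_bp}, end={rec.end_bp}, "
                    f"type={rec.alt_type}, biopsy={b})"
                )
            seen[key] = i
        records.append(rec)

    if len({r.event_id for r in records}) != len(records):
        raise SegmentFormatError("duplicate event_id values in segment table")
    values = np.array(
        [[np.nan if r.mcf[b] is None else r.mcf[b] for b in biopsies] for r in records],
        dtype=float,
    ).reshape(len(records), len(biopsies))
    matrix = McfMatrix([r.event_id for r in records], biopsies, values)
    return records, matrix


def write_segment_table(
    records: Iterable[AlterationRecord],
    biopsies: Sequence[str],
    path: str | Path,
) -> None:
    """Write records in the canonical dialect (missing MCF -> empty cell)."""
    rows = []
    for r in records:
        row = {
            "event_id": r.event_id,
            "chrom": r.chrom,
            "start": r.start_bp,
            "end": r.end_bp,
            "type": r.alt_type,
            "label": r.label,
            "source": r.source,
        }
        for b in biopsies:
            v = r.mcf.get(b)
            row[b] = "" if v is None else f"{v:g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rules(path: str | Path, known_events: Iterable[str] | None = None) -> RulesMatrix:
    """Read a two-column mother/daughter table of forbidden orderings.

    An empty file yields an empty matrix (no constraints).  Self-pairs
    are rejected; if ``known_events`` is given, unknown ids are rejected
    listing the offenders.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        return RulesMatrix([])
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise SegmentFormatError("rules table must have two columns (mother, daughter)")
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if first[:2] == ["mother", "daughter"]:
        df = df.iloc[1:]
    pairs: list[tuple[str, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        mother, daughter = str(row[0]).strip(), str(row[1]).strip()
        if mother == daughter:
            raise SegmentFormatError(f"rules row {i}: self-pair ({mother!r})")
        pairs.append((mother, daughter))
    if known_events is not None:
        known = set(known_events)
        unknown = sorted({e for p in pairs for e in p if e not in known})
        if unknown:
            raise SegmentFormatError(f"rules reference unknown event ids: {unknown}")
    return RulesMatrix(pairs)


def write_newick(tree, path: str | Path) -> None:
    """Serialize a rooted phylogeny (branch lengths in alterations).

    Child order is lexicographic so output is reproducible.
    """
    from .phylogeny import Phylogeny  # deferred: avoids an import cycle

    if not isinstance(tree, Phylogeny):
        raise TypeError("write_newick expects a Phylogeny")
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_newick(path: str | Path):
    from .phylogeny import Phylogeny

    return Phylogeny.from_newick(Path(path).read_text(encoding="utf-8"))


def write_event_matrix(event_df: pd.DataFrame, path: str | Path) -> None:
    """Binary events x subclones matrix as TSV (index = event ids)."""
    event_df.astype(int).to_csv(path, sep="\t", index_label="event_id")


def write_fractions(frac_df: pd.DataFrame, path: str | Path) -> None:
    """Subclone x biopsy percentage table as TSV."""
    frac_df.to_csv(path, sep="\t", index_label="subclone", float_format="%.4f")
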