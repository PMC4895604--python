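"""On-disk formats: editing-site TSV, candidate/feature TSV, BED regions.

Every writer emits a header line beginning with ``#`` so files are
self-describing; every reader/writer pair round-trips exactly on its valid
domain.  Site lists are 1-based; BED is 0-based half-open and used only for
region exchange (error-prone regions, repeat masks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import pandas as pd

from .sites import BASES, STRANDS, EDIT_TYPES, EditingSiteDB

#: the 15 read-alignment-pattern attributes, in canonical column order.
FEATURE_ORDER = [
    "ReadDepth", "VAF", "SGB", "FQ", "CallQual",
    "PV3", "MQB", "MQ0F", "MQ", "VDB",
    "RPB", "PV4", "PV2", "BQB", "PV1",
]

#: attribute -> read-alignment-pattern category.
FEATURE_CATEGORY = {
    "ReadDepth": "Read depth",
    "VAF": "Allele segregation",
    "SGB": "Allele segregation",
    "FQ": "Allele segregation",
    "CallQual": "Allele segregation",
    "PV3": "Mapping quality",
    "MQB": "Mapping quality",
    "MQ0F": "Mapping quality",
    "MQ": "Mapping quality",
    "VDB": "Read position",
    "RPB": "Read position",
    "PV4": "Read position",
    "PV2": "Base quality",
    "BQB": "Base quality",
    "PV1": "Read strand",
}

SITE_COLUMNS = ["chrom", "pos", "strand", "ref", "alt", "depth", "alt_count"]


class ParseError(ValueError):
    """A malformed row in a tab-separated input, reported with its line number."""


class SchemaError(ValueError):
    """A tabular file missing required columns."""


# ---------------------------------------------------------------------------
# editing-site databases (DARNED / RADAR style TSV)
# ---------------------------------------------------------------------------

_DB_ALIASES = {
    "chrom": {"chrom", "chromosome", "chr"},
    "position": {"position", "pos", "coordinate"},
    "strand": {"strand"},
    "type": {"type", "edit_type", "editing_type"},
}


def _resolve_columns(header: Sequence[str]) -> dict:
    lowered = [h.lower().lstrip("#") for h in header]
    out = {}
    for canon, aliases in _DB_ALIASES.items():
        for i, name in enumerate(lowered):
            if name in aliases:
                out[canon] = i
                break
        else:
            raise SchemaError(f"editing DB header lacks a {canon!r} column: {header}")
    return out


def read_editing_db(path, source_tag: str = "") -> EditingSiteDB:
    """Parse a known-editing-site table (chrom, position, strand, type).

    Duplicate (chrom, pos, strand) rows are collapsed with a warning giving
    the duplicate count; malformed strands, types or positions raise
    :class:`ParseError` naming the offending line.
    """
    db = EditingSiteDB(source_tag=source_tag or str(path))
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if header is None:
                header = _resolve_columns(fields)
                continue
            try:
                pos = int(fields[header["position"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: bad position field: {line!r}") from exc
            strand = fields[header["strand"]]
            if strand not in STRANDS:
                raise ParseError(f"line {lineno}: strand must be + or -, got {strand!r}")
            edit_type = fields[header["type"]]
            if edit_type not in EDIT_TYPES:
                raise ParseError(f"line {lineno}: unknown edit type {edit_type!r}")
            db.add(fields[header["chrom"]], pos, strand, edit_type)
    if header is None:
        raise SchemaError(f"{path}: empty file without header")
    if db.n_duplicates:
        warnings.warn(f"{path}: collapsed {db.n_duplicates} duplicate site rows")
    return db


def write_editing_db(db: EditingSiteDB, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tposition\tstrand\ttype\n")
        for (chrom, pos, strand), edit_type in sorted(db.entries.items()):
            fh.write(f"{chrom}\t{pos}\t{strand}\t{edit_type}\n")


# ---------------------------------------------------------------------------
# candidate tables (sites + 15 features)
# ---------------------------------------------------------------------------

@dataclass
class CandidateTable:
    """Raw RDD candidates: one row per (chrom, pos) with supporting counts
    and, once computed, the 15 feature columns."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    n_multiallelic_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_features(self) -> bool:
        return all(c in self.df.columns for c in FEATURE_ORDER)


def write_candidates(table: CandidateTable, path) -> None:
    cols = SITE_COLUMNS + [c for c in FEATURE_ORDER if c in table.df.columns]
    df = table.df[cols]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for row in df.itertuples(index=False):
            out = []
            for v in row:
                if isinstance(v, float):
                    out.append(repr(v))  # full precision round-trip
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")


def read_candidates(path, require_features: bool = False) -> CandidateTable:
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise SchemaError(f"{path}: empty candidate file")
        cols = header_line.lstrip("#").split("\t")
        missing = [c for c in SITE_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"{path}: missing site columns {missing}")
        has_any_feature = any(c in cols for c in FEATURE_ORDER)
        if require_features or has_any_feature:
            missing = [c for c in FEATURE_ORDER if c not in cols]
            if missing:
                raise SchemaError(f"{path}: missing feature columns {missing}")
        df = pd.read_csv(fh, sep="\t", names=cols, dtype={"chrom": str},
                         float_precision="round_trip")
    if df.empty:
        df = pd.DataFrame(columns=cols)
    df["pos"] = df["pos"].astype(int)
    return CandidateTable(df=df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# BED regions (0-based half-open), used for error-prone-region exchange
# ---------------------------------------------------------------------------

Region = Tuple[str, int, int]


def merge_regions(regions: Iterable[Region]) -> List[Region]:
    """Sort and merge overlapping or book-ended intervals per chromosome."""
    out: List[Region] = []
    for chrom, start, end in sorted(regions):
        if start >= end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end} (start >= end)")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


def site_to_bed(pos: int) -> Tuple[int, int]:
    """1-based single-base site -> 0-based half-open interval."""
    return pos - 1, pos


def bed_to_site(start: int) -> int:
    """0-based interval start -> 1-based position of its first base."""
    return start + 1


def write_bed_regions(regions: Iterable[Region], path) -> List[Region]:
    merged = merge_regions(regions)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\n")
        for chrom, start, end in merged:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return merged


def read_bed_regions(path) -> List[Region]:
    regions: List[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {lineno}: bad BED row {line!r}") from exc
            if start >= end:
                raise ParseError(f"line {lineno}: start >= end in {line!r}")
            regions.append((chrom, start, end))
    return merge_regions(regions)
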