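"""Core genomic-site types shared across the pipeline.

Coordinates are 1-based and strand-explicit throughout the package (the
DARNED/RADAR convention); BED's 0-based half-open intervals appear only at
the file boundary in :mod:`rddkit.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

BASES = ("A", "C", "G", "T")
STRANDS = ("+", "-")
EDIT_TYPES = ("A-to-I", "C-to-U")

#: genomic (ref, alt) implied by an edit type on a given strand.  A-to-I
#: editing reads as A>G on the annotated strand, hence T>C on the genomic
#: plus strand when the edited transcript is on minus; likewise C-to-U
#: reads as C>T / G>A.
EDIT_CLASS = {
    ("A-to-I", "+"): ("A", "G"),
    ("A-to-I", "-"): ("T", "C"),
    ("C-to-U", "+"): ("C", "T"),
    ("C-to-U", "-"): ("G", "A"),
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A strand-aware single-base substitution: the pipeline's join key."""

    chrom: str
    pos: int  # 1-based
    strand: str
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError(
                f"bases must be A/C/G/T, got {self.ref_base!r}>{self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt are both {self.ref_base!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.strand)

    @property
    def substitution(self) -> str:
        """ref>alt on the annotated strand — one of the 12 classes."""
        return f"{self.ref_base}>{self.alt_base}"


@dataclass
class EditingSiteDB:
    """A curated set of known editing sites (DARNED/RADAR style).

    Rows are keyed by (chrom, pos, strand); a row records the edit type
    (A-to-I or C-to-U) rather than an explicit alt allele, so candidate
    matching goes through substitution-class compatibility.
    """

    entries: dict = field(default_factory=dict)  # (chrom,pos,strand) -> edit type
    source_tag: str = ""
    n_duplicates: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple) -> bool:
        return key in self.entries

    def add(self, chrom: str, pos: int, strand: str, edit_type: str) -> bool:
        """Add a row; returns False (and counts a duplicate) if already present."""
        if edit_type not in EDIT_TYPES:
            raise ValueError(f"unknown edit type {edit_type!r}")
        if strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {strand!r}")
        key = (chrom, int(pos), strand)
        if key in self.entries:
            self.n_duplicates += 1
            return False
        self.entries[key] = edit_type
        return True

    def matches(self, chrom: str, pos: int, ref: str, alt: str,
                mode: str = "class") -> bool:
        """Does a candidate substitution match a database row?

        mode="class": the row's (edit type, strand) must imply exactly the
        candidate's genomic ref>alt (A>G for A-to-I/+, T>C for A-to-I/-, ...).
        mode="position": any row at (chrom, pos) matches regardless of allele.
        """
        for strand in STRANDS:
            edit_type = self.entries.get((chrom, pos, strand))
            if edit_type is None:
                continue
            if mode == "position":
                return True
            if EDIT_CLASS[(edit_type, strand)] == (ref, alt):
                return True
        if mode not in ("class", "position"):
            raise ValueError(f"unknown matching mode {mode!r}")
        return False

    def positions(self) -> set:
        return {(c, p) for (c, p, _s) in self.entries}


def consensus(db_a: EditingSiteDB, db_b: EditingSiteDB) -> EditingSiteDB:
    """Intersection of two databases on (chrom, pos, strand).

    Edit types are taken from the first database; a shared key with a
    conflicting type in the second is dropped (it cannot be a consensus call).
    """
    out = EditingSiteDB(source_tag="consensus")
    for key, edit_type in db_a.entries.items():
        other = db_b.entries.get(key)
        if other == edit_type:
            out.entries[key] = edit_type
    return out
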