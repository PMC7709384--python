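"""Shared domain types and coordinate conventions.

Conventions used throughout the package:

* CpG positions are 1-based (the Bismark coverage convention); every
  interval type is 0-based half-open (the BED convention).  The two
  converters below are exact inverses.
* Strand is one of ``+``, ``-`` or ``.`` (unknown).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class SiteCounts:
    """Methylated/unmethylated read counts at one cytosine.

    ``pos`` is the 1-based genomic position of the C.  ``n_meth`` is the
    number of reads reporting C (methylated, bisulfite-protected) and
    ``n_unmeth`` the number reporting T.
    """

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError(
                f"counts must be non-negative, got ({self.n_meth}, {self.n_unmeth})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def n_total(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos: int) -> bool:
        """True if the 1-based position ``pos`` falls inside the interval."""
        return self.start < pos <= self.end


def pos_to_bed(pos: int) -> tuple[int, int]:
    """1-based point position -> 0-based half-open single-base interval."""
    return pos - 1, pos


def bed_to_pos(start: int) -> int:
    """0-based interval start -> 1-based position of that base."""
    return start + 1


@dataclass(frozen=True)
class GeneModel:
    """One transcript: TSS/TTS, exon blocks and (optionally) UTRs.

    ``start``/``end`` are 0-based half-open transcript bounds.  The TSS is
    the 5' end in transcript orientation: ``start`` on the plus strand,
    ``end`` on the minus strand (as a 0-based coordinate of the boundary).
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"exon [{s},{e}) outside transcript bounds of {self.name}"
                )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)
                if ex[i + 1][0] > ex[i][1]]

    def utr_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'UTR intervals, 3'UTR intervals), empty when no CDS annotated."""
        if self.cds_start is None or self.cds_end is None or self.cds_start >= self.cds_end:
            return [], []
        left, right = [], []
        for s, e in self.exons:
            if s < self.cds_start:
                left.append((s, min(e, self.cds_start)))
            if e > self.cds_end:
                right.append((max(s, self.cds_end), e))
        if self.strand == "+":
            return left, right
        return right, left


@dataclass
class ElementInstance:
    """One genomic copy of a repeat element.

    ``consensus_start``/``consensus_end`` are 1-based positions on the
    subfamily consensus sequence covered by this instance (RepeatMasker
    repStart/repEnd); ``None`` when the source table lacked them, in which
    case consensus projection refuses the instance.
    """

    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    subfamily: str
    repeat_class: str
    consensus_start: Optional[int] = None
    consensus_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def has_consensus(self) -> bool:
        return self.consensus_start is not None and self.consensus_end is not None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               self.strand, self.subfamily)

    def contains_pos(self, pos: int) -> bool:
        return self.start < pos <= self.end


_CHROM_RE = re.compile(r"^(chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def chromosome_sort_key(chrom: str) -> tuple[int, float, str]:
    """Natural chromosome order: chr1..chr19, chrX, chrY, chrM, then others."""
    m = _CHROM_RE.match(chrom)
    if m:
        tag = m.group(2).upper()
        if tag.isdigit():
            return (0, int(tag), chrom)
        special = {"X": 100, "Y": 101, "M": 102, "MT": 102}
        return (0, special[tag], chrom)
    return (1, 0, chrom)
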