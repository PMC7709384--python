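"""Readers and writers for the external formats the pipeline touches.

Supported formats:

* Bismark coverage files (``.cov``): tab-separated
  ``chrom  start  end  percent_methylated  count_methylated  count_unmethylated``
  with 1-based start == end.  The percent column is ignored on input and
  recomputed from counts on output.
* BED3/BED6/BED12 (0-based half-open).
* Repeat tables: either a HOMER-style BED-like annotation table or
  RepeatMasker ``.out``, selected by a dialect flag.
* FASTA (via Biopython) for consensus and genome sequences.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO

from .core import ElementInstance, GeneModel, GenomicInterval, SiteCounts

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input row; message carries the file and line number."""


def _open_text(path: PathLike):
    if isinstance(path, io.TextIOBase):
        return path
    return open(path, "rt", encoding="utf-8")


# ---------------------------------------------------------------------------
# Bismark coverage
# ---------------------------------------------------------------------------

def read_coverage_file(path: PathLike) -> list[SiteCounts]:
    """Read a Bismark-coverage-dialect file into SiteCounts records.

    Raises :class:`ParseError` naming the offending line for malformed rows
    and ``ValueError`` for invariant violations (negative counts).
    """
    sites: list[SiteCounts] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, _end_s, _pct, meth_s, unmeth_s = fields
            try:
                pos = int(start_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from exc
            try:
                sites.append(SiteCounts(chrom, pos, n_meth, n_unmeth))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_coverage_file(path: PathLike, sites: Iterable[SiteCounts]) -> None:
    """Write SiteCounts in Bismark coverage dialect (percent recomputed)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for s in sites:
            pct = 100.0 * s.n_meth / s.n_total if s.n_total else 0.0
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos}\t{pct:g}\t{s.n_meth}\t{s.n_unmeth}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 into GenomicInterval records (0-based half-open)."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in {"+", "-"} else "."
            try:
                out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path: PathLike, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: PathLike) -> list[GeneModel]:
    """Read BED12 transcripts into GeneModel records.

    thickStart/thickEnd delimit the CDS; a zero-length thick region means a
    non-coding transcript (no UTRs).  Blocks outside the transcript bounds
    raise a validation error.
    """
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + sz) for o, sz in zip(starts, sizes))
            cds = (thick_start, thick_end) if thick_end > thick_start else (None, None)
            try:
                genes.append(GeneModel(name, chrom, start, end, strand, exons,
                                       cds_start=cds[0], cds_end=cds[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_models(path: PathLike, genes: Iterable[GeneModel]) -> None:
    """Write GeneModel records as BED12."""
    with open(path, "wt", encoding="utf-8") as fh:
        for g in genes:
            ex = sorted(g.exons)
            sizes = ",".join(str(e - s) for s, e in ex) + ","
            starts = ",".join(str(s - g.start) for s, e in ex) + ","
            cs = g.cds_start if g.cds_start is not None else g.start
            ce = g.cds_end if g.cds_end is not None else g.start
            fh.write("\t".join(map(str, [
                g.chrom, g.start, g.end, g.name, 0, g.strand,
                cs, ce, 0, len(ex), sizes, starts,
            ])) + "\n")


# ---------------------------------------------------------------------------
# Repeat tables
# ---------------------------------------------------------------------------

_HOMER_HEADER = ["chrom", "start", "end", "subfamily", "class", "strand",
                 "consensus_start", "consensus_end"]


def read_repeat_table(path: PathLike, dialect: str = "homer") -> list[ElementInstance]:
    """Read a repeat catalog into ElementInstance records.

    dialect="homer": tab-separated BED-like table with columns
    ``chrom start end subfamily class strand [consensus_start consensus_end]``
    (0-based half-open genomic, 1-based consensus).  A header line starting
    with ``chrom`` is skipped.

    dialect="rmsk": RepeatMasker ``.out``: whitespace-delimited with the
    standard 3-line header; strand ``C`` means minus, and for minus-strand
    hits repStart/repEnd come from the "(left) end begin" triplet.
    """
    if dialect == "homer":
        return _read_homer_repeats(path)
    if dialect == "rmsk":
        return _read_rmsk_out(path)
    raise ValueError(f"unknown repeat table dialect {dialect!r}")


def _read_homer_repeats(path: PathLike) -> list[ElementInstance]:
    out: list[ElementInstance] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: need >= 6 columns, got {len(f)}")
            cons: tuple[Optional[int], Optional[int]] = (None, None)
            if len(f) >= 8 and f[6] not in ("", ".") and f[7] not in ("", "."):
                cons = (int(f[6]), int(f[7]))
            try:
                out.append(ElementInstance(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    strand=f[5] if f[5] in {"+", "-"} else ".",
                    subfamily=f[3], repeat_class=f[4],
                    consensus_start=cons[0], consensus_end=cons[1],
                ))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def _read_rmsk_out(path: PathLike) -> list[ElementInstance]:
    out: list[ElementInstance] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.split()
            if not f or not f[0].replace(".", "").isdigit():
                continue  # header / blank lines
            if len(f) < 14:
                raise ParseError(f"{path}:{lineno}: truncated RepeatMasker row")
            chrom = f[4]
            start = int(f[5]) - 1  # .out is 1-based inclusive
            end = int(f[6])
            strand = "+" if f[8] == "+" else "-"
            subfamily, repclass = f[9], f[10]
            if strand == "+":
                rep_start, rep_end = f[11], f[12]
            else:
                rep_start, rep_end = f[13], f[12]
            try:
                cs = int(rep_start.strip("()"))
                ce = int(rep_end.strip("()"))
                cons: tuple[Optional[int], Optional[int]] = (cs, ce)
            except ValueError:
                cons = (None, None)
            out.append(ElementInstance(
                chrom=chrom, start=start, end=end, strand=strand,
                subfamily=subfamily, repeat_class=repclass,
                consensus_start=cons[0], consensus_end=cons[1],
            ))
    return out


def write_repeat_table(path: PathLike, elements: Iterable[ElementInstance]) -> None:
    """Write ElementInstance records in the HOMER-style dialect."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_HOMER_HEADER) + "\n")
        for e in elements:
            cs = e.consensus_start if e.consensus_start is not None else "."
            ce = e.consensus_end if e.consensus_end is not None else "."
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.subfamily}\t"
                     f"{e.repeat_class}\t{e.strand}\t{cs}\t{ce}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
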