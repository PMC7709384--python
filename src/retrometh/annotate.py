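"""Two-level genomic annotation of CpGs, DMCs and DMRs.

Basic annotation assigns each position one gene-model context with the
fixed precedence

    promoter-TSS > TTS > 5UTR > 3UTR > exon > intron > intergenic

using strand-aware windows around the TSS (default -1000..+100 bp) and the
TTS (default -100..+1000 bp).  Detailed annotation then replaces the basic
label with the repeat subfamily when the position falls inside a repeat
instance; when repeats nest or overlap, the smallest instance wins (ties
broken by lower start), reporting the most specific element.  The repeat
group (LINE / LTR / SINE / other-repeat / non-repeat) is derived from the
repeat class string via an editable TSV prefix map shipped with the
package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .core import ElementInstance, GeneModel

PROMOTER = "promoter-TSS"
TTS = "TTS"
UTR5 = "5UTR"
UTR3 = "3UTR"
EXON = "exon"
INTRON = "intron"
INTERGENIC = "intergenic"

BASIC_PRECEDENCE = (PROMOTER, TTS, UTR5, UTR3, EXON, INTRON)

NON_REPEAT = "non-repeat"
OTHER_REPEAT = "other-repeat"


@dataclass(frozen=True)
class AnnotationLabel:
    basic: str
    detailed: str
    group: str


def load_group_map(path: Optional[Union[str, Path]] = None) -> dict[str, str]:
    """Load the repeat class-prefix -> group map (TSV, header line)."""
    if path is None:
        src = resources.files("retrometh").joinpath("data/repeat_groups.tsv")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    out: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        prefix, group = line.split("\t")[:2]
        out[prefix.upper()] = group
    return out


def repeat_group(repeat_class: str, group_map: Optional[dict[str, str]] = None) -> str:
    """Map a repeat class string (e.g. ``LINE/L1``) to its display group."""
    if group_map is None:
        group_map = load_group_map()
    head = repeat_class.split("/")[0].strip().upper()
    if head in group_map:
        return group_map[head]
    for part in repeat_class.upper().replace("/", " ").split():
        if part in group_map:
            return group_map[part]
    return OTHER_REPEAT


class Annotator:
    """Pre-indexed gene models and repeat catalog for position queries."""

    def __init__(
        self,
        gene_models: Sequence[GeneModel],
        repeats: Sequence[ElementInstance] = (),
        promoter_window: tuple[int, int] = (-1000, 100),
        tts_window: tuple[int, int] = (-100, 1000),
        group_map: Optional[dict[str, str]] = None,
    ) -> None:
        self.promoter_window = promoter_window
        self.tts_window = tts_window
        self.group_map = group_map or load_group_map()
        self._basic: dict[str, dict[str, IntervalTree]] = {
            lab: {} for lab in BASIC_PRECEDENCE
        }
        for g in gene_models:
            self._index_gene(g)
        self._repeats: dict[str, IntervalTree] = {}
        for el in repeats:
            self._repeats.setdefault(el.chrom, IntervalTree()).addi(
                el.start, el.end, el
            )

    def _add(self, label: str, chrom: str, start: int, end: int) -> None:
        if end > start:
            self._basic[label].setdefault(chrom, IntervalTree()).addi(start, end)

    def _index_gene(self, g: GeneModel) -> None:
        up, down = self.promoter_window
        if g.strand == "+":
            self._add(PROMOTER, g.chrom, g.tss + up, g.tss + down)
        else:
            self._add(PROMOTER, g.chrom, g.tss - down, g.tss - up)
        t_up, t_down = self.tts_window
        if g.strand == "+":
            self._add(TTS, g.chrom, g.tts + t_up, g.tts + t_down)
        else:
            self._add(TTS, g.chrom, g.tts - t_down, g.tts - t_up)
        utr5, utr3 = g.utr_intervals()
        for s, e in utr5:
            self._add(UTR5, g.chrom, s, e)
        for s, e in utr3:
            self._add(UTR3, g.chrom, s, e)
        for s, e in g.exons:
            self._add(EXON, g.chrom, s, e)
        for s, e in g.introns():
            self._add(INTRON, g.chrom, s, e)

    # -- queries ----------------------------------------------------------

    def annotate_basic(self, chrom: str, pos: int) -> str:
        """Basic gene-context label of a 1-based position."""
        point = pos - 1
        for label in BASIC_PRECEDENCE:
            tree = self._basic[label].get(chrom)
            if tree is not None and tree.overlaps_point(point):
                return label
        return INTERGENIC

    def repeat_at(self, chrom: str, pos: int) -> Optional[ElementInstance]:
        """Smallest repeat instance covering the 1-based position, if any."""
        tree = self._repeats.get(chrom)
        if tree is None:
            return None
        hits = tree[pos - 1]
        if not hits:
            return None
        best = min(hits, key=lambda iv: (iv.end - iv.begin, iv.begin))
        return best.data

    def annotate_detailed(self, chrom: str, pos: int,
                          basic_label: Optional[str] = None) -> AnnotationLabel:
        """Full two-level label of a 1-based position."""
        if basic_label is None:
            basic_label = self.annotate_basic(chrom, pos)
        el = self.repeat_at(chrom, pos)
        if el is None:
            return AnnotationLabel(basic_label, basic_label, NON_REPEAT)
        return AnnotationLabel(
            basic_label, el.subfamily, repeat_group(el.repeat_class, self.group_map)
        )

    def annotate_sites(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Annotate a site table (columns chrom, pos) -> adds basic/detailed/group."""
        labels = [
            self.annotate_detailed(c, int(p))
            for c, p in zip(sites["chrom"], sites["pos"])
        ]
        out = sites.copy()
        out["basic"] = [l.basic for l in labels]
        out["detailed"] = [l.detailed for l in labels]
        out["group"] = [l.group for l in labels]
        return out

    def annotate_intervals(self, intervals: pd.DataFrame) -> pd.DataFrame:
        """Annotate intervals (columns chrom, start, end; BED) by midpoint."""
        out = intervals.copy()
        if out.empty:
            for col in ("midpoint", "basic", "detailed", "group"):
                out[col] = pd.Series(dtype=object)
            return out
        mid_pos = ((out["start"] + out["end"]) // 2 + 1).astype(int)  # 1-based
        labels = [
            self.annotate_detailed(c, int(p))
            for c, p in zip(out["chrom"], mid_pos)
        ]
        out["midpoint"] = mid_pos
        out["basic"] = [l.basic for l in labels]
        out["detailed"] = [l.detailed for l in labels]
        out["group"] = [l.group for l in labels]
        return out


def dmrs_near_tss(
    dmrs: pd.DataFrame, gene_models: Sequence[GeneModel], window: int = 2000
) -> pd.DataFrame:
    """DMRs whose midpoint lies within +-window of a TSS.

    Adds the nearest gene and the signed midpoint-to-TSS distance
    (negative = upstream of the TSS in gene orientation).  Ties in absolute
    distance resolve to the TSS at the lower genomic coordinate.
    """
    tss_by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}
    for g in gene_models:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g))
    rows = []
    for _, dmr in dmrs.iterrows():
        mid = int((dmr["start"] + dmr["end"]) // 2)  # 0-based midpoint
        best = None
        for tss, g in sorted(tss_by_chrom.get(dmr["chrom"], [])):
            d_abs = abs(mid - tss)
            if best is None or d_abs < best[0]:
                best = (d_abs, tss, g)
        if best is None or best[0] > window:
            continue
        _, tss, g = best
        signed = (mid - tss) if g.strand == "+" else (tss - mid)
        row = dict(dmr)
        row["gene"] = g.name
        row["distance"] = int(signed)
        rows.append(row)
    cols = list(dmrs.columns) + ["gene", "distance"]
    return pd.DataFrame(rows, columns=cols)
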