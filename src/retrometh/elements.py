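"""Element-relative positional analysis of retrotransposon methylation.

This module projects differentially methylated cytosines into the
coordinate frame of individual repeat copies and of their subfamily
consensus, classifies element structure, and scans promoter sequences for
motifs:

* L1 (LINE-1) elements: full-length detection (catalog overlap or length
  fallback) and assignment of element offsets to the promoter (tandem
  ~200 bp monomers + 203 bp 5'UTR), ORF1, ORF2 and 3'UTR domains.
* IAP-type LTR elements: classification of each genomic fragment as
  5'LTR, 3'LTR, solo LTR or internal segment from its neighborhood, and
  subdivision of the LTR into U3 / R / U5 using sequence landmarks (R
  starts just after the TATA box; R ends at the end of the
  polyadenylation signal AATAAA).
* Consensus profiles: per-consensus-position DMC counts across all copies
  of a subfamily, with hot spots where counts reach a minimum recurrence.
* PWM scanning (JASPAR-style relative score) and approximate
  motif search by sliding-window identity.

Consensus projection assumes the instance is colinear with its consensus
(no indels); offsets are measured from the element's 5' end in element
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ElementInstance, GenomicInterval

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FIVE_LTR = "5LTR"
THREE_LTR = "3LTR"
SOLO_LTR = "soloLTR"
INTERNAL = "internal"
FRAGMENT_KINDS = (FIVE_LTR, THREE_LTR, SOLO_LTR, INTERNAL)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Element-relative coordinates
# ---------------------------------------------------------------------------

def element_relative_position(
    pos: int, element: ElementInstance
) -> tuple[int, Optional[int]]:
    """(offset from element 5' end, consensus position) of a 1-based site.

    Offsets are 1-based: the first base of the element (in element
    orientation) is offset 1.  The consensus position additionally shifts
    by the instance's consensus_start; it is ``None`` when the instance
    lacks consensus offsets.
    """
    if not element.contains_pos(pos):
        raise ValueError(
            f"position {pos} outside element "
            f"{element.chrom}:{element.start}-{element.end}"
        )
    if element.strand == "-":
        offset = element.end - pos + 1
    else:
        offset = pos - element.start
    cons = None
    if element.has_consensus:
        cons = element.consensus_start + offset - 1
    return offset, cons


def genomic_position_of_offset(offset: int, element: ElementInstance) -> int:
    """Inverse of :func:`element_relative_position` (1-based genomic pos)."""
    if not 1 <= offset <= len(element):
        raise ValueError(f"offset {offset} outside element of length {len(element)}")
    if element.strand == "-":
        return element.end - offset + 1
    return element.start + offset


# ---------------------------------------------------------------------------
# L1 structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class L1Structure:
    """Element-relative domain map of a full-length L1.

    The promoter is ``n_monomers`` tandem monomers (~200 bp each) followed
    by the 203 bp 5'UTR; ORF1, ORF2 and the 3'UTR follow in order.
    """

    n_monomers: int = 2
    monomer_length: int = 200
    utr5_length: int = 203
    orf1_length: int = 1014
    orf2_length: int = 3828
    utr3_length: int = 600

    def domain_spans(self) -> dict[str, tuple[int, int]]:
        """1-based inclusive element-relative spans, 5' to 3'."""
        spans: dict[str, tuple[int, int]] = {}
        pos = 1
        mono_end = pos + self.n_monomers * self.monomer_length - 1
        spans["monomer"] = (pos, mono_end)
        pos = mono_end + 1
        spans["5UTR"] = (pos, pos + self.utr5_length - 1)
        pos = spans["5UTR"][1] + 1
        spans["ORF1"] = (pos, pos + self.orf1_length - 1)
        pos = spans["ORF1"][1] + 1
        spans["ORF2"] = (pos, pos + self.orf2_length - 1)
        pos = spans["ORF2"][1] + 1
        spans["3UTR"] = (pos, pos + self.utr3_length - 1)
        return spans

    @property
    def length(self) -> int:
        return self.domain_spans()["3UTR"][1]

    def domain_of(self, offset: int) -> str:
        """Domain label of a 1-based element offset; monomers report as
        'monomer' (the promoter together with the 5'UTR)."""
        for name, (s, e) in self.domain_spans().items():
            if s <= offset <= e:
                return name
        raise ValueError(f"offset {offset} beyond L1 structure of length {self.length}")


def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def classify_l1(
    element: ElementInstance,
    full_length_catalog: Optional[Sequence[GenomicInterval]] = None,
    min_length: int = 6000,
    min_reciprocal_overlap: float = 0.9,
) -> bool:
    """True when the L1 instance is full-length (retrotransposition-capable
    architecture).

    With a catalog of known full-length elements, the instance must overlap
    a catalog entry reciprocally by >= 90%; without one, a length threshold
    (default 6 kb) is the fallback.
    """
    if not element.repeat_class.upper().startswith("LINE"):
        raise ValueError(f"classify_l1 requires a LINE/L1 instance, "
                         f"got class {element.repeat_class!r}")
    if full_length_catalog is not None:
        return any(
            iv.chrom == element.chrom
            and _reciprocal_overlap(element.start, element.end, iv.start, iv.end)
            >= min_reciprocal_overlap
            for iv in full_length_catalog
        )
    return len(element) >= min_length


# ---------------------------------------------------------------------------
# IAP / LTR fragment classification
# ---------------------------------------------------------------------------

def _is_internal(element: ElementInstance) -> bool:
    return "-int" in element.subfamily or element.subfamily.endswith("_I")


def classify_iap_fragment(
    element: ElementInstance,
    neighbors: Sequence[ElementInstance],
    max_join_gap: int = 50,
) -> str:
    """Classify an LTR-class fragment as 5'LTR, 3'LTR, solo LTR or internal.

    An LTR fragment adjacent (gap <= max_join_gap, same chromosome and
    strand) to an internal segment on its downstream side (element
    orientation) is a 5'LTR; adjacent on its upstream side, a 3'LTR; with
    internal segments on both sides the consensus orientation breaks the
    tie in favor of 5'LTR; an isolated LTR is a solo LTR.
    """
    if not element.repeat_class.upper().startswith(("LTR", "ERV")):
        raise ValueError(f"classify_iap_fragment requires an LTR-class instance, "
                         f"got class {element.repeat_class!r}")
    if _is_internal(element):
        return INTERNAL

    has_down = has_up = False
    for nb in neighbors:
        if nb is element or nb.chrom != element.chrom or nb.strand != element.strand:
            continue
        if not _is_internal(nb):
            continue
        if 0 <= nb.start - element.end <= max_join_gap:
            gap_right = True
        elif 0 <= element.start - nb.end <= max_join_gap:
            gap_right = False
        else:
            continue
        # genomic right is downstream for + strand, upstream for -
        downstream = gap_right if element.strand != "-" else not gap_right
        if downstream:
            has_down = True
        else:
            has_up = True

    if has_down and has_up:
        return FIVE_LTR  # ambiguity tie-break: LTR preceding an internal segment
    if has_down:
        return FIVE_LTR
    if has_up:
        return THREE_LTR
    return SOLO_LTR


def fragment_composition(
    dmc_elements: Sequence[ElementInstance],
    catalog: Sequence[ElementInstance],
    max_join_gap: int = 50,
) -> pd.DataFrame:
    """Counts and proportions of DMC-bearing fragments per fragment kind.

    ``dmc_elements``: one entry per DMC, the fragment the DMC falls in
    (entries repeat when one fragment carries several DMCs).
    """
    counts = {k: 0 for k in FRAGMENT_KINDS}
    for el in dmc_elements:
        counts[classify_iap_fragment(el, catalog, max_join_gap)] += 1
    total = sum(counts.values())
    return pd.DataFrame({
        "fragment_kind": list(counts),
        "n_dmc": list(counts.values()),
        "proportion": [c / total if total else np.nan for c in counts.values()],
    })


# ---------------------------------------------------------------------------
# LTR U3 / R / U5 domains
# ---------------------------------------------------------------------------

TATA_BOX = "ATTATAAGA"
POLYA_SIGNAL = "AATAAA"


@dataclass(frozen=True)
class LtrAnnotation:
    """U3/R/U5 boundaries of one LTR (1-based, inclusive).

    R spans [r_start, r_end]; U3 is everything before, U5 everything after.
    """

    length: int
    r_start: int
    r_end: int

    def __post_init__(self) -> None:
        if not 1 < self.r_start <= self.r_end < self.length:
            raise ValueError("require 1 < r_start <= r_end < length")

    @classmethod
    def from_sequence(cls, seq: str, tata: str = TATA_BOX,
                      polya: str = POLYA_SIGNAL) -> "LtrAnnotation":
        """Locate domains from landmarks: R begins immediately after the
        TATA-box region; R ends at the end of the polyadenylation signal."""
        seq = seq.upper()
        i = seq.find(tata)
        if i < 0:
            raise ValueError("TATA box not found in LTR sequence")
        r_start = i + len(tata) + 1  # 1-based position after the TATA box
        j = seq.find(polya, r_start - 1)
        if j < 0:
            raise ValueError("polyadenylation signal not found downstream of TATA")
        r_end = j + len(polya)  # 1-based end of AATAAA
        return cls(length=len(seq), r_start=r_start, r_end=r_end)


def ltr_domain_of(offset: int, annotation: LtrAnnotation) -> str:
    """U3 / R / U5 label of a 1-based LTR offset."""
    if not 1 <= offset <= annotation.length:
        raise ValueError(f"offset {offset} beyond LTR length {annotation.length}")
    if offset < annotation.r_start:
        return "U3"
    if offset <= annotation.r_end:
        return "R"
    return "U5"


# ---------------------------------------------------------------------------
# Consensus profiles
# ---------------------------------------------------------------------------

@dataclass
class ConsensusProfile:
    subfamily: str
    consensus_length: int
    hypo_counts: np.ndarray  # length consensus_length, index = position - 1
    hyper_counts: np.ndarray
    n_elements: int
    hot_spot_min: int = 3
    n_unmapped: int = 0

    @property
    def hot_spots(self) -> list[int]:
        """1-based consensus positions with hypoDMC count >= hot_spot_min."""
        return [int(i) + 1 for i in
                np.flatnonzero(self.hypo_counts >= self.hot_spot_min)]

    def percentages(self, which: str = "hypo") -> np.ndarray:
        """Per-position percentage of mapped DMCs of that direction."""
        counts = self.hypo_counts if which == "hypo" else self.hyper_counts
        total = counts.sum()
        return 100.0 * counts / total if total else counts.astype(float)


def consensus_dmc_profile(
    dmcs: pd.DataFrame,
    instances: Sequence[ElementInstance],
    subfamily: str,
    consensus_length: Optional[int] = None,
    hot_spot_min: int = 3,
) -> ConsensusProfile:
    """Aggregate DMC counts by consensus position for one subfamily.

    ``dmcs`` needs columns chrom, pos, call.  DMCs in instances without
    consensus offsets, or projecting beyond the consensus length, are
    counted as unmapped.
    """
    members = [el for el in instances if el.subfamily == subfamily]
    if consensus_length is None:
        ends = [el.consensus_end for el in members if el.has_consensus]
        if not ends:
            raise ValueError(f"no consensus offsets available for {subfamily!r}")
        consensus_length = max(ends)
    hypo = np.zeros(consensus_length, dtype=int)
    hyper = np.zeros(consensus_length, dtype=int)
    unmapped = 0
    contributing: set[tuple[str, int, int]] = set()
    for _, row in dmcs.iterrows():
        if row["call"] not in ("hypo", "hyper"):
            continue
        for el in members:
            if el.chrom == row["chrom"] and el.contains_pos(int(row["pos"])):
                _, cons = element_relative_position(int(row["pos"]), el)
                if cons is None or not 1 <= cons <= consensus_length:
                    unmapped += 1
                else:
                    (hypo if row["call"] == "hypo" else hyper)[cons - 1] += 1
                    contributing.add((el.chrom, el.start, el.end))
                break
    return ConsensusProfile(subfamily, consensus_length, hypo, hyper,
                            n_elements=len(contributing),
                            hot_spot_min=hot_spot_min, n_unmapped=unmapped)


def sample_elements(
    elements: Sequence[ElementInstance], n: int, seed: int
) -> list[ElementInstance]:
    """Uniform sample without replacement, reproducible by seed.

    When n exceeds the population, the whole population is returned.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    if n >= len(elements):
        return list(elements)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(elements), size=n, replace=False)
    return [elements[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Pwm:
    """Position weight matrix: 4 x L log-odds, rows ordered A, C, G, T."""

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM must be a 4 x L matrix with L >= 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def score_range(self) -> tuple[float, float]:
        return float(self.matrix.min(axis=0).sum()), float(self.matrix.max(axis=0).sum())

    def score(self, window: str) -> float:
        idx = [_BASE_INDEX[b] for b in window]
        return float(self.matrix[idx, np.arange(self.length)].sum())

    def relative_score(self, window: str) -> float:
        lo, hi = self.score_range
        if hi == lo:
            return 1.0  # degenerate matrix: every window is maximal
        return (self.score(window) - lo) / (hi - lo)

    @classmethod
    def from_counts(cls, counts: np.ndarray, motif_id: str = "",
                    pseudocount: float = 0.8,
                    background: Optional[np.ndarray] = None) -> "Pwm":
        """Build log-odds from a 4 x L count (PFM) matrix, JASPAR-style."""
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        freqs = (counts + pseudocount * background[:, None]) / (
            counts.sum(axis=0) + pseudocount
        )
        return cls(motif_id, np.log2(freqs / background[:, None]))

    @classmethod
    def from_sequences(cls, sequences: Sequence[str], motif_id: str = "") -> "Pwm":
        L = len(sequences[0])
        if any(len(s) != L for s in sequences):
            raise ValueError("aligned sequences must share one length")
        counts = np.zeros((4, L))
        for s in sequences:
            for j, b in enumerate(s.upper()):
                counts[_BASE_INDEX[b], j] += 1
        return cls.from_counts(counts, motif_id)


def read_jaspar_pfms(path) -> list[Pwm]:
    """Read motifs from a JASPAR PFM/jaspar text file into Pwm objects."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out.append(Pwm.from_counts(counts, motif_id=m.matrix_id or m.name or ""))
    return out


@dataclass(frozen=True)
class MotifHit:
    position: int  # 1-based start on the forward sequence
    strand: str
    score: float


def pwm_scan(
    sequence: str,
    pwm: Pwm,
    rel_threshold: float = 0.90,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan a sequence with a PWM at a JASPAR-style relative-score threshold.

    Windows containing N are skipped.  Minus-strand hits are reported at
    the 1-based forward-strand start of the matched window.
    """
    seq = sequence.upper()
    L = pwm.length
    hits: list[MotifHit] = []
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", reverse_complement(seq)))
    for strand, s in strands:
        for i in range(len(s) - L + 1):
            window = s[i:i + L]
            if "N" in window:
                continue
            rs = pwm.relative_score(window)
            if rs >= rel_threshold:
                pos = i + 1 if strand == "+" else len(seq) - (i + L) + 1
                hits.append(MotifHit(pos, strand, rs))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass(frozen=True)
class IdentityMatch:
    position: int  # 1-based start on the forward sequence
    strand: str
    identity: float


def approximate_motif_search(
    sequence: str, motif: str, min_identity: float = 0.90
) -> list[IdentityMatch]:
    """Sliding-window Hamming identity search on both strands.

    A window matches when the fraction of identical bases is
    >= min_identity (an 11-mer with one mismatch, 10/11 ~ 0.909, passes
    the default threshold).
    """
    motif = motif.upper()
    if len(motif) < 2:
        raise ValueError("motif must be at least 2 bases long")
    seq = sequence.upper()
    L = len(motif)
    out: list[IdentityMatch] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for i in range(len(s) - L + 1):
            window = s[i:i + L]
            ident = sum(a == b for a, b in zip(window, motif)) / L
            if ident >= min_identity:
                pos = i + 1 if strand == "+" else len(seq) - (i + L) + 1
                out.append(IdentityMatch(pos, strand, ident))
    out.sort(key=lambda h: (h.position, h.strand))
    return out
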