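"""Synthetic genomes, annotations and bisulfite count data with known truth.

The generator emulates the statistical structure the analysis assumes:

* a small multi-chromosome genome (autosome analogs plus short "chrX" and
  "chrY" analogs) carrying genes, full-length and truncated L1 copies of
  three subfamilies (L1MdA, L1MdF, L1MdT), IAP-type LTR proviruses
  (5'LTR + internal + 3'LTR), solo LTRs and SINE B1 copies, each built
  from a subfamily consensus so genomic copies are colinear with their
  consensus coordinates;
* per-CpG baseline methylation with the bimodal shape of sperm RRBS data
  (low at gene promoters, high in repeats and intergenic background);
* a 5-vs-5 two-group design with per-sample read totals from a negative
  binomial (mean ~30) truncated at the unite threshold (10), mild
  between-sample beta noise on the methylation proportion, and binomial
  methylated counts;
* hypomethylation effects concentrated on designated element CpG classes
  (by default the monomeric promoter CpGs of full-length L1MdA and the
  U3/R CpGs of IAPE 5'LTRs), recorded site-by-site in a truth table.

Every CpG the generator emits appears exactly once in the truth table,
and every ``CG`` dinucleotide in the emitted sequence is a registered CpG.
CpGs inside repeat copies are registered on the element's strand, so the
read cytosine projects to the exact seeded consensus position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ElementInstance, GeneModel, GenomicInterval, SiteCounts
from .elements import (L1Structure, LtrAnnotation, POLYA_SIGNAL, TATA_BOX,
                       ltr_domain_of, reverse_complement)
from .formats_io import (write_coverage_file, write_fasta, write_gene_models,
                         write_bed, write_repeat_table)
from .methcall import CONTROL, EXPOSED, GroupDesign

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """One seeded hypomethylation effect class.

    ``label_prefixes`` match the truth table's region labels by prefix;
    ``delta`` is the group-mean drop in percentage points; ``penetrance``
    is the per-CpG probability of carrying the effect;
    ``full_length_only`` restricts to CpGs in full-length elements.
    """

    label_prefixes: tuple[str, ...]
    delta: float = 30.0
    penetrance: float = 1.0
    full_length_only: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 100.0:
            raise ValueError("delta must lie in [0, 100] percentage points")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")


DEFAULT_EFFECTS = (
    EffectSpec(("L1MdA:monomer",), delta=30.0, penetrance=1.0,
               full_length_only=True),
    EffectSpec(("IAPE:5LTR:U3", "IAPE:5LTR:R"), delta=30.0, penetrance=1.0),
)

DEFAULT_CHROM_LENGTHS = {
    "chr1": 400_000, "chr2": 300_000, "chrX": 150_000, "chrY": 80_000,
}

DEFAULT_FEATURES: dict[str, dict[str, int]] = {
    "chr1": {"gene": 8, "L1MdA_full": 4, "L1MdF_full": 2, "L1MdT_full": 2,
             "L1MdA_trunc": 2, "L1MdF_trunc": 2, "L1MdT_trunc": 2,
             "IAPE_provirus": 2, "IAPE_solo": 2, "B1": 10},
    "chr2": {"gene": 6, "L1MdA_full": 3, "L1MdF_full": 1, "L1MdT_full": 1,
             "L1MdA_trunc": 2, "L1MdF_trunc": 2, "L1MdT_trunc": 2,
             "IAPE_provirus": 2, "IAPE_solo": 1, "B1": 8},
    "chrX": {"gene": 3, "L1MdA_full": 5, "L1MdF_full": 1, "L1MdT_full": 1,
             "L1MdA_trunc": 1, "L1MdF_trunc": 1, "L1MdT_trunc": 1,
             "IAPE_provirus": 0, "IAPE_solo": 1, "B1": 4},
    "chrY": {"gene": 1, "L1MdA_full": 0, "L1MdF_full": 0, "L1MdT_full": 0,
             "L1MdA_trunc": 0, "L1MdF_trunc": 1, "L1MdT_trunc": 0,
             "IAPE_provirus": 3, "IAPE_solo": 2, "B1": 2},
}

BASELINE_MEANS = {
    "promoter": 0.06,
    "gene_body": 0.75,
    "background": 0.80,
    "repeat": 0.85,
}
BASELINE_CONCENTRATION = 60.0


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_per_group: int = 5
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0
    min_coverage: int = 10
    sample_level_sd: float = 0.02
    background_cpg_spacing: int = 300
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    features: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {c: dict(f) for c, f in DEFAULT_FEATURES.items()})
    effects: tuple[EffectSpec, ...] = DEFAULT_EFFECTS

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("need at least one sample per group")

    def design(self) -> GroupDesign:
        groups = {}
        for i in range(1, self.n_per_group + 1):
            groups[f"control_{i}"] = CONTROL
        for i in range(1, self.n_per_group + 1):
            groups[f"exposed_{i}"] = EXPOSED
        return GroupDesign(groups)

    def null(self) -> "SynthConfig":
        """Copy of the config with every seeded effect removed."""
        return replace(self, effects=())


# ---------------------------------------------------------------------------
# Consensus sequences
# ---------------------------------------------------------------------------

AER_LIKE_MOTIF = "GAGACTCGAGC"  # carries one CpG at motif offset 7

L1_STRUCTURE = L1Structure()  # 2 x 200 bp monomers + 203 bp 5'UTR + ORFs


@dataclass
class ConsensusModel:
    subfamily: str
    repeat_class: str
    sequence: str
    cpg_positions: tuple[int, ...]          # 1-based, position of the C
    cpg_labels: tuple[str, ...]             # region label per CpG

    @property
    def length(self) -> int:
        return len(self.sequence)


def _random_seq_no_cpg(rng: np.random.Generator, n: int) -> list[str]:
    seq = list(BASES[rng.integers(0, 4, size=n)])
    for i in range(1, n):
        if seq[i - 1] == "C" and seq[i] == "G":
            seq[i] = "A"
    return seq


def _plant(seq: list[str], pos: int, text: str) -> None:
    """Plant ``text`` at 1-based position ``pos``, fixing CG junctions."""
    i = pos - 1
    seq[i:i + len(text)] = list(text)
    if i > 0 and seq[i - 1] == "C" and text[0] == "G":
        seq[i - 1] = "T"
    j = i + len(text)
    if j < len(seq) and text[-1] == "C" and seq[j] == "G":
        seq[j] = "A"


def _l1_consensus(rng: np.random.Generator, subfamily: str) -> ConsensusModel:
    st = L1_STRUCTURE
    seq = _random_seq_no_cpg(rng, st.length)
    spans = st.domain_spans()
    positions: list[int] = []
    labels: list[str] = []

    monomer_offsets = (21, 61, 121, 161)
    for m in range(st.n_monomers):
        for off in monomer_offsets:
            positions.append(m * st.monomer_length + off)
            labels.append(f"{subfamily}:monomer")
    utr5_start = spans["5UTR"][0]
    # AER-like motif sits in the 5'UTR; its internal CpG is registered
    motif_start = utr5_start + 40
    _plant(seq, motif_start, AER_LIKE_MOTIF)
    positions.append(motif_start + 6)
    labels.append(f"{subfamily}:5UTR")
    for off in (80, 150):
        positions.append(utr5_start + off)
        labels.append(f"{subfamily}:5UTR")
    for pos in (spans["ORF1"][0] + 96, spans["ORF1"][0] + 496):
        positions.append(pos)
        labels.append(f"{subfamily}:ORF1")
    for pos in range(spans["ORF2"][0] + 382, spans["ORF2"][1] - 100, 1000):
        positions.append(pos)
        labels.append(f"{subfamily}:ORF2")
    positions.append(spans["3UTR"][0] + 154)
    labels.append(f"{subfamily}:3UTR")

    for p in positions:
        if seq[p - 1:p + 1] != ["C", "G"]:
            _plant(seq, p, "CG")
    return ConsensusModel(subfamily, "LINE/L1", "".join(seq),
                          tuple(positions), tuple(labels))


IAP_LTR_LENGTH = 350
IAP_INT_LENGTH = 2000
IAP_CAAT_POS = 120
IAP_TATA_POS = 163
IAP_POLYA_POS = 235


def _iap_ltr_consensus(rng: np.random.Generator) -> tuple[ConsensusModel, LtrAnnotation]:
    seq = _random_seq_no_cpg(rng, IAP_LTR_LENGTH)
    _plant(seq, IAP_CAAT_POS, "CCAAT")
    _plant(seq, IAP_TATA_POS, TATA_BOX)
    _plant(seq, IAP_POLYA_POS, POLYA_SIGNAL)
    positions = (41, 91, 141, 181, 221, 281, 321)
    for p in positions:
        _plant(seq, p, "CG")
    sequence = "".join(seq)
    ann = LtrAnnotation.from_sequence(sequence)
    labels = tuple(f"IAPE:LTR:{ltr_domain_of(p, ann)}" for p in positions)
    return ConsensusModel("IAPE", "LTR/ERVK", sequence, positions, labels), ann


def _iap_int_consensus(rng: np.random.Generator) -> ConsensusModel:
    seq = _random_seq_no_cpg(rng, IAP_INT_LENGTH)
    positions = tuple(range(75, IAP_INT_LENGTH - 25, 150))
    for p in positions:
        _plant(seq, p, "CG")
    return ConsensusModel("IAPE-int", "LTR/ERVK", "".join(seq),
                          positions, tuple("IAPE:int" for _ in positions))


def _b1_consensus(rng: np.random.Generator) -> ConsensusModel:
    seq = _random_seq_no_cpg(rng, 150)
    positions = (31, 76, 111)
    for p in positions:
        _plant(seq, p, "CG")
    return ConsensusModel("B1", "SINE/Alu", "".join(seq),
                          positions, tuple("B1" for _ in positions))


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    config: SynthConfig
    sequences: dict[str, str]
    genes: list[GeneModel]
    repeats: list[ElementInstance]
    full_length_l1: list[GenomicInterval]
    cpg_table: pd.DataFrame
    consensus: dict[str, ConsensusModel]
    ltr_annotation: LtrAnnotation

    def consensus_fasta(self) -> dict[str, str]:
        return {name: m.sequence for name, m in self.consensus.items()}


GENE_PAD = 800          # promoter pad beyond the transcript
GENE_TX_LEN = 3000
GENE_BLOCK = GENE_PAD + GENE_TX_LEN
TRUNC_L1_LEN = 1500


class _ChromBuilder:
    def __init__(self, name: str, length: int, rng: np.random.Generator,
                 spacing: int) -> None:
        self.name = name
        self.length = length
        self.rng = rng
        self.spacing = spacing
        self.seq = _random_seq_no_cpg(rng, length)
        self.cpgs: list[dict] = []

    def add_cpg(self, pos: int, strand: str, label: str,
                full_length: bool = False,
                consensus_pos: Optional[int] = None) -> None:
        self.cpgs.append({
            "chrom": self.name, "pos": pos, "strand": strand,
            "region_label": label, "full_length": full_length,
            "consensus_pos": consensus_pos,
        })

    def plant_forward_cpg(self, pos: int, label: str) -> None:
        _plant(self.seq, pos, "CG")
        self.add_cpg(pos, "+", label)

    def place_sequence(self, start0: int, text: str) -> None:
        _plant(self.seq, start0 + 1, text)

    def background_cpgs(self, lo0: int, hi0: int) -> None:
        """Plant background CpGs in the 0-based gap [lo0, hi0)."""
        pos = lo0 + 20
        while pos + 2 < hi0 - 20:
            jitter = int(self.rng.integers(-self.spacing // 4,
                                           self.spacing // 4 + 1))
            p1 = pos + 1  # 1-based
            self.plant_forward_cpg(p1, "background")
            pos += self.spacing + jitter


def _place_element(
    builder: _ChromBuilder,
    start0: int,
    model: ConsensusModel,
    strand: str,
    cons_lo: int,
    cons_hi: int,
    full_length: bool,
    label_override: Optional[dict[int, str]] = None,
) -> ElementInstance:
    """Insert the consensus slice [cons_lo, cons_hi] (1-based, inclusive)
    at 0-based genomic start, honoring strand, and register its CpGs."""
    piece = model.sequence[cons_lo - 1:cons_hi]
    if strand == "-":
        piece = reverse_complement(piece)
    builder.place_sequence(start0, piece)
    end0 = start0 + len(piece)
    el = ElementInstance(
        chrom=builder.name, start=start0, end=end0, strand=strand,
        subfamily=model.subfamily, repeat_class=model.repeat_class,
        consensus_start=cons_lo, consensus_end=cons_hi,
    )
    for cons_pos, label in zip(model.cpg_positions, model.cpg_labels):
        if not cons_lo <= cons_pos <= cons_hi:
            continue
        # skip CpGs whose G partner would fall outside the slice
        if cons_pos + 1 > cons_hi:
            continue
        offset = cons_pos - cons_lo + 1
        if strand == "-":
            genomic = end0 - offset + 1
        else:
            genomic = start0 + offset
        lab = label_override.get(cons_pos, label) if label_override else label
        builder.add_cpg(genomic, strand, lab, full_length=full_length,
                        consensus_pos=cons_pos)
    return el


def _place_gene(builder: _ChromBuilder, start0: int, name: str,
                strand: str) -> GeneModel:
    if strand == "+":
        t0 = start0 + GENE_PAD
    else:
        t0 = start0
    exons = ((t0, t0 + 500), (t0 + 2500, t0 + GENE_TX_LEN))
    gene = GeneModel(name, builder.name, t0, t0 + GENE_TX_LEN, strand, exons,
                     cds_start=t0 + 300, cds_end=t0 + 2800)
    # promoter CpG island: every 60 bp within -770..-50 of the TSS
    for k in range(12):
        if strand == "+":
            p = gene.tss - 770 + 60 * k + 1      # 1-based
        else:
            p = gene.tss + 770 - 60 * k
        builder.plant_forward_cpg(p, "promoter")
    for off in (1500, 2600):
        builder.plant_forward_cpg(t0 + off + 1, "gene_body")
    return gene


def generate_genome(config: SynthConfig) -> SyntheticGenome:
    """Build the synthetic genome, annotations and CpG truth skeleton.

    Deterministic for a fixed config (including its seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    consensus: dict[str, ConsensusModel] = {}
    for sub in ("L1MdA", "L1MdF", "L1MdT"):
        consensus[sub] = _l1_consensus(rng, sub)
    ltr_model, ltr_ann = _iap_ltr_consensus(rng)
    consensus["IAPE"] = ltr_model
    consensus["IAPE-int"] = _iap_int_consensus(rng)
    consensus["B1"] = _b1_consensus(rng)

    genes: list[GeneModel] = []
    repeats: list[ElementInstance] = []
    full_length_l1: list[GenomicInterval] = []
    sequences: dict[str, str] = {}
    all_cpgs: list[dict] = []
    gene_counter = 0

    ltr_labels = {p: lab for p, lab in
                  zip(ltr_model.cpg_positions, ltr_model.cpg_labels)}

    def ltr_override(kind: str) -> dict[int, str]:
        return {p: lab.replace(":LTR:", f":{kind}:")
                for p, lab in ltr_labels.items()}

    for chrom, length in config.chrom_lengths.items():
        counts = config.features.get(chrom, {})
        builder = _ChromBuilder(chrom, length, rng,
                                config.background_cpg_spacing)

        blocks: list[tuple[str, str, int]] = []  # (kind, subfamily, length)
        for _ in range(counts.get("gene", 0)):
            blocks.append(("gene", "", GENE_BLOCK))
        for sub in ("L1MdA", "L1MdF", "L1MdT"):
            for _ in range(counts.get(f"{sub}_full", 0)):
                blocks.append(("l1_full", sub, consensus[sub].length))
            for _ in range(counts.get(f"{sub}_trunc", 0)):
                blocks.append(("l1_trunc", sub, TRUNC_L1_LEN))
        for _ in range(counts.get("IAPE_provirus", 0)):
            blocks.append(("iap_provirus", "IAPE",
                           2 * IAP_LTR_LENGTH + IAP_INT_LENGTH + 10))
        for _ in range(counts.get("IAPE_solo", 0)):
            blocks.append(("iap_solo", "IAPE", IAP_LTR_LENGTH))
        for _ in range(counts.get("B1", 0)):
            blocks.append(("b1", "B1", 150))
        rng.shuffle(blocks)

        total_feat = sum(b[2] for b in blocks)
        n_gaps = len(blocks) + 1
        free = length - total_feat - 2 * n_gaps * 30
        if free <= 0:
            raise ValueError(f"chromosome {chrom} too short for its features")
        weights = rng.random(n_gaps) + 0.2
        gaps = np.floor(free * weights / weights.sum()).astype(int) + 30

        cursor = 0
        for (kind, sub, blen), gap in zip(blocks, gaps[:-1]):
            builder.background_cpgs(cursor, cursor + gap)
            cursor += int(gap)
            start0 = cursor
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "gene":
                gene_counter += 1
                genes.append(_place_gene(builder, start0,
                                         f"Gene{gene_counter}", strand))
            elif kind == "l1_full":
                model = consensus[sub]
                el = _place_element(builder, start0, model, strand,
                                    1, model.length, full_length=True)
                repeats.append(el)
                full_length_l1.append(GenomicInterval(
                    chrom, el.start, el.end, strand, f"{sub}_FL"))
            elif kind == "l1_trunc":
                model = consensus[sub]
                el = _place_element(builder, start0, model, strand,
                                    model.length - TRUNC_L1_LEN + 1,
                                    model.length, full_length=False)
                repeats.append(el)
            elif kind == "iap_provirus":
                over5 = ltr_override("5LTR")
                over3 = ltr_override("3LTR")
                # element 5' end sits at genomic left for +, right for -
                first, last = (over5, over3) if strand == "+" else (over3, over5)
                p = start0
                repeats.append(_place_element(
                    builder, p, ltr_model, strand, 1, IAP_LTR_LENGTH,
                    False, label_override=first))
                p += IAP_LTR_LENGTH + 5
                repeats.append(_place_element(
                    builder, p, consensus["IAPE-int"], strand,
                    1, IAP_INT_LENGTH, False))
                p += IAP_INT_LENGTH + 5
                repeats.append(_place_element(
                    builder, p, ltr_model, strand, 1, IAP_LTR_LENGTH,
                    False, label_override=last))
            elif kind == "iap_solo":
                repeats.append(_place_element(
                    builder, start0, ltr_model, strand, 1, IAP_LTR_LENGTH,
                    False, label_override=ltr_override("soloLTR")))
            elif kind == "b1":
                model = consensus["B1"]
                repeats.append(_place_element(
                    builder, start0, model, strand, 1, model.length, False))
            cursor += blen
        builder.background_cpgs(cursor, cursor + int(gaps[-1]))

        sequences[chrom] = "".join(builder.seq)
        all_cpgs.extend(builder.cpgs)

    cpg_table = pd.DataFrame(all_cpgs)
    cpg_table = cpg_table.sort_values(["chrom", "pos"],
                                      key=lambda s: s.map(_sort_key_series)
                                      ).reset_index(drop=True)
    if cpg_table.duplicated(["chrom", "pos"]).any():
        raise AssertionError("generator produced duplicate CpG positions")

    # baseline methylation: bimodal by genomic context
    base_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    means = np.where(
        cpg_table["region_label"].isin(["promoter"]), BASELINE_MEANS["promoter"],
        np.where(cpg_table["region_label"].eq("gene_body"),
                 BASELINE_MEANS["gene_body"],
                 np.where(cpg_table["region_label"].eq("background"),
                          BASELINE_MEANS["background"],
                          BASELINE_MEANS["repeat"])))
    k = BASELINE_CONCENTRATION
    baseline = base_rng.beta(means * k, (1.0 - means) * k)
    cpg_table["baseline"] = np.clip(baseline, 0.02, 0.98)

    return SyntheticGenome(config, sequences, genes, repeats, full_length_l1,
                           cpg_table, consensus, ltr_ann)


def _sort_key_series(v):
    from .core import chromosome_sort_key
    if isinstance(v, str):
        return chromosome_sort_key(v)
    return v


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def _truncated_nb(rng: np.random.Generator, mean: float, dispersion: float,
                  minimum: int, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    x = rng.negative_binomial(dispersion, p, size=size)
    for _ in range(200):
        low = x < minimum
        if not low.any():
            break
        x[low] = rng.negative_binomial(dispersion, p, size=int(low.sum()))
    np.maximum(x, minimum, out=x)
    return x


def apply_effects(cpg_table: pd.DataFrame, config: SynthConfig,
                  rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Return the truth table with the per-CpG applied delta column."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    truth = cpg_table.copy()
    delta = np.zeros(len(truth))
    labels = truth["region_label"].astype(str)
    for spec in config.effects:
        mask = np.zeros(len(truth), dtype=bool)
        for prefix in spec.label_prefixes:
            mask |= labels.str.startswith(prefix).to_numpy()
        if spec.full_length_only:
            mask &= truth["full_length"].to_numpy().astype(bool)
        hit = mask & (rng.random(len(truth)) < spec.penetrance)
        delta[hit] = spec.delta
    truth["delta_applied"] = delta
    return truth


def simulate_counts(
    genome_or_table, config: SynthConfig, seed: Optional[int] = None
) -> tuple[dict[str, list[SiteCounts]], pd.DataFrame]:
    """Simulate per-sample coverage files from a genome (or bare CpG table).

    Returns (sample -> SiteCounts list, truth table with delta_applied).
    Group-level means are baseline (control) and baseline minus the applied
    delta (exposed); per-sample proportions add mild beta noise.
    """
    table = (genome_or_table.cpg_table
             if isinstance(genome_or_table, SyntheticGenome) else genome_or_table)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    truth = apply_effects(table, config, rng)

    design = config.design()
    n_sites = len(truth)
    baseline = truth["baseline"].to_numpy()
    exposed_mean = np.clip(baseline - truth["delta_applied"].to_numpy() / 100.0,
                           0.01, 0.99)
    group_mean = {CONTROL: np.clip(baseline, 0.01, 0.99), EXPOSED: exposed_mean}

    samples: dict[str, list[SiteCounts]] = {}
    chroms = truth["chrom"].to_numpy()
    positions = truth["pos"].to_numpy()
    strands = truth["strand"].to_numpy()
    sd = config.sample_level_sd
    for sample in design.samples:
        m = group_mean[design.groups[sample]]
        totals = _truncated_nb(rng, config.coverage_mean,
                               config.coverage_dispersion,
                               config.min_coverage, n_sites)
        if sd > 0:
            var = np.minimum(sd ** 2, 0.5 * m * (1.0 - m))
            kk = m * (1.0 - m) / var - 1.0
            pi = np.where(kk > 0, rng.beta(np.maximum(m * kk, 1e-9),
                                           np.maximum((1.0 - m) * kk, 1e-9)), m)
        else:
            pi = m
        meth = rng.binomial(totals, pi)
        samples[sample] = [
            SiteCounts(c, int(p), int(mm), int(tt - mm), s)
            for c, p, s, mm, tt in zip(chroms, positions, strands, meth, totals)
        ]
    return samples, truth


def null_cpg_table(n_cpgs: int, seed: int = 0, spacing: int = 1000,
                   chrom: str = "chr1") -> pd.DataFrame:
    """Flat CpG table with bimodal baseline and no effects (null model)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    pos = spacing * np.arange(1, n_cpgs + 1)
    low = rng.random(n_cpgs) < 0.3
    k = BASELINE_CONCENTRATION
    means = np.where(low, 0.08, 0.80)
    baseline = np.clip(rng.beta(means * k, (1.0 - means) * k), 0.02, 0.98)
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "strand": "+",
        "region_label": np.where(low, "promoter", "background"),
        "full_length": False, "consensus_pos": None,
        "baseline": baseline,
    })


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    n_effect_cpgs: int
    n_null_cpgs: int
    sensitivity: float          # hypoDMC calls among effect CpGs; NaN if none
    false_positive_rate: float  # any DMC call among null CpGs


def evaluate_recovery(dmc_calls: pd.DataFrame, truth: pd.DataFrame) -> RecoveryReport:
    """Compare DMC calls to generator truth, keyed by (chrom, pos)."""
    merged = truth.merge(dmc_calls[["chrom", "pos", "call"]],
                         on=["chrom", "pos"], how="left", validate="1:1")
    if merged["call"].isna().any():
        n = int(merged["call"].isna().sum())
        raise ValueError(f"{n} truth CpGs missing from DMC calls "
                         "(truth/result key mismatch)")
    effect = merged["delta_applied"] > 0
    null = ~effect
    n_eff = int(effect.sum())
    sens = (float((merged.loc[effect, "call"] == "hypo").mean())
            if n_eff else float("nan"))
    fpr = (float((merged.loc[null, "call"] != "none").mean())
           if null.any() else float("nan"))
    return RecoveryReport(n_eff, int(null.sum()), sens, fpr)


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_genome(genome: SyntheticGenome, outdir) -> dict[str, Path]:
    """Write FASTA, gene BED12, repeat table, full-length L1 catalog and
    consensus FASTA; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_fasta": outdir / "genome.fa",
        "genes_bed": outdir / "genes.bed12",
        "repeats_tsv": outdir / "repeats.tsv",
        "full_length_l1_bed": outdir / "full_length_l1.bed",
        "consensus_fasta": outdir / "consensus.fa",
    }
    write_fasta(paths["genome_fasta"], genome.sequences)
    write_gene_models(paths["genes_bed"], genome.genes)
    write_repeat_table(paths["repeats_tsv"], genome.repeats)
    write_bed(paths["full_length_l1_bed"], genome.full_length_l1)
    write_fasta(paths["consensus_fasta"], genome.consensus_fasta())
    return paths


def write_counts(samples: Mapping[str, Sequence[SiteCounts]],
                 truth: pd.DataFrame, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample, sites in samples.items():
        p = outdir / f"{sample}.cov"
        write_coverage_file(p, sites)
        paths[sample] = p
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
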