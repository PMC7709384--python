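# retrometh

Differential DNA-methylation analysis of reduced-representation bisulfite
sequencing (RRBS) data, with element-relative positional analysis of
retrotransposon subfamilies.

## The problem

Gestational exposure to environmental chemicals can perturb the epigenetic
reprogramming of fetal germ cells, leaving methylation scars in mature
sperm.  Detecting such effects requires comparing per-cytosine methylation
between exposed and control animals genome-wide — and, because many of
the affected cytosines fall in repetitive DNA, projecting each hit into
the coordinate frame of the retrotransposon copy that carries it: is a
hypomethylated CpG sitting in the tandem-monomer promoter of a full-length
LINE-1, or in the U3/R promoter domains of an IAP 5′LTR?  Those positions
determine whether the change can plausibly reactivate the element.

`retrometh` implements that full analysis as a tested, reusable library
for epigenomics researchers working from Bismark-style coverage files:

* **methcall** — unite per-sample counts into a methylation matrix,
  keeping CpGs covered ≥ 10× in *every* sample; methylation level of a
  site is C/(C+T).
* **diffmeth** — per-CpG binomial logistic regression on the group
  indicator, tested by likelihood ratio: with a single binary covariate
  the deviance has the closed form of the pooled-table G statistic,
  2·Σ O·ln(O/E) on the 2(group)×2(meth) table, with p from χ²(1 df) and
  Benjamini–Hochberg q values.  hypoDMC: q ≤ 0.01 and an
  exposed-minus-control difference ≤ −10 points (inclusive); hyperDMC
  symmetric.  DMRs chain united CpGs ≤ 100 bp apart and require ≥ 3 CpGs,
  ≥ 1 DMC, a pooled region difference strictly > 10 points, and a
  Stouffer-combined q ≤ 0.01.
* **annotate** — HOMER-style two-level labels: gene context
  (promoter-TSS > TTS > 5UTR > 3UTR > exon > intron > intergenic, promoter
  window −1000/+100 bp around the TSS) and repeat subfamily with
  LINE/LTR/SINE grouping (smallest overlapping instance wins).
* **enrich** — two-sided Fisher's exact tests of DMC occurrence per
  category against the all-CpG background (raw p < 0.001 genome-wide,
  p < 0.01 per chromosome).
* **elements** — element-relative offsets and consensus-coordinate
  projection; full-length L1 calling (catalog overlap or ≥ 6 kb);
  L1 domain maps (monomers, 203 bp 5′UTR, ORF1/ORF2, 3′UTR); IAP fragment
  classification (5′LTR / 3′LTR / solo LTR / internal) and U3/R/U5
  domains located from the TATA box and polyadenylation signal; consensus
  DMC profiles with hot spots; JASPAR-style PWM scanning (relative score
  ≥ 0.90) and approximate motif search (≥ 90% identity).
* **synthetic** — a generator for toy genomes, annotations and 5-vs-5
  count data with seeded hypomethylation effects and a per-CpG truth
  table, so every stage can be validated without external data.

## Worked example

One command simulates a study (5 control vs 5 exposed samples, coverage
~30×, 30-point hypomethylation seeded at full-length L1MdA promoter
monomers and IAPE 5′LTR U3/R CpGs) and analyzes it:

```bash
retrometh run-all --seed 1 --out demo/
```

```
united CpGs: 3278; hypoDMCs: 129; hyperDMCs: 0; DMRs: 19
outputs in demo/results
```

All 129 DMCs are hypomethylated, as expected from a purely hypomethylating
exposure; the 19 DMRs are the chained promoter CpG clusters.  The
consensus profile of the seeded L1 subfamily then recovers the planted
promoter positions exactly:

```bash
retrometh elements --dmc demo/results/dmc.tsv \
    --repeats demo/inputs/repeats.tsv --subfamily L1MdA --out demo/prof.tsv
```

```
hot spots at consensus positions: [21, 61, 121, 161, 221, 261, 321, 361]
```

Those eight positions are the monomer CpGs of the synthetic L1MdA
consensus — the positions at which the effect was seeded.  The library
API mirrors the CLI; see the module docstrings and `docs/methods.md`.

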