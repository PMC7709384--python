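# Methods

This note documents the statistical model, the conventions and defaults,
the synthetic-data model used for validation, and the design choices made
where the design was genuinely open.

## Coordinates and input model

CpG positions are 1-based internally (the Bismark coverage convention);
all interval I/O is BED (0-based half-open), and the two converters are
exact inverses.  Counts are **not** destranded: each input cytosine is an
independent unit, and symmetric CpG pairs on opposite strands are never
collapsed.  The repeat catalog is read either as a HOMER-style BED-like
table or as RepeatMasker `.out`; consensus offsets (repStart/repEnd) are
optional on input but required for consensus projection, which refuses
instances without them.

## Uniting and methylation levels

A site enters the analysis only when covered by at least `min_coverage`
reads (default 10) in every sample of the two-group design; the united
matrix is the intersection over samples, invariant to sample input order.
The level of a site in a sample is `n_meth / n_total`.  Descriptive group
means are means of per-sample means, so each animal contributes equally
regardless of its coverage; a pooled-count alternative is available via
`mean_methylation(..., pooled=True)`.  Per-chromosome group comparisons
are two-sided equal-variance Student t tests on per-sample chromosome
means (n animals per group as the unit of replication); a degenerate case
in which every sample mean is identical is reported as t = 0, p = 1.
Region means (e.g. over imprinting-control regions) are unweighted across
sites.

## The DMC test

Per CpG, methylated counts are modeled by binomial logistic regression on
the group indicator and tested against the intercept-only model with a
likelihood-ratio χ² (1 df).  With a single binary covariate the
maximum-likelihood fitted proportions are the pooled per-group
proportions, so the deviance is evaluated in closed form from per-sample
binomial log-likelihoods — exactly the logistic-regression LRT, without
iterative fitting, and identical (to < 1e-6; asserted in tests against
both the algebraic G statistic and an iteratively fitted GLM) to the
pooled-table G statistic.  No overdispersion correction is applied.  The
reported `meth_diff` is the difference of pooled group proportions
(exposed − control) in percentage points, which matches the fitted
logistic proportions; the per-sample descriptive mean remains available
upstream.

Multiple testing uses Benjamini–Hochberg q values.  Calls are
**inclusive** at both boundaries: hypoDMC when q ≤ 0.01 and
meth_diff ≤ −10.0; hyperDMC symmetric.

## DMRs

Candidate regions chain consecutive united CpGs with inter-CpG distance
≤ `max_gap` (default 100 bp, configurable).  A candidate becomes a DMR
when it has ≥ 3 CpGs, contains ≥ 1 DMC, its pooled region-level group
difference is **strictly** greater than 10 points in magnitude (the
strict/inclusive asymmetry with the DMC filter is deliberate and follows
the respective definitions; the strict comparison carries a 1e-9
float-round-off guard), and its Stouffer-combined per-CpG p value
survives BH at q ≤ 0.01 across candidates.  This chaining-plus-Stouffer
construction is this package's own region model — a deliberately simple,
fully specified substitute for dedicated DMR callers whose distance
models are not reproducible from their descriptions.  Exact DMR counts
are therefore comparable only between runs of this package, not across
callers.

## Annotation

Basic labels follow the fixed precedence promoter-TSS > TTS > 5UTR >
3UTR > exon > intron > intergenic, with a strand-aware promoter window of
−1000..+100 bp around the TSS and, by convention, −100..+1000 bp around
the TTS (the TTS window mirrors the promoter window; only the promoter
window has a stated reference value).  Repeat (detailed) labels override
the basic label when the position falls inside an instance; nested or
overlapping instances resolve to the smallest interval (then lowest
start), reporting the most specific element.  The subfamily→group map
(LINE / LTR / SINE / other-repeat) ships as an editable TSV of class
prefixes.  DMRs are annotated by midpoint, the peak convention.  DMRs
near genes are selected by midpoint within ±2000 bp of a TSS, with
signed distance negative upstream in gene orientation and coordinate
ties resolved to the lower TSS.

## Enrichment

Each test is a two-sided Fisher's exact test (point-probability rule, as
in mainstream exact-test implementations) on [DMC vs non-DMC] × [in
category vs not], with all united CpGs as the shared background for every
DMC subset (hypo-only, hyper-only, combined).  Raw p values are compared
against fixed cutoffs — 0.001 genome-wide, 0.01 per chromosome — with a
BH column emitted additionally for convenience only.  The odds ratio is
the sample cross-ratio with a 0.5 Haldane correction applied only when a
zero cell occurs; tables with an empty row or column have no estimable
contrast and report OR = 1 (their p is 1).  "Enriched" in reports means
significant **and** OR > 1; the two-sided p alone also flags depletion.

## Element-relative analysis

Offsets count from the element's 5′ end in element orientation (offset 1
= first base): `pos − start` on the plus strand, `end − pos + 1` on the
minus strand, inverted exactly by `genomic_position_of_offset`.
Consensus position = `consensus_start + offset − 1`, assuming the
instance is colinear with its consensus — no indel modeling.  This is a
documented limitation, adequate for promoter-proximal positions where
the analysis concentrates.

Full-length L1 status is catalog-driven (≥ 90% reciprocal overlap with a
provided full-length catalog) with a ≥ 6 kb length fallback.  The L1
domain map is ordered monomers (k × ~200 bp) + 203 bp 5′UTR (together
the promoter) + ORF1 + ORF2 + 3′UTR.

IAP fragments classify as internal (name contains `-int`), 5′LTR
(internal segment within 50 bp on the element-downstream side,
strand-aware), 3′LTR (upstream side), or solo LTR (isolated).  The 50 bp
join gap and the both-sides tie-break (resolved to 5′LTR, the fragment
preceding an internal segment in element orientation) are this package's
conventions; the underlying classification scheme is described in the
literature without parameter values.  LTR sub-domains are located from
sequence landmarks: R starts immediately after the TATA-box region
(`ATTATAAGA`) and ends at the end of the polyadenylation signal
(`AATAAA`); U3 precedes, U5 follows.  Landmark-to-boundary mapping at
base precision is likewise a stated convention.

Consensus profiles count hypo/hyper DMCs per consensus position over all
copies of a subfamily; hot spots are positions with count ≥ 3 (default;
no reference value exists for this cutoff).  PWM scanning uses the
JASPAR relative score (score − min)/(max − min) with threshold 0.90 and
skips windows containing N; a degenerate matrix with zero score range
scores every window 1.0.  Approximate motif search uses sliding-window
Hamming identity ≥ 0.90 on both strands, so an 11-mer with one mismatch
(10/11 ≈ 0.909) matches and one with two (9/11 ≈ 0.818) does not.

## Synthetic data model

The generator emulates the structure the analysis assumes, not real
mouse sequence.  Default conditions: 5 samples per group; per-site
per-sample totals from a negative binomial with mean 30 and dispersion 8,
truncated at 10 so every simulated site survives uniting by construction;
per-sample methylation proportions drawn from a Beta around the group
mean with σ ≈ 0.02 (small enough that the uncorrected logistic test
stays near-calibrated — the null false-call rate is checked, not
assumed); methylated counts binomial.  Baselines are bimodal by context:
gene-promoter CpGs ≈ 0.06, gene bodies ≈ 0.75, intergenic background
≈ 0.80, repeats ≈ 0.85 (Beta, concentration 60).  The default genome is
four chromosomes (400/300/150/80 kb analogs of two autosomes, chrX and
chrY) carrying genes, full-length and truncated L1 copies of three
subfamilies, IAP proviruses (5′LTR + internal + 3′LTR with 5 bp joins),
solo LTRs and SINEs, each pasted from a subfamily consensus so genomic
copies are exactly colinear with consensus coordinates; the chrX analog
is L1-rich and the chrY analog IAP-rich, mirroring the skew of the real
sex chromosomes.  The default seeded effect is a 30-point drop at
full-length-L1MdA monomer CpGs and IAPE 5′LTR U3/R CpGs with penetrance
1.0, recorded site-by-site in the truth table.  Two invariants are
enforced: every emitted CpG appears exactly once in the truth table, and
every `CG` dinucleotide in the emitted sequence is a registered CpG.
Element CpGs are registered on the element's strand so the read cytosine
projects to the exact seeded consensus position.

What the generator does **not** model: read-level data (FASTQ, bisulfite
conversion error, MspI fragment selection), indels between element copies
and consensus, CpG islands as sequence features, sequencing batch
effects, and biological between-animal variance beyond the Beta noise.
Passing tests on synthetic data therefore demonstrate the correctness and
calibration of the statistical machinery under the stated model, not
performance on real RRBS libraries, where overdispersion and coverage
heterogeneity are larger.

Problem sizes used in validation — ~3,300 CpGs for the effect genome and
20,000 CpGs for null calibration — were chosen as the smallest sizes at
which the binomial machinery is exercised across all contexts and the
null p-value distribution can be assessed to a KS distance of 0.05.

## Numerical choices and degenerate inputs

* LRT deviance is clamped at 0 to absorb negative round-off; 0·log 0
  terms use `xlogy`.
* p values are clipped to [1e-300, 1] before Stouffer combination.
* Identical-proportion sites report statistic 0, p = 1.
* Empty site subsets raise rather than return NaN; regions with no
  united CpG report missing values.
* Zero-coverage sites cannot occur after uniting and are rejected by the
  scalar test.
* Element sampling uses a seeded generator and returns the whole
  population when n exceeds it.

## Known limitations

* No overdispersion correction in the DMC test: with strong biological
  replicate variance the test is anticonservative; the 10-point
  difference filter absorbs much of this in practice, but a
  beta-binomial test would be the principled extension.
* The region model is intentionally minimal (no bimodal inter-CpG
  distance model, no weighting by coverage in the combined p).
* Consensus projection ignores indels; positional profiles of old,
  indel-rich subfamilies will blur.
* DMR and enrichment results depend on the annotation catalog supplied;
  the shipped group map covers the common repeat classes only.
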