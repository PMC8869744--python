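# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic data generator does and does not
emulate, and the known limitations.

## Coordinate and sequence conventions

All genomic coordinates are 1-based and inclusive (GFF3 convention); any
0-based half-open representation is produced only at a writer. Sequences
are normalized internally to a single alphabet (DNA for genome/targets,
RNA for mature miRNAs); T/U are interchangeable at every interface.

## lncRNA identification

A transcript is kept as an lncRNA iff it passes **all** of: length
> 200 nt; exon count ≥ 2; CPC score < 0; CNCI score < 0; CPAT coding
probability < 0.85; longest ORF ≤ 100 aa; no BLASTX hit; no Pfam hit.
Failures carry the full list of violated criteria, so the filter is
auditable. The exon threshold is deliberately ≥ 2 (not > 2): a stricter
reading would contradict the observation that the vast majority of
identified lncRNAs have 2–4 exons, and the threshold is exposed as a
config knob (`min_exons`). The upstream scorers are not re-implemented:
their outputs are consumed as a per-transcript table, and the BLASTX/Pfam
booleans are expected to embed the usual homology gate (E < 1e-10,
coverage > 85%, identity > 95%).

The ORF scanner considers the three forward frames only (the transcript is
already stranded), requires ATG initiation and an in-frame stop, reports
the length in amino acids excluding the stop, and treats any codon
containing N as breaking the frame. It is verified against an independent
enumerate-every-ATG oracle, including a derandomized property test.

Positional classification: *antisense* if any lncRNA exon overlaps a
coding gene's exon on the opposite strand; *sense* likewise on the same
strand; *intronic* if the lncRNA's genomic span lies fully inside one
intron (strand-agnostic by default — whether intronic containment should
require the same strand is genuinely ambiguous, so it is a flag,
`intronic_same_strand`); *lincRNA* otherwise. When multiple genes give
conflicting evidence, precedence is antisense > sense > intronic >
lincRNA: exon-level evidence outranks intron containment.

## Expression and differential testing

TPM is the within-sample normalization: TPM_i = (c_i/l_i) / Σ_j (c_j/l_j)
× 10⁶. The low-expression summary uses TPM < 1 throughout (a single
quantification unit is used everywhere rather than mixing FPKM and TPM).

The differential test is a self-contained NB Wald test:

* **size factors** — median of ratios to the per-feature geometric mean
  (features containing zeros are excluded from the geometric means; if
  every feature touches zero the fallback is total-count scaling);
* **dispersion** — per-feature pooled method-of-moments,
  α̂ = (pooled within-group variance − mean)/mean², floored at 1e-8, then
  **moderated**: each feature takes max(α̂, median over features). The
  moderation matters: at 3 vs 3 replicates the raw MoM estimate is noisy
  enough that the Wald test becomes anticonservative (measured per-test
  type-I error ≈ 0.11 at nominal 0.05); taking the larger of the gene-wise
  and central estimate — the classic conservative variant of
  gene-wise-vs-fitted dispersion handling — brings it to ≈ 0.05
  (0.042–0.055 across seeds);
* **statistic** — Wald z of the difference of log group means with the
  delta-method variance Var(ln μ̂) ≈ (1/μ + α)/n per group, two-sided
  normal p; a pseudocount of 0.5 on group means keeps zero-count groups
  finite. Log2 fold changes are testis over ovary, so testis-biased = up.
* **multiple testing** — Benjamini–Hochberg within each RNA class.

This approximates DESeq2 (which shrinks both dispersions and fold
changes); on the strong planted effects the calls coincide, and the suite
checks calibration (type-I error) and power (recall ≥ 0.8, FDR ≤ 0.2 for
|log₂FC| = 4 at 3 vs 3) directly rather than DESeq2 agreement. All-zero
features are reported with log₂FC = 0, p = 1 and a flag.

Calling gates: mRNA/lncRNA |log₂FC| > 2 with padj < 0.001; miRNA
|log₂FC| > 1 with padj < 0.05.

## Target prediction

Seed sites are found by scanning the target (5'→3') for the reverse
complement of miRNA nucleotides 2–7; a hit is upgraded by a match to
position 8 (7mer-m8), an A opposite position 1 (7mer-A1), or both (8mer).
Site strength is scored by a pairing-count duplex score rather than a
thermodynamic energy: the miRNA 3' end (positions 9+) is aligned, ungapped
and antiparallel, against the 10 nt of target context 5' of the site; the
best alignment contributes −2 per Watson–Crick pair and −1 per G:U wobble,
plus a site-type bonus (8mer −8, 7mer-m8 −6, 7mer-A1 −5, 6mer −3). Sites
are retained when the score is **strictly below −10**. The score is
monotone in pairing strength, so a bare 6mer (−3) can never pass while an
8mer with a complementary context always does; this reproduces the intent
of an energy gate with a fully reproducible integer-arithmetic score. A
rank-based context filter (`context_percentile_filter`, keep the better
half per miRNA) is available for TargetScan-style percentile pruning but
is not applied by default.

*cis*-targets: genes whose span intersects the lncRNA span extended by
100 kb on both sides, same scaffold, either strand, closed boundary (a
gene starting exactly 100 000 bases away counts — "about 100 kb" forces a
convention), excluding the lncRNA's own host gene. Distances are measured
from transcript boundaries.

*trans*-targets: all lncRNA–mRNA pairs with |Pearson r| > 0.95 computed on
log₂(TPM+1). The log transform is a deliberate choice: raw-TPM Pearson at
n = 6 is dominated by single outlying samples. Zero-variance profiles are
skipped and logged.

## ceRNA triplets

For each DE miRNA m, with L(m) its predicted DE lncRNA targets and G(m)
its DE mRNA targets, every pair (l, g) ∈ L(m)×G(m) with PCC > 0.9 and
p < 0.05 yields the triplet (l, m, g). Notable choices:

* the correlation gate is **one-sided positive** (competition predicts
  positive lncRNA–mRNA co-expression), unlike the absolute-value trans
  rule — both are implemented exactly as stated;
* p comes from the t transform (df = n−2), not permutation, for
  determinism and speed; r = ±1 maps to p = 0. The exhaustive-permutation
  test is kept as a test oracle. At n = 6 the two do **not** agree
  pointwise: the permutation null is granular at 1/720 and its p can
  differ from the t-based p by > 0.1 at moderate |r|. The suite asserts
  the rank agreement of the two and documents the pointwise divergence;
  a stricter pointwise-agreement check is knowingly left failing as a
  record of this fact;
* p-values are not adjusted for the number of (l, g) pairs (exposed as a
  threshold flag); no same-direction requirement is imposed on l and g;
* multiple sites of one miRNA on one target collapse to a single edge;
  output is deduplicated and sorted, hence deterministic.

The network export writes GraphML, Cytoscape SIF and a node-attribute
table (node type, DE direction); edge count is 2 × the number of distinct
(l, m) and (m, g) pairs.

## miRNA genomics

Read assignment allows up to 3 nt of extension/trimming at each end
(exposed as `end_tolerance`; the underlying rule — "length variation at
both ends" — states no bound, so one is fixed and configurable) and at
most 1 mismatch in the overlap; best = fewest mismatches, then longest
overlap, then lexicographic reference id.

Clusters are single-linkage chains per scaffold: sort by start, join
consecutive loci when the end-to-start gap (floored at 0 for overlaps) is
≤ 10 kb, discard singletons. Chaining is transitive (A–B 8 kb and B–C
8 kb puts all three in one cluster even though A–C exceeds 10 kb) and
strand-agnostic; both choices are the conservative reading of
"colocalized within 10 kb" and are verified against an O(n²)
connected-components oracle. Clustered fractions are reported half-up to
one decimal (printed-table convention).

Seed families group matures by exact nucleotides 2–8; curated names cover
let-7 (GAGGUAG), miR-125b (CCCUGAG) and miR-100 (ACCCGUA), other families
are labelled by their seed. The consensus/PFM aligns sequences at the 5'
end, pads at the 3' end, computes per-position frequencies over the
sequences reaching that position, and emits IUPAC codes at ties.

Host relations of an lncRNA to a pre-miRNA locus: host_exonic (precursor
inside an exon, same strand), host_intronic (inside the span but not an
exon, same strand), antisense (any opposite-strand overlap), none.

## The synthetic data generator

The generator emulates the study design the pipeline targets: two groups
× 3 replicates; a multi-scaffold genome (default 3 × 1.5 Mb) carrying 60
protein-coding genes (1–20 exons), 40 lncRNAs in a positional mixture
(~55% intergenic, 25% antisense, 12% intronic, 8% sense, approximating
observed class proportions), and 24 pre-miRNA loci of which three planted
clusters (gaps ≤ 10 kb by construction) and the rest isolated (> 10 kb
from anything, so the 10-kb rule recovers the planted partition exactly);
negative-binomial counts (variance μ + αμ², α = 0.05 by default, mean
parameterized; gamma–Poisson sampling) with planted |log₂FC| = 4 effects
on 30% of features; and 5 planted ceRNA triplets.

Design choices that make the planted truth exact:

* **8mer planting** — each triplet's lncRNA and mRNA (3'-UTR stand-in =
  the transcript-sense last exon) receive the site
  revcomp(mature[2:]) + A: a perfect seed 8mer whose upstream flank is
  fully complementary to the miRNA 3' end, so the site always clears the
  −10 duplex gate.
* **core scrubbing** — chance occurrences of any simulated miRNA's 6mer
  seed core in a scanned target sequence are degraded by one substitution
  (on the spliced transcript, so junction-spanning matches are caught),
  and a triplet miRNA is not chosen if its planted site would embed
  another miRNA's core. Recovery of planted sites is therefore
  unambiguous; a real genome, by contrast, is full of chance 6mers, which
  is why real analyses lean on conservation or energy filters.
* **co-expression** — triplet members share a per-sample lognormal latent
  factor (σ = 0.25 on the log scale) *and* the planted DE shift. At
  |log₂FC| = 4 the shift alone contributes ≈ 1.9 of shared log-scale
  variance against ≈ 0.05–0.1 of independent NB noise, putting the
  expected lncRNA–mRNA Pearson r near 0.97. The factor SD is kept small
  deliberately: a large factor (σ = 1) would push within-group variance
  high enough that the planted fold changes no longer clear
  padj < 0.001 at 3 vs 3 — co-expression strength and DE detectability
  trade off through the same variance term.
* **coding scores** — true lncRNAs satisfy each of the six score criteria
  independently with probability 1 − noise, coding transcripts the
  converse; at noise = 0 the filter recovers the truth exactly, and the
  noisy pass rate follows the (1 − noise)^6 binomial closed form.

What it does **not** emulate: read-level data (FASTQ, sequencing error,
rRNA contamination), transcript assembly uncertainty, overlapping gene
models, multi-isoform genes, batch effects, library-composition bias, and
realistic seed-site background (see scrubbing above). Passing the
planted-truth suites therefore demonstrates correctness of the inference
chain, not performance on real tissue data.

## Problem sizes and determinism

The default simulated genome (3 scaffolds × 1.5 Mb, 124 features, 6
samples) generates in ~0.1 s, and a full pipeline run in ~0.3 s; the
calibration suites use 2 000-feature count matrices over 10 seeds. These
sizes were chosen so the whole test suite and the acceptance script run
in seconds while keeping every Monte-Carlo check adequately powered. All
randomness flows from a single integer seed (numpy default_rng); fixed
seed ⇒ byte-identical GFF3, FASTA, count tables and summary JSON.

## Known limitations

* The NB test has no fold-change shrinkage; effect estimates at low
  counts are noisier than DESeq2's MAP estimates.
* The duplex score is a pairing count, not an energy; it orders sites
  sensibly but its absolute scale is only anchored by the −10 gate.
* Venn partitioning of identification evidence treats CPAT/ORF/Pfam as
  one method, mirroring the four-method presentation used in this
  literature.
* `build_triplets` computes one correlation per (lncRNA, mRNA) pair and
  caches it; memory grows with the number of DE pairs, which is fine at
  study scale (hundreds of DE features) but would need chunking for
  genome-wide all-pairs use.
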