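# cernapipe

Inference of lncRNA–miRNA–mRNA *competing endogenous RNA* (ceRNA) networks
from gonad transcriptomes, built for studies that contrast ovary and testis
expression — e.g. gynogenetic fish where genetically female (XX) individuals
sex-reverse into functional neo-males. The package chains the five analysis
stages such studies run between a genome annotation plus count matrices and
a ceRNA network, and ships a planted-truth simulator so every stage is
testable end to end without any external data.

## What it computes

1. **lncRNA identification** — candidate transcripts pass the intersection
   filter: length > 200 nt, ≥ 2 exons, CPC score < 0, CNCI score < 0, CPAT
   coding probability < 0.85, longest ORF ≤ 100 aa, and no BLASTX/Pfam
   homology (the external scorers are consumed as a table). Survivors are
   classified by position against protein-coding genes as intergenic
   (lincRNA), intronic, antisense, or sense.
2. **Differential expression** — TPM normalization and a self-contained
   negative-binomial Wald test (median-of-ratios size factors,
   trend-moderated method-of-moments dispersion, BH adjustment). Calls use
   class-specific gates: |log₂FC| > 2 and adjusted *p* < 0.001 for
   mRNA/lncRNA, |log₂FC| > 1 and adjusted *p* < 0.05 for miRNA; positive
   fold change (testis/ovary) means testis-biased.
3. **Target prediction** — canonical seed matching (8mer, 7mer-m8, 7mer-A1,
   6mer sites against miRNA nucleotides 2–8) gated by a pairing-count
   duplex score (sites kept below −10); lncRNA *cis*-targets (genes within
   100 kb) and *trans*-targets (|Pearson r| > 0.95 on log₂(TPM+1)).
4. **ceRNA triplets** — for every DE miRNA, each pair of its DE lncRNA and
   DE mRNA targets with co-expression PCC > 0.9 at *p* < 0.05 (two-sided
   *t* transform, *t* = r·√(n−2)/√(1−r²)) becomes a triplet
   (lncRNA, miRNA, mRNA); the network exports to GraphML/SIF.
5. **miRNA genomics** — small-RNA read assignment (±3 nt end variation,
   ≤ 1 internal mismatch), genomic miRNA clusters (loci chained within
   10 kb), seed families (nucleotides 2–8; let-7 = GAGGUAG), consensus
   position-frequency matrices, and miRNA-host lncRNA (lncmiRHG)
   classification.

The simulator (`cernapipe.synthetic`) generates a toy multi-scaffold genome
with genes, lncRNAs in all four positional classes, clustered and isolated
pre-miRNA loci, negative-binomial counts for two groups × 3 replicates with
planted sex-biased fold changes, and ceRNA triplets whose members carry
planted 8mer seed sites and a shared expression factor — all returned with
a machine-readable ground truth.

## Worked example

```python
from cernapipe import SimConfig, generate_annotation, simulate_counts, NBDifferential

cfg = SimConfig(seed=1)                      # 60 genes, 40 lncRNAs, 24 miRNA loci
ann, seqs, truth = generate_annotation(cfg)
mats = simulate_counts(truth, cfg)
res = NBDifferential(mats["mRNA"], "mRNA").fit()
print(res.summary())
```

prints

```
NB Wald differential expression (mRNA)
features: 60   gates: |log2FC| > 2, padj < 0.001
testis-biased: 11   ovary-biased: 10   ns: 39
```

i.e. 21 of 60 simulated mRNAs are called sex-biased at the mRNA gates
(the generator planted ~30% DE features at |log₂FC| = 4, and the first
rows of `res.frame` show the per-feature estimates):

```
           log2fc        p     padj           call
mrna_0000   -0.37    0.181    0.339             ns
mrna_0001    4.33 2.62e-51 7.85e-50  testis-biased
mrna_0002   -3.98 4.02e-23 1.86e-22   ovary-biased
```

Running every stage at once:

```python
from cernapipe.io import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(seed=1), outdir="run1")
print(summary["cerna"], summary["recovery"]["triplets"])
```

```
{'n_triplets': 5} {'n_true': 5, 'n_recovered': 5, 'recall': 1.0, 'precision': 1.0}
```

— all five planted ceRNA triplets are recovered with no spurious ones, and
`run1/` holds each stage's artifacts (GFF3, count and DE tables, seed-site
table, GraphML/SIF network, cluster table, `summary.json`).

The same stages are available as CLI subcommands
(`cernapipe simulate | lncid | de | targets | cerna | mirclust | run`).

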