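# promnet

Promoter-centric discovery of candidate regulatory transcription factors
(TFs) for a disease gene set, with estrogen-responsiveness stratification.

## The problem

Given a curated set of disease-associated genes, which TFs are the most
plausible master regulators — and therefore candidate biomarkers?  promnet
answers this with a classic promoter-scanning pipeline:

1. **ERE prediction.** Each gene promoter (window `[-1000, +200]` around the
   TSS) is scanned for estrogen response elements — degenerate palindromes
   `GGTCA-nnn-TGACC`, matched with up to 2 mismatches over the ten half-site
   positions.
2. **Four-group partition.** Genes are partitioned by (ERE predicted,
   experimental estrogen evidence): group 1 = both, 2 = ERE only,
   3 = evidence only, 4 = neither.  Groups 1 and 3 pooled form the
   *experimentally estrogen-controlled* set.
3. **TFBS scanning.** Promoters are scanned with a library of
   position-frequency matrices using Match-style scoring.  With
   `I(i) = Σ_b f(i,b) ln(4 f(i,b))`, a window `s` scores

       MSS = (Σ_i I(i) f(i, s_i) − Min) / (Max − Min)  ∈ [0, 1]

   and the core similarity score (CSS) applies the same normalisation to
   the 5 most informative consecutive positions.  Per-matrix cutoff pairs
   emulating a minimum-false-positive profile are calibrated so background
   hit density stays below a target rate (default 0.5 sites/kb).
4. **Enrichment filter.** Each matrix receives an over-representation
   index against a background promoter set,

       ORI = [(t+p)/T_kb] / [(b+p)/B_kb] × [(cov_t+ε)/(cov_b+ε)],

   (hit-density ratio × promoter-coverage ratio, pseudocount `p`,
   `ε = 1/n_background`); matrices with ORI ≥ 2 are kept.
5. **Network and ranking.** Enriched matrices link their TFs to every gene
   whose promoter they hit.  TFs are ranked by out-degree (distinct target
   genes) and only TFs at or above the 80th percentile (nearest-rank) of
   the out-degree distribution are retained as candidates.
6. **Site statistics.** TFBS-to-nearest-ERE distance records and
   histograms, a Gaussian-kernel density of TFBS positions around the TSS,
   and annotation-term fractions per gene group.

A seeded synthetic-cohort generator (`promnet.synthetic_data`) emulates the
study conditions — background promoters from a base-composition model,
consensus motifs planted at controlled enrichment ratios, planted EREs,
Bernoulli evidence flags — with a truth ledger for recovery benchmarks.

## Worked example

Generate the study-scale reference cohort (323 target genes, 200
background promoters, 25 planted matrices of which 5 are designated
high-enrichment TFs) and run the full analysis:

```
promnet simulate --out cohort/ --seed 1
promnet run --config config.yaml          # paths as written by simulate
```

or in Python:

```python
from promnet import synthetic_data as sd
from promnet.pipeline import PipelineConfig, run_full

cohort = sd.generate_cohort(sd.reference_cohort_spec(seed=1), outdir="cohort")
result = run_full(PipelineConfig(
    pwm_library="cohort/pwm_library.jaspar",
    target_fasta="cohort/target_promoters.fasta",
    background_fasta="cohort/background_promoters.fasta",
    gene_table="cohort/gene_table.tsv",
    matrix_tf_map="cohort/matrix_tf_map.tsv",
    out_dir="run",
))
print(result.counts)
```

At seed 1 this prints (among other counts):

```
group1_genes=11  group2_genes=54  group3_genes=66  group4_genes=192
experimental_genes=77  ere_promoters=65
tfbs_target_hits=8403  enriched_matrices_full=24
retained_tfs_full=5
```

Reading: the scanned ERE flags split the 323 genes exactly into the
configured group sizes (11/54/66/192; 77 in the experimentally controlled
union; 65 ERE-bearing promoters).  8403 TFBSs are predicted on target
promoters; 24 of 25 matrices pass the ORI ≥ 2 filter, and the percentile
rule retains 5 top-ranked TFs — exactly the five designated
high-enrichment TFs (`TF001`–`TF005`), i.e. the planted regulators are
recovered.  The output directory holds the group table, BED site files,
per-scope ORI/edge/ranking tables, TFBS–ERE distance statistics, the TSS
density profile and a stage-count log.

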