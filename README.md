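# atacnet

Integration toolkit for two-condition ATAC-seq studies of regulatory
chromatin, written for the isogenic tumor-versus-edited comparisons used in
pediatric glioma epigenomics (e.g. H3.3K27M DIPG lines against their
CRISPR-reverted wild-type counterparts).  Starting from replicate peak sets,
a genome, gene models, an expression table and an H3K27ac/super-enhancer
catalog, it answers the chain of questions such a study asks:

1. **Which peaks are condition-specific?**  Occupancy-based calling
   (consensus across replicates of one condition, zero overlap with any
   replicate of the other) or a count-based test: median-of-ratios size
   factors, a common negative-binomial dispersion α (variance = μ + αμ²)
   estimated by bias-corrected method of moments, and a per-peak
   likelihood-ratio test of equal means referred to χ²₁, with
   Benjamini–Hochberg FDR across peaks.
2. **Where do they fall?**  Promoter (−2 kb/+1 kb around the TSS,
   strand-aware) / exon / intron / intergenic classification with
   promoter-first precedence.
3. **Which expression changes do they explain?**  Peak-to-gene-body links
   and selection of genes whose significant up(or down)-regulation is
   concordant with condition-specific accessibility.
4. **Which enhancers and super-enhancers are involved?**  Enhancers =
   H3K27ac minus promoters; regions are tied to genes with a GREAT-style
   basal-plus-extension rule (5 kb/1 kb basal, ≤1 Mb extension truncated at
   neighboring basal domains); super-enhancers containing condition-unique
   peaks are reported with their associated upregulated genes.
5. **Which TF motifs drive them?**  FIMO-style PWM scanning on both strands
   with exact score p-values P(S ≥ s) under the background model, and fold
   enrichment against composition-preserving scrambles of the same
   sequences (enriched ⇔ regularized fold ≥ 2).
6. **What is the regulatory network?**  A bipartite TF→gene graph linking
   each enriched motif's TF to the upregulated genes whose
   condition-specific peaks carry its sites, with peak-level evidence per
   edge, pairwise target-overlap (Jaccard) statistics and
   GraphML/SIF/TSV export.

Gene-set over-representation (hypergeometric upper tail, per-category
Benjamini–Hochberg) is included for GO/KEGG-style readouts of any gene list
the pipeline produces.

Because studies of this design are frequently analyzed before raw data are
public, the package ships a first-class synthetic-data generator
(`atacnet.simulate`) that reproduces the statistical structure the analysis
assumes — two conditions × replicates, shared and condition-unique peaks,
NB-distributed counts, motif instances implanted into condition-specific
peaks, an expression table coupled to those peaks, and an H3K27ac /
super-enhancer layer — together with exact truth tables, so every stage is
testable end to end without downloads.

## Worked example

```python
from atacnet import SimulationConfig, generate_dataset, fixture_library, run_pipeline
from atacnet.network import tf_overlap

ds = generate_dataset(SimulationConfig(seed=1))     # 2 conditions x 2 replicates
res = run_pipeline(ds, fixture_library(), shuffle_seed=1)
k27m = res.conditions["K27M"]
print(f"condition-unique peaks: K27M={len(k27m.unique_peaks)}, "
      f"WT={len(res.conditions['WT'].unique_peaks)}, shared={len(res.shared_peaks)}")
for m, e in sorted(k27m.enrichments.items()):
    print(f"{m:>13}: observed={e.observed:3d} background={e.background_mean:5.2f} "
          f"fold={e.fold:5.2f} enriched={e.enriched}")
print(f"upregulated genes with K27M-specific peaks: {len(k27m.selected_genes)}")
print(f"network: {len(k27m.network.tf_nodes)} TFs -> "
      f"{len(k27m.network.gene_nodes)} genes, {len(k27m.network)} edges")
```

prints

```
condition-unique peaks: K27M=50, WT=50, shared=150
   AP1_FOSJUN: observed=  1 background= 0.20 fold= 1.67 enriched=False
   EBOX_ASCL1: observed= 13 background= 0.10 fold=12.73 enriched=True
 EBOX_NEUROD1: observed= 12 background= 0.10 fold=11.82 enriched=True
upregulated genes with K27M-specific peaks: 30
network: 2 TFs -> 14 genes, 14 edges
```

Reading this: the occupancy caller recovered all 50 truth-unique peaks per
condition; the two E-box proneural motifs implanted into K27M-specific
peaks are strongly enriched over their scrambled backgrounds (fold ≈ 12–13)
while the un-implanted AP-1 control stays below the fold-2 line; the 30
upregulated genes hosting K27M-specific peaks are exactly the generator's
coupled genes; and the network connects the two enriched TFs to the 14
upregulated genes whose peaks carry implanted sites.  (In this synthetic
default each gene receives one implant, so the two TFs' target sets are
disjoint — `tf_overlap` reports Jaccard 0; real data typically show
substantial overlap.)

The same stages are available from the shell via the `atacnet` CLI
(`simulate`, `annotate`, `diff`, `integrate`, `enhancers`, `motifs`,
`enrich`, `network`); run `atacnet --help`.

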