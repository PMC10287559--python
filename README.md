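# gutsig

Analysis toolkit for transcriptional profiling of colonic inflammation in
primary sclerosing cholangitis (PSC) and inflammatory bowel disease (IBD)
cohorts — for computational immunologists and GI researchers studying how
inflammation relates to colorectal dysplasia risk.

Patients with PSC (which co-occurs with IBD in ~90% of cases) face a much
higher risk of colorectal neoplasia than patients with IBD alone. `gutsig`
implements the analysis chain that links a distinctive, highly inflamed
right-colon transcriptional state ("I2") to dysplasia risk:

1. **Bulk transcriptome clustering** — log2 CPM normalisation with
   expression (median count > 5) and biotype (protein-coding + TCR/Ig
   receptor) filters, per-gene batch-mean correction, mean–variance
   highly-variable-gene selection (top 3,000), PCA (40 components), Ward
   hierarchical clustering into two uninflamed (U1, U2) and two inflamed
   (I1, I2) patient groups, ordered by a single-sample GSEA (ssGSEA)
   inflammatory score.
2. **I2 classifier** — silhouette-positive "core" samples, features from the
   union of differentially expressed genes (moderated-t linear models with
   sex/age/batch covariates, BH-adjusted p < 0.05 in any U2/I1/I2 contrast),
   then elastic-net logistic regression (mixing α = 0.5, penalty chosen by
   10-fold CV over a 100-point λ path) on a stratified 70/30 split,
   evaluated by rank-based AUC on the held-out 30%.
3. **Double-positive CD4 T cells** — pooled-deconvolution size factors,
   flow-cytometry-calibrated UMI thresholds for IL17A+FOXP3+ (DP) versus
   single-positive cells, a pathogenic IL-17 signature score, Fisher-exact
   top-versus-bottom-decile enrichment (conditional-MLE odds ratios), and
   pseudobulk moderated-t differential expression with patient blocking.
4. **TCR repertoire** — CDR3s trimmed to the span between the leftmost and
   rightmost codon that is mutated or overlaps a non-templated N-region;
   motif (default "LA") proportions compared between subsets by Wilcoxon
   rank-sum; a three-frame census showing the leucine–alanine motif is
   germline-encoded in exactly one TRBD2 reading frame; V/D/J usage tables.
5. **BCR clones** — single-linkage clonal grouping (shared V/J/junction
   length, ≤ 0.15 junction Hamming), top clones with ties, light-chain
   consistency enforcement, and amino-acid divergence (germline and
   pairwise) for CDR3 versus the full heavy chain.
6. **Survival** — ever-I2 patient classification, time from colitis
   diagnosis to right-sided (or non-right-sided) dysplasia, Tukey-fence
   follow-up outlier removal, Kaplan–Meier curves and log-rank tests.

A synthetic-data module (`gutsig.synthetic`) generates cohorts with the
statistical structure every stage assumes — negative-binomial bulk counts
with planted cluster programs, DP/SP CD4 cells with a matched flow table,
V(D)J repertoires assembled from germline segments, power-law B-cell clones
with CDR3-hotspot hypermutation, and a replica clinical cohort whose event
margins are reproduced exactly — so the full pipeline runs at desk scale
with no downloads.

## Worked example

```python
from gutsig import pipeline, synthetic

cfg = synthetic.SimConfig(seed=7)          # 150 samples, effect = 2
gcm, samples = synthetic.simulate_bulk_cohort(cfg)
model, expr = pipeline.cluster_bulk(gcm, samples)
print(model.labels.value_counts().to_dict())

run = pipeline.train_i2_classifier(expr, model, samples, seed=7)
print("held-out AUC:", run.test_auc,
      "| nonzero genes:", len(run.enet.nonzero_genes()))
```

prints

```
{'U1': 75, 'U2': 42, 'I1': 22, 'I2': 11}
held-out AUC: 1.0 | nonzero genes: 58
```

The cohort splits into the two uninflamed groups, a moderately inflamed I1
and a small highly inflamed I2 (mean ssGSEA inflammatory scores 0.04/0.07 <
0.23 < 0.36); the elastic-net model separates held-out I2 samples perfectly
(AUC = 1), with most of its nonzero coefficients on the planted 81-gene
inflammation program.

The same stages are scriptable from the shell:

```sh
gutsig simulate bulk --seed 7 --out demo/
gutsig cluster --counts demo/counts.tsv --genes demo/genes.tsv \
       --meta demo/samples.tsv --out demo/
gutsig simulate survival --seed 0 --out demo/
gutsig survival --records demo/survival.tsv --side right --out demo/km.json
```

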