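# Methods

This note records the statistical models, defaults and design choices behind
each `gutsig` module, and what the synthetic cohorts do and do not show
about real data.

## Bulk transcriptome clustering

Counts are normalised to log2 counts-per-million with a 0.5 pseudocount and
library size + 1 (the voom convention); the source description names only
"log2 CPM", so the pseudocount is our choice and is fixed rather than
exposed. Genes enter the analysis when their median count across samples is
strictly greater than 5 and their biotype is protein-coding or a TCR/Ig
receptor gene.

Batch correction subtracts per-gene batch-mean offsets relative to the grand
mean, which preserves each gene's overall mean exactly. The correction
method was an open choice; mean-centring is the simplest operator consistent
with a linear batch effect, and singleton batches are left untouched (their
batch mean is confounded with the sample). Whether highly variable genes are
selected before or after correction was also open; we correct first, then
select.

Highly variable genes are ranked by the residual of log10 variance from a
LOESS trend on mean expression (span 0.3). Residuals are standardised and
clipped at sqrt(n_samples) so one extreme sample cannot dominate, with raw
residuals breaking ties among clipped genes; zero-variance genes are never
selected. The default panel is 3,000 genes (shrunk to the available count on
small matrices).

PCA is computed on centred, per-gene unit-scaled expression (scaling is a
flag; on by default). The default 40 components are chosen for consistency
with cohorts where they explain at least 70% of variance; on noisier
matrices the function warns rather than fails. Clustering is Ward
agglomeration on Euclidean distances in PC space, cut at k = 4. Clusters are
named by their mean inflammatory ssGSEA score: the two lowest become U1
(the larger) and U2, then I1, then I2. The U1/U2 size rule is cosmetic — the
two uninflamed clusters are treated as one group ("U") in most downstream
analyses.

The ssGSEA score ranks genes per sample (descending), accumulates
rank-weight^alpha (alpha = 0.25, weights normalised over in-set genes) at
in-set positions and 1/(N − |S|) at out-of-set positions, and reports the
sum of the running statistic divided by N. With every gene in the set the
statistic degenerates and the score is defined as 0. The statistic is purely
rank-based, hence invariant under monotone transformations of expression.

Differential expression fits per-gene linear models of log2 CPM on group
membership plus covariates (sex, age, batch in the emulated design).
Residual variances are shrunk toward their grand mean with 4 prior degrees
of freedom (empirical-Bayes moderation in the limma style; `prior_df = 0`
recovers the classical equal-variance t exactly). Confounded designs (group
collinear with a covariate) are rejected. Multiple testing uses
Benjamini–Hochberg throughout.

## I2 elastic-net classifier

Core samples are those with strictly positive silhouette on the same PC
coordinates used for clustering (singleton clusters score 0 and drop out).
Features are the union of genes with adjusted p < 0.05 in any of the three
pairwise contrasts among U2, I1 and I2 on core samples. The model is binary
I2-versus-rest (a multinomial variant was considered and rejected as the
target label is a single state); features are z-scored on the training
split.

The penalty path follows glmnet's parameterisation: 100 log-spaced lambdas
from lambda_max (the smallest penalty that zeroes every coefficient) down
four decades, solved by iteratively reweighted least squares with cyclic
coordinate descent, warm-started along the path (numba-compiled; the test
suite cross-checks coefficients against scikit-learn's saga solver to
~1e-5). The mixing parameter defaults to alpha = 0.5 and is exposed. Lambda
is chosen to minimise mean 10-fold cross-validated binomial deviance; folds
are stratified and reduced with a warning when a class has fewer than 10
training members. The train/test split is stratified 70/30 with a fixed
seed. Predictions use the logistic of the standardised linear score with a
0.5 label threshold; evaluation is the rank-based AUC (Mann–Whitney U
normalised, ties counted one half).

New cohorts are predicted with the training standardisation statistics; no
joint re-correction with the training batches is attempted unless the caller
applies `batch_correct` with overlapping batches first.

## Double-positive CD4 T cell analysis

Genes with mean log2 CPM ≤ 0.01 are removed, then pooled-deconvolution size
factors are computed: cells are ordered by library size and interleaved on a
ring; for pools of 21, 41 and 61 consecutive cells, the median ratio of the
pooled normalised profile to the average cell gives one linear equation in
the per-cell factors, and the stacked sparse system is solved by least
squares with a low-weight mean-1 anchor. Factors are scaled to mean 1 and
cells outside [0.125, 8] are removed.

The DP/SP threshold is a single integer UMI cutoff shared by both markers
(per-gene thresholds are available by flag), searched over 1..10 to minimise
the summed absolute difference between per-sample single-cell DP frequencies
and the flow-cytometry DP frequencies; ties break toward the smaller
threshold. Labels partition cells into DP, IL17A_SP, FOXP3_SP and DN.

The pathogenic IL-17 signature score is the z-scored mean of normalised log
expression over the signature panel — a deliberate simplification of
per-cell GSEA that is robust at shallow UMI depth. The packaged default gene
list is a replaceable stand-in; any GMT can be supplied. Decile enrichment
takes exactly ⌊0.1·n⌉ cells from each end of the score distribution (ties
broken by stable cell-id order), builds the (top/bottom) × (DP/not) table,
and reports the sample odds ratio ad/bc, the conditional-MLE odds ratio with
its exact 95% CI, and the two-sided Fisher exact p. When stratified, deciles
are computed within stratum. A mitochondrial-fraction filter (< 50%) applies
only when a mito gene list is provided.

Pseudobulk DE averages normalised log counts per (patient, subset), keeps
patients contributing both subsets, and fits the moderated-t model with the
patient as a blocking factor.

## TCR repertoire

Nonproductive chains are removed; among same-locus chains sharing a barcode
the highest-read-support chain wins (ties to the lexicographically smallest
junction). Trimming marks a CDR3 position as mutated when its codon differs
from the aligned germline codon at any nucleotide or overlaps an N-region
(codons spanning templated and non-templated nucleotides count as mutated —
the goal is isolating non-germline-encoded sequence; a flag excludes
N-regions). The trimmed span is inclusive of both boundary mutated residues
and empty when nothing is mutated; re-trimming a trimmed span is a no-op.

Motif proportions are computed per (patient, subset) over deduplicated
chains and compared by two-sided Wilcoxon rank-sum on per-patient
proportions. De novo motif discovery is out of scope; the motif is a
parameter (default "LA") and an exhaustive k-mer (k = 2, 3) scan is provided
as a simple substitute. The TRBD2 frame census translates the germline
segment at offsets 0/1/2 (stops rendered '*', trailing partial codons
dropped) and reports which frames contain the motif; for both packaged TRBD2
alleles "LA" appears in exactly one frame (offset 1, GLAGG).

## BCR clones

Clonal grouping uses the standard repertoire heuristic: sequences sharing V
gene, J gene and junction length are single-linkage-merged when junction
nucleotide Hamming distance ≤ 0.15 (normalised). A supplied clone_id column
bypasses grouping entirely, so externally inferred clonal families can be
consumed as-is. The clone germline is the fixture germline when members
agree on one, else the column-wise majority consensus — full naive-ancestor
reconstruction is out of scope. Divergence statistics are amino-acid Hamming
proportions on gap-free alignments (ambiguity positions excluded from both
numerator and denominator): mean member-to-germline divergence, and mean
over all unordered member pairs (undefined for singletons), each for the
CDR3 span or the full chain. Top clones are all clones tied at maximum size;
light-chain consistency keeps the majority light chain (ties keep the
lexicographically smallest id, with a warning).

## Survival

A patient is ever-I2 when any visit, including visits during or after the
first dysplasia diagnosis, carries the I2 label. Time runs from colitis
diagnosis to the first event on the requested side, else to the last
colonoscopy (censored); right-sided and non-right-sided dysplasia are
independent endpoints, so a patient with only the other side's event is
censored. Times are days / 365.25. Follow-up outliers are removed once (not
iterated) using Tukey fences at 1.5×IQR within each diagnosis group, with
type-7 (linear interpolation) quartiles — fence membership depends on the
quantile convention, so it is fixed and documented; the multiplier is
configurable. The removal is applied by the caller (the CLI exposes it as a
flag) because whether it applies to the right-sided endpoint as well as the
non-right-sided one was an open choice; the default workflow applies it only
to the non-right-sided analysis. Curves are product-limit estimates with
simultaneous handling of tied event times; groups are compared by the
two-sided log-rank test (lifelines).

## Synthetic cohorts

The bulk generator draws gene-wise negative-binomial counts (shared
dispersion 0.1, log-normal gene means, log-normal per-sample depth). Two
planted programs define the four clusters: an 81-gene inflammation program
up-shifted by half the configured effect (default 2 log2 units) in I1 and
the full effect in I2, and an 80-gene subtype program (0.75× the effect) on
U1 only, so that all four clusters are separable when the effect is nonzero
and none are when it is zero. The subtype program deliberately sits on U1 —
the one cluster absent from the classifier's U2/I1/I2 feature contrasts — so
the I2 signal is carried by the inflammation program alone. Cluster
membership is drawn per diagnosis (50 PSC / 50 IBD / 50 healthy controls by
default) with I2 common in PSC (27%), rare in IBD (7%) and nearly absent in
controls (1%). Per-gene batch shifts are Gaussian with 0.2 log2 sd over 2
batches.

CD4 cells carry marker transcripts only in truth-positive cells (1 + Poisson
counts; cytokine transcripts at 10x depth are effectively absent in negative
cells), a 25-gene signature panel doubled in DP cells, and 5% DP / 15% + 15%
SP frequencies; the flow table holds the per-sample truth frequencies. TCR
chains are assembled as V end + N codon + TRBD2 segment + N codon + J start,
with the D segment in the LA-containing reading frame with probability
`la_enrichment` for DP chains (0.6 by default; 0.15 for SP); point mutations
at `shm_rate` hit only V/J-templated nucleotides, so the planted D-segment
motif is never destroyed and trimming — which always spans the two N
codons — retains it. BCR clones have power-law sizes (exponent 2, clipped to
[2, 40]), clone-specific CDR3s kept ≥ 0.3 apart within a V/J class, and
per-nucleotide mutation at `shm_rate` (0.01) outside the CDR3 and
`shm_rate × cdr3_hotspot_multiplier` (×5) inside it. The replica survival
cohort assigns event labels deterministically so the cohort margins
(64 PSC with 10 right-sided events of which 6 ever-I2; 127 IBD with 17 of
which 0; 10 and 23 non-right-sided events with 5 and 0 ever-I2) and the
median follow-up grids (15.5 and 13.8 years) reproduce exactly, with ever-I2
events placed earliest so the PSC curves separate.

What passing tests on these cohorts show: the pipeline's operations are
internally correct (oracle agreement), its tests are calibrated under the
null, and planted signals of realistic size are recovered end to end. What
they do not show: robustness to real-data features the generators omit —
gene–gene correlation, compositional library effects, ambient RNA and
doublets, batch-biotype interactions, clinical covariate structure, or
repertoire biases beyond the planted motif. Real deployments should treat
the thresholds (median > 5, silhouette > 0, adjusted p < 0.05) as the
analysis conventions they are, not tuned constants.

## Numerical choices

Problem sizes in the tests and acceptance script (150 bulk samples × 2,000
genes, 2,000 cells, 8 × 40 TCR chains, 5–12 clones, 191-patient survival
cohort) are the package's desk-scale defaults; they keep every planted
effect comfortably detectable. Coordinate-descent tolerance is 1e-7 on the
max coefficient update; logistic weights are floored at 1e-5 and linear
predictors capped at ±30 for stability on separable data. Coefficients below
1e-8 after fitting are treated as zero. Percentile and quartile computations
use numpy's default linear interpolation. Ties are broken deterministically
everywhere (stable sorts on ids), so identical seeds give bit-identical
outputs.
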