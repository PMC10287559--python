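"""Bulk biopsy transcriptome analysis.

Normalisation (log2 CPM), expression/biotype gene filtering, batch
correction, mean-variance highly-variable-gene selection, PCA embedding,
Ward hierarchical clustering into U1/U2/I1/I2, single-sample gene-set
enrichment (ssGSEA) scoring and moderated-t differential expression.

The clustering contract mirrors the study design this package emulates:
right-colon biopsies cluster into two uninflamed groups (U1 larger than U2),
an intermediate inflamed group I1 and a highly inflamed group I2, ordered by
their inflammatory ssGSEA score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

ALLOWED_BIOTYPES = frozenset({"protein_coding", "TR_gene", "IG_gene"})


@dataclass
class GeneCountMatrix:
    """Gene-level integer counts (genes x samples) with gene annotation.

    ``gene_meta`` must carry a ``biotype`` column; extra columns (for example
    simulated program membership) are passed through untouched.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not self.gene_meta.index.equals(self.counts.index):
            raise ValueError("gene_meta index must match counts index")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class LogExpressionMatrix:
    """log2 counts-per-million (genes x samples) plus library sizes."""

    values: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite expression values")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")


@dataclass
class ClusterModel:
    """PCA embedding, dendrogram and labelled clusters of bulk samples."""

    pc_scores: pd.DataFrame
    pc_loadings: pd.DataFrame
    variance_explained: np.ndarray
    linkage_tree: np.ndarray | None = None
    labels: pd.Series | None = None
    inflammatory_score: pd.Series | None = None
    silhouette: pd.Series | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.pc_scores.index


def log_cpm(gcm: GeneCountMatrix) -> LogExpressionMatrix:
    """log2 counts-per-million with a 0.5 pseudocount and libsize + 1.

    values[g, s] = log2((counts[g, s] + 0.5) / (libsize[s] + 1) * 1e6).
    """
    libsize = gcm.counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    vals = np.log2(
        (gcm.counts.to_numpy(dtype=float) + 0.5)
        / (libsize.to_numpy(dtype=float) + 1.0)
        * 1e6
    )
    return LogExpressionMatrix(
        values=pd.DataFrame(vals, index=gcm.counts.index, columns=gcm.counts.columns),
        library_sizes=libsize.astype(float),
    )


def filter_genes(gcm: GeneCountMatrix) -> GeneCountMatrix:
    """Keep genes with median count strictly > 5 and an adaptive-receptor or
    protein-coding biotype (protein_coding, TR_gene, IG_gene)."""
    if "biotype" not in gcm.gene_meta.columns:
        raise ValueError("gene_meta must contain a 'biotype' column")
    med = gcm.counts.median(axis=1)
    keep = (med > 5) & gcm.gene_meta["biotype"].isin(ALLOWED_BIOTYPES)
    return GeneCountMatrix(
        counts=gcm.counts.loc[keep].copy(), gene_meta=gcm.gene_meta.loc[keep].copy()
    )


def batch_correct(expr: LogExpressionMatrix, batch: pd.Series) -> LogExpressionMatrix:
    """Remove per-gene batch-mean offsets while preserving each gene's grand mean.

    Singleton batches receive a zero offset (with a warning) because their
    batch mean is not estimable separately from the sample effect.
    """
    batch = batch.reindex(expr.values.columns)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    vals = expr.values.to_numpy(dtype=float).copy()
    grand = vals.mean(axis=1, keepdims=True)
    for b, cols in expr.values.columns.groupby(batch).items():
        idx = expr.values.columns.get_indexer(cols)
        if len(idx) < 2:
            warnings.warn(f"singleton batch {b!r}: offset set to 0", stacklevel=2)
            continue
        offset = vals[:, idx].mean(axis=1, keepdims=True) - grand
        vals[:, idx] -= offset
    out = pd.DataFrame(vals, index=expr.values.index, columns=expr.values.columns)
    return LogExpressionMatrix(values=out, library_sizes=expr.library_sizes)


def select_hvg(expr: LogExpressionMatrix, n: int = 3000, span: float = 0.3) -> list[str]:
    """Top-``n`` highly variable genes by mean-variance trend residuals.

    A LOESS trend of log10 variance on mean expression is fitted across
    genes; genes are ranked by their standardised residual from the trend,
    clipped at sqrt(n_samples) so single extreme samples cannot dominate.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    vals = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape
    if n > n_genes:
        raise ValueError(f"n={n} exceeds gene count {n_genes}")
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    logvar = np.log10(var + 1e-12)
    fit = lowess(logvar, mean, frac=span, return_sorted=False)
    resid = logvar - fit
    sd = resid.std(ddof=1)
    if sd == 0:
        std_resid = np.zeros_like(resid)
    else:
        std_resid = np.clip(resid / sd, None, np.sqrt(n_samples))
    # constant genes can never be selected ahead of varying ones
    std_resid = np.where(var == 0, -np.inf, std_resid)
    order = np.lexsort((-resid, -std_resid))
    return list(expr.values.index[order[:n]])


def pca_embed(
    expr: LogExpressionMatrix,
    hvg: list[str],
    n_pcs: int = 40,
    scale: bool = True,
) -> ClusterModel:
    """Centered (optionally unit-scaled) PCA of samples on the HVG panel.

    Records the fraction of total variance per component and warns when the
    requested components explain less than 70% of the variance or when the
    matrix is rank-deficient.
    """
    X = expr.values.loc[hvg].to_numpy(dtype=float).T  # samples x genes
    n_samples = X.shape[0]
    if n_samples < n_pcs + 1:
        warnings.warn(
            f"only {n_samples} samples for {n_pcs} PCs; reducing", stacklevel=2
        )
        n_pcs = max(1, n_samples - 1)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = (S**2).sum()
    rank = int((S > S[0] * 1e-12).sum()) if len(S) else 0
    if rank < n_pcs:
        warnings.warn(
            f"rank-deficient input: only {rank} non-trivial components", stacklevel=2
        )
        n_pcs = max(1, rank)
    var_frac = (S[:n_pcs] ** 2) / total_var
    if var_frac.sum() < 0.70:
        warnings.warn(
            f"{n_pcs} PCs explain {var_frac.sum():.1%} (< 70%) of variance",
            stacklevel=2,
        )
    scores = U[:, :n_pcs] * S[:n_pcs]
    pc_names = [f"PC{i + 1}" for i in range(n_pcs)]
    return ClusterModel(
        pc_scores=pd.DataFrame(scores, index=expr.values.columns, columns=pc_names),
        pc_loadings=pd.DataFrame(Vt[:n_pcs].T, index=hvg, columns=pc_names),
        variance_explained=var_frac,
    )


def _label_clusters(
    assignment: pd.Series, scores: pd.Series, k: int
) -> pd.Series:
    """Name clusters by mean inflammatory score.

    For k = 4 the two lowest-scoring clusters become U1 (larger) and U2, the
    next I1 and the highest I2; other k get C1..Ck in score order.
    """
    means = scores.groupby(assignment).mean().sort_values()
    order = list(means.index)
    if k == 4:
        low_pair = order[:2]
        sizes = assignment.value_counts()
        u1, u2 = sorted(low_pair, key=lambda c: (-sizes[c], c))
        mapping = {u1: "U1", u2: "U2", order[2]: "I1", order[3]: "I2"}
    else:
        mapping = {c: f"C{i + 1}" for i, c in enumerate(order)}
    return assignment.map(mapping)


def hierarchical_cluster(
    model: ClusterModel, scores: pd.Series, k: int = 4
) -> ClusterModel:
    """Ward agglomerative clustering on Euclidean PC distances, cut at ``k``.

    ``scores`` (inflammatory ssGSEA score per sample) drives the naming of
    the resulting clusters; see :func:`_label_clusters`.
    """
    n = model.pc_scores.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    Z = linkage(model.pc_scores.to_numpy(), method="ward")
    raw = pd.Series(
        fcluster(Z, t=k, criterion="maxclust"), index=model.pc_scores.index
    )
    scores = scores.reindex(model.pc_scores.index)
    labels = _label_clusters(raw, scores, k)
    return ClusterModel(
        pc_scores=model.pc_scores,
        pc_loadings=model.pc_loadings,
        variance_explained=model.variance_explained,
        linkage_tree=Z,
        labels=labels,
        inflammatory_score=scores,
    )


def ssgsea_score(
    expr: LogExpressionMatrix, gene_set: list[str], alpha: float = 0.25
) -> pd.Series:
    """Single-sample gene-set enrichment score per sample.

    Genes are ranked by expression (descending); the running sum gains
    rank-weight^alpha (normalised over in-set genes) at in-set positions and
    loses 1/(N - |S|) at out-of-set positions. The score is the sum of the
    running statistic divided by the total gene count. With every gene in
    the set the statistic degenerates and the score is defined as 0.
    """
    genes = expr.values.index
    in_set = genes.isin(set(gene_set))
    n_genes = len(genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no genes in the expression matrix")
    out = {}
    vals = expr.values.to_numpy(dtype=float)
    for j, sample in enumerate(expr.values.columns):
        if n_in == n_genes:
            out[sample] = 0.0
            continue
        order = np.argsort(-vals[:, j], kind="stable")
        set_mask = in_set[order]
        rank_weight = (np.arange(n_genes, 0, -1, dtype=float)) ** alpha
        inc = np.where(set_mask, rank_weight, 0.0)
        inc_total = inc.sum()
        dec = np.where(set_mask, 0.0, 1.0 / (n_genes - n_in))
        running = np.cumsum(inc / inc_total - dec)
        out[sample] = running.sum() / n_genes
    return pd.Series(out, name="ssgsea")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def _design_matrix(
    groups: pd.Series, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(groups)), groups.to_numpy(dtype=float)]
    names = ["intercept", "group"]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, drop_first=True, dtype=float)
                for dc in dummies.columns:
                    cols.append(dummies[dc].to_numpy())
                    names.append(f"{c}[{dc}]")
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(c)
    return np.column_stack(cols), names


def differential_expression(
    expr: LogExpressionMatrix,
    group_labels: pd.Series,
    contrast: tuple[str, str],
    covariates: pd.DataFrame | None = None,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-gene moderated-t differential expression between two groups.

    Fits a gene-wise linear model of log2 CPM on group membership plus
    covariates (sex, age, batch in the study design this emulates), shrinks
    residual variances toward their grand mean with ``prior_df`` prior
    degrees of freedom (empirical-Bayes moderation; ``prior_df=0`` recovers
    the classical t) and BH-adjusts p-values across genes.

    ``contrast`` is (test, reference): positive log2 fold changes mean
    higher expression in the first group.
    """
    test, ref = contrast
    mask = group_labels.isin([test, ref])
    samples = group_labels.index[mask]
    if (group_labels[samples] == test).sum() < 2 or (
        group_labels[samples] == ref
    ).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    g = (group_labels[samples] == test).astype(float)
    cov = covariates.loc[samples] if covariates is not None else None
    X, names = _design_matrix(g, cov)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confounded design: group is collinear with covariates")
    Y = expr.values[samples].to_numpy(dtype=float)  # genes x n
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv  # genes x p
    resid = Y - B @ X.T
    df_resid = n - p
    s2 = (resid**2).sum(axis=1) / df_resid
    if prior_df > 0:
        s0_2 = s2.mean()
        s2_post = (prior_df * s0_2 + df_resid * s2) / (prior_df + df_resid)
        df_total = prior_df + df_resid
    else:
        s2_post = s2
        df_total = df_resid
    gi = names.index("group")
    se = np.sqrt(s2_post * XtX_inv[gi, gi])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, B[:, gi] / se, 0.0)
    pval = 2 * stats.t.sf(np.abs(tstat), df_total)
    return pd.DataFrame(
        {
            "log2fc": B[:, gi],
            "t": tstat,
            "pvalue": pval,
            "adj_pvalue": bh_adjust(pval),
        },
        index=expr.values.index,
    )
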