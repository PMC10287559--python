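"""End-to-end convenience pipelines tying the analysis stages together."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import bulk, classifier


@dataclass
class ClassifierRun:
    """Everything produced by a full train/evaluate classifier run."""

    cluster_model: bulk.ClusterModel
    core_samples: list[str]
    features: list[str]
    enet: classifier.EnetModel
    test_auc: float


def cluster_bulk(
    gcm: bulk.GeneCountMatrix,
    samples: pd.DataFrame,
    gene_set: list[str] | None = None,
    k: int = 4,
    n_hvg: int = 3000,
    n_pcs: int = 40,
) -> tuple[bulk.ClusterModel, bulk.LogExpressionMatrix]:
    """Filter, normalise, batch-correct, embed and cluster a bulk cohort.

    ``gene_set`` supplies the inflammatory score gene set; when omitted, a
    simulated cohort's planted inflammation program (gene_meta ``program``
    column) is used.
    """
    filtered = bulk.filter_genes(gcm)
    expr = bulk.log_cpm(filtered)
    expr = bulk.batch_correct(expr, samples["batch"])
    if gene_set is None:
        if "program" not in gcm.gene_meta.columns:
            raise ValueError("no gene_set given and no program annotation present")
        gene_set = list(gcm.gene_meta.index[gcm.gene_meta["program"] == "inflammation"])
    hvg = bulk.select_hvg(expr, n=min(n_hvg, expr.values.shape[0]))
    model = bulk.pca_embed(expr, hvg, n_pcs=n_pcs)
    scores = bulk.ssgsea_score(expr, gene_set)
    model = bulk.hierarchical_cluster(model, scores, k=k)
    return model, expr


def train_i2_classifier(
    expr: bulk.LogExpressionMatrix,
    model: bulk.ClusterModel,
    samples: pd.DataFrame,
    seed: int,
    mixing_alpha: float = 0.5,
) -> ClassifierRun:
    """Silhouette-core selection, DEG features, elastic-net fit, held-out AUC.

    Differential expression contrasts run among the U2/I1/I2 core clusters
    with sex, age and batch covariates; the union of adjusted-p < 0.05 genes
    feeds a stratified 70/30 elastic-net fit of I2 versus rest, evaluated by
    rank-based AUC on the held-out split.
    """
    core = classifier.silhouette_core(model)
    labels = model.labels
    core_labels = labels[core]
    covs = samples.loc[core, ["sex", "age", "batch"]]
    core_expr = bulk.LogExpressionMatrix(
        values=expr.values[core], library_sizes=expr.library_sizes[core]
    )
    de_tables = {}
    for a, b in (("I2", "U2"), ("I2", "I1"), ("I1", "U2")):
        mask = core_labels.isin([a, b])
        ids = core_labels.index[mask]
        sub_cov = covs.loc[ids].copy()
        # drop covariates that are constant (or confounded) within the contrast
        usable = [
            c
            for c in sub_cov.columns
            if sub_cov[c].nunique() > 1
        ]
        de_tables[f"{a}_vs_{b}"] = bulk.differential_expression(
            bulk.LogExpressionMatrix(
                values=expr.values[ids], library_sizes=expr.library_sizes[ids]
            ),
            core_labels[ids],
            contrast=(a, b),
            covariates=sub_cov[usable] if usable else None,
        )
    features = classifier.select_features(de_tables)
    is_i2 = (core_labels == "I2").astype(int)
    enet = classifier.fit_enet(core_expr, is_i2, features, seed=seed, mixing_alpha=mixing_alpha)
    preds = classifier.predict_cluster(
        enet,
        bulk.LogExpressionMatrix(
            values=expr.values[enet.test_samples],
            library_sizes=expr.library_sizes[enet.test_samples],
        ),
    )
    auc = classifier.evaluate_auc(
        preds["probability"].to_numpy(), is_i2[enet.test_samples].to_numpy().astype(bool)
    )
    return ClassifierRun(
        cluster_model=model,
        core_samples=core,
        features=features,
        enet=enet,
        test_auc=auc,
    )
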