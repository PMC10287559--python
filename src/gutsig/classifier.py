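"""Elastic-net classifier for the highly inflamed I2 transcriptional state.

Core-sample selection by positive silhouette, DEG-union feature selection,
a glmnet-style regularisation path (lambda chosen by 10-fold CV on binomial
deviance) and rank-based AUC evaluation. The binary formulation is
I2-versus-rest; new (for example dysplastic) samples are assigned I2 when
their predicted probability reaches 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import silhouette_samples
from sklearn.model_selection import StratifiedKFold, train_test_split

from .bulk import ClusterModel, LogExpressionMatrix
from .enet_path import enet_logistic_path


@dataclass
class EnetModel:
    """Fitted elastic-net logistic model with its standardisation stats."""

    feature_genes: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    mixing_alpha: float
    lam: float
    cv_curve: pd.DataFrame
    seed: int
    train_samples: list[str] = field(default_factory=list)
    test_samples: list[str] = field(default_factory=list)

    def nonzero_genes(self) -> list[str]:
        return [g for g, c in zip(self.feature_genes, self.coefficients) if c != 0]

    def to_json(self, path: str) -> None:
        obj = {
            "feature_genes": self.feature_genes,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "mixing_alpha": self.mixing_alpha,
            "lambda": self.lam,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "EnetModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            feature_genes=obj["feature_genes"],
            feature_means=np.asarray(obj["feature_means"]),
            feature_sds=np.asarray(obj["feature_sds"]),
            coefficients=np.asarray(obj["coefficients"]),
            intercept=obj["intercept"],
            mixing_alpha=obj["mixing_alpha"],
            lam=obj["lambda"],
            cv_curve=pd.DataFrame(),
            seed=obj["seed"],
        )


def silhouette_core(model: ClusterModel) -> list[str]:
    """Samples with strictly positive silhouette in PC space.

    Silhouettes use the same Euclidean PC distances as the clustering;
    singleton clusters get silhouette 0 and are therefore excluded.
    """
    if model.labels is None:
        raise ValueError("model has no cluster labels")
    if model.labels.nunique() < 2:
        raise ValueError("need at least 2 clusters for silhouettes")
    sil = silhouette_samples(model.pc_scores.to_numpy(), model.labels.to_numpy())
    model.silhouette = pd.Series(sil, index=model.pc_scores.index)
    return list(model.pc_scores.index[sil > 0])


def select_features(de_tables: dict[str, pd.DataFrame], threshold: float = 0.05) -> list[str]:
    """Union of genes with adjusted p strictly below ``threshold`` in any contrast."""
    selected: set[str] = set()
    for table in de_tables.values():
        selected |= set(table.index[table["adj_pvalue"] < threshold])
    if not selected:
        raise ValueError(
            "no differentially expressed genes at the threshold; "
            "increase effect sizes or sample numbers"
        )
    return sorted(selected)


def _lambda_grid(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 100, decades: float = 4.0
) -> np.ndarray:
    """glmnet-style grid: from the smallest lambda that zeroes every
    coefficient down ``decades`` decades, log-spaced."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / (n * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * 10 ** (-decades), n_lambda)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, alpha: float
) -> list[tuple[np.ndarray, float]]:
    """Warm-started elastic-net logistic path, strongest penalty first."""
    return enet_logistic_path(X, y, np.asarray(lambdas), alpha)


def fit_enet(
    expr: LogExpressionMatrix,
    labels: pd.Series,
    features: list[str],
    seed: int,
    mixing_alpha: float = 0.5,
    n_folds: int = 10,
    test_fraction: float = 0.30,
) -> EnetModel:
    """Train the I2 elastic-net model on a stratified 70/30 split.

    Features are z-scored on the training data; the penalty is chosen by
    ``n_folds``-fold cross-validation minimising mean binomial deviance over
    a 100-point lambda grid, then the model is refitted on the full training
    set at the chosen lambda.
    """
    labels = labels.reindex(expr.values.columns)
    y_all = labels.to_numpy(dtype=float)
    if len(np.unique(y_all)) < 2:
        raise ValueError("both classes must be present")
    train_ids, test_ids = train_test_split(
        list(expr.values.columns),
        test_size=test_fraction,
        stratify=y_all,
        random_state=seed,
    )
    Xtr_raw = expr.values.loc[features, train_ids].to_numpy(dtype=float).T
    ytr = labels[train_ids].to_numpy(dtype=float)
    means = Xtr_raw.mean(axis=0)
    sds = Xtr_raw.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Xtr = (Xtr_raw - means) / sds

    min_class = int(min((ytr == 1).sum(), (ytr == 0).sum()))
    if min_class < n_folds:
        warnings.warn(
            f"reducing CV folds from {n_folds} to {max(2, min_class)}", stacklevel=2
        )
        n_folds = max(2, min_class)
    lambdas = _lambda_grid(Xtr, ytr, mixing_alpha)
    fold_dev = np.zeros((n_folds, len(lambdas)))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for f, (tr, va) in enumerate(skf.split(Xtr, ytr)):
        path = _fit_path(Xtr[tr], ytr[tr], lambdas, mixing_alpha)
        for i, (coef, icpt) in enumerate(path):
            p = 1.0 / (1.0 + np.exp(-(Xtr[va] @ coef + icpt)))
            fold_dev[f, i] = _binomial_deviance(ytr[va], p)
    mean_dev = fold_dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    lam = float(lambdas[best])
    final_path = _fit_path(Xtr, ytr, lambdas[: best + 1], mixing_alpha)
    coef, icpt = final_path[-1]
    # prune numerically-zero coefficients left by the saga solver
    coef[np.abs(coef) < 1e-8] = 0.0
    return EnetModel(
        feature_genes=list(features),
        feature_means=means,
        feature_sds=sds,
        coefficients=coef,
        intercept=icpt,
        mixing_alpha=mixing_alpha,
        lam=lam,
        cv_curve=pd.DataFrame({"lambda": lambdas, "mean_deviance": mean_dev}),
        seed=seed,
        train_samples=list(train_ids),
        test_samples=list(test_ids),
    )


def predict_cluster(
    model: EnetModel, expr: LogExpressionMatrix, threshold: float = 0.5
) -> pd.DataFrame:
    """I2 probability and label per sample from z-scored feature expression."""
    missing = [g for g in model.feature_genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"feature genes missing from expression matrix: {missing}")
    X = expr.values.loc[model.feature_genes].to_numpy(dtype=float).T
    Z = (X - model.feature_means) / model.feature_sds
    logit = Z @ model.coefficients + model.intercept
    prob = 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame(
        {"probability": prob, "label": np.where(prob >= threshold, "I2", "non-I2")},
        index=expr.values.columns,
    )


def evaluate_auc(probabilities: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney U / (n1 * n0), ties count one half)."""
    truth = np.asarray(truth, dtype=bool)
    probabilities = np.asarray(probabilities, dtype=float)
    n1 = int(truth.sum())
    n0 = int((~truth).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present in truth")
    ranks = rankdata(probabilities)
    u = ranks[truth].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))
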