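"""IL17A+FOXP3+ double-positive CD4 T cell analysis.

Pooled-deconvolution size factors, flow-calibrated transcript thresholds for
DP/SP/DN subset labels, a pathogenic IL-17 signature score, top-versus-bottom
decile enrichment (Fisher exact, conditional-MLE odds ratio) and pseudobulk
moderated-t differential expression with patient blocking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import lsqr
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from .bulk import LogExpressionMatrix, differential_expression

SUBSETS = ("DP", "IL17A_SP", "FOXP3_SP", "DN")


@dataclass
class CellCountMatrix:
    """UMI counts (genes x cells) with per-cell sample and cluster labels."""

    counts: pd.DataFrame
    cell_meta: pd.DataFrame  # index = cell ids; columns sample_id, patient_cluster

    def __post_init__(self) -> None:
        if not self.cell_meta.index.equals(self.counts.columns):
            raise ValueError("cell_meta index must match count columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")


@dataclass
class EnrichmentResult:
    """Top-versus-bottom decile 2x2 enrichment for DP membership.

    ``odds_ratio`` is the sample cross-product ad/bc; ``odds_ratio_cmle``
    the conditional maximum-likelihood estimate whose exact 95% CI is
    reported. With a zero cell the sample OR is inf or 0 and the CI is
    one-sided.
    """

    contingency: np.ndarray
    odds_ratio: float
    odds_ratio_cmle: float
    fisher_p: float
    ci95: tuple[float, float]
    stratum: str


def filter_mito(
    cells: CellCountMatrix, mito_genes: list[str] | None, max_fraction: float = 0.5
) -> CellCountMatrix:
    """Drop cells whose mitochondrial read fraction exceeds ``max_fraction``.

    Skipped (with a warning) when no mitochondrial gene list is supplied.
    """
    if not mito_genes:
        warnings.warn("no mitochondrial gene list; skipping mito filter", stacklevel=2)
        return cells
    present = [g for g in mito_genes if g in cells.counts.index]
    frac = cells.counts.loc[present].sum(axis=0) / cells.counts.sum(axis=0).clip(lower=1)
    keep = frac <= max_fraction
    return CellCountMatrix(
        counts=cells.counts.loc[:, keep].copy(), cell_meta=cells.cell_meta.loc[keep].copy()
    )


def compute_size_factors(
    cells: CellCountMatrix,
    pool_sizes: tuple[int, ...] = (21, 41, 61),
    factor_bounds: tuple[float, float] = (0.125, 8.0),
    min_log_cpm: float = 0.01,
) -> tuple[pd.Series, CellCountMatrix]:
    """Pooled-deconvolution size factors, scaled to mean 1.

    Genes with mean log2 CPM at or below ``min_log_cpm`` are removed first.
    Cells are ordered by library size on a ring; for every pool of
    consecutive cells the median ratio of the pooled normalised profile to
    the average cell provides one linear equation in the per-cell factors,
    and the stacked system is solved by sparse least squares. Cells whose
    factor falls outside ``factor_bounds`` are dropped.
    """
    n_cells = cells.counts.shape[1]
    if n_cells < 50:
        raise ValueError("need at least 50 cells")
    counts = cells.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("cells with zero total counts")
    log_cpm_mean = np.log2(counts / lib * 1e6 + 1).mean(axis=1)
    gene_keep = log_cpm_mean > min_log_cpm
    counts = counts[gene_keep]
    if counts.shape[0] == 0:
        raise ValueError("all genes removed by expression filter")

    norm = counts / lib  # per-cell proportion profiles
    ref = norm.mean(axis=1)
    nonzero_ref = ref > 0
    order = np.argsort(lib, kind="stable")
    # interleave so pools mix small and large libraries, as in deconvolution
    ring = np.empty(n_cells, dtype=int)
    ring[0::2] = order[: (n_cells + 1) // 2]
    ring[1::2] = order[(n_cells + 1) // 2 :][::-1]

    rows, cols, data, b = [], [], [], []
    eq = 0
    for size in pool_sizes:
        size = min(size, n_cells)
        for start in range(n_cells):
            members = ring[(start + np.arange(size)) % n_cells]
            pooled = norm[:, members].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = pooled[nonzero_ref] / ref[nonzero_ref]
            theta = np.median(ratios)
            rows.extend([eq] * size)
            cols.extend(members.tolist())
            data.extend([1.0] * size)
            b.append(theta)
            eq += 1
    # low-weight anchoring equation: mean relative factor = 1
    rows.extend([eq] * n_cells)
    cols.extend(range(n_cells))
    data.extend([0.01] * n_cells)
    b.append(0.01 * n_cells)
    A = sparse.csr_matrix((data, (rows, cols)), shape=(eq + 1, n_cells))
    rel = lsqr(A, np.asarray(b))[0]
    rel = np.clip(rel, 1e-8, None)
    factors = rel * lib
    factors = factors / factors.mean()
    fac = pd.Series(factors, index=cells.counts.columns, name="size_factor")
    lo, hi = factor_bounds
    keep = (fac >= lo) & (fac <= hi)
    if not keep.any():
        raise ValueError("all cells removed by size-factor bounds")
    filtered = CellCountMatrix(
        counts=cells.counts.loc[gene_keep, keep].copy(),
        cell_meta=cells.cell_meta.loc[keep].copy(),
    )
    fac = fac[keep]
    return fac / fac.mean(), filtered


def normalized_log(cells: CellCountMatrix, size_factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1) per gene and cell."""
    if size_factors is None:
        lib = cells.counts.sum(axis=0).clip(lower=1)  # zero-count cells stay zero
        size_factors = lib / lib.mean()
    return np.log2(cells.counts / size_factors.reindex(cells.counts.columns) + 1)


def calibrate_dp_threshold(
    cells: CellCountMatrix,
    flow: pd.DataFrame,
    il17a_gene: str = "IL17A",
    foxp3_gene: str = "FOXP3",
    grid: range = range(1, 11),
    per_gene: bool = False,
) -> tuple[pd.Series, int | tuple[int, int]]:
    """Flow-calibrated transcript threshold and DP/SP/DN subset labels.

    Searches integer UMI thresholds, picking the one minimising the summed
    absolute difference between per-sample single-cell DP frequencies and
    the flow-cytometry DP frequencies (``flow`` indexed by sample_id with a
    ``dp_freq`` column). Ties break toward the smaller threshold. With
    ``per_gene`` a separate threshold per marker is searched.
    """
    samples = cells.cell_meta["sample_id"]
    missing = set(samples.unique()) - set(flow.index)
    if missing:
        raise ValueError(f"flow table missing sample(s): {sorted(missing)}")
    il17a = cells.counts.loc[il17a_gene]
    foxp3 = cells.counts.loc[foxp3_gene]

    def objective(t_il17a: int, t_foxp3: int) -> float:
        dp = (il17a >= t_il17a) & (foxp3 >= t_foxp3)
        sc_freq = dp.groupby(samples).mean()
        target = flow["dp_freq"].reindex(sc_freq.index)
        return float((sc_freq - target).abs().sum())

    if per_gene:
        best = min(
            ((objective(a, b), a, b) for a in grid for b in grid),
            key=lambda x: (x[0], x[1], x[2]),
        )
        chosen: int | tuple[int, int] = (best[1], best[2])
        ta, tb = best[1], best[2]
    else:
        best = min(((objective(t, t), t) for t in grid), key=lambda x: (x[0], x[1]))
        chosen = best[1]
        ta = tb = best[1]
    pos_a = il17a >= ta
    pos_b = foxp3 >= tb
    labels = pd.Series(
        np.select(
            [pos_a & pos_b, pos_a & ~pos_b, ~pos_a & pos_b],
            ["DP", "IL17A_SP", "FOXP3_SP"],
            default="DN",
        ),
        index=cells.counts.columns,
        name="subset",
    )
    return labels, chosen


def pathogenic_score(
    cells: CellCountMatrix,
    signature: list[str],
    size_factors: pd.Series | None = None,
) -> pd.Series:
    """Z-scored mean normalised log expression over the signature genes."""
    present = [g for g in signature if g in cells.counts.index]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    logn = normalized_log(cells, size_factors)
    raw = logn.loc[present].mean(axis=0)
    sd = raw.std(ddof=0)
    if sd == 0:
        return raw * 0.0
    return (raw - raw.mean()) / sd


def _decile_sets(scores: pd.Series, fraction: float = 0.10) -> tuple[pd.Index, pd.Index]:
    """Exact top/bottom deciles by (score, cell id) stable order."""
    order = scores.reset_index()
    order.columns = ["cell", "score"]
    order = order.sort_values(["score", "cell"], kind="stable")
    k = max(1, int(round(fraction * len(order))))
    bottom = pd.Index(order["cell"].iloc[:k])
    top = pd.Index(order["cell"].iloc[-k:])
    return top, bottom


def decile_enrichment(
    scores: pd.Series,
    labels: pd.Series,
    stratify_by: pd.Series | None = None,
    min_cells: int = 20,
) -> list[EnrichmentResult]:
    """DP enrichment of the top versus bottom score decile.

    Within each stratum the 2x2 table (top/bottom) x (DP/not-DP) is tested
    with the two-sided Fisher exact test; the conditional-MLE odds ratio and
    its exact 95% CI come from the noncentral hypergeometric model.
    """
    if stratify_by is None:
        strata = {"all": scores.index}
    else:
        strata = {
            str(s): scores.index[stratify_by.reindex(scores.index) == s]
            for s in sorted(stratify_by.unique())
        }
    results = []
    for name, idx in strata.items():
        if len(idx) < min_cells:
            raise ValueError(f"stratum {name!r} has fewer than {min_cells} cells")
        top, bottom = _decile_sets(scores[idx])
        if len(top) == 0 or len(bottom) == 0:
            raise ValueError(f"empty decile in stratum {name!r}")
        is_dp = labels.reindex(scores.index) == "DP"
        a = int(is_dp[top].sum())
        b = int(len(top) - a)
        c = int(is_dp[bottom].sum())
        d = int(len(bottom) - c)
        table = np.array([[a, b], [c, d]])
        with np.errstate(divide="ignore"):
            if b * c == 0:
                sample_or = np.inf if a * d > 0 else 0.0
            else:
                sample_or = (a * d) / (b * c)
        res = _cmle_odds_ratio(table)
        ci = res.confidence_interval(0.95)
        _, p = fisher_exact(table, alternative="two-sided")
        results.append(
            EnrichmentResult(
                contingency=table,
                odds_ratio=float(sample_or),
                odds_ratio_cmle=float(res.statistic),
                fisher_p=float(p),
                ci95=(float(ci.low), float(ci.high)),
                stratum=name,
            )
        )
    return results


def pseudobulk_de(
    cells: CellCountMatrix,
    subset_labels: pd.Series,
    contrast: tuple[str, str],
    size_factors: pd.Series | None = None,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Moderated-t DE between two cell subsets on patient pseudobulks.

    Pseudobulk = per-gene mean of normalised log counts within each
    (patient, subset) group; the linear model includes the patient as a
    blocking factor. Subsets present in fewer than 2 patients are dropped
    with a warning.
    """
    logn = normalized_log(cells, size_factors)
    key = pd.DataFrame(
        {
            "patient": cells.cell_meta["sample_id"],
            "subset": subset_labels.reindex(cells.counts.columns),
        }
    )
    groups = key[key["subset"].isin(contrast)]
    counts_per = groups.groupby("subset")["patient"].nunique()
    for s in contrast:
        if counts_per.get(s, 0) < 2:
            raise ValueError(f"subset {s!r} present in fewer than 2 patients")
    pseudo = {}
    meta = []
    for (patient, subset), members in groups.groupby(["patient", "subset"]):
        pb_id = f"{patient}|{subset}"
        pseudo[pb_id] = logn[members.index].mean(axis=1)
        meta.append((pb_id, patient, subset))
    pb = pd.DataFrame(pseudo)
    meta_df = pd.DataFrame(meta, columns=["pb_id", "patient", "subset"]).set_index("pb_id")
    # keep only patients contributing both subsets so the blocked design is estimable
    full = meta_df.groupby("patient")["subset"].nunique()
    keep_patients = full.index[full == 2]
    dropped = sorted(set(meta_df["patient"]) - set(keep_patients))
    if dropped:
        warnings.warn(f"dropping patients without both subsets: {dropped}", stacklevel=2)
    meta_df = meta_df[meta_df["patient"].isin(keep_patients)]
    pb = pb[meta_df.index]
    expr = LogExpressionMatrix(
        values=pb, library_sizes=pd.Series(1.0, index=pb.columns)
    )
    covariates = pd.DataFrame({"patient": meta_df["patient"].astype(str)})
    return differential_expression(
        expr,
        meta_df["subset"],
        contrast=contrast,
        covariates=covariates,
        prior_df=prior_df,
    )


def fisher_exact_p(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tails)."""
    _, p = fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)
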