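"""Longitudinal single-cell phenotype-switch pipeline.

From a genes x cells counts matrix with protein-coding / mitochondrial /
ribosomal gene flags and paired day-1 / day-4 cell annotations, the
pipeline applies the platform's QC filters (>150 expressed protein-coding
genes, <10% ribosomal, <30% mitochondrial counts), keeps protein-coding
genes with >3 counts in at least two cells, log-normalises to 10,000
counts per cell, regresses out per-cell technical covariates, z-scales
with an upper clip at +5, selects the top-600 dispersion-based highly
variable genes, embeds with 8 principal components, scores each cell
against proneural (PN) and mesenchymal (MES) gene sets with a rank-walk
enrichment statistic, classifies each cell by the larger score, tabulates
day-1 -> day-4 subtype switches per treatment arm, and tests the 2x2
switch table with a two-sided Fisher exact test.

The enrichment operator is a single-sample rank-walk score (a GSVA-style
surrogate): genes are ranked by scaled expression, the running sum gains
|stat| / sum(|stat| in set) at set genes and loses 1/(N - n_set)
elsewhere, and the score is the signed maximum deviation, in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA

from .sicm_model import InvalidParameterError

__all__ = [
    "CountsMatrix",
    "QC_THRESHOLDS",
    "compute_qc_metrics",
    "filter_cells",
    "filter_genes",
    "lognormalize",
    "regress_out",
    "scale_clip",
    "select_hvg",
    "run_pca",
    "enrichment_score",
    "score_cells",
    "classify_phenotype",
    "tabulate_switches",
    "SwitchResult",
    "fisher_exact_two_sided",
    "score_change_summary",
    "run_pipeline",
]

# Strict thresholds, exactly as stated for the platform's QC.
QC_THRESHOLDS = {"min_genes": 150, "max_ribo_pct": 10.0, "max_mito_pct": 30.0}

NORM_TARGET = 1e4


@dataclass
class CountsMatrix:
    """Genes x cells raw counts with gene and cell annotations.

    ``genes`` must carry boolean columns ``protein_coding``, ``mito`` and
    ``ribo``; ``cells`` may carry ``group``, ``pair_id``, ``timepoint``
    and ``treated`` for the longitudinal analysis.
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise InvalidParameterError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise InvalidParameterError("counts must be non-negative")
        for flag in ("protein_coding", "mito", "ribo"):
            if flag not in self.genes.columns:
                raise InvalidParameterError(f"gene annotation column '{flag}' is required")
        if self.genes.index.duplicated().any():
            raise InvalidParameterError("duplicate gene identifiers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask) -> "CountsMatrix":
        mask = np.asarray(mask)
        return CountsMatrix(self.counts[:, mask], self.genes, self.cells.loc[mask])

    def subset_genes(self, mask) -> "CountsMatrix":
        mask = np.asarray(mask)
        return CountsMatrix(self.counts[mask, :], self.genes.loc[mask], self.cells)


def compute_qc_metrics(matrix: CountsMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: expressed protein-coding genes, % mitochondrial
    and % ribosomal counts (plus total counts and a % mRNA proxy)."""
    counts = matrix.counts
    pc = matrix.genes["protein_coding"].to_numpy(bool)
    mito = matrix.genes["mito"].to_numpy(bool)
    ribo = matrix.genes["ribo"].to_numpy(bool)
    total = np.asarray(counts.sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = 100.0 * np.asarray(counts[mito].sum(axis=0)).ravel() / np.maximum(total, 1)
        pct_ribo = 100.0 * np.asarray(counts[ribo].sum(axis=0)).ravel() / np.maximum(total, 1)
    n_expr = np.asarray((counts[pc] > 0).sum(axis=0)).ravel()
    return pd.DataFrame(
        {
            "n_expressed_pc_genes": n_expr,
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
            "total_counts": total,
            "pct_mrna_proxy": 100.0 - pct_mito - pct_ribo,
        },
        index=matrix.cells.index,
    )


def filter_cells(metrics: pd.DataFrame, thresholds: dict = QC_THRESHOLDS) -> pd.Series:
    """Strict-inequality cell filter: genes > 150, ribo < 10%, mito < 30%."""
    return (
        (metrics["n_expressed_pc_genes"] > thresholds["min_genes"])
        & (metrics["pct_ribo"] < thresholds["max_ribo_pct"])
        & (metrics["pct_mito"] < thresholds["max_mito_pct"])
    )


def filter_genes(matrix: CountsMatrix, min_count: int = 3, min_cells: int = 2) -> np.ndarray:
    """Keep protein-coding genes with > ``min_count`` counts in at least
    ``min_cells`` cells (applied after the cell filter)."""
    expressed = np.asarray((matrix.counts > min_count).sum(axis=1)).ravel()
    return (expressed >= min_cells) & matrix.genes["protein_coding"].to_numpy(bool)


def lognormalize(counts, target: float = NORM_TARGET) -> np.ndarray:
    """Per-cell depth normalisation to ``target`` counts, then log1p.

    Cells with zero total are left at zero and flagged with a warning.
    """
    if isinstance(counts, CountsMatrix):
        counts = counts.counts
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    totals = dense.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-total cells excluded from normalization")
        totals = np.where(zero, 1.0, totals)
    return np.log1p(dense / totals * target)


def regress_out(normalized: np.ndarray, covariates) -> np.ndarray:
    """Per-gene OLS residuals of expression on the covariates + intercept.

    Collinear covariate columns are dropped with a warning.  Residuals are
    orthogonal to the retained covariates by construction.
    """
    y = np.asarray(normalized, dtype=float)  # genes x cells
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != y.shape[1]:
        raise InvalidParameterError("covariates must have one row per cell")
    if not np.all(np.isfinite(cov)):
        raise InvalidParameterError("covariates must be finite")
    x = np.column_stack([np.ones(cov.shape[0]), cov])
    # drop collinear columns (keep intercept), greedily by rank
    keep = [0]
    for j in range(1, x.shape[1]):
        trial = x[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate column {j - 1}")
    x = x[:, keep]
    coef, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    return y - (x @ coef).T


def scale_clip(matrix: np.ndarray, cap: float = 5.0, ddof: int = 1) -> np.ndarray:
    """Per-gene z-score with values clipped from above at ``cap``.

    Zero-variance genes scale to all zeros.
    """
    x = np.asarray(matrix, dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    # zero-variance detection needs a tolerance relative to the level:
    # a numerically constant gene leaves rounding residues of order eps*mean
    zero_var = sd <= 1e-12 * (np.abs(mean) + 1.0)
    safe = np.where(zero_var, 1.0, sd)
    z = (x - mean) / safe
    z[zero_var.ravel(), :] = 0.0
    return np.minimum(z, cap)


def select_hvg(
    normalized: np.ndarray,
    gene_ids,
    n: int = 600,
    n_bins: int = 20,
) -> np.ndarray:
    """Top-``n`` highly variable genes by the dispersion method.

    Dispersion = variance / mean on the normalized data, z-scored within
    ``n_bins`` equal-frequency mean bins; ties broken by lexicographic
    gene identifier.  Returns positional gene indices in matrix order.
    """
    x = np.asarray(normalized, dtype=float)
    gene_ids = pd.Index(gene_ids)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), np.nan)
    df = pd.DataFrame({"mean": mean, "disp": disp, "gene": gene_ids}).dropna(subset=["disp"])
    if len(df) <= n:
        if len(df) < n:
            warnings.warn(f"only {len(df)} informative genes available for top-{n} selection")
        sel = df.index.to_numpy()
        return np.sort(sel)
    bins = pd.qcut(df["mean"], min(n_bins, len(df)), duplicates="drop", labels=False)
    grouped = df.groupby(bins)["disp"]
    mu = grouped.transform("mean")
    sd = grouped.transform("std").fillna(0.0)
    z = (df["disp"] - mu) / sd.replace(0.0, np.inf)
    order = pd.DataFrame({"z": z, "gene": df["gene"]}, index=df.index).sort_values(
        ["z", "gene"], ascending=[False, True], kind="mergesort"
    )
    return np.sort(order.index.to_numpy()[:n])


def run_pca(scaled: np.ndarray, k: int = 8) -> tuple:
    """Top-``k`` principal components of a scaled genes x cells matrix.

    Returns ``(embeddings cells x k, explained_variance, loadings)``.
    Component signs follow the convention that the largest-magnitude gene
    loading of each component is positive.
    """
    x = np.asarray(scaled, dtype=float).T  # cells x genes
    rank = min(x.shape[0] - 1, x.shape[1])
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; reducing")
        k = max(rank, 1)
    pca = PCA(n_components=k, svd_solver="full")
    emb = pca.fit_transform(x)
    loadings = pca.components_  # k x genes
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            loadings[j] *= -1.0
            emb[:, j] *= -1.0
    return emb, pca.explained_variance_, loadings


def enrichment_score(profile: np.ndarray, in_set: np.ndarray) -> float:
    """Signed rank-walk enrichment of one cell profile against a gene set.

    Genes are ranked by the statistic (scaled expression) in descending
    order; the running sum adds ``|stat| / sum(|stat| over the set)`` at
    set genes and subtracts ``1 / (N - n_set)`` elsewhere.  The score is
    the maximum-magnitude deviation of the walk, signed, in [-1, 1].
    """
    v = np.asarray(profile, dtype=float)
    mask = np.asarray(in_set, dtype=bool)
    n = len(v)
    n_set = int(mask.sum())
    if n_set == 0:
        raise InvalidParameterError("gene set has no overlap with the measured genes")
    if n_set == n:
        raise InvalidParameterError("gene set covers all measured genes")
    order = np.argsort(-v, kind="mergesort")
    hit = mask[order]
    weights = np.abs(v[order])
    hit_w = np.where(hit, weights, 0.0)
    total_w = hit_w.sum()
    if total_w == 0:
        hit_w = hit / n_set
        total_w = 1.0
    steps = np.where(hit, hit_w / total_w, -1.0 / (n - n_set))
    walk = np.cumsum(steps)
    i_max = int(np.argmax(np.abs(walk)))
    return float(walk[i_max])


def classify_phenotype(pn_score: float, mes_score: float) -> str:
    """Argmax label over the two subtype scores; exact ties unclassified."""
    if not (np.isfinite(pn_score) and np.isfinite(mes_score)):
        raise InvalidParameterError("scores must be finite")
    if pn_score > mes_score:
        return "PN"
    if mes_score > pn_score:
        return "MES"
    return "unclassified"


def score_cells(scaled: np.ndarray, gene_ids, gene_sets: dict) -> pd.DataFrame:
    """Score every cell against each gene set and classify PN vs MES.

    ``gene_sets`` maps set name (must include 'PN' and 'MES') to a list of
    gene identifiers; identifiers not measured are ignored.
    """
    gene_ids = pd.Index(gene_ids)
    masks = {}
    for name, members in gene_sets.items():
        masks[name] = gene_ids.isin(members)
        if not masks[name].any():
            raise InvalidParameterError(f"gene set '{name}' has no measured genes")
    records = {name: [] for name in gene_sets}
    x = np.asarray(scaled, dtype=float)
    for c in range(x.shape[1]):
        for name, mask in masks.items():
            records[name].append(enrichment_score(x[:, c], mask))
    table = pd.DataFrame(records)
    table["label"] = [
        classify_phenotype(p, m) for p, m in zip(table["PN"], table["MES"])
    ]
    return table


@dataclass
class SwitchResult:
    """2x2 switch table (rows untreated / treated, columns switched /
    not switched) plus excluded-pair bookkeeping."""

    table: np.ndarray
    n_excluded_unclassified: int = 0
    unpaired: list = field(default_factory=list)

    def counts(self) -> dict:
        return {
            "untreated_switched": int(self.table[0, 0]),
            "untreated_not": int(self.table[0, 1]),
            "treated_switched": int(self.table[1, 0]),
            "treated_not": int(self.table[1, 1]),
        }


def tabulate_switches(labels: pd.DataFrame) -> SwitchResult:
    """Paired day-1 -> day-4 subtype-switch table.

    ``labels`` needs columns ``pair_id``, ``timepoint`` ('day1'/'day4'),
    ``treated`` (bool) and ``label``.  A pair switched iff its two labels
    differ; pairs with an unclassified member are excluded and counted,
    incomplete pairs are reported in ``unpaired``.
    """
    table = np.zeros((2, 2), dtype=int)
    excluded = 0
    unpaired = []
    for pair_id, grp in labels.groupby("pair_id", sort=True):
        d1 = grp[grp["timepoint"] == "day1"]
        d4 = grp[grp["timepoint"] == "day4"]
        if len(d1) != 1 or len(d4) != 1:
            unpaired.append(pair_id)
            continue
        l1, l4 = d1["label"].iloc[0], d4["label"].iloc[0]
        if "unclassified" in (l1, l4):
            excluded += 1
            continue
        row = 1 if bool(d1["treated"].iloc[0]) else 0
        col = 0 if l1 != l4 else 1
        table[row, col] += 1
    return SwitchResult(table=table, n_excluded_unclassified=excluded, unpaired=unpaired)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 integer table.

    Empty margins give p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise InvalidParameterError("table must be a non-negative 2x2 integer table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("empty margin in the 2x2 table; p = 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def score_change_summary(scores: pd.DataFrame) -> dict:
    """Plasticity summary: per-arm mean |day1 -> day4| score changes.

    ``scores`` needs columns ``pair_id``, ``timepoint``, ``treated``,
    ``PN`` and ``MES``.  Returns the untreated / treated fold ratio of the
    mean absolute change for each score and Welch two-sample two-tailed
    t-test p-values.  Requires at least two complete pairs per arm.
    """
    changes = {"PN": {False: [], True: []}, "MES": {False: [], True: []}}
    for _, grp in scores.groupby("pair_id", sort=True):
        d1 = grp[grp["timepoint"] == "day1"]
        d4 = grp[grp["timepoint"] == "day4"]
        if len(d1) != 1 or len(d4) != 1:
            continue
        arm = bool(d1["treated"].iloc[0])
        for key in ("PN", "MES"):
            changes[key][arm].append(abs(d4[key].iloc[0] - d1[key].iloc[0]))
    out = {}
    for key in ("PN", "MES"):
        untreated = np.array(changes[key][False])
        treated = np.array(changes[key][True])
        if len(untreated) < 2 or len(treated) < 2:
            raise InvalidParameterError(
                f"need >= 2 complete pairs per arm for {key} "
                f"(got {len(untreated)} untreated, {len(treated)} treated)"
            )
        ratio = float(untreated.mean() / treated.mean()) if treated.mean() > 0 else np.inf
        if untreated.std(ddof=1) == 0 and treated.std(ddof=1) == 0:
            pval = None  # degenerate variance: report ratio without a p-value
        else:
            pval = float(stats.ttest_ind(untreated, treated, equal_var=False)[1])
        out[key] = {
            "mean_abs_change_untreated": float(untreated.mean()),
            "mean_abs_change_treated": float(treated.mean()),
            "fold_ratio": ratio,
            "p_value": pval,
        }
    return out


def run_pipeline(
    matrix: CountsMatrix,
    gene_sets: dict,
    n_hvg: int = 600,
    n_pcs: int = 8,
    qc_thresholds: dict = QC_THRESHOLDS,
    covariate_columns: tuple = ("n_expressed_pc_genes", "pct_mrna_proxy"),
) -> dict:
    """End-to-end longitudinal analysis on a counts matrix.

    QC filter -> gene filter -> log-normalise -> regress out per-cell
    covariates -> scale/clip -> HVG + PCA -> PN/MES scoring -> switch
    table -> Fisher exact test.  Returns a dict with every intermediate
    table; deterministic for identical input.
    """
    qc = compute_qc_metrics(matrix)
    cell_mask = filter_cells(qc, qc_thresholds).to_numpy()
    filtered = matrix.subset_cells(cell_mask)
    gene_mask = filter_genes(filtered)
    filtered = filtered.subset_genes(gene_mask)

    normalized = lognormalize(filtered.counts)
    covs = qc.loc[cell_mask, list(covariate_columns)].to_numpy()
    residuals = regress_out(normalized, covs)
    scaled = scale_clip(residuals)

    hvg_idx = select_hvg(normalized, filtered.genes.index, n=n_hvg)
    embeddings, explained, _ = run_pca(scaled[hvg_idx], k=n_pcs)

    scores = score_cells(scaled, filtered.genes.index, gene_sets)
    scores.index = filtered.cells.index
    labeled = pd.concat([filtered.cells.reset_index(drop=True),
                         scores.reset_index(drop=True)], axis=1)
    result = {
        "qc": qc,
        "cell_mask": cell_mask,
        "gene_mask": gene_mask,
        "normalized": normalized,
        "scaled": scaled,
        "hvg": hvg_idx,
        "embeddings": embeddings,
        "explained_variance": explained,
        "scores": labeled,
    }
    if {"pair_id", "timepoint", "treated"}.issubset(labeled.columns):
        paired = labeled.dropna(subset=["pair_id"])
        if len(paired):
            switch = tabulate_switches(paired)
            result["switch"] = switch
            result["fisher_p"] = fisher_exact_two_sided(switch.table)
    return result
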