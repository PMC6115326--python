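"""Multi-stage selection of tissue-preferential genes.

The chain mirrors the microarray-compendium workflow for picking out genes
preferentially expressed in one target tissue (e.g. root hairs) against a
reference tissue (e.g. whole root) within a multi-organ panel:

1. quantile-normalize the sample columns,
2. average replicate arrays into one column per tissue,
3. keep genes whose maximum tissue-level log2 intensity exceeds a threshold
   (default > 8),
4. K-means cluster the surviving expression profiles (default 12 clusters,
   Euclidean distance) and take the cluster with the strongest
   target-vs-best-other centroid contrast,
5. drop genes that are also high in a non-target, non-reference tissue
   (margin rule, default 1 log2 unit),
6. keep genes at least ``fold_min``-fold (default 2) higher in the target
   than in the reference tissue.

Every stage records which genes it removed and why, so the final gene list
carries full provenance.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .data_io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SelectionParams:
    """Tunable thresholds of the selection chain (all log2 scale except
    ``fold_min``, which is a linear fold)."""

    expression_threshold: float = 8.0
    n_clusters: int = 12
    fold_min: float = 2.0
    cross_tissue_margin: float = 1.0
    kmeans_restarts: int = 10
    seed: int = 0
    quantile_normalize: bool = True
    center_profiles: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.expression_threshold):
            raise ValidationError("expression_threshold must be finite")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be ≥ 1")
        if self.fold_min < 1:
            raise ValidationError("fold_min must be ≥ 1")


@dataclass
class ClusteringResult:
    assignment: pd.Series        # gene id → cluster index in [0, n_clusters)
    centroids: pd.DataFrame      # cluster × tissue, log2 units
    inertia: float               # sum of squared Euclidean distances


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    removed: dict[str, str]      # gene id → reason


@dataclass
class SelectionResult:
    selected: list[str]
    stages: list[StageRecord]

    def provenance_frame(self) -> pd.DataFrame:
        rows = [(s.stage, s.n_in, s.n_out, len(s.removed))
                for s in self.stages]
        return pd.DataFrame(rows, columns=["stage", "genes_in", "genes_out",
                                           "genes_removed"])

    def removed_frame(self) -> pd.DataFrame:
        rows = [(s.stage, g, r) for s in self.stages
                for g, r in s.removed.items()]
        return pd.DataFrame(rows, columns=["stage", "gene_id", "reason"])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the identical value distribution.

    Rank each column (ties averaged), then replace values by the across-
    column mean of the per-rank sorted values; fractional (tied) ranks
    interpolate between adjacent rank means.  With a single sample the
    matrix is returned unchanged with a warning.
    """
    values = matrix.values
    n, p = values.shape
    if p < 2:
        logger.warning("quantile normalization skipped: single sample")
        return matrix
    arr = values.to_numpy(dtype=float)
    rank_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(p):
        ranks = rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, rank_means)
    return dataclasses.replace(
        matrix, values=pd.DataFrame(out, index=values.index,
                                    columns=values.columns))


def collapse_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """One column per tissue: the arithmetic mean of its replicate columns
    (log2 units).  Column order follows first appearance of each tissue."""
    tissues = matrix.tissues
    cols = {t: matrix.values[matrix.samples_for(t)].mean(axis=1)
            for t in tissues}
    values = pd.DataFrame(cols, index=matrix.values.index)[tissues]
    return dataclasses.replace(
        matrix, values=values, sample_tissue={t: t for t in tissues})


def filter_expressed(matrix: ExpressionMatrix,
                     threshold: float = 8.0) -> list[str]:
    """Genes whose maximum over tissue columns is strictly above threshold,
    original order preserved."""
    maxima = matrix.values.max(axis=1)
    return list(matrix.values.index[maxima > threshold])


def kmeans_cluster(matrix: ExpressionMatrix,
                   params: SelectionParams) -> ClusteringResult:
    """Lloyd's K-means (k-means++ init, ``kmeans_restarts`` restarts, best
    inertia kept) on the gene expression profiles.

    With ``params.center_profiles`` (default) each gene profile is mean-
    centered first so clusters group genes by expression *shape* across
    tissues rather than absolute level; centroids are reported in the
    centered space.  Deterministic given ``params.seed``.
    """
    values = matrix.values
    if len(values) < params.n_clusters:
        raise ValidationError(
            f"{len(values)} genes < {params.n_clusters} clusters"
        )
    X = values.to_numpy(dtype=float)
    if params.center_profiles:
        X = X - X.mean(axis=1, keepdims=True)
    km = KMeans(n_clusters=params.n_clusters, init="k-means++",
                n_init=params.kmeans_restarts, random_state=params.seed)
    labels = km.fit_predict(X)
    centroids = pd.DataFrame(km.cluster_centers_, columns=values.columns)
    return ClusteringResult(
        assignment=pd.Series(labels, index=values.index),
        centroids=centroids,
        inertia=float(km.inertia_),
    )


def select_preferential_cluster(clustering: ClusteringResult,
                                target_tissue: str) -> int:
    """Cluster with the largest centroid contrast
    ``centroid[target] − max(centroid[other tissues])``; ties go to the
    lowest cluster index."""
    cent = clustering.centroids
    if target_tissue not in cent.columns:
        raise ValidationError(f"no centroid column for {target_tissue!r}")
    others = cent.drop(columns=[target_tissue])
    contrast = cent[target_tissue] - others.max(axis=1)
    return int(contrast.idxmax())  # idxmax takes the first (lowest) index on ties


def eliminate_cross_tissue_high(genes: Sequence[str],
                                matrix: ExpressionMatrix,
                                margin: float = 1.0) -> list[str]:
    """Drop genes also highly expressed in tissues other than the target and
    reference: keep gene iff
    ``expr[target] − max(expr[other tissues]) ≥ margin`` (log2 units)."""
    target = matrix.target_tissue
    others = [t for t in matrix.tissues
              if t not in (target, matrix.reference_tissue)]
    vals = matrix.values.loc[list(genes)]
    if not others:
        return list(genes)
    keep = vals[target] - vals[others].max(axis=1) >= margin
    return list(vals.index[keep])


def fold_change_filter(genes: Sequence[str], matrix: ExpressionMatrix,
                       fold_min: float = 2.0) -> list[str]:
    """Keep genes at least ``fold_min``-fold higher in the target than in
    the reference tissue (inclusive): ``t − r ≥ log2(fold_min)``."""
    vals = matrix.values.loc[list(genes)]
    diff = vals[matrix.target_tissue] - vals[matrix.reference_tissue]
    keep = diff >= math.log2(fold_min)
    return list(vals.index[keep])


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def run_selection(matrix: ExpressionMatrix,
                  params: SelectionParams | None = None) -> SelectionResult:
    """Run the full chain and return the selected genes with per-stage
    provenance."""
    params = params or SelectionParams()
    stages: list[StageRecord] = []

    if params.quantile_normalize:
        matrix = quantile_normalize(matrix)
    collapsed = collapse_replicates(matrix)
    all_genes = collapsed.gene_ids

    expressed = filter_expressed(collapsed, params.expression_threshold)
    stages.append(StageRecord(
        "expression_filter", len(all_genes), len(expressed),
        {g: f"max log2 ≤ {params.expression_threshold:g}"
         for g in set(all_genes) - set(expressed)}))

    restricted = collapsed.restrict_genes(expressed)
    clustering = kmeans_cluster(restricted, params)
    chosen = select_preferential_cluster(clustering, collapsed.target_tissue)
    in_cluster = [g for g in expressed
                  if clustering.assignment[g] == chosen]
    stages.append(StageRecord(
        "preferential_cluster", len(expressed), len(in_cluster),
        {g: f"assigned to cluster {clustering.assignment[g]} != {chosen}"
         for g in expressed if clustering.assignment[g] != chosen}))

    not_cross_high = eliminate_cross_tissue_high(
        in_cluster, collapsed, params.cross_tissue_margin)
    stages.append(StageRecord(
        "cross_tissue_elimination", len(in_cluster), len(not_cross_high),
        {g: f"target margin < {params.cross_tissue_margin:g} log2 over "
            f"another tissue"
         for g in set(in_cluster) - set(not_cross_high)}))

    selected = fold_change_filter(not_cross_high, collapsed, params.fold_min)
    stages.append(StageRecord(
        "fold_change_filter", len(not_cross_high), len(selected),
        {g: f"target/reference fold < {params.fold_min:g}"
         for g in set(not_cross_high) - set(selected)}))

    return SelectionResult(selected=selected, stages=stages)
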