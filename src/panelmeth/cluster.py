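"""Methylome clustering, KNN imputation, sample outliers, reproducibility.

Clustering follows the heatmap convention for methylation matrices:
average-linkage agglomeration under correlation distance (1 - Pearson r) on
both axes, applied to the row-standardized (Z-score) matrix. Missing region
values are first filled by k-nearest-neighbour imputation over regions
(Euclidean distance on shared observed samples, mean of the neighbours'
values), the behaviour of the classic microarray KNN imputer.

Reproducibility of the assay is summarized as the coefficient of variation
(CV% = sd / mean x 100) of region means across replicate runs, optionally on
randomized small CpG subsets to quantify how much representing a region by
few CpGs inflates variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .aggregate import MethylationMatrix


class ClusterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# KNN imputation over regions
# ---------------------------------------------------------------------------

class KNNMatrixImputer(BaseEstimator, TransformerMixin):
    """Impute missing region values from the k nearest regions.

    Rows are regions, columns samples. For a missing cell (r, s) the imputed
    value is the mean over the ``n_neighbors`` rows closest to r -- Euclidean
    distance computed over the columns observed in both rows -- among rows
    that are observed at column s. Observed cells are never altered.

    Parameters
    ----------
    n_neighbors : int, default 10
        Neighbour count k; the classic microarray imputer's default.
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None) -> "KNNMatrixImputer":
        if self.n_neighbors < 1:
            raise ClusterError("n_neighbors must be >= 1")
        self.n_features_in_ = np.asarray(
            X.values if isinstance(X, MethylationMatrix) else X
        ).shape[1]
        return self

    def transform(self, X) -> pd.DataFrame | MethylationMatrix:
        wrap = isinstance(X, MethylationMatrix)
        values = X.values if wrap else X
        arr = values.to_numpy(dtype=float, copy=True)
        missing_rows, missing_cols = np.where(np.isnan(arr))
        if missing_rows.size == 0:
            return X
        observed = ~np.isnan(arr)
        if (~observed).all(axis=1).any():
            raise ClusterError("cannot impute a fully missing region row")

        for r in np.unique(missing_rows):
            # distances from row r to every other row over shared observed cols
            shared = observed[r] & observed
            diffs = arr[r] - arr
            with np.errstate(invalid="ignore"):
                sq = np.where(shared, diffs**2, 0.0)
            n_shared = shared.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                dist = np.sqrt(sq.sum(axis=1) / n_shared)  # mean-scaled Euclidean
            dist[r] = np.inf
            dist[n_shared == 0] = np.inf
            for c in missing_cols[missing_rows == r]:
                candidates = np.where(observed[:, c], dist, np.inf)
                order = np.argsort(candidates, kind="stable")
                k = min(self.n_neighbors, int(np.isfinite(candidates).sum()))
                if k == 0:
                    raise ClusterError(
                        f"no observed neighbour for cell ({values.index[r]}, "
                        f"{values.columns[c]})"
                    )
                arr[r, c] = arr[order[:k], c].mean()

        out = pd.DataFrame(arr, index=values.index, columns=values.columns)
        if wrap:
            return MethylationMatrix(values=out, region_meta=X.region_meta)
        return out


def impute_missing(matrix, k: int = 10):
    """Functional wrapper over :class:`KNNMatrixImputer`."""
    return KNNMatrixImputer(n_neighbors=k).fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    sample_linkage: np.ndarray
    region_linkage: np.ndarray
    sample_labels: pd.Series  # 1 / 2 for the two-way cut
    group_a: list[str]  # regions high in cluster 1, low in cluster 2
    group_b: list[str]  # the converse
    region_variance: pd.Series
    sample_ids: list[str]
    region_ids: list[str]

    def newick(self, axis: str = "samples") -> str:
        """Serialize a linkage tree as Newick."""
        import skbio

        if axis == "samples":
            linkage, labels = self.sample_linkage, self.sample_ids
        elif axis == "regions":
            linkage, labels = self.region_linkage, self.region_ids
        else:
            raise ClusterError("axis must be 'samples' or 'regions'")
        tree = skbio.TreeNode.from_linkage_matrix(linkage, labels)
        return str(tree).strip()


def _correlation_condensed(arr: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        return pdist(arr, metric="correlation")
    if metric == "spearman":
        rho, _ = stats.spearmanr(arr.T)
        rho = np.atleast_2d(rho)
        return squareform(1 - rho, checks=False)
    raise ClusterError(f"unknown metric {metric!r}")


def hierarchical_cluster(
    matrix,
    metric: str = "correlation",
    method: str = "average",
    contrast: float = 1.0,
) -> ClusterResult:
    """Average-linkage correlation-distance clustering of samples and regions.

    Expects a *complete* matrix (impute first); constant rows or columns have
    undefined correlation and are dropped with a warning. The sample tree is
    cut into two clusters at the top split; gene groups A and B are the
    regions whose cluster-wise mean value differs by more than ``contrast``
    (in units of the input, so pass the Z matrix for interpretable groups):
    A is high in cluster 1, B high in cluster 2.
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ClusterError("matrix has missing values; impute before clustering")

    row_const = arr.std(axis=1) == 0
    col_const = arr.std(axis=0) == 0
    if row_const.any():
        warnings.warn(f"dropping {int(row_const.sum())} constant region row(s)")
    if col_const.any():
        warnings.warn(f"dropping {int(col_const.sum())} constant sample column(s)")
    values = values.loc[~row_const, ~col_const]
    arr = values.to_numpy(dtype=float)
    if min(arr.shape) < 2:
        raise ClusterError("need >= 2 assessable rows and columns")

    region_linkage = hierarchy.linkage(_correlation_condensed(arr, metric), method)
    sample_linkage = hierarchy.linkage(_correlation_condensed(arr.T, metric), method)
    labels = hierarchy.fcluster(sample_linkage, t=2, criterion="maxclust")
    sample_labels = pd.Series(labels, index=values.columns, name="cluster")

    in1 = sample_labels.to_numpy() == 1
    delta = arr[:, in1].mean(axis=1) - arr[:, ~in1].mean(axis=1)
    group_a = [str(r) for r, d in zip(values.index, delta) if d > contrast]
    group_b = [str(r) for r, d in zip(values.index, delta) if d < -contrast]

    return ClusterResult(
        sample_linkage=sample_linkage,
        region_linkage=region_linkage,
        sample_labels=sample_labels,
        group_a=group_a,
        group_b=group_b,
        region_variance=pd.Series(arr.var(axis=1, ddof=1), index=values.index),
        sample_ids=[str(c) for c in values.columns],
        region_ids=[str(r) for r in values.index],
    )


def overall_sample_outliers(
    matrix, confidence: float = 0.95
) -> pd.DataFrame:
    """Flag samples whose overall mean methylation is extreme for the cohort.

    Per-sample mean across regions, compared against the prediction-style
    interval for individual observations: cohort mean +- z * sd of the
    per-sample means (z two-sided at ``confidence``).
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    if values.shape[1] < 3:
        raise ClusterError("need >= 3 samples")
    means = values.mean(axis=0, skipna=True)
    center, sd = means.mean(), means.std(ddof=1)
    z = stats.norm.ppf((1 + confidence) / 2)
    lo, hi = center - z * sd, center + z * sd
    flag = np.where(means < lo, "low", np.where(means > hi, "high", ""))
    return pd.DataFrame(
        {"overall_mean": means, "flag": flag, "lower": lo, "upper": hi}
    )


# ---------------------------------------------------------------------------
# replicate reproducibility
# ---------------------------------------------------------------------------

@dataclass
class ReproducibilityReport:
    """Per-region replicate statistics; CV is NaN (undefined) at zero mean."""

    table: pd.DataFrame  # columns: mean, sd, cv_pct (+ round for subsets)

    @property
    def mean_cv(self) -> float:
        return float(self.table["cv_pct"].mean(skipna=True))

    @property
    def median_cv(self) -> float:
        return float(self.table["cv_pct"].median(skipna=True))


def replicate_cv(replicates: pd.DataFrame) -> ReproducibilityReport:
    """CV% of region means across replicate runs (rows = regions)."""
    if replicates.shape[1] < 2:
        raise ClusterError("need >= 2 replicates")
    mean = replicates.mean(axis=1)
    sd = replicates.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean == 0, np.nan, sd / mean * 100.0)
    return ReproducibilityReport(
        table=pd.DataFrame({"mean": mean, "sd": sd, "cv_pct": cv}, index=replicates.index)
    )


def randomized_cpg_cv(
    cpg_by_replicate: pd.DataFrame,
    subset_size: int = 5,
    n_rounds: int = 5,
    seed: int | None = None,
) -> ReproducibilityReport:
    """Replicate CV when a region is represented by random CpG subsets.

    ``cpg_by_replicate``: rows = CpG sites of one region, columns =
    replicates. Each round draws ``subset_size`` CpGs without replacement,
    averages them per replicate, and computes the CV across replicates.
    """
    n_cpgs = cpg_by_replicate.shape[0]
    if n_cpgs < subset_size:
        raise ClusterError(
            f"region has {n_cpgs} CpGs; cannot draw subsets of {subset_size}"
        )
    if cpg_by_replicate.shape[1] < 2:
        raise ClusterError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for rnd in range(1, n_rounds + 1):
        idx = rng.choice(n_cpgs, size=subset_size, replace=False)
        means = cpg_by_replicate.iloc[idx].mean(axis=0)
        m, sd = means.mean(), means.std(ddof=1)
        cv = np.nan if m == 0 else sd / m * 100.0
        rows.append({"round": rnd, "mean": m, "sd": sd, "cv_pct": cv})
    return ReproducibilityReport(table=pd.DataFrame(rows).set_index("round"))
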