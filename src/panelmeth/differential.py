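"""Z-score minority rule for differential promoter methylation.

Each region's methylation values are standardized across samples
(z = (m - mean) / sd, sample sd). A region is called differentially
methylated when between 1 and ``minority_max`` (default ceil(n/3)) samples
fall outside the two-sided normal interval at the chosen confidence
(|z| > 2.5758 at 99%): a minority of individuals departs from an otherwise
stable majority, the signature of a constitutional (mosaic) epimutation.

Effect sizes per region are summarized as the extremes across samples:
percent-point difference (max - min) x 100 and fold change max / min.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .aggregate import MethylationMatrix


class DifferentialError(ValueError):
    pass


def zscore(matrix: MethylationMatrix | pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a regions x samples matrix (sample sd, n-1 denominator).

    Missing cells are excluded per region; rows with < 3 observed values or
    zero spread are non-assessable and come back all-NaN.
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    if values.shape[1] < 3:
        raise DifferentialError("need >= 3 samples to standardize")
    arr = values.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(arr), axis=1)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(arr, axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z = (arr - mean) / sd
        constant = np.nanmax(arr, axis=1) == np.nanmin(arr, axis=1)
    z[(n_obs < 3) | constant | (sd[:, 0] == 0) | np.isnan(sd[:, 0])] = np.nan
    return pd.DataFrame(z, index=values.index, columns=values.columns)


@dataclass
class DifferentialRegion:
    """One minority differential-methylation call with its effect summary."""

    region_id: str
    gene: str
    outlier_samples: list[tuple[str, int]]  # (sample id, sign of z)
    direction: str  # positive | negative | mixed
    min_ratio: float
    max_ratio: float

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_samples)

    @property
    def diff_pp(self) -> float:
        return (self.max_ratio - self.min_ratio) * 100.0

    @property
    def fold(self) -> float:
        """max/min ratio; NaN (undefined) when the minimum is 0."""
        if self.min_ratio == 0:
            return float("nan")
        return self.max_ratio / self.min_ratio

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "gene": self.gene,
            "direction": self.direction,
            "n_outliers": self.n_outliers,
            "outliers": ";".join(f"{s}{'+' if sg > 0 else '-'}" for s, sg in self.outlier_samples),
            "min_ratio": self.min_ratio,
            "max_ratio": self.max_ratio,
            "diff_pp": self.diff_pp,
            "fold": self.fold,
        }


def region_extremes(
    matrix: MethylationMatrix | pd.DataFrame, region_id: str
) -> tuple[float, float, float, float]:
    """(min, max, percent-point difference, fold) across samples for a region.

    Fold is NaN when the minimum is exactly 0.
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    row = values.loc[region_id].dropna()
    if len(row) < 2:
        raise DifferentialError(
            f"region {region_id}: need >= 2 observed samples for extremes"
        )
    lo, hi = float(row.min()), float(row.max())
    diff_pp = (hi - lo) * 100.0
    fold = float("nan") if lo == 0 else hi / lo
    return lo, hi, diff_pp, fold


class MinorityZScoreCaller(BaseEstimator):
    """Detect regions where a minority of samples is differentially methylated.

    Parameters
    ----------
    confidence : float, default 0.99
        Two-sided confidence level; a sample is an outlier in a region when
        |z| exceeds the standard-normal quantile at (1 + confidence) / 2.
    minority_max : int or None, default None
        Largest outlier count still treated as a minority; ``None`` uses
        ceil(n_samples / 3) (12 for a cohort of 34).

    Attributes
    ----------
    z_matrix_ : DataFrame
        Row-standardized matrix (NaN rows = non-assessable).
    calls_ : list of DifferentialRegion
        Regions satisfying the minority rule, in input row order.
    is_called_ : Series of bool, indexed by region.
    minority_max_ : int
        The resolved minority bound.

    The estimator is fit/predict-shaped: input is the regions x samples
    methylation matrix (a :class:`MethylationMatrix` or plain DataFrame with
    regions as rows). ``predict`` returns the boolean call per region.
    """

    def __init__(self, confidence: float = 0.99, minority_max: int | None = None):
        self.confidence = confidence
        self.minority_max = minority_max

    def _validate(self, X) -> tuple[pd.DataFrame, pd.DataFrame | None]:
        if isinstance(X, MethylationMatrix):
            return X.values, X.region_meta
        if isinstance(X, pd.DataFrame):
            return X, None
        raise DifferentialError("X must be a MethylationMatrix or DataFrame")

    @property
    def z_crit_(self) -> float:
        return float(stats.norm.ppf((1 + self.confidence) / 2))

    def fit(self, X, y=None) -> "MinorityZScoreCaller":
        if not (0 < self.confidence < 1):
            raise DifferentialError("confidence must be in (0, 1)")
        values, meta = self._validate(X)
        n = values.shape[1]
        if n < 3:
            raise DifferentialError("need >= 3 samples")
        self.minority_max_ = (
            math.ceil(n / 3) if self.minority_max is None else self.minority_max
        )
        self.z_matrix_ = zscore(values)
        zcrit = self.z_crit_
        calls: list[DifferentialRegion] = []
        called = pd.Series(False, index=values.index)
        for region_id, zrow in self.z_matrix_.iterrows():
            zvals = zrow.dropna()
            if zvals.empty:
                continue
            outliers = zvals[zvals.abs() > zcrit]
            if not (1 <= len(outliers) <= self.minority_max_):
                continue
            signs = [int(s) for s in np.sign(outliers.to_numpy())]
            signs_arr = np.asarray(signs)
            if (signs_arr > 0).all():
                direction = "positive"
            elif (signs_arr < 0).all():
                direction = "negative"
            else:
                direction = "mixed"
            lo, hi, _, _ = region_extremes(values, region_id)
            gene = str(meta.at[region_id, "gene"]) if meta is not None else ""
            calls.append(
                DifferentialRegion(
                    region_id=str(region_id),
                    gene=gene,
                    outlier_samples=list(zip(outliers.index, signs)),
                    direction=direction,
                    min_ratio=lo,
                    max_ratio=hi,
                )
            )
            called.loc[region_id] = True
        self.calls_ = calls
        self.is_called_ = called
        self.n_features_in_ = n
        return self

    def predict(self, X) -> np.ndarray:
        """Boolean minority-differential call per region of ``X``."""
        return type(self)(
            confidence=self.confidence, minority_max=self.minority_max
        ).fit(X).is_called_.to_numpy()

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).is_called_.to_numpy()


def call_differential(
    matrix: MethylationMatrix | pd.DataFrame,
    confidence: float = 0.99,
    minority_max: int | None = None,
) -> list[DifferentialRegion]:
    """Functional wrapper over :class:`MinorityZScoreCaller`."""
    return MinorityZScoreCaller(confidence=confidence, minority_max=minority_max).fit(
        matrix
    ).calls_


def rank_and_threshold(
    regions: list[DifferentialRegion],
    pp_cuts: tuple[float, ...] = (5, 10, 20),
    fold_cut: float = 2.0,
) -> dict:
    """Effect-size summary of a differential call set.

    Returns counts of regions above each percent-point cut, the regions with
    fold > ``fold_cut`` despite diff <= 20 pp (high relative, low absolute
    difference), and rankings by absolute and relative effect.
    """
    counts = {
        f">{int(cut)}pp": sum(1 for r in regions if r.diff_pp > cut) for cut in pp_cuts
    }
    high_fold_low_pp = [
        r for r in regions if not math.isnan(r.fold) and r.fold > fold_cut and r.diff_pp <= 20
    ]
    by_pp = sorted(regions, key=lambda r: r.diff_pp, reverse=True)
    by_fold = sorted(
        (r for r in regions if not math.isnan(r.fold)),
        key=lambda r: r.fold,
        reverse=True,
    )
    return {
        "n_regions": len(regions),
        "pp_counts": counts,
        "high_fold_low_pp": high_fold_low_pp,
        "ranked_by_diff_pp": by_pp,
        "ranked_by_fold": by_fold,
    }


def hypermethylated_subset(
    regions: list[DifferentialRegion],
    pp_cut: float = 20.0,
    fold_cut: float = 2.0,
) -> dict:
    """Restrict calls to regions hyper-methylated in the minority.

    Only regions whose outliers all have positive z-scores qualify
    (mixed-direction regions are excluded). The report separates regions
    above the percent-point cut from those below it that still show a fold
    change above ``fold_cut``.
    """
    positive = [r for r in regions if r.direction == "positive"]
    above_pp = [r for r in positive if r.diff_pp > pp_cut]
    high_fold = [
        r
        for r in positive
        if r.diff_pp <= pp_cut and not math.isnan(r.fold) and r.fold > fold_cut
    ]
    return {
        "positive": positive,
        "above_pp": above_pp,
        "high_fold_low_pp": high_fold,
    }


def differential_table(regions: list[DifferentialRegion]) -> pd.DataFrame:
    """Flat table of calls (one row per region) for TSV export."""
    return pd.DataFrame([r.to_dict() for r in regions])
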