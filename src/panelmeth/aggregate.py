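"""Regions x samples methylation matrix under the common-CpG inclusion rule.

A CpG site enters the analysis only if it is covered by at least
``min_depth`` reads (default 10) in *every* sample of the cohort; a region's
value for a sample is the unweighted mean of the qualifying per-CpG ratios
within the capture region extended by ``flank`` bp on each side. Regions
with no qualifying CpG are recorded as missing in all samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import CapturePanel

META_COLUMNS = ["gene", "chrom", "start", "end"]


class AggregationError(ValueError):
    pass


@dataclass
class MethylationMatrix:
    """Mean methylation ratio per (capture region, sample), with metadata.

    ``values``: DataFrame, rows = region ids, columns = sample ids, entries
    in [0, 1] or NaN (missing). ``region_meta``: gene / coordinates per row.
    """

    values: pd.DataFrame
    region_meta: pd.DataFrame

    def __post_init__(self):
        if not self.values.index.equals(self.region_meta.index):
            raise AggregationError("values and region_meta must share the region index")
        bad = self.values.to_numpy(dtype=float)
        if np.nanmin(bad, initial=0.0) < 0 or np.nanmax(bad, initial=1.0) > 1:
            raise AggregationError("methylation ratios must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.index)

    def gene_of(self, region_id: str) -> str:
        return str(self.region_meta.at[region_id, "gene"])

    def to_csv(self, path: str | Path) -> None:
        pd.concat([self.region_meta, self.values], axis=1).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MethylationMatrix":
        df = pd.read_csv(path, index_col=0)
        meta = df[META_COLUMNS]
        values = df.drop(columns=META_COLUMNS)
        return cls(values=values, region_meta=meta)


def select_common_cpgs(
    sites_by_sample: dict[str, pd.DataFrame],
    min_depth: int = 10,
) -> pd.DataFrame:
    """Sites (chrom, pos, strand) with depth >= ``min_depth`` in every sample.

    Input frames come from :func:`panelmeth.calling.call_methylation`, which
    already restricts sites to regions +- flank.
    """
    if len(sites_by_sample) < 2:
        raise AggregationError("need at least 2 samples to intersect coverage")
    common: pd.DataFrame | None = None
    for sample, sites in sites_by_sample.items():
        ok = sites.loc[sites["depth"] >= min_depth, ["chrom", "pos", "strand"]]
        common = ok if common is None else common.merge(ok, on=["chrom", "pos", "strand"])
    return common.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def region_mean(
    sites: pd.DataFrame,
    region,
    common_cpgs: pd.DataFrame,
    flank: int = 250,
) -> float:
    """Unweighted mean ratio over a region's common CpGs; NaN if none qualify."""
    in_region = common_cpgs[
        (common_cpgs["chrom"] == region.chrom)
        & (common_cpgs["pos"] >= region.start - flank)
        & (common_cpgs["pos"] < region.end + flank)
    ]
    if in_region.empty:
        return float("nan")
    merged = in_region.merge(sites, on=["chrom", "pos", "strand"], how="left")
    return float(merged["ratio"].mean())


def build_matrix(
    sites_by_sample: dict[str, pd.DataFrame],
    panel: CapturePanel,
    min_depth: int = 10,
    flank: int = 250,
) -> MethylationMatrix:
    """Assemble the regions x samples matrix of mean methylation ratios."""
    regions = panel.capture_regions
    if not regions:
        raise AggregationError("panel has no capture regions")
    common = select_common_cpgs(sites_by_sample, min_depth=min_depth)
    samples = list(sites_by_sample)
    values = np.full((len(regions), len(samples)), np.nan)

    # assign each common CpG to the regions whose flanked window contains it,
    # then average per (region, sample) in one pass
    for j, sample in enumerate(samples):
        sites = sites_by_sample[sample]
        merged = common.merge(sites, on=["chrom", "pos", "strand"], how="left")
        for i, region in enumerate(regions):
            mask = (
                (merged["chrom"] == region.chrom)
                & (merged["pos"] >= region.start - flank)
                & (merged["pos"] < region.end + flank)
            )
            if mask.any():
                values[i, j] = merged.loc[mask, "ratio"].mean()

    meta = pd.DataFrame(
        {
            "gene": [r.gene for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        },
        index=pd.Index([r.region_id for r in regions], name="region_id"),
    )
    vals = pd.DataFrame(values, index=meta.index, columns=samples)
    return MethylationMatrix(values=vals, region_meta=meta)
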