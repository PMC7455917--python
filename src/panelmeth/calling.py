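"""Per-CpG methylation calling from filtered aligned bisulfite read pairs.

The caller restricts analysis to mapped, properly paired, non-duplicate
pairs, masks mate overlap so each genomic base counts at most once per pair,
splits reads by bisulfite strand, and reports one site per CpG cytosine
(both strands separately, methratio-style): top-strand sites count C vs T
from original-top (OT) reads only, bottom-strand sites count G vs A from
original-bottom (OB) reads.

Also here: lambda-spike-in conversion efficiency, read/coverage accounting,
the 1/depth sensitivity statistic, and informative-CpG counts.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import CapturePanel, Region, cpg_positions
from .simulate import AlignedReadPair, Mate

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "meth_count", "unmeth_count",
                "depth", "ratio"]


class CallingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# read filtering
# ---------------------------------------------------------------------------

def preprocess_reads(pairs: list[AlignedReadPair]) -> list[AlignedReadPair]:
    """Retain mapped, properly paired, non-duplicate pairs; clip mate overlap.

    Where mates overlap, the overlapping bases of mate2 are removed (the
    leftmost copy wins) so each genomic base contributes at most one call per
    pair. A mate2 fully contained in mate1 is kept with an empty sequence.
    """
    out = []
    for pair in pairs:
        if not (pair.mapped and pair.proper_pair) or pair.duplicate:
            continue
        m1, m2 = pair.mate1, pair.mate2
        if m2.pos < m1.pos:
            m1, m2 = m2, m1
        if m2.pos < m1.end:  # overlap: drop mate2's bases under mate1
            keep_from = min(m1.end, m2.end) - m2.pos
            m2 = Mate(m2.pos + keep_from, m2.seq[keep_from:])
        out.append(replace(pair, mate1=m1, mate2=m2))
    return out


def split_by_strand(
    pairs: list[AlignedReadPair],
) -> tuple[list[AlignedReadPair], list[AlignedReadPair]]:
    """Partition pairs into (original-top, original-bottom) sets."""
    top, bottom = [], []
    for pair in pairs:
        if pair.strand == "OT":
            top.append(pair)
        elif pair.strand == "OB":
            bottom.append(pair)
        else:
            raise CallingError(
                f"read {pair.read_id}: missing/unknown bisulfite strand tag "
                f"{pair.strand!r}"
            )
    return top, bottom


# ---------------------------------------------------------------------------
# CpG pileup
# ---------------------------------------------------------------------------

def _windows(panel: CapturePanel, flank: int) -> dict[str, list[tuple[int, int]]]:
    """Merged capture-region +- flank windows per contig."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in panel.capture_regions:
        per_chrom.setdefault(r.chrom, []).append((r.start - flank, r.end + flank))
    merged = {}
    for chrom, spans in per_chrom.items():
        spans.sort()
        acc = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[chrom] = [(max(0, s), e) for s, e in acc]
    return merged


def _in_windows(positions: np.ndarray, windows: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(positions.shape, dtype=bool)
    for s, e in windows:
        mask |= (positions >= s) & (positions < e)
    return mask


def _count_sites(
    pairs: list[AlignedReadPair],
    site_pos: dict[str, np.ndarray],
    meth_base: bytes,
    unmeth_base: bytes,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    counts = {
        chrom: (np.zeros(len(p), dtype=np.int64), np.zeros(len(p), dtype=np.int64))
        for chrom, p in site_pos.items()
    }
    for pair in pairs:
        pos = site_pos.get(pair.chrom)
        if pos is None or pos.size == 0:
            continue
        meth, unmeth = counts[pair.chrom]
        for mate in pair.mates():
            if not mate.seq:
                continue
            lo = np.searchsorted(pos, mate.pos, side="left")
            hi = np.searchsorted(pos, mate.end, side="left")
            if lo == hi:
                continue
            bases = np.frombuffer(mate.seq.encode(), dtype="S1")
            offs = pos[lo:hi] - mate.pos
            calls = bases[offs]
            meth[lo:hi] += calls == meth_base
            unmeth[lo:hi] += calls == unmeth_base
    return counts


def call_methylation(
    pairs: list[AlignedReadPair],
    reference: dict[str, str],
    panel: CapturePanel,
    flank: int = 250,
) -> pd.DataFrame:
    """Per-CpG methylation ratios within capture regions +- ``flank``.

    ``pairs`` must already be filtered (see :func:`preprocess_reads`).
    Returns a methratio-style frame with one row per reference CpG cytosine
    (both strands), 0-based positions, ``ratio`` NaN where depth is 0.
    """
    for chrom in {r.chrom for r in panel.capture_regions}:
        if chrom not in reference:
            raise CallingError(f"reference lacks panel contig {chrom!r}")
    windows = _windows(panel, flank)
    top, bottom = split_by_strand(pairs)

    plus_pos: dict[str, np.ndarray] = {}
    minus_pos: dict[str, np.ndarray] = {}
    for chrom, spans in windows.items():
        plus, minus = cpg_positions(reference[chrom])
        plus_pos[chrom] = plus[_in_windows(plus, spans)]
        minus_pos[chrom] = minus[_in_windows(minus, spans)]

    plus_counts = _count_sites(top, plus_pos, b"C", b"T")
    minus_counts = _count_sites(bottom, minus_pos, b"G", b"A")

    frames = []
    for strand, positions, counts in (
        ("+", plus_pos, plus_counts),
        ("-", minus_pos, minus_counts),
    ):
        for chrom, pos in positions.items():
            meth, unmeth = counts[chrom]
            depth = meth + unmeth
            with np.errstate(invalid="ignore"):
                ratio = np.where(depth > 0, meth / np.maximum(depth, 1), np.nan)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "context": "CG",
                        "meth_count": meth,
                        "unmeth_count": unmeth,
                        "depth": depth,
                        "ratio": ratio,
                    }
                )
            )
    sites = pd.concat(frames, ignore_index=True)
    return sites.sort_values(["chrom", "pos", "strand"], ignore_index=True)


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

@dataclass
class ConversionReport:
    """Lambda spike-in conversion accounting: C = unconverted, T = converted."""

    C: int
    T: int

    @property
    def efficiency_pct(self) -> float:
        return self.T / (self.C + self.T) * 100.0


def conversion_efficiency(
    pairs: list[AlignedReadPair],
    lambda_seq: str,
    lambda_contig: str = "lambda",
) -> ConversionReport:
    """Conversion (%) = T/(C+T) x 100 over *all* reference cytosines of the
    unmethylated lambda control, both strands (OT reads at reference Cs, OB
    reads at reference Gs)."""
    lam = [p for p in pairs if p.chrom == lambda_contig]
    arr = np.frombuffer(lambda_seq.encode(), dtype="S1")
    c_pos = np.flatnonzero(arr == b"C")
    g_pos = np.flatnonzero(arr == b"G")
    top, bottom = split_by_strand(lam)
    c = t = 0
    for reads, positions, unconv, conv in (
        (top, c_pos, b"C", b"T"),
        (bottom, g_pos, b"G", b"A"),
    ):
        counts = _count_sites(reads, {lambda_contig: positions}, unconv, conv)
        meth, unmeth = counts[lambda_contig]
        c += int(meth.sum())
        t += int(unmeth.sum())
    if c + t == 0:
        raise CallingError("no lambda coverage: conversion efficiency undefined")
    return ConversionReport(C=c, T=t)


def sensitivity(mean_depth: float) -> float:
    """Detection sensitivity of the assay as a percentage: (1/depth) x 100.

    One aberrant allele among ``depth`` reads is the smallest detectable
    signal, so sensitivity decreases with coverage. Rounded half-up to two
    decimals (0.53 at depth 189.6).
    """
    if mean_depth <= 0:
        raise CallingError("mean depth must be positive")
    pct = decimal.Decimal(100) / decimal.Decimal(str(mean_depth))
    return float(pct.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


@dataclass
class CoverageReport:
    input_reads: int
    pct_post_qc: float
    pct_mapped: float
    paired_clipped_reads: int
    pct_on_primary: float
    pct_on_capture: float
    mean_cov_primary: float
    mean_cov_capture: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _region_depth(
    pairs: list[AlignedReadPair], regions: list[Region]
) -> tuple[float, int]:
    """(mean per-base depth over region bases, reads overlapping any region)."""
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    depth_arrays = {
        (r.chrom, r.start): np.zeros(r.width, dtype=np.int64) for r in regions
    }
    n_overlapping = 0
    for pair in pairs:
        regs = by_chrom.get(pair.chrom, ())
        for mate in pair.mates():
            if not mate.seq:
                continue
            hit = False
            for r in regs:
                s = max(mate.pos, r.start)
                e = min(mate.end, r.end)
                if s < e:
                    depth_arrays[(r.chrom, r.start)][s - r.start : e - r.start] += 1
                    hit = True
            if hit:
                n_overlapping += 1
    total = sum(int(a.sum()) for a in depth_arrays.values())
    bases = sum(r.width for r in regions)
    return (total / bases if bases else 0.0), n_overlapping


def coverage_report(
    pairs: list[AlignedReadPair],
    panel: CapturePanel,
    exclude_lambda: bool = True,
) -> CoverageReport:
    """Read and coverage accounting over the panel for one sample.

    ``pairs`` is the *raw* pair set; filtering (proper pair, duplicate,
    overlap clipping) is applied internally so mean coverages reflect the
    depth actually used for methylation calling.
    """
    if not panel.capture_regions:
        raise CallingError("panel has no capture regions")
    if exclude_lambda:
        pairs = [p for p in pairs if p.chrom != panel.lambda_contig]
    input_reads = 2 * len(pairs)
    mapped_reads = 2 * sum(1 for p in pairs if p.mapped)
    filtered = preprocess_reads(pairs)
    retained_reads = sum(
        (1 if p.mate1.seq else 0) + (1 if p.mate2.seq else 0) for p in filtered
    )
    primary = panel.primary_regions or panel.capture_regions
    cov_primary, on_primary = _region_depth(filtered, primary)
    cov_capture, on_capture = _region_depth(filtered, panel.capture_regions)
    return CoverageReport(
        input_reads=input_reads,
        pct_post_qc=100.0,  # quality trimming happens upstream of this pipeline
        pct_mapped=(mapped_reads / input_reads * 100.0) if input_reads else 0.0,
        paired_clipped_reads=retained_reads,
        pct_on_primary=(on_primary / mapped_reads * 100.0) if mapped_reads else 0.0,
        pct_on_capture=(on_capture / mapped_reads * 100.0) if mapped_reads else 0.0,
        mean_cov_primary=cov_primary,
        mean_cov_capture=cov_capture,
    )


def count_informative_cpgs(sites: pd.DataFrame) -> tuple[int, int]:
    """(n_total, n_strict): covered sites, and sites with depth > 10 and a
    non-zero methylation ratio."""
    covered = sites["depth"] >= 1
    strict = (sites["depth"] > 10) & (sites["ratio"] > 0)
    return int(covered.sum()), int(strict.sum())


# ---------------------------------------------------------------------------
# methratio-style TSV
# ---------------------------------------------------------------------------

def write_methratio_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    """methratio-style TSV: 1-based positions on disk."""
    out = sites.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_methratio_tsv(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t")
    sites["pos"] = sites["pos"] - 1
    return sites[SITE_COLUMNS]
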