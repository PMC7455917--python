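"""Synthetic cohort truth and aligned bisulfite read-pair simulation.

The generator emulates the statistical structure of a targeted
methylation-specific sequencing experiment on white blood cell DNA:

* a cohort (default 34 samples) whose per-region methylation is stable
  across individuals except for a planted minority of hyper- or
  hypo-methylated samples in a subset of regions;
* paired-end reads produced *already aligned* (alignment is out of scope);
  bisulfite chemistry is applied per read so that mosaic alleles are
  representable: each fragment draws its methylation state per CpG from the
  sample's true level;
* an unmethylated lambda contig sequenced alongside, from which conversion
  efficiency is estimated;
* duplicates as exact positional copies and a configurable fraction of
  improper / unmapped pairs, all discoverable downstream via flags.

Methylation states and conversion follow the standard bisulfite model: a
covering top-strand read shows C at a CpG cytosine with probability
``m + (1 - m) * (1 - conversion_eff)`` before sequencing error, where ``m``
is the fragment's drawn methylation state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .panel import CapturePanel, Region, cpg_positions

STRAND_TAG = "ZS"  # SAM tag carrying the bisulfite strand (OT / OB)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cohort truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted per-sample, per-region methylation levels.

    ``levels`` is a regions x samples DataFrame of true methylation levels in
    [0, 1]; ``region_info`` records baseline, differential flag, direction,
    minority sample ids and effect size per region.
    """

    levels: pd.DataFrame
    region_info: pd.DataFrame
    conversion_eff: float = 0.995
    seq_error: float = 0.001
    dup_rate: float = 0.05
    seed: int | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def region_ids(self) -> list[str]:
        return list(self.levels.index)

    def differential_regions(self) -> pd.DataFrame:
        return self.region_info[self.region_info["differential"]]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# region_info\n")
            self.region_info.to_csv(fh, sep="\t")
            fh.write("# levels\n")
            self.levels.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "SyntheticTruth":
        text = Path(path).read_text().split("# levels\n")
        import io as _io

        info = pd.read_csv(
            _io.StringIO(text[0].replace("# region_info\n", "")), sep="\t", index_col=0
        )
        info["differential"] = info["differential"].astype(bool)
        levels = pd.read_csv(_io.StringIO(text[1]), sep="\t", index_col=0)
        return cls(levels=levels, region_info=info, **kwargs)


def _beta_around(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Beta draws with the given mean and (approximate) sd, clipped away from 0/1."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-3, 1 - 1e-3)
    if sd <= 0:
        return mean.copy()
    nu = mean * (1 - mean) / sd**2 - 1
    nu = np.maximum(nu, 2.0)
    return rng.beta(mean * nu, (1 - mean) * nu)


def generate_cohort_truth(
    panel: CapturePanel,
    n_samples: int = 34,
    baseline_sampler: tuple | None = ("beta", 0.6, 1.6),
    differential_spec: tuple | None = None,
    jitter_sd: float = 0.01,
    conversion_eff: float = 0.995,
    seq_error: float = 0.001,
    dup_rate: float = 0.05,
    seed: int | None = None,
) -> SyntheticTruth:
    """Plant per-sample true methylation levels over the panel's capture regions.

    Parameters
    ----------
    baseline_sampler
        ``("beta", a, b)`` or ``("uniform", lo, hi)``; the region baseline
        distribution. The default skews low with a long high tail, the shape
        promoter methylation shows in blood.
    differential_spec
        ``(n_diff_regions, minority_size, effect_pp, direction_mix)``.
        ``effect_pp`` is in percent points; ``direction_mix`` is ``"hyper"``,
        ``"hypo"`` or a float = fraction of differential regions that are
        hyper-methylated. ``None`` plants no effects.
    jitter_sd
        Biological scatter of non-minority samples around the region baseline
        (beta-distributed); the default keeps null regions effectively null.
    """
    if n_samples < 1:
        raise SimulationError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    regions = panel.capture_regions
    region_ids = [r.region_id for r in regions]
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]

    kind = baseline_sampler[0]
    if kind == "beta":
        baselines = rng.beta(baseline_sampler[1], baseline_sampler[2], size=len(regions))
    elif kind == "uniform":
        baselines = rng.uniform(baseline_sampler[1], baseline_sampler[2], size=len(regions))
    else:
        raise SimulationError(f"unknown baseline sampler {kind!r}")
    baselines = np.clip(baselines, 0.02, 0.98)

    levels = np.empty((len(regions), n_samples))
    for i, b in enumerate(baselines):
        levels[i] = _beta_around(rng, np.full(n_samples, b), jitter_sd)

    info = pd.DataFrame(
        {
            "gene": [r.gene for r in regions],
            "baseline": baselines,
            "differential": False,
            "direction": "",
            "minority_samples": "",
            "effect": 0.0,
        },
        index=pd.Index(region_ids, name="region_id"),
    )

    if differential_spec is not None:
        n_diff, minority_size, effect_pp, direction_mix = differential_spec
        minority_cap = math.ceil(n_samples / 3)
        if not (1 <= minority_size <= minority_cap):
            raise SimulationError(
                f"minority_size must be in [1, ceil(n/3)] = [1, {minority_cap}]"
            )
        if not (0 < effect_pp <= 100):
            raise SimulationError("effect_pp must be in (0, 100]")
        effect = effect_pp / 100.0
        if direction_mix == "hyper":
            frac_hyper = 1.0
        elif direction_mix == "hypo":
            frac_hyper = 0.0
        else:
            frac_hyper = float(direction_mix)

        n_hyper = int(round(n_diff * frac_hyper))
        directions = ["hyper"] * n_hyper + ["hypo"] * (n_diff - n_hyper)
        # a region is eligible for a direction if the shifted level stays in [0,1]
        feasible_hyper = np.flatnonzero(baselines + effect <= 0.99)
        feasible_hypo = np.flatnonzero(baselines - effect >= 0.01)
        chosen: list[int] = []
        pool_h = list(rng.permutation(feasible_hyper))
        pool_o = list(rng.permutation(feasible_hypo))
        for d in directions:
            pool = pool_h if d == "hyper" else pool_o
            while pool and pool[-1] in chosen:
                pool.pop()
            if not pool:
                raise SimulationError(
                    f"no region has a baseline compatible with a {effect_pp} pp "
                    f"{d} effect"
                )
            chosen.append(pool.pop())

        for idx, d in zip(chosen, directions):
            minority = rng.choice(n_samples, size=minority_size, replace=False)
            shift = effect if d == "hyper" else -effect
            levels[idx, minority] = np.clip(baselines[idx] + shift, 0.0, 1.0)
            rid = region_ids[idx]
            info.loc[rid, ["differential", "direction", "effect"]] = [True, d, effect]
            info.loc[rid, "minority_samples"] = ",".join(
                sample_ids[s] for s in sorted(minority)
            )

    return SyntheticTruth(
        levels=pd.DataFrame(levels, index=info.index, columns=sample_ids),
        region_info=info,
        conversion_eff=conversion_eff,
        seq_error=seq_error,
        dup_rate=dup_rate,
        seed=seed,
    )


def simulate_region_means(
    truth: SyntheticTruth,
    depth: int = 190,
    n_cpgs: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample a regions x samples matrix of observed region means directly.

    A fast, read-free surrogate for the full simulator: each region mean is
    the average of ``n_cpgs`` per-CpG ratios, each Binomial(depth, level)/depth.
    Shares the sampling distribution of the read-level pipeline when
    conversion is perfect and error-free.
    """
    rng = np.random.default_rng(seed)
    p = truth.levels.to_numpy()
    draws = rng.binomial(depth, p[..., None], size=(*p.shape, n_cpgs)) / depth
    return pd.DataFrame(
        draws.mean(axis=-1), index=truth.levels.index, columns=truth.levels.columns
    )


# ---------------------------------------------------------------------------
# aligned read pairs
# ---------------------------------------------------------------------------

@dataclass
class Mate:
    pos: int  # 0-based leftmost aligned position
    seq: str

    @property
    def end(self) -> int:
        return self.pos + len(self.seq)


@dataclass
class AlignedReadPair:
    """A pre-aligned bisulfite read pair (top-strand coordinates).

    OT pairs carry C->T conversions on the top strand; OB pairs carry G->A
    conversions relative to the top-strand reference.
    """

    read_id: str
    chrom: str
    mate1: Mate
    mate2: Mate
    strand: str  # "OT" | "OB"
    proper_pair: bool = True
    duplicate: bool = False
    mapped: bool = True

    def mates(self):
        return (self.mate1, self.mate2)


def _bisulfite_seq(
    ref: np.ndarray,
    start: int,
    length: int,
    strand: str,
    meth_state: dict[int, bool],
    is_cpg: np.ndarray,
    conversion_eff: float,
    seq_error: float,
    rng: np.random.Generator,
) -> str:
    """Observed read bases for one mate, top-strand coordinates."""
    seq = ref[start : start + length].copy()
    if strand == "OT":
        target, converted = b"C", b"T"
    else:
        target, converted = b"G", b"A"
    offs = np.flatnonzero(seq == target)
    if offs.size:
        cpg = is_cpg[start + offs]
        # unmethylated cytosines convert with probability conversion_eff
        meth = np.zeros(offs.size, dtype=bool)
        cpg_idx = np.flatnonzero(cpg)
        for i in cpg_idx:
            meth[i] = meth_state.get(start + int(offs[i]), False)
        convert = ~meth & (rng.random(offs.size) < conversion_eff)
        seq[offs[convert]] = converted
    if seq_error > 0:
        errs = np.flatnonzero(rng.random(length) < seq_error)
        if errs.size:
            alts = np.frombuffer(b"ACGT", dtype="S1")
            for off in errs:
                choices = alts[alts != seq[off]]
                seq[off] = choices[rng.integers(0, 3)]
    return seq.tobytes().decode()


def _expected_counted_bases(insert: tuple[int, int], read_len: int) -> float:
    """Mean distinct bases one pair contributes after overlap clipping."""
    lo, hi = insert
    lengths = np.arange(lo, hi + 1)
    return float(np.minimum(lengths, 2 * read_len).mean())


def generate_reads(
    truth: SyntheticTruth,
    panel: CapturePanel,
    reference: dict[str, str],
    mean_depth: float = 190.0,
    conversion_eff: float | None = None,
    seq_error: float | None = None,
    dup_rate: float | None = None,
    insert: tuple[int, int] = (150, 250),
    read_len: int = 100,
    flank: int = 250,
    improper_frac: float = 0.02,
    unmapped_frac: float = 0.005,
    lambda_depth: float | None = None,
    seed: int | None = None,
) -> dict[str, list[AlignedReadPair]]:
    """Simulate aligned read pairs for every sample in the cohort.

    Fragments are laid uniformly over the union of capture regions extended
    by ``flank`` (merged per contig, so adjacent regions are never covered
    twice); the pair count is set so the post-filter (deduplicated, properly
    paired, overlap-clipped) depth over target bases matches ``mean_depth``.
    Each covered CpG draws its per-fragment methylation state from the truth
    level of the capture region it belongs to (flanking CpGs inherit the
    nearest region's level). Duplicate, improper and unmapped pairs are
    generated *in addition* and flagged.

    Lambda control pairs are drawn from the fully unmethylated lambda contig
    at ``lambda_depth`` (defaults to ``mean_depth``).

    Returns a mapping sample_id -> list of pairs (target + lambda).
    """
    conversion_eff = truth.conversion_eff if conversion_eff is None else conversion_eff
    seq_error = truth.seq_error if seq_error is None else seq_error
    dup_rate = truth.dup_rate if dup_rate is None else dup_rate
    if not (0 < conversion_eff <= 1):
        raise SimulationError("conversion_eff must be in (0, 1]")
    if mean_depth <= 0:
        raise SimulationError("mean_depth must be positive")
    if insert[0] > insert[1] or insert[0] < read_len // 2:
        raise SimulationError("degenerate insert range")
    if lambda_depth is None:
        lambda_depth = mean_depth

    rng = np.random.default_rng(seed)
    refs = {c: np.frombuffer(s.encode(), dtype="S1") for c, s in reference.items()}
    cpg_sets: dict[str, dict[str, np.ndarray]] = {}
    for chrom, seq in reference.items():
        plus, minus = cpg_positions(seq)
        is_cpg = np.zeros(len(seq) + 1, dtype=bool)
        is_cpg[plus] = True
        is_cpg[minus] = True
        cpg_sets[chrom] = {"OT": plus, "OB": minus, "is_cpg": is_cpg}

    # merged fragment windows per contig, and each CpG's governing region
    regions_by_chrom: dict[str, list[Region]] = {}
    for r in panel.capture_regions:
        regions_by_chrom.setdefault(r.chrom, []).append(r)
    windows_by_chrom: dict[str, list[tuple[int, int]]] = {}
    region_of_cpg: dict[str, dict[str, np.ndarray]] = {}
    for chrom, regs in regions_by_chrom.items():
        contig_len = len(reference[chrom])
        spans = sorted((max(0, r.start - flank), min(contig_len, r.end + flank))
                       for r in regs)
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        windows_by_chrom[chrom] = [tuple(w) for w in merged]
        region_of_cpg[chrom] = {}
        for strand in ("OT", "OB"):
            pos = cpg_sets[chrom][strand]
            # nearest capture region decides the CpG's methylation level
            dist = np.stack([
                np.maximum.reduce([r.start - pos, pos - r.end + 1,
                                   np.zeros(len(pos), dtype=int)])
                for r in regs
            ])
            region_of_cpg[chrom][strand] = np.asarray(
                [regs[i].region_id for i in dist.argmin(axis=0)]
            )

    lam_chrom = panel.lambda_contig
    windows_by_chrom[lam_chrom] = [(0, len(reference[lam_chrom]))]

    counted = _expected_counted_bases(insert, read_len)
    mean_l = (insert[0] + insert[1]) / 2
    out: dict[str, list[AlignedReadPair]] = {}
    serial = 0

    for sample in truth.sample_ids:
        pairs: list[AlignedReadPair] = []
        jobs: list[tuple[str, int, int, float]] = []
        for chrom, windows in windows_by_chrom.items():
            depth = lambda_depth if chrom == lam_chrom else mean_depth
            for w_start, w_end in windows:
                jobs.append((chrom, w_start, w_end, depth))

        for chrom, w_start, w_end, depth in jobs:
            ref = refs[chrom]
            contig_len = len(ref)
            is_lambda = chrom == lam_chrom
            span = w_end - w_start
            # starts are uniform over span + L - 1 placements, of which each
            # interior base is hit by `counted` of the fragment's bases
            n_pairs = max(1, int(round(depth * (span + mean_l - 1) / counted)))
            levels = None
            if not is_lambda:
                levels = {
                    strand: truth.levels.loc[region_of_cpg[chrom][strand], sample]
                    .to_numpy(dtype=float)
                    for strand in ("OT", "OB")
                }

            for _ in range(n_pairs):
                L = int(rng.integers(insert[0], insert[1] + 1))
                s = int(rng.integers(w_start - L + 1, w_end))
                s = max(0, min(s, contig_len - L))
                strand = "OT" if rng.random() < 0.5 else "OB"
                # per-fragment allele: draw methylation state at each CpG covered
                meth_state: dict[int, bool] = {}
                if not is_lambda:
                    strand_pos = cpg_sets[chrom][strand]
                    lo = np.searchsorted(strand_pos, s)
                    hi = np.searchsorted(strand_pos, s + L)
                    if hi > lo:
                        states = rng.random(hi - lo) < levels[strand][lo:hi]
                        for pos, st in zip(strand_pos[lo:hi], states):
                            meth_state[int(pos)] = bool(st)
                is_cpg = cpg_sets[chrom]["is_cpg"]
                m1 = Mate(s, _bisulfite_seq(ref, s, read_len, strand, meth_state,
                                            is_cpg, conversion_eff, seq_error, rng))
                p2 = s + L - read_len
                m2 = Mate(p2, _bisulfite_seq(ref, p2, read_len, strand, meth_state,
                                             is_cpg, conversion_eff, seq_error, rng))
                serial += 1
                pair = AlignedReadPair(
                    read_id=f"rp{serial:08d}", chrom=chrom, mate1=m1, mate2=m2,
                    strand=strand,
                )
                pairs.append(pair)
                if rng.random() < dup_rate:
                    serial += 1
                    pairs.append(replace(pair, read_id=f"rp{serial:08d}", duplicate=True))
                if rng.random() < improper_frac:
                    serial += 1
                    pairs.append(replace(pair, read_id=f"rp{serial:08d}",
                                         proper_pair=False))
                if rng.random() < unmapped_frac:
                    serial += 1
                    pairs.append(replace(pair, read_id=f"rp{serial:08d}", mapped=False,
                                         proper_pair=False))
        out[sample] = pairs
    return out


# ---------------------------------------------------------------------------
# SAM round trip
# ---------------------------------------------------------------------------

def write_sam(
    pairs: list[AlignedReadPair],
    reference: dict[str, str],
    path: str | Path,
) -> None:
    """Write pairs as a coordinate-sorted SAM with bisulfite-strand tags."""
    contigs = list(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in contigs],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    records = []
    for pair in pairs:
        for i, mate in enumerate(pair.mates()):
            a = pysam.AlignedSegment()
            a.query_name = pair.read_id
            a.query_sequence = mate.seq
            a.reference_id = tid[pair.chrom]
            a.reference_start = mate.pos
            a.mapping_quality = 40
            a.cigarstring = f"{len(mate.seq)}M"
            other = pair.mates()[1 - i]
            a.next_reference_id = tid[pair.chrom]
            a.next_reference_start = other.pos
            a.template_length = (pair.mate2.end - pair.mate1.pos) * (1 if i == 0 else -1)
            flag = 0x1  # paired
            flag |= 0x40 if i == 0 else 0x80
            if pair.proper_pair:
                flag |= 0x2
            if not pair.mapped:
                flag |= 0x4
            if pair.duplicate:
                flag |= 0x400
            # mate orientation: mate2 reported on reverse strand
            flag |= 0x10 if i == 1 else 0x20
            a.flag = flag
            a.set_tag(STRAND_TAG, pair.strand)
            records.append((mate.pos, pair.read_id, i, a))
    records.sort(key=lambda t: (t[3].reference_id, t[0], t[1], t[2]))
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for *_, a in records:
            fh.write(a)


def read_sam(path: str | Path) -> list[AlignedReadPair]:
    """Read pairs back from a SAM/BAM produced by :func:`write_sam`."""
    firsts: dict[str, pysam.AlignedSegment] = {}
    seconds: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            (firsts if a.is_read1 else seconds)[a.query_name] = a
    pairs = []
    for name, a1 in firsts.items():
        a2 = seconds.get(name)
        if a2 is None:
            raise SimulationError(f"read {name} is missing its mate")
        if not a1.has_tag(STRAND_TAG):
            raise SimulationError(f"read {name} lacks the {STRAND_TAG} strand tag")
        pairs.append(
            AlignedReadPair(
                read_id=name,
                chrom=a1.reference_name,
                mate1=Mate(a1.reference_start, a1.query_sequence),
                mate2=Mate(a2.reference_start, a2.query_sequence),
                strand=a1.get_tag(STRAND_TAG),
                proper_pair=a1.is_proper_pair,
                duplicate=a1.is_duplicate,
                mapped=not a1.is_unmapped,
            )
        )
    pairs.sort(key=lambda p: (p.chrom, p.mate1.pos, p.read_id))
    return pairs
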