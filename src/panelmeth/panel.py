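"""Capture-panel model: promoter capture regions grouped into target regions and genes.

A panel is a set of genomic intervals with two roles:

* ``primary`` -- the designed target region, a promoter-like span
  (nominally -1500/+500 around a transcription start site);
* ``capture`` -- the probe-level intervals that split each primary region.

All coordinates are 0-based half-open internally; BED on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

ROLES = ("capture", "primary")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


@dataclass(frozen=True)
class Region:
    """One panel interval, half-open [start, end)."""

    region_id: str
    gene: str
    chrom: str
    start: int
    end: int
    role: str

    def __post_init__(self):
        if self.start >= self.end:
            raise PanelError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )
        if self.role not in ROLES:
            raise PanelError(f"region {self.region_id}: unknown role {self.role!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class CapturePanel:
    """Capture regions nested in primary target regions, plus a conversion-control contig."""

    regions: list[Region]
    lambda_contig: str = "lambda"

    def __post_init__(self):
        self.validate()

    # -- accessors ---------------------------------------------------------
    def by_role(self, role: str) -> list[Region]:
        return [r for r in self.regions if r.role == role]

    @property
    def capture_regions(self) -> list[Region]:
        return self.by_role("capture")

    @property
    def primary_regions(self) -> list[Region]:
        return self.by_role("primary")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.gene, None)
        return list(seen)

    @property
    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.chrom, None)
        return list(seen)

    def validate(self) -> None:
        if not self.regions:
            raise PanelError("panel has no regions")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate region ids in panel")
        for role in ROLES:
            regs = sorted(self.by_role(role), key=lambda r: (r.chrom, r.start))
            for a, b in zip(regs, regs[1:]):
                if a.overlaps(b):
                    raise PanelError(
                        f"overlapping {role} regions {a.region_id} and {b.region_id}"
                    )
        # every capture region nests inside exactly one primary region (if any primaries)
        primaries = self.primary_regions
        if primaries:
            for c in self.capture_regions:
                hosts = [
                    p
                    for p in primaries
                    if p.chrom == c.chrom and p.start <= c.start and c.end <= p.end
                ]
                if len(hosts) != 1:
                    raise PanelError(
                        f"capture region {c.region_id} is contained in "
                        f"{len(hosts)} primary regions (expected 1)"
                    )

    # -- BED round trip ----------------------------------------------------
    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in sorted(self.regions, key=lambda r: (r.chrom, r.start, r.role)):
                name = f"{r.gene}|{r.region_id}|{r.role}"
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t.\n")

    @classmethod
    def from_bed(cls, path: str | Path, lambda_contig: str = "lambda") -> "CapturePanel":
        regions = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise PanelError(f"{path}:{lineno}: expected >= 4 BED columns")
                chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise PanelError(f"{path}:{lineno}: non-integer coordinates") from exc
                if start_i >= end_i:
                    raise PanelError(f"{path}:{lineno}: start >= end")
                fields = name.split("|")
                if len(fields) != 3:
                    raise PanelError(
                        f"{path}:{lineno}: name must be gene|region_id|role, got {name!r}"
                    )
                gene, region_id, role = fields
                regions.append(Region(region_id, gene, chrom, start_i, end_i, role))
        return cls(regions=regions, lambda_contig=lambda_contig)


# ---------------------------------------------------------------------------
# synthetic panel + reference generation
# ---------------------------------------------------------------------------

def _random_sequence_no_cpg(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random DNA with CG dinucleotides suppressed (so CpGs sit only where planted)."""
    seq = _BASES[rng.integers(0, 4, size=n)]
    # break any accidental CG by flipping the G to an A
    for _ in range(4):
        cg = np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G"))
        if cg.size == 0:
            break
        seq[cg + 1] = b"A"
    return seq


def _plant_cpgs(seq: np.ndarray, start: int, end: int, spacing: int,
                rng: np.random.Generator) -> np.ndarray:
    """Place CG dinucleotides every ~spacing bp in [start, end); returns C positions."""
    positions = []
    pos = start + int(rng.integers(2, max(3, spacing // 2)))
    while pos < end - 1:
        seq[pos] = b"C"
        seq[pos + 1] = b"G"
        positions.append(pos)
        pos += spacing + int(rng.integers(-spacing // 4, spacing // 4 + 1))
    return np.asarray(positions, dtype=int)


def generate_panel(
    n_genes: int,
    regions_per_gene: tuple[int, int] = (1, 3),
    region_length: tuple[int, int] = (300, 900),
    seed: int | None = None,
    cpg_spacing: int = 30,
    flank: int = 250,
) -> tuple[CapturePanel, dict[str, str]]:
    """Generate a promoter capture panel and a matching reference.

    Each gene gets one contig carrying a promoter-like primary target region
    split into 1+ contiguous capture regions; CpG dinucleotides are planted at
    roughly ``cpg_spacing`` bp intervals across the primary span and its
    flanks. A ``lambda`` contig (fully unmethylated in simulations, natural
    CpG content) is appended as the bisulfite-conversion control.

    Returns
    -------
    (panel, reference)
        ``reference`` maps contig name -> sequence string.
    """
    if n_genes < 1:
        raise PanelError("n_genes must be >= 1")
    lo_n, hi_n = regions_per_gene
    lo_l, hi_l = region_length
    if lo_n < 1 or hi_n < lo_n:
        raise PanelError("regions_per_gene must be a nondecreasing range with min >= 1")
    if lo_l < 100 or hi_l < lo_l:
        raise PanelError("region_length must be a nondecreasing range with min >= 100 bp")

    rng = np.random.default_rng(seed)
    regions: list[Region] = []
    reference: dict[str, str] = {}
    margin = flank + 60  # room before/after the primary span

    for g in range(n_genes):
        gene = f"TSG{g + 1:03d}"
        chrom = f"chr_{gene}"
        k = int(rng.integers(lo_n, hi_n + 1))
        lengths = rng.integers(lo_l, hi_l + 1, size=k)
        span = int(lengths.sum())
        contig_len = span + 2 * margin
        seq = _random_sequence_no_cpg(rng, contig_len)
        p_start = margin
        _plant_cpgs(seq, p_start - flank, p_start + span + flank, cpg_spacing, rng)
        pos = p_start
        for j, length in enumerate(lengths):
            regions.append(
                Region(
                    region_id=f"{gene}_r{j + 1}",
                    gene=gene,
                    chrom=chrom,
                    start=pos,
                    end=pos + int(length),
                    role="capture",
                )
            )
            pos += int(length)
        regions.append(
            Region(
                region_id=f"{gene}_target",
                gene=gene,
                chrom=chrom,
                start=p_start,
                end=p_start + span,
                role="primary",
            )
        )
        reference[chrom] = seq.tobytes().decode()

    # conversion-control contig: unconstrained base composition
    lam = _BASES[rng.integers(0, 4, size=3000)]
    reference["lambda"] = lam.tobytes().decode()
    return CapturePanel(regions=regions, lambda_contig="lambda"), reference


def write_fasta(reference: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a reference FASTA into memory (panel contigs are small)."""
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, rebuild=True) as fasta:
        return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def cpg_positions(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Positions of CpG cytosines on both strands of a contig.

    Returns ``(plus, minus)``: ``plus`` holds 0-based positions of the C of
    each CG dinucleotide (top strand), ``minus`` the positions of the G
    (the bottom-strand cytosine of the same dinucleotide).
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    c = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
    return c, c + 1
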