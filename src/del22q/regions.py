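"""Genomic coordinate model for the 22q11.2 low-copy-repeat region.

The recurrent 22q11.2 deletions are mediated by non-allelic homologous
recombination between four low-copy-repeat blocks, LCR22A-D.  The common
deletion runs from LCR22A to LCR22D (~2.5 Mb); nested deletions span
subsets (A-B, B-D, C-D, or intervals inside A-B).  Clinical FISH probes
(N25, TUPLE1/HIRA, TBX1) all hybridize between LCR22A and LCR22B, so
deletions that do not reach that interval escape FISH.

This module defines the interval arithmetic, the fixed-width bin grid the
read-depth caller operates on, the default region model, and BED I/O.
Default coordinates are representative GRCh38 positions; they are
overridable via BED files and nothing downstream depends on the exact
values, only on the relative LCR/probe architecture.

All coordinates are 0-based half-open, matching the BED convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "BinGrid",
    "RegionModel",
    "overlap_bp",
    "make_bins",
    "read_bed",
    "write_bed",
    "load_region_model",
    "canonical_deletions",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_BUILD",
]

DEFAULT_BIN_WIDTH = 50_000
DEFAULT_BUILD = "GRCh38"

_CHROM = "chr22"

# Representative GRCh38 coordinates for the 22q11.2 analysis window.
# Window is 7 Mb = 140 bins of 50 kb, with ample flanking sequence on
# both sides of the LCR22 cluster: sample depth is normalized within the
# window (standing in for the genome-wide normalization of a production
# assay), so enough unaffected bins must remain to anchor the scale even
# under the largest deletions.  The canonical A-D deletion (LCR22A start
# to LCR22D start) is 2.55 Mb.
_DEFAULT_REGION = (17_400_000, 24_400_000)
_DEFAULT_LCR_BLOCKS = {
    "A": (18_950_000, 19_050_000),
    "B": (20_350_000, 20_450_000),
    "C": (20_950_000, 21_050_000),
    "D": (21_500_000, 21_600_000),
}
# Clinical FISH probe targets; all lie strictly between LCR22A and LCR22B.
_DEFAULT_PROBES = {
    "N25": (19_100_000, 19_200_000),
    "TUPLE1_HIRA": (19_330_000, 19_430_000),
    "TBX1": (19_750_000, 19_800_000),
}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two half-open intervals.

    Symmetric in its arguments.  Intervals on different chromosomes do
    not overlap; this returns 0 with a warning rather than raising, so
    probe/deletion comparisons across models degrade gracefully.
    """
    if a.chrom != b.chrom:
        warnings.warn(
            f"overlap_bp called on different chromosomes ({a.chrom} vs {b.chrom}); "
            "returning 0",
            stacklevel=2,
        )
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class BinGrid:
    """A contiguous, sorted, non-overlapping tiling of a region by fixed-width bins."""

    bins: tuple[GenomicInterval, ...]
    bin_width: int

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("empty bin grid")
        prev = None
        for b in self.bins:
            if b.length != self.bin_width:
                raise ValueError(f"bin {b} does not have width {self.bin_width}")
            if prev is not None and (b.chrom != prev.chrom or b.start != prev.end):
                raise ValueError(f"bins not contiguous at {prev} / {b}")
            prev = b

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chrom(self) -> str:
        return self.bins[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.bins[0].start, self.bins[-1].end)

    @property
    def starts(self) -> np.ndarray:
        return np.array([b.start for b in self.bins], dtype=np.int64)

    def overlap_fractions(self, interval: GenomicInterval) -> np.ndarray:
        """Fraction of each bin covered by ``interval`` (0..1 per bin)."""
        if interval.chrom != self.chrom:
            return np.zeros(self.n_bins)
        starts = self.starts
        ends = starts + self.bin_width
        ov = np.minimum(ends, interval.end) - np.maximum(starts, interval.start)
        return np.clip(ov, 0, None) / self.bin_width

    def interval_for(self, i: int, j: int) -> GenomicInterval:
        """Genomic interval spanned by bins ``i:j`` (half-open bin slice)."""
        if not (0 <= i < j <= self.n_bins):
            raise IndexError(f"bin slice {i}:{j} outside grid of {self.n_bins} bins")
        return GenomicInterval(self.chrom, self.bins[i].start, self.bins[j - 1].end)


def make_bins(region: GenomicInterval, width: int) -> BinGrid:
    """Tile ``region`` with fixed-width bins.

    If the region length is not a multiple of ``width`` the end is padded
    upward to the next bin boundary so that every base of the region is
    covered exactly once; the padding amount is recoverable from
    ``grid.span.end - region.end``.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    n = -(-region.length // width)  # ceil division
    bins = tuple(
        GenomicInterval(region.chrom, region.start + k * width, region.start + (k + 1) * width)
        for k in range(n)
    )
    return BinGrid(bins=bins, bin_width=width)


@dataclass
class RegionModel:
    """The 22q11.2 analysis window, LCR22 A-D blocks, FISH probe targets and bin grid.

    Invariants enforced at construction: LCR blocks ordered A<B<C<D and
    non-overlapping; every probe strictly between LCR22A and LCR22B; all
    features inside the region; the grid tiles the (padded) region.
    """

    region: GenomicInterval
    lcr_blocks: dict[str, GenomicInterval]
    probes: dict[str, GenomicInterval]
    bin_width: int = DEFAULT_BIN_WIDTH
    build: str = DEFAULT_BUILD
    grid: BinGrid = field(init=False, repr=False)
    padding_bp: int = field(init=False)

    def __post_init__(self) -> None:
        missing = [k for k in "ABCD" if k not in self.lcr_blocks]
        if missing:
            raise ValueError(f"LCR blocks missing: {missing}")
        blocks = [self.lcr_blocks[k] for k in "ABCD"]
        for blk in blocks:
            if not self.region.contains(blk):
                raise ValueError(f"LCR block {blk} outside region {self.region}")
        for prev, cur in zip(blocks, blocks[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"LCR blocks out of order or overlapping: {prev} then {cur}"
                )
        a, b = self.lcr_blocks["A"], self.lcr_blocks["B"]
        for name, probe in self.probes.items():
            if not self.region.contains(probe):
                raise ValueError(f"probe {name} {probe} outside region {self.region}")
            if not (a.end <= probe.start and probe.end <= b.start):
                raise ValueError(
                    f"probe {name} {probe} must lie strictly between LCR22A and LCR22B"
                )
        self.grid = make_bins(self.region, self.bin_width)
        self.padding_bp = self.grid.span.end - self.region.end

    @property
    def n_bins(self) -> int:
        return self.grid.n_bins


def canonical_deletions(model: RegionModel) -> dict[str, GenomicInterval]:
    """Menu of recurrent deletion intervals for a region model.

    LCR-to-LCR deletions run from the start of the proximal block to the
    start of the distal block (the recombined repeat collapses onto one
    copy).  ``A-B_small`` is a representative nested interval inside the
    A-B segment, placed a few bins distal of LCR22A so that it overlaps
    the TUPLE1/HIRA and TBX1 probe targets but not N25.
    """
    blk = model.lcr_blocks
    c = model.region.chrom
    w = model.bin_width
    small_start = blk["A"].end + 6 * w
    dels = {
        "A-D": GenomicInterval(c, blk["A"].start, blk["D"].start),
        "A-B": GenomicInterval(c, blk["A"].start, blk["B"].start),
        "B-D": GenomicInterval(c, blk["B"].start, blk["D"].start),
        "C-D": GenomicInterval(c, blk["C"].start, blk["D"].start),
        "A-B_small": GenomicInterval(c, small_start, small_start + 13 * w),
    }
    return dels


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open, tab-separated, 3-4 columns)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str | None, GenomicInterval]]:
    """Read a 3-4 column BED file into (name, interval) pairs.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    out: list[tuple[str | None, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated BED columns"
                )
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates {s!r}/{e!r}"
                ) from exc
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else None
            out.append((name, iv))
    return out


def write_bed(path: str | Path, items: Iterable[tuple[str | None, GenomicInterval]]) -> None:
    with open(path, "w") as fh:
        for name, iv in items:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if name is not None:
                cols.append(name)
            fh.write("\t".join(cols) + "\n")


def _named_map(pairs: Sequence[tuple[str | None, GenomicInterval]], what: str) -> dict[str, GenomicInterval]:
    out = {}
    for name, iv in pairs:
        if name is None:
            raise ValueError(f"{what} BED requires a name column (4th field)")
        out[name] = iv
    return out


def load_region_model(
    region_bed: str | Path | None = None,
    lcr_bed: str | Path | None = None,
    probe_bed: str | Path | None = None,
    bin_width: int = DEFAULT_BIN_WIDTH,
    build: str = DEFAULT_BUILD,
) -> RegionModel:
    """Build a :class:`RegionModel` from BED files, or the built-in defaults.

    ``lcr_bed`` must name its records A, B, C, D; ``probe_bed`` records
    are named probe targets.  Any argument left ``None`` falls back to
    the default GRCh38-representative coordinates.
    """
    if region_bed is not None:
        recs = read_bed(region_bed)
        if len(recs) != 1:
            raise ValueError(f"region BED {region_bed} must contain exactly one record")
        region = recs[0][1]
    else:
        region = GenomicInterval(_CHROM, *_DEFAULT_REGION)

    if lcr_bed is not None:
        lcr = _named_map(read_bed(lcr_bed), "LCR")
    else:
        lcr = {k: GenomicInterval(_CHROM, s, e) for k, (s, e) in _DEFAULT_LCR_BLOCKS.items()}

    if probe_bed is not None:
        probes = _named_map(read_bed(probe_bed), "probe")
    else:
        probes = {k: GenomicInterval(_CHROM, s, e) for k, (s, e) in _DEFAULT_PROBES.items()}

    return RegionModel(region=region, lcr_blocks=lcr, probes=probes,
                       bin_width=bin_width, build=build)
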