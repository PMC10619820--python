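"""Genome-wide bin scaffold: construction, read counting, blacklist exclusion, track I/O.

All coordinates are 0-based, half-open (BED convention), everywhere. Bins are
fixed-width, non-overlapping windows per chromosome; the trailing partial bin of
each chromosome is emitted but flagged ``excluded`` (reason ``partial_bin``) so
bin indices stay reconstructible from coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBins",
    "BinTrack",
    "make_genome_bins",
    "count_reads",
    "apply_blacklist",
    "read_bin_values",
    "write_bin_track",
    "read_chrom_sizes",
]

#: exclusion reason codes
REASON_BLACKLIST = "blacklist"
REASON_LOW_MAPPABILITY = "low_mappability"
REASON_PARTIAL_BIN = "partial_bin"

_TRACK_KINDS = ("raw_counts", "rescaled_counts", "pbs", "diff_pbs")


@dataclass
class GenomeBins:
    """Ordered set of fixed-width genomic windows.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``chrom`` (str), ``start``, ``end`` (int, 0-based half-open),
        ``mappability`` (float in [0,1] or NaN), ``copy_ratio`` (float > 0),
        ``excluded_reason`` (str or None). Sorted by (chrom, start).
    bin_size : int
        Nominal bin width in base pairs.
    """

    table: pd.DataFrame
    bin_size: int

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def excluded(self) -> np.ndarray:
        return self.table["excluded_reason"].notna().to_numpy()

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of bins that participate in downstream computation."""
        return ~self.excluded

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def copy(self) -> "GenomeBins":
        return GenomeBins(self.table.copy(), self.bin_size)

    def bin_index(self, chrom: str, pos: int) -> Optional[int]:
        """Index of the bin containing genomic position ``pos`` on ``chrom``."""
        offsets = self._chrom_offsets()
        if chrom not in offsets:
            return None
        off, n = offsets[chrom]
        i = pos // self.bin_size
        if i >= n:
            return None
        return off + i

    def _chrom_offsets(self) -> dict[str, tuple[int, int]]:
        if not hasattr(self, "_offsets"):
            offsets: dict[str, tuple[int, int]] = {}
            for chrom, grp in self.table.groupby("chrom", sort=False):
                offsets[str(chrom)] = (int(grp.index[0]), len(grp))
            self._offsets = offsets
        return self._offsets


@dataclass
class BinTrack:
    """One floating-point value per bin of an associated :class:`GenomeBins`.

    Missing values are NaN. ``kind`` is one of ``raw_counts``,
    ``rescaled_counts``, ``pbs``, ``diff_pbs``.
    """

    values: np.ndarray
    bins: GenomeBins
    kind: str = "raw_counts"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bins):
            raise ValueError(
                f"track length {len(self.values)} != number of bins {len(self.bins)}"
            )
        if self.kind not in _TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        self.validate()

    def validate(self) -> None:
        v = self.values[~np.isnan(self.values)]
        if self.kind == "pbs":
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("pbs values must lie in [0, 1]")
        elif self.kind == "diff_pbs":
            if v.size and (v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("diff_pbs values must lie in [-1, 1]")
        else:
            if v.size and v.min() < 0:
                raise ValueError(f"{self.kind} values must be non-negative")

    def with_values(self, values: np.ndarray, kind: Optional[str] = None) -> "BinTrack":
        return BinTrack(values, self.bins, kind or self.kind, dict(self.metadata))

    def usable_values(self) -> np.ndarray:
        """Values on usable (non-excluded) bins, NaNs dropped."""
        v = self.values[self.bins.usable]
        return v[~np.isnan(v)]


# ---------------------------------------------------------------------------
# scaffold construction
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: Union[str, Path]) -> dict[str, int]:
    """Read a 2-column chrom.sizes TSV into an ordered mapping."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def make_genome_bins(
    chrom_sizes: Union[Mapping[str, int], str, Path], bin_size: int = 5000
) -> GenomeBins:
    """Divide each chromosome into non-overlapping fixed-width bins.

    Per chromosome, ``floor(length / bin_size)`` full bins start at 0; a
    trailing partial bin, when the length is not a multiple of ``bin_size``,
    is emitted but flagged excluded (reason ``partial_bin``).
    """
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    if bin_size < 1:
        raise ValueError("bin_size must be a positive integer")
    if bin_size < 3000:
        warnings.warn(
            f"bin_size {bin_size} < 3000 bp: counts per bin become discrete and the "
            "continuous gamma background may need adaptation",
            UserWarning,
            stacklevel=2,
        )
    if not chrom_sizes:
        raise ValueError("empty chrom_sizes")
    rows = []
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        n_full = length // bin_size
        for i in range(n_full):
            rows.append((chrom, i * bin_size, (i + 1) * bin_size, None))
        if n_full * bin_size < length:
            rows.append((chrom, n_full * bin_size, length, REASON_PARTIAL_BIN))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "excluded_reason"])
    table["mappability"] = np.nan
    table["copy_ratio"] = 1.0
    table = table[["chrom", "start", "end", "mappability", "copy_ratio", "excluded_reason"]]
    return GenomeBins(table, bin_size)


# ---------------------------------------------------------------------------
# chromosome-name reconciliation
# ---------------------------------------------------------------------------

def _reconcile_chrom(name: str, known: set[str], warned: set) -> Optional[str]:
    """Map an external chromosome name onto the scaffold's naming.

    Strips or adds a ``chr`` prefix; warns once per run on the first rename.
    Returns None when the name cannot be reconciled.
    """
    if name in known:
        return name
    alt = name[3:] if name.startswith("chr") else "chr" + name
    if alt in known:
        if "renamed" not in warned:
            warned.add("renamed")
            warnings.warn(
                f"reconciling chromosome names by chr-prefix (e.g. {name!r} -> {alt!r})",
                UserWarning,
                stacklevel=3,
            )
        return alt
    return None


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def count_reads(
    alignments: Union[str, Path, Iterable],
    bins: GenomeBins,
    mapq_min: int = 1,
) -> BinTrack:
    """Count aligned reads per bin with fractional-overlap weighting.

    Each kept read contributes ``overlap_bp / read_length`` to every bin it
    overlaps, so a boundary read splits its unit weight across bins instead of
    double-counting or vanishing. Reads that are unmapped, secondary,
    supplementary, QC-fail, duplicate-flagged, or have MAPQ < ``mapq_min``
    contribute nothing.

    Parameters
    ----------
    alignments : path or iterable
        Path to a coordinate-sorted SAM/BAM file (read with pysam), or an
        iterable of ``(chrom, start, end, mapq)`` tuples (already filtered for
        flags) for testing.
    """
    values = np.zeros(len(bins), dtype=float)
    offsets = bins._chrom_offsets()
    known = set(offsets)
    warned: set = set()
    bs = bins.bin_size
    starts = bins.table["start"].to_numpy()
    ends = bins.table["end"].to_numpy()
    n_skipped_chrom = 0
    last_pos: dict[str, int] = {}

    def add(chrom: str, start: int, end: int, read_length: int) -> None:
        nonlocal n_skipped_chrom
        c = _reconcile_chrom(chrom, known, warned)
        if c is None:
            n_skipped_chrom += 1
            return
        prev = last_pos.get(c)
        if prev is not None and start < prev:
            raise ValueError(
                f"input alignments are not coordinate-sorted at {chrom}:{start}"
            )
        last_pos[c] = start
        off, n = offsets[c]
        i0 = max(start // bs, 0)
        i1 = min((end - 1) // bs, n - 1)
        if read_length <= 0:
            return
        for i in range(i0, i1 + 1):
            j = off + i
            ov = min(end, ends[j]) - max(start, starts[j])
            if ov > 0:
                values[j] += ov / read_length

    if isinstance(alignments, (str, Path)):
        import pysam

        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            for read in fh:
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.is_qcfail
                ):
                    continue
                if read.mapping_quality < mapq_min:
                    continue
                rl = read.query_length or read.infer_read_length()
                if not rl:
                    rl = read.reference_end - read.reference_start
                add(read.reference_name, read.reference_start, read.reference_end, rl)
    else:
        for chrom, start, end, mapq in alignments:
            if mapq < mapq_min:
                continue
            add(chrom, int(start), int(end), int(end) - int(start))

    if n_skipped_chrom:
        warnings.warn(
            f"skipped {n_skipped_chrom} reads on chromosomes absent from the bin scaffold",
            UserWarning,
            stacklevel=2,
        )
    track = BinTrack(values, bins, "raw_counts")
    track.metadata["n_skipped_unknown_chrom"] = n_skipped_chrom
    return track


# ---------------------------------------------------------------------------
# blacklist
# ---------------------------------------------------------------------------

def _read_bed3(path: Union[str, Path]) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line (need >= 3 columns)")
            try:
                out.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {e}") from None
    return out


def apply_blacklist(
    bins: GenomeBins,
    blacklist: Union[str, Path, Iterable[tuple[str, int, int]]],
) -> GenomeBins:
    """Flag every bin overlapping a blacklist interval by >= 1 bp as excluded.

    Idempotent and order-independent; previously set exclusion reasons are
    preserved (a bin keeps exactly one reason).
    """
    if isinstance(blacklist, (str, Path)):
        intervals = _read_bed3(blacklist)
    else:
        intervals = [(c, int(s), int(e)) for c, s, e in blacklist]
    out = bins.copy()
    offsets = out._chrom_offsets()
    known = set(offsets)
    warned: set = set()
    reasons = out.table["excluded_reason"].to_numpy(dtype=object)
    bs = out.bin_size
    for chrom, start, end in intervals:
        if end <= start:
            continue
        c = _reconcile_chrom(chrom, known, warned)
        if c is None:
            continue
        off, n = offsets[c]
        i0 = max(start // bs, 0)
        i1 = min((end - 1) // bs, n - 1)
        for i in range(i0, i1 + 1):
            if reasons[off + i] is None:
                reasons[off + i] = REASON_BLACKLIST
    out.table["excluded_reason"] = reasons
    return out


# ---------------------------------------------------------------------------
# track I/O (bedGraph, bigWig)
# ---------------------------------------------------------------------------

def read_bin_values(
    path: Union[str, Path],
    bins: GenomeBins,
    kind: str = "raw_counts",
    read_length: Optional[int] = None,
) -> BinTrack:
    """Import per-bin values from a bedGraph or bigWig file.

    When intervals coincide with bins the value is taken directly; otherwise
    the bin value is the coverage-weighted mean over the bin, multiplied by
    ``bin_size / read_length`` when ``read_length`` is given (converting mean
    per-base coverage into an expected read count). Chromosomes with no data
    yield missing values.
    """
    wsum = np.zeros(len(bins))
    cov = np.zeros(len(bins))
    exact = np.full(len(bins), np.nan)
    offsets = bins._chrom_offsets()
    known = set(offsets)
    warned: set = set()
    bs = bins.bin_size
    starts = bins.table["start"].to_numpy()
    ends = bins.table["end"].to_numpy()

    def feed(chrom: str, start: int, end: int, value: float) -> None:
        c = _reconcile_chrom(chrom, known, warned)
        if c is None:
            return
        off, n = offsets[c]
        i0 = max(start // bs, 0)
        i1 = min((end - 1) // bs, n - 1)
        for i in range(i0, i1 + 1):
            j = off + i
            ov = min(end, ends[j]) - max(start, starts[j])
            if ov <= 0:
                continue
            if start == starts[j] and end == ends[j]:
                exact[j] = value
            wsum[j] += ov * value
            cov[j] += ov

    p = str(path)
    if p.endswith((".bw", ".bigwig", ".bigWig")):
        import pyBigWig

        with pyBigWig.open(p) as bw:
            for chrom in bw.chroms():
                for start, end, value in bw.intervals(chrom) or []:
                    feed(chrom, start, end, value)
    else:
        with open(p) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 4:
                    raise ValueError(f"{p}:{lineno}: malformed bedGraph line")
                feed(parts[0], int(parts[1]), int(parts[2]), float(parts[3]))

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cov > 0, wsum / np.maximum(cov, 1), np.nan)
    values = np.where(~np.isnan(exact), exact, mean)
    if read_length is not None:
        inexact = np.isnan(exact) & ~np.isnan(values)
        values = np.where(inexact, values * bs / read_length, values)
    return BinTrack(values, bins, kind)


def write_bin_track(
    track: BinTrack,
    path: Union[str, Path],
    format: str = "bedGraph",
    threshold: float = 0.9,
    header: Optional[str] = None,
) -> None:
    """Write a track as a sorted 4-column bedGraph, or as a thresholded BED.

    ``bed_threshold`` emits only bins with ``value > threshold`` (strict) as
    BED3 intervals — e.g. PBS > 0.9 annotations for partitioned-heritability
    input. Excluded bins and missing values are omitted in both formats.
    """
    if format not in ("bedGraph", "bed_threshold"):
        raise ValueError(f"unknown format {format!r}")
    tab = track.bins.table
    keep = track.bins.usable & ~np.isnan(track.values)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        if format == "bedGraph":
            fh.write(f"# binpbs bedGraph kind={track.kind}\n")
            for j in np.flatnonzero(keep):
                fh.write(
                    f"{tab.at[j, 'chrom']}\t{tab.at[j, 'start']}\t{tab.at[j, 'end']}"
                    f"\t{track.values[j]:.10g}\n"
                )
        else:
            fh.write(f"# binpbs bed_threshold kind={track.kind} threshold={threshold:g}\n")
            for j in np.flatnonzero(keep & (track.values > threshold)):
                fh.write(f"{tab.at[j, 'chrom']}\t{tab.at[j, 'start']}\t{tab.at[j, 'end']}\n")
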