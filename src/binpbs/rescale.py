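"""Mappability and copy-number correction of binned read counts.

Two local corrections are applied to raw per-bin counts before the global
background fit:

* mappability — each bin's count is divided by the fraction of its positions
  where a read of the sequencing read length aligns uniquely; bins scoring
  below 0.5 are excluded outright (their residual counts are unreliable);
* copy number — on genomes with CNVs, counts are divided by a per-bin
  fold-change-from-diploid ratio estimated from an input-control track.

CNV *detection* splits the usable bins, in genome order, into contiguous
equal-count subsets that deliberately do not align with chromosomes, and runs
the Hartigan & Hartigan dip test for multimodality on the count distribution
of each subset (Bonferroni-adjusted). Ploidy *estimation* segments the input
counts, fits a gaussian mixture to segment medians, calls the most populous
component diploid, and emits each bin's ratio to the diploid mean.

The dip statistic is implemented here (sorted-sample greatest-convex-minorant
/ least-concave-majorant algorithm); p-values are calibrated by simulation
against uniform samples of the same size, the standard conservative null for
unimodality testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .genome_bins import (
    REASON_LOW_MAPPABILITY,
    BinTrack,
    GenomeBins,
    _read_bed3,
    _reconcile_chrom,
)

__all__ = [
    "CnvResult",
    "average_mappability",
    "mappability_rescale",
    "dip_statistic",
    "dip_test",
    "detect_cnv",
    "estimate_ploidy",
    "cnv_rescale",
    "write_ploidy_ratios",
]

#: read lengths with published genome-wide mappability tracks
SUPPORTED_READ_LENGTHS = (25, 36, 50, 75, 100)


# ---------------------------------------------------------------------------
# mappability
# ---------------------------------------------------------------------------

def average_mappability(
    bins: GenomeBins,
    mappability: Union[str, Path, list],
    read_length: int = 100,
    paired_end: bool = False,
) -> GenomeBins:
    """Fill each bin's mappability with the mean track value over its span.

    The track gives, per base or per interval, the fraction of reads of the
    given length that align uniquely starting there. ``read_length`` must be
    one with a published track (25/36/50/75/100 bp); paired-end data use the
    100 bp track because paired reads have no single well-defined length.
    Accepts a 4-column BED/bedGraph path or a bigWig, or a list of
    ``(chrom, start, end, score)`` tuples. Bins with no covering data get a
    missing score.
    """
    if paired_end:
        read_length = 100
    if read_length not in SUPPORTED_READ_LENGTHS:
        raise ValueError(
            f"read_length {read_length} has no published mappability track; "
            f"choose one of {SUPPORTED_READ_LENGTHS}"
        )
    if isinstance(mappability, (str, Path)):
        p = str(mappability)
        if p.endswith((".bw", ".bigwig", ".bigWig")):
            import pyBigWig

            intervals = []
            with pyBigWig.open(p) as bw:
                for chrom in bw.chroms():
                    for s, e, v in bw.intervals(chrom) or []:
                        intervals.append((chrom, s, e, v))
        else:
            intervals = []
            with open(p) as fh:
                for lineno, line in enumerate(fh, 1):
                    line = line.rstrip("\n")
                    if not line or line.startswith(("#", "track", "browser")):
                        continue
                    parts = line.split("\t") if "\t" in line else line.split()
                    if len(parts) < 4:
                        raise ValueError(f"{p}:{lineno}: need chrom start end score")
                    intervals.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    else:
        intervals = list(mappability)

    out = bins.copy()
    offsets = out._chrom_offsets()
    known = set(offsets)
    warned: set = set()
    bs = out.bin_size
    starts = out.table["start"].to_numpy()
    ends = out.table["end"].to_numpy()
    wsum = np.zeros(len(out))
    cov = np.zeros(len(out))
    for chrom, s, e, v in intervals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"mappability score {v} outside [0, 1]")
        c = _reconcile_chrom(chrom, known, warned)
        if c is None:
            continue
        off, n = offsets[c]
        i0 = max(s // bs, 0)
        i1 = min((e - 1) // bs, n - 1)
        for i in range(i0, i1 + 1):
            j = off + i
            ov = min(e, ends[j]) - max(s, starts[j])
            if ov > 0:
                wsum[j] += ov * v
                cov[j] += ov
    with np.errstate(invalid="ignore"):
        out.table["mappability"] = np.where(cov > 0, wsum / np.maximum(cov, 1), np.nan)
    return out


def mappability_rescale(
    counts: BinTrack, bins: Optional[GenomeBins] = None, min_mappability: float = 0.5
) -> BinTrack:
    """Divide counts by per-bin mappability; exclude bins scoring below 0.5.

    Returns a ``rescaled_counts`` track on a copy of the scaffold in which
    newly excluded bins carry reason ``low_mappability``. A score of exactly
    1 leaves the count unchanged; rescaling never decreases a count.
    """
    if not 0.0 < min_mappability <= 1.0:
        raise ValueError("min_mappability must be in (0, 1]")
    bins = bins if bins is not None else counts.bins
    out = bins.copy()
    mapp = out.table["mappability"].to_numpy(dtype=float)
    usable = out.usable
    if np.isnan(mapp[usable]).any():
        raise ValueError("mappability missing on usable bins; run average_mappability first")
    reasons = out.table["excluded_reason"].to_numpy(dtype=object)
    low = usable & (mapp < min_mappability)
    reasons[low] = REASON_LOW_MAPPABILITY
    out.table["excluded_reason"] = reasons
    values = counts.values.copy()
    values[low] = np.nan
    ok = ~np.isnan(values) & ~low & ~np.isnan(mapp)
    values[ok] = values[ok] / mapp[ok]
    track = BinTrack(values, out, "rescaled_counts", dict(counts.metadata))
    return track


# ---------------------------------------------------------------------------
# Hartigan & Hartigan dip statistic
# ---------------------------------------------------------------------------

def _dip_sorted(x: np.ndarray) -> float:
    """Dip statistic of a sorted sample.

    Iteratively fits the greatest convex minorant and least concave majorant
    of the empirical CDF on a shrinking candidate modal interval, tracking the
    largest deviation that any unimodal CDF must incur; the dip is half that
    deviation. Distances are accumulated in count units and divided by 2n at
    the end. Lower bound 1/(2n) for samples with unequal extremes.
    """
    n = x.shape[0]
    if n < 2 or x[n - 1] == x[0]:
        return 0.0
    low = 0
    high = n - 1
    dip = 1.0  # in count units; final dip >= 1/(2n)

    # mn[j]: previous vertex of the greatest convex minorant through (x_i, i)
    mn = np.zeros(n, dtype=np.int64)
    mj = np.zeros(n, dtype=np.int64)
    mn[0] = 0
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    gcm = np.zeros(n, dtype=np.int64)
    lcm = np.zeros(n, dtype=np.int64)
    while True:
        # change points of the GCM from high down to low, and LCM from low up
        gcm[0] = high
        i = 0
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        l_gcm = i + 1
        ig = l_gcm - 1
        ix = l_gcm - 2

        lcm[0] = low
        i = 0
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        l_lcm = i + 1
        ih = l_lcm - 1
        iv = 1

        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # maximum deviation of the LCM point below the GCM segment
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # maximum deviation of the GCM point above the LCM segment
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (x[lcmiv] - x[lcmiv1]) - (
                        gcmix - lcmiv1 - 1
                    )
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # largest ECDF deviation from the GCM within [low .. gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb = gcm[j + 1]
            je = gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > max_t:
                        max_t = t
            if max_t > dip_l:
                dip_l = max_t

        # largest ECDF deviation from the LCM within [lcm[ih] .. high]
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb = lcm[j]
            je = lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if max_t > dip_u:
                dip_u = max_t

        dipnew = dip_u if dip_u > dip_l else dip_l
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


try:  # pure-python fallback keeps the dependency optional
    from numba import njit as _njit

    _dip_sorted_fast = _njit(cache=False)(_dip_sorted)
except Exception:  # pragma: no cover - numba present in the supported stack
    _dip_sorted_fast = _dip_sorted


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan & Hartigan dip statistic of a 1-d sample (unsorted OK)."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    return float(_dip_sorted_fast(x))


def _null_dips(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Dip statistics of ``n_boot`` uniform(0,1) samples of size ``n``."""
    u = rng.random((n_boot, n))
    u.sort(axis=1)
    return np.array([_dip_sorted_fast(u[b]) for b in range(n_boot)])


def dip_test(
    values: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    null_dips: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against a uniform null.

    The p-value is the fraction of ``n_boot`` uniform samples of the same size
    whose dip is at least the observed dip (add-one correction). A precomputed
    ``null_dips`` array for this sample size may be supplied to amortize the
    simulation across repeated tests.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 4:
        raise ValueError("dip test requires at least 4 observations")
    if np.all(values == values[0]):
        warnings.warn("degenerate constant sample: dip undefined, returning p=1", UserWarning)
        return 0.0, 1.0
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    d = dip_statistic(values)
    if null_dips is None:
        null_dips = _null_dips(values.size, n_boot, np.random.default_rng(seed))
    p = (1.0 + np.count_nonzero(null_dips >= d)) / (len(null_dips) + 1.0)
    return d, float(p)


# ---------------------------------------------------------------------------
# CNV detection and ploidy estimation
# ---------------------------------------------------------------------------

@dataclass
class CnvResult:
    """Outcome of CNV detection / ploidy estimation on an input control.

    ``ploidy_ratio`` holds each bin's fold-change from diploid (1.0 when no
    CNV was detected).
    """

    subset_pvalues: np.ndarray
    detected: bool
    ploidy_ratio: Optional[BinTrack] = None
    alpha: float = 0.05
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subset_pvalues = np.asarray(self.subset_pvalues, dtype=float)


def detect_cnv(
    input_counts: BinTrack,
    n_subsets: int = 20,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> CnvResult:
    """Dip-test genome subsets of an input control for CNV multimodality.

    Usable bins, in genome order, are split into ``n_subsets`` contiguous
    subsets of (near-)equal bin count spanning chromosome boundaries; each
    subset's count distribution is dip-tested and a CNV is called when any
    Bonferroni-adjusted p-value falls below ``alpha``. Run this on an input
    control, not an epitope track, so enrichment is not mistaken for a CNV.
    """
    mask = input_counts.bins.usable & ~np.isnan(input_counts.values)
    vals = input_counts.values[mask]
    if vals.size < 4 * n_subsets:
        raise ValueError(
            f"need at least {4 * n_subsets} usable bins for {n_subsets} subsets, have {vals.size}"
        )
    if np.all(vals == vals[0]):
        warnings.warn("constant counts: dip test degenerate, reporting no CNV", UserWarning)
        return CnvResult(np.ones(n_subsets), False, _unit_ratio(input_counts), alpha)
    edges = np.linspace(0, vals.size, n_subsets + 1).astype(int)
    sizes = np.diff(edges)
    rng = np.random.default_rng(seed)
    # the null depends only on the sample size; subsets differ by at most one
    # bin, so one null per distinct size is simulated and shared
    nulls = {int(n): _null_dips(int(n), n_boot, rng) for n in np.unique(sizes)}
    pvals = np.empty(n_subsets)
    for i in range(n_subsets):
        sub = vals[edges[i] : edges[i + 1]]
        _, pvals[i] = dip_test(sub, n_boot=n_boot, null_dips=nulls[int(sub.size)])
    detected = bool(pvals.min() < alpha / n_subsets)
    ratio = None if detected else _unit_ratio(input_counts)
    return CnvResult(pvals, detected, ratio, alpha)


def _unit_ratio(counts: BinTrack) -> BinTrack:
    return BinTrack(np.ones(len(counts.bins)), counts.bins, "rescaled_counts", {"kind_note": "ploidy_ratio"})


def _running_median(v: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    padded = np.pad(v, half, mode="edge")
    return np.array(
        [np.median(padded[i : i + window]) for i in range(v.size)]
    )


def estimate_ploidy(
    input_counts: BinTrack,
    max_states: int = 6,
    seed: int = 0,
    smooth_window: int = 11,
) -> CnvResult:
    """Estimate each bin's fold-change from diploid on a CNV genome.

    Counts are smoothed with a running median, split into segments at change
    points (jumps exceeding three scaled-MAD of the smoothed differences), and
    a gaussian mixture (1..``max_states`` components, BIC-selected) is fitted
    to segment medians weighted by segment length. The component holding the
    most bins is labeled diploid; every bin's ratio is its component mean over
    the diploid mean. Falls back to an all-diploid result with a warning when
    the mixture fit fails.
    """
    from sklearn.mixture import GaussianMixture

    bins = input_counts.bins
    mask = bins.usable & ~np.isnan(input_counts.values)
    idx = np.flatnonzero(mask)
    vals = input_counts.values[idx]
    sm = _running_median(vals, smooth_window)
    dif = np.abs(np.diff(sm))
    mad = np.median(dif[dif > 0]) if np.any(dif > 0) else 0.0
    jump = 3.0 * 1.4826 * mad
    cuts = np.flatnonzero(dif > jump) + 1 if jump > 0 else np.array([], dtype=int)
    bounds = np.concatenate(([0], cuts, [vals.size]))
    seg_median = []
    seg_len = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            seg_median.append(np.median(vals[a:b]))
            seg_len.append(b - a)
    seg_median = np.asarray(seg_median)
    seg_len = np.asarray(seg_len)

    ratios = np.ones(len(bins))
    try:
        # expand segment medians by length so component weights reflect bins
        X = np.repeat(seg_median, np.minimum(seg_len, 1000))[:, None]
        best, best_bic = None, np.inf
        for k in range(1, min(max_states, len(seg_median)) + 1):
            gm = GaussianMixture(n_components=k, random_state=seed, n_init=2)
            gm.fit(X)
            bic = gm.bic(X)
            # require a clear BIC improvement before adding copy states, so
            # sampling noise on a diploid genome stays a single component
            if bic < best_bic - 10.0:
                best, best_bic = gm, bic
        if best is None:
            raise RuntimeError("no mixture converged")
        seg_comp = best.predict(seg_median[:, None])
        comp_bins = np.zeros(best.n_components)
        for c, ln in zip(seg_comp, seg_len):
            comp_bins[c] += ln
        diploid = int(np.argmax(comp_bins))
        means = best.means_.ravel()
        ratios_by_comp = means / means[diploid]
        # copy states are discrete (0.5, 1.5, 2 ... of diploid); components
        # within 10% of the diploid mean are sampling noise, not CNVs
        ratios_by_comp[np.abs(ratios_by_comp - 1.0) < 0.1] = 1.0
        seg_ratio = ratios_by_comp[seg_comp]
        per_bin = np.ones(vals.size)
        for (a, b), r in zip(zip(bounds[:-1], bounds[1:]), seg_ratio):
            per_bin[a:b] = r
        ratios[idx] = per_bin
    except Exception as e:  # mixture failure: conservative fallback
        warnings.warn(f"ploidy mixture fit failed ({e}); treating genome as diploid", UserWarning)
        return CnvResult(np.array([]), False, _unit_ratio(input_counts),
                         segments=[])
    ratio_track = BinTrack(ratios, bins, "rescaled_counts", {"kind_note": "ploidy_ratio"})
    segments = [
        (int(idx[a]), int(idx[b - 1]) + 1, float(r))
        for (a, b), r in zip(zip(bounds[:-1], bounds[1:]), seg_ratio)
    ]
    return CnvResult(np.array([]), True, ratio_track, segments=segments)


def cnv_rescale(counts: BinTrack, cnv: CnvResult) -> BinTrack:
    """Divide each bin's count by its estimated ploidy ratio."""
    if cnv.ploidy_ratio is None:
        raise ValueError("CnvResult carries no ploidy ratios; run estimate_ploidy")
    r = cnv.ploidy_ratio.values
    if np.nanmin(r) <= 0:
        raise ValueError("ploidy ratios must be positive")
    if len(r) != len(counts.values):
        raise ValueError("ploidy ratio track not aligned to counts")
    values = counts.values / r
    return BinTrack(values, counts.bins, "rescaled_counts", dict(counts.metadata))


def write_ploidy_ratios(cnv: CnvResult, path: Union[str, Path]) -> None:
    """Save per-bin fold-change-from-diploid values as a 4-column bedGraph."""
    from .genome_bins import write_bin_track

    if cnv.ploidy_ratio is None:
        raise ValueError("no ploidy ratios to write")
    write_bin_track(cnv.ploidy_ratio, path, "bedGraph", header="binpbs ploidy fold-change from diploid")
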