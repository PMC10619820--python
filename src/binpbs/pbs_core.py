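"""Per-bin probability of being signal (PBS), differential PBS, and summaries.

Given the empirical count density f and the fitted background lam * f*, the
probability that a bin with count x carries signal is the fraction of the
local density not explained by the background:

    PBS(x) = (f(x) - lam f*(x)) / f(x)   where f(x) > lam f*(x),  else 0

i.e. one minus a local false-discovery rate. PBS is evaluated per histogram
cell, so identical counts always receive identical PBS, and clamped to [0,1].
Differential PBS between two samples is plain bin-wise subtraction; values
beyond +/-0.9 mark on/off transitions rather than mere magnitude changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .background_fit import EmpiricalDistribution, GammaBackgroundFit
from .genome_bins import BinTrack

__all__ = [
    "PbsCategories",
    "compute_pbs",
    "differential_pbs",
    "threshold_pbs",
    "summarize_categories",
    "pbs_matrix",
    "DEFAULT_EDGES_THREE",
    "DEFAULT_EDGES_FIVE",
]

#: low / moderate / high cut points
DEFAULT_EDGES_THREE = (0.1, 0.9)
#: five equal groups of 0.2 PBS units
DEFAULT_EDGES_FIVE = (0.2, 0.4, 0.6, 0.8)


@dataclass
class PbsCategories:
    """Bin counts and fractions per PBS category.

    Categories are half-open ``[e_i, e_{i+1})`` with the last closed at 1;
    fractions are normalized over usable, non-missing bins.
    """

    edges: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": self.labels, "count": self.counts, "fraction": self.fractions}
        )


def _smooth_density(density: np.ndarray, widths: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over equal-width cells (overflow cell untouched)."""
    if window <= 1:
        return density
    d = density.copy()
    core = np.isclose(widths, widths[0])
    k = np.ones(window)
    num = np.convolve(np.where(core, d, 0.0), k, mode="same")
    den = np.convolve(core.astype(float), k, mode="same")
    with np.errstate(invalid="ignore"):
        d[core] = (num / den)[core]
    return d


def compute_pbs(
    counts: BinTrack,
    emp: EmpiricalDistribution,
    fit: GammaBackgroundFit,
    isotonic: bool = False,
    density_smooth: int = 9,
) -> BinTrack:
    """Probability of being signal for every usable bin.

    Each bin's count is mapped to its histogram cell and receives that cell's
    PBS, so identical counts always receive identical PBS. The empirical
    density entering the ratio is lightly smoothed (centered moving average
    over ``density_smooth`` cells, ~1% of the count range by default): the
    raw per-cell ratio is noisy enough that on a pure-background genome a few
    percent of bins would spuriously score PBS > 0.1, while the posterior the
    ratio estimates varies slowly on that scale. Set ``density_smooth=1`` for
    the raw histogram ratio. Cells with zero density yield missing PBS
    (warned); counts beyond the grid fall in the overflow cell (PBS ~ 1).
    ``isotonic`` optionally enforces a non-decreasing PBS-vs-count profile
    (off by default: the raw density ratio may legitimately wiggle).
    """
    if not fit.converged:
        raise ValueError("background fit did not converge; refusing to compute PBS")
    f = _smooth_density(emp.density, emp.widths, density_smooth)
    fstar = fit.lam * fit.pdf(emp.grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_pbs = np.where(f > fstar, (f - fstar) / f, 0.0)
    cell_pbs = np.clip(cell_pbs, 0.0, 1.0)
    empty = f == 0
    cell_pbs[empty] = np.nan
    if isotonic:
        from sklearn.isotonic import IsotonicRegression

        ok = ~np.isnan(cell_pbs)
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
        cell_pbs[ok] = iso.fit_transform(emp.grid[ok], cell_pbs[ok])

    values = np.full(len(counts.values), np.nan)
    mask = counts.bins.usable & ~np.isnan(counts.values)
    cells = emp.cell_of(counts.values[mask])
    values[mask] = cell_pbs[cells]
    n_empty = int(np.isnan(values[mask]).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} bins fall in empty histogram cells; their PBS is missing",
            UserWarning,
            stacklevel=2,
        )
    n_over = int(np.count_nonzero(counts.values[mask] > emp.edges[-1]))
    track = BinTrack(values, counts.bins, "pbs", dict(counts.metadata))
    track.metadata.update({"isotonic": isotonic, "n_overflow": n_over,
                           "density_smooth": density_smooth})
    return track


def differential_pbs(a: BinTrack, b: BinTrack) -> BinTrack:
    """Bin-wise PBS difference a - b; missing in either operand stays missing."""
    if a.kind != "pbs" or b.kind != "pbs":
        raise ValueError("differential_pbs expects two pbs tracks")
    if len(a.values) != len(b.values) or a.bins.bin_size != b.bins.bin_size:
        raise ValueError("tracks are not on the same bin scaffold")
    if not (
        a.bins.table["chrom"].equals(b.bins.table["chrom"])
        and a.bins.table["start"].equals(b.bins.table["start"])
    ):
        raise ValueError("tracks are not on the same bin scaffold")
    return BinTrack(a.values - b.values, a.bins, "diff_pbs")


def threshold_pbs(
    track: BinTrack, cutoff: float = 0.9, absolute: bool = False
) -> np.ndarray:
    """Boolean mask of bins with value strictly above the cutoff.

    With ``absolute=True`` (for differential tracks), |value| > cutoff, so
    both gained and lost signal pass. Missing values never pass.
    """
    v = np.abs(track.values) if absolute else track.values
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(v), False, v > cutoff)


def summarize_categories(
    track: BinTrack, edges: Sequence[float] = DEFAULT_EDGES_FIVE
) -> PbsCategories:
    """Cross-tabulate PBS values into categories delimited by ``edges``.

    ``edges`` are interior cut points (0 and 1 are implicit); e.g.
    ``(0.1, 0.9)`` gives low/moderate/high and ``(0.2, 0.4, 0.6, 0.8)`` the
    five 0.2-wide groups. Intervals are ``[e_i, e_{i+1})`` with the last
    closed at 1.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) == 0:
        raise ValueError("edges must be a non-empty 1-d sequence")
    if edges[0] <= 0.0 or edges[-1] >= 1.0:
        edges = edges[(edges > 0) & (edges < 1)]
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    full = np.concatenate(([0.0], edges, [1.0]))
    v = track.usable_values()
    if v.size == 0:
        raise ValueError("no usable PBS values to summarize")
    idx = np.searchsorted(full, v, side="right") - 1
    idx = np.clip(idx, 0, len(full) - 2)  # value 1 joins the last category
    counts = np.bincount(idx, minlength=len(full) - 1)
    labels = [
        f"[{full[i]:g},{full[i + 1]:g}" + (")" if i < len(full) - 2 else "]")
        for i in range(len(full) - 1)
    ]
    return PbsCategories(full, counts, counts / v.size, labels)


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        raise ValueError(f"region {region!r} must look like chrom:start-end")
    lo, _, hi = span.replace(",", "").partition("-")
    return chrom, int(lo), int(hi)


def pbs_matrix(
    tracks: Sequence[BinTrack],
    region: Union[str, tuple[str, int, int]],
    labels: Optional[Sequence[str]] = None,
    path=None,
) -> pd.DataFrame:
    """Samples-by-bins PBS matrix over a genomic region.

    Columns are the bins with any overlap of ``region`` ("chrom:start-end");
    rows are samples. Written as TSV with coordinate column headers when
    ``path`` is given — a compact heatmap-ready export.
    """
    if not tracks:
        raise ValueError("need at least one track")
    bins = tracks[0].bins
    for t in tracks[1:]:
        if len(t.values) != len(bins):
            raise ValueError("tracks are not on a shared scaffold")
    chrom, lo, hi = _parse_region(region) if isinstance(region, str) else region
    tab = bins.table
    sel = (tab["chrom"] == chrom) & (tab["start"] < hi) & (tab["end"] > lo)
    idx = np.flatnonzero(sel.to_numpy())
    if idx.size == 0:
        raise ValueError(f"region {chrom}:{lo}-{hi} overlaps no bins on the scaffold")
    cols = [f"{chrom}:{tab.at[j, 'start']}-{tab.at[j, 'end']}" for j in idx]
    if labels is None:
        labels = [t.metadata.get("sample", f"sample{i}") for i, t in enumerate(tracks)]
    mat = pd.DataFrame([t.values[idx] for t in tracks], index=list(labels), columns=cols)
    if path is not None:
        mat.to_csv(path, sep="\t", index_label="sample", float_format="%.4f")
    return mat
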