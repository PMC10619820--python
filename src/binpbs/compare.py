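"""Overlap of PBS tracks with peak calls and annotation intervals.

Reproduces the bin-level agreement analyses: annotate each bin by whether it
overlaps a peak (or any BED annotation), cross-tabulate PBS categories against
one or two annotations, and test 2x2 proportion differences with Fisher's
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .genome_bins import BinTrack, GenomeBins, _read_bed3, _reconcile_chrom
from .pbs_core import summarize_categories

__all__ = ["OverlapTable", "annotate_bins", "overlap_table", "proportion_test"]


@dataclass
class OverlapTable:
    """PBS-category x annotation-state bin counts, with margins."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    def two_by_two(self, category_split: float = 0.9) -> np.ndarray:
        """Collapse rows into (> split, <= split) x first-annotation 2x2 counts."""
        t = self.table.drop(index="total", columns="total")
        hi = np.array([r >= category_split - 1e-12 for r in t.index.map(_row_lo)])
        if t.columns.nlevels > 1:
            t = t.T.groupby(level=0).sum().T
        return np.array(
            [
                [t.loc[hi].iloc[:, 1].sum(), t.loc[hi].iloc[:, 0].sum()],
                [t.loc[~hi].iloc[:, 1].sum(), t.loc[~hi].iloc[:, 0].sum()],
            ],
            dtype=int,
        )


def _row_lo(label: str) -> float:
    return float(label.strip("[]()").split(",")[0])


def annotate_bins(
    bins: GenomeBins,
    intervals: Union[str, Path, Iterable[tuple]],
    min_overlap_bp: int = 1,
) -> np.ndarray:
    """True per bin iff it overlaps any interval by >= ``min_overlap_bp``.

    Accepts BED / narrowPeak / broadPeak paths (first three columns used) or
    an iterable of (chrom, start, end[, ...]) tuples. Idempotent: merging
    adjacent or duplicate intervals does not change the annotation.
    """
    if isinstance(intervals, (str, Path)):
        rows = _read_bed3(intervals)
    else:
        rows = [(r[0], int(r[1]), int(r[2])) for r in intervals]
    out = np.zeros(len(bins), dtype=bool)
    offsets = bins._chrom_offsets()
    known = set(offsets)
    warned: set = set()
    bs = bins.bin_size
    starts = bins.table["start"].to_numpy()
    ends = bins.table["end"].to_numpy()
    for chrom, s, e in rows:
        if e <= s:
            continue
        c = _reconcile_chrom(chrom, known, warned)
        if c is None:
            continue
        off, n = offsets[c]
        i0 = max(s // bs, 0)
        i1 = min((e - 1) // bs, n - 1)
        for i in range(i0, i1 + 1):
            j = off + i
            if min(e, ends[j]) - max(s, starts[j]) >= min_overlap_bp:
                out[j] = True
    return out


def overlap_table(
    track: BinTrack,
    annotations: Union[np.ndarray, Sequence[np.ndarray]],
    edges: Sequence[float] = (0.1, 0.9),
    annotation_names: Optional[Sequence[str]] = None,
) -> OverlapTable:
    """Cross-tabulate PBS (or diff-PBS) categories against annotation states.

    One boolean vector gives a categories x {False, True} table; two vectors
    give a nested (faceted) cross-tabulation, e.g. hypomethylated-block
    membership stratified by chromatin compartment. Marginal totals are
    appended. Only usable bins with non-missing track values are counted.
    """
    arr = np.asarray(annotations)
    if arr.ndim == 1 and arr.dtype != object:
        ann_list = [arr.astype(bool)]
    else:
        ann_list = [np.asarray(a, dtype=bool) for a in annotations]
    if len(ann_list) not in (1, 2):
        raise ValueError("provide one or two annotation vectors")
    for a in ann_list:
        if len(a) != len(track.values):
            raise ValueError("annotation length does not match the track")
    if annotation_names is None:
        annotation_names = [f"ann{i + 1}" for i in range(len(ann_list))]

    mask = track.bins.usable & ~np.isnan(track.values)
    cats = summarize_categories(
        BinTrack(np.abs(track.values) if track.kind == "diff_pbs" else track.values,
                 track.bins, "pbs"),
        edges,
    )
    full = cats.edges
    v = track.values[mask]
    vv = np.abs(v) if track.kind == "diff_pbs" else v
    idx = np.clip(np.searchsorted(full, vv, side="right") - 1, 0, len(full) - 2)
    frame = pd.DataFrame({"category": [cats.labels[i] for i in idx]})
    for name, a in zip(annotation_names, ann_list):
        frame[name] = a[mask]
    tab = pd.crosstab(
        frame["category"], [frame[n] for n in annotation_names], dropna=False
    )
    tab = tab.reindex(index=cats.labels, fill_value=0)
    tab.loc["total"] = tab.sum(axis=0)
    tab["total"] = tab.sum(axis=1)
    return OverlapTable(tab)


def proportion_test(table: np.ndarray) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p-value for a 2x2 count table.

    The odds ratio is the cross-product ratio (a*d)/(b*c); inf when b*c = 0
    with a*d > 0.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t != np.round(t)) or np.any(t < 0):
            raise ValueError("cells must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("2x2 table has an all-zero margin")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)
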