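"""Interval-set overlap statistics for DMR comparisons.

Two DMR sets are compared with the pairwise rule used throughout the
analysis: an interval of set A "overlaps" set B when its intersection with
some single interval of B spans at least ``min_overlap`` base pairs
(default 50).  The chance expectation for the number of overlapping DMRs is
(A*B)/N where A and B are the set sizes and N the total number of genome
bins, and enrichment is assessed with the hypergeometric upper tail
P[X >= observed], X ~ Hypergeom(N, B, A).

N is always an explicit parameter (e.g. the number of 50-bp bins in the
analysed genome, or the number of testable bins); it is never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import hypergeom_upper_tail

DEFAULT_MIN_OVERLAP = 50


@dataclass
class IntervalSet:
    """Sorted, merged, 0-based half-open genomic intervals."""

    label: str
    intervals: pd.DataFrame = field(repr=False)  # chrom, start, end

    def __post_init__(self) -> None:
        df = self.intervals[["chrom", "start", "end"]].copy()
        if (df["end"] <= df["start"]).any():
            raise ValueError("intervals must satisfy end > start")
        df = df.sort_values(["chrom", "start"], ignore_index=True)
        merged = []
        for row in df.itertuples(index=False):
            if merged and merged[-1][0] == row.chrom \
                    and row.start <= merged[-1][2]:
                merged[-1][2] = max(merged[-1][2], row.end)
            else:
                merged.append([row.chrom, row.start, row.end])
        self.intervals = pd.DataFrame(merged, columns=["chrom", "start", "end"])

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_tuples(cls, label: str, tuples) -> "IntervalSet":
        return cls(label, pd.DataFrame(tuples,
                                       columns=["chrom", "start", "end"]))

    @classmethod
    def from_dmrs(cls, label: str, dmrs) -> "IntervalSet":
        return cls.from_tuples(label,
                               [(d.chrom, d.start, d.end) for d in dmrs])

    def total_bases(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


@dataclass
class OverlapResult:
    """A-vs-B overlap counts with chance expectation and enrichment p."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_overlap_a: int     # members of A overlapping B by >= min_overlap bp
    min_overlap: int
    n_bins: int
    expected: float      # (n_a * n_b) / n_bins
    p_value: float       # hypergeometric upper tail P[X >= n_overlap_a]


def max_pairwise_intersection(set_a: IntervalSet,
                              set_b: IntervalSet) -> np.ndarray:
    """For each interval of A, its largest intersection with any single
    interval of B (in bp)."""
    best = np.zeros(len(set_a), dtype=np.int64)
    b_by_chrom = {c: g for c, g in set_b.intervals.groupby("chrom", sort=False)}
    for i, row in enumerate(set_a.intervals.itertuples(index=False)):
        sub = b_by_chrom.get(row.chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # B sorted and merged: candidates bracket the A interval
        lo = np.searchsorted(ends, row.start, side="right")
        hi = np.searchsorted(starts, row.end, side="left")
        if hi > lo:
            inter = (np.minimum(ends[lo:hi], row.end)
                     - np.maximum(starts[lo:hi], row.start))
            best[i] = int(inter.max(initial=0))
    return best


def summed_intersection(set_a: IntervalSet, set_b: IntervalSet) -> np.ndarray:
    """For each interval of A, total intersected bp with B (B is merged,
    so the per-interval pieces are disjoint)."""
    total = np.zeros(len(set_a), dtype=np.int64)
    b_by_chrom = {c: g for c, g in set_b.intervals.groupby("chrom", sort=False)}
    for i, row in enumerate(set_a.intervals.itertuples(index=False)):
        sub = b_by_chrom.get(row.chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(ends, row.start, side="right")
        hi = np.searchsorted(starts, row.end, side="left")
        if hi > lo:
            inter = (np.minimum(ends[lo:hi], row.end)
                     - np.maximum(starts[lo:hi], row.start))
            total[i] = int(inter.sum())
    return total


def call_overlaps(set_a: IntervalSet, set_b: IntervalSet,
                  min_overlap: int = DEFAULT_MIN_OVERLAP,
                  summed: bool = False) -> int:
    """Number of A intervals overlapping B by >= min_overlap bp.

    Default uses the maximal single-B-interval intersection; ``summed``
    instead accumulates across B intervals.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    inter = (summed_intersection if summed
             else max_pairwise_intersection)(set_a, set_b)
    return int((inter >= min_overlap).sum())


def expected_overlap(n_a: int, n_b: int, n_bins: int) -> float:
    """Chance expectation (A*B)/N for the overlapped-DMR count."""
    if n_bins <= 0:
        raise ValueError("N (total number of bins) must be positive")
    return n_a * n_b / n_bins


def hypergeometric_enrichment(n_a: int, n_b: int, n_overlap: int,
                              n_bins: int) -> float:
    """Upper-tail hypergeometric p for observing >= n_overlap overlaps."""
    if n_overlap > min(n_a, n_b) or min(n_a, n_b, n_overlap) < 0:
        raise ValueError("inconsistent overlap counts")
    if max(n_a, n_b) > n_bins:
        raise ValueError("set sizes exceed the bin population")
    return hypergeom_upper_tail(n_overlap, n_bins, n_b, n_a)


def overlap_enrichment(set_a: IntervalSet, set_b: IntervalSet, n_bins: int,
                       min_overlap: int = DEFAULT_MIN_OVERLAP,
                       summed: bool = False) -> OverlapResult:
    """Count A-in-B overlaps and attach the chance expectation and p-value."""
    k = call_overlaps(set_a, set_b, min_overlap, summed)
    return OverlapResult(
        label_a=set_a.label, label_b=set_b.label,
        n_a=len(set_a), n_b=len(set_b), n_overlap_a=k,
        min_overlap=min_overlap, n_bins=n_bins,
        expected=expected_overlap(len(set_a), len(set_b), n_bins),
        p_value=hypergeometric_enrichment(len(set_a), len(set_b), k, n_bins),
    )


def overlap_percentage(n_overlap: int, n_total: int) -> float:
    """Percent of a DMR set that overlaps another, reporting-rounded.

    One decimal at >= 1%, two decimals below 1% (sub-percent values lose
    all precision at one decimal).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    pct = 100.0 * n_overlap / n_total
    return round(pct, 1) if pct >= 1.0 else round(pct, 2)


def venn3_counts(set_a: IntervalSet, set_b: IntervalSet, set_c: IntervalSet,
                 min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Three-set overlap summary in the style of a Venn count table.

    For each set: its size, how many of its members overlap each other set,
    and how many overlap both others (counts are from the row set's
    perspective; with the >= min_overlap rule they need not be symmetric).
    """
    sets = {s.label: s for s in (set_a, set_b, set_c)}
    labels = list(sets)
    rows = []
    for la in labels:
        others = [l for l in labels if l != la]
        inter = {lb: max_pairwise_intersection(sets[la], sets[lb]) >= min_overlap
                 for lb in others}
        rows.append({
            "set": la,
            "n": len(sets[la]),
            f"overlap_{others[0]}": int(inter[others[0]].sum()),
            f"overlap_{others[1]}": int(inter[others[1]].sum()),
            "overlap_both": int((inter[others[0]] & inter[others[1]]).sum()),
        })
    return pd.DataFrame(rows)


def read_bed(path, label: str | None = None) -> IntervalSet:
    """BED3+ reader (extra columns ignored)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={"chrom": str, "start": np.int64,
                                "end": np.int64})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return IntervalSet(label or str(path), df)


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.intervals.to_csv(path, sep="\t", header=False, index=False)
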