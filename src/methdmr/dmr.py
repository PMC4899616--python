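"""Bin-based differential methylation calling.

The caller compares methylation between two genotypes in fixed 50-bp bins:
coverage-passing cytosine read counts are pooled per bin (all contexts by
default), each testable bin gets a two-sided Fisher exact p-value on the
2x2 methylated/unmethylated x genotype table, and significant same-direction
bins are merged into differentially methylated regions whenever the gap
between them is at most 50 bp — with 50-bp bins, that allows at most one
intervening non-significant bin.

The per-bin significance threshold (alpha) and minimum methylation-level
difference (min_delta) are explicit parameters: conventional defaults are
alpha=0.01 and min_delta=0.1.  Bins with zero passing coverage in either
genotype are untestable and never significant.  No multiple-testing
correction is applied by default; an optional Benjamini-Hochberg mode is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log10
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CONTEXTS
from .methylome import (DEFAULT_MIN_COV, MethylomeSample, RegionMethylation,
                        passing_mask, region_methylation)
from .stats import fisher_exact_two_sided


@dataclass
class DmrParams:
    bin_size: int = 50
    merge_gap: int = 50
    min_cov: int = DEFAULT_MIN_COV
    alpha: float = 0.01
    min_delta: float = 0.1
    min_total: int = 1          # minimum pooled reads per bin per sample
    direction: str = "hyper"    # 'hyper', 'hypo' or 'both'
    context: str | None = None  # None pools all contexts; or 'CG'/'CHG'/'CHH'
    fdr: bool = False           # Benjamini-Hochberg on bin p-values

    def __post_init__(self) -> None:
        if self.bin_size < 1 or self.merge_gap < 0 or self.min_total < 1:
            raise ValueError("bin_size/merge_gap/min_total out of range")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0,1]")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")
        if self.direction not in ("hyper", "hypo", "both"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.context is not None and self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")


@dataclass
class GenomicBin:
    """One fixed-width window with pooled counts for both samples."""

    chrom: str
    start: int
    end: int
    meth_a: int
    total_a: int
    meth_b: int
    total_b: int

    def level_a(self) -> float:
        return self.meth_a / self.total_a if self.total_a else float("nan")

    def level_b(self) -> float:
        return self.meth_b / self.total_b if self.total_b else float("nan")


@dataclass
class BinTest:
    bin: GenomicBin
    p_value: float      # NaN when untestable
    delta: float        # level_b - level_a, NaN when untestable
    direction: str      # 'hyper', 'hypo' or 'none'


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    n_bins: int
    min_p: float
    median_p: float
    direction: str
    meth_a: RegionMethylation | None = None
    meth_b: RegionMethylation | None = None

    @property
    def width(self) -> int:
        return self.end - self.start


def bin_methylome(sample: MethylomeSample, chrom_lengths: dict[str, int],
                  params: DmrParams = DmrParams()) -> pd.DataFrame:
    """Tile each chromosome from 0 in bin_size steps and pool passing counts.

    Returns one row per bin (empty bins kept with zero counts): chrom,
    start, end, n_meth, n_total, n_sites.
    """
    frames = []
    df = sample.sites
    keep = passing_mask(df, params.min_cov)
    if params.context is not None:
        keep &= (df["context"] == params.context).to_numpy()
    df = df[keep]
    for chrom, length in chrom_lengths.items():
        n_bins = (length + params.bin_size - 1) // params.bin_size
        sub = df[df["chrom"] == chrom]
        idx = (sub["pos"].to_numpy(dtype=np.int64) - 1) // params.bin_size
        meth = np.bincount(idx, weights=sub["n_meth"].to_numpy(dtype=float),
                           minlength=n_bins)
        total = np.bincount(idx, weights=sub["n_total"].to_numpy(dtype=float),
                            minlength=n_bins)
        sites = np.bincount(idx, minlength=n_bins)
        starts = np.arange(n_bins, dtype=np.int64) * params.bin_size
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + params.bin_size, length),
            "n_meth": meth.astype(np.int64),
            "n_total": total.astype(np.int64),
            "n_sites": sites.astype(np.int64),
        }))
    return pd.concat(frames, ignore_index=True)


def fisher_bin_test(bin: GenomicBin) -> BinTest:
    """Two-sided Fisher exact test on one bin's pooled 2x2 table."""
    if bin.total_a == 0 or bin.total_b == 0:
        return BinTest(bin, float("nan"), float("nan"), "none")
    p = fisher_exact_two_sided(bin.meth_a, bin.total_a - bin.meth_a,
                               bin.meth_b, bin.total_b - bin.meth_b)
    delta = bin.level_b() - bin.level_a()
    direction = "hyper" if delta > 0 else ("hypo" if delta < 0 else "none")
    return BinTest(bin, p, delta, direction)


def evaluate_bins(bins_a: pd.DataFrame, bins_b: pd.DataFrame,
              params: DmrParams = DmrParams()) -> pd.DataFrame:
    """Join the two samples' bin tables and test every testable bin.

    Returns the joint table with columns p, delta and testable; p and delta
    are NaN where untestable (pooled reads below min_total in either sample).
    """
    if not (bins_a["chrom"].equals(bins_b["chrom"])
            and bins_a["start"].equals(bins_b["start"])):
        raise ValueError("bin tilings disagree between samples")
    out = bins_a[["chrom", "start", "end"]].copy()
    out["meth_a"] = bins_a["n_meth"].to_numpy()
    out["total_a"] = bins_a["n_total"].to_numpy()
    out["meth_b"] = bins_b["n_meth"].to_numpy()
    out["total_b"] = bins_b["n_total"].to_numpy()
    testable = ((out["total_a"] >= params.min_total)
                & (out["total_b"] >= params.min_total)).to_numpy()
    p = np.full(len(out), np.nan)
    ma = out["meth_a"].to_numpy()
    ta = out["total_a"].to_numpy()
    mb = out["meth_b"].to_numpy()
    tb = out["total_b"].to_numpy()
    for i in np.flatnonzero(testable):
        p[i] = fisher_exact_two_sided(int(ma[i]), int(ta[i] - ma[i]),
                                      int(mb[i]), int(tb[i] - mb[i]))
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(testable, mb / np.maximum(tb, 1)
                         - ma / np.maximum(ta, 1), np.nan)
    out["p"] = p
    out["delta"] = delta
    out["testable"] = testable
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def significant_mask(tested: pd.DataFrame,
                     params: DmrParams = DmrParams()) -> np.ndarray:
    p = tested["p"].to_numpy(dtype=float)
    if params.fdr:
        p = _bh_adjust(p)
    delta = tested["delta"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        sig_p = p <= params.alpha
        if params.direction == "hyper":
            sig_d = delta >= params.min_delta
        elif params.direction == "hypo":
            sig_d = delta <= -params.min_delta
        else:
            sig_d = np.abs(delta) >= params.min_delta
    return sig_p & sig_d & tested["testable"].to_numpy()


def merge_significant_bins(bins: pd.DataFrame,
                           merge_gap: int) -> list[tuple[str, int, int, list[int]]]:
    """Merge significant bins left to right while gap <= merge_gap.

    ``bins`` holds the significant bins only (chrom/start/end + original
    index); returns (chrom, start, end, member row positions).  The result
    is independent of input row order (sorted internally) and idempotent.
    """
    bins = bins.sort_values(["chrom", "start"])
    merged: list[tuple[str, int, int, list[int]]] = []
    cur = None
    for row in bins.itertuples():
        if cur is not None and row.chrom == cur[0] \
                and row.start - cur[2] <= merge_gap:
            cur = (cur[0], cur[1], max(cur[2], row.end), cur[3] + [row.Index])
        else:
            if cur is not None:
                merged.append(cur)
            cur = (row.chrom, row.start, row.end, [row.Index])
    if cur is not None:
        merged.append(cur)
    return merged


def call_dmrs(sample_a: MethylomeSample, sample_b: MethylomeSample,
              chrom_lengths: dict[str, int],
              params: DmrParams = DmrParams(),
              annotate_levels: bool = True) -> list[DMR]:
    """Full caller: bin both samples, test, select and merge into DMRs.

    sample_a is the reference genotype (wild type), sample_b the mutant;
    'hyper' means higher methylation in sample_b.
    """
    if set(sample_a.chroms()) - set(chrom_lengths) \
            or set(sample_b.chroms()) - set(chrom_lengths):
        raise ValueError("samples contain chromosomes absent from genome")
    bins_a = bin_methylome(sample_a, chrom_lengths, params)
    bins_b = bin_methylome(sample_b, chrom_lengths, params)
    tested = evaluate_bins(bins_a, bins_b, params)
    sig = significant_mask(tested, params)
    members = merge_significant_bins(tested[sig], params.merge_gap)

    dmrs: list[DMR] = []
    p_all = tested["p"].to_numpy(dtype=float)
    delta_all = tested["delta"].to_numpy(dtype=float)
    for chrom, start, end, rows in members:
        ps = p_all[rows]
        direction = "hyper" if delta_all[rows[0]] > 0 else "hypo"
        dmr = DMR(chrom=chrom, start=int(start), end=int(end),
                  n_bins=len(rows), min_p=float(np.min(ps)),
                  median_p=float(np.median(ps)), direction=direction)
        if annotate_levels:
            dmr.meth_a = region_methylation(sample_a, chrom, start, end,
                                            params.min_cov)
            dmr.meth_b = region_methylation(sample_b, chrom, start, end,
                                            params.min_cov)
        dmrs.append(dmr)
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    rows = []
    for i, d in enumerate(dmrs, start=1):
        row = {
            "chrom": d.chrom, "start": d.start, "end": d.end,
            "name": f"dmr_{i}",
            "score": round(min(-log10(d.min_p), 999.0), 3) if d.min_p > 0 else 999.0,
            "strand": ".",
            "n_bins": d.n_bins, "min_p": d.min_p, "direction": d.direction,
        }
        for label, rm in (("a", d.meth_a), ("b", d.meth_b)):
            for ctx in CONTEXTS:
                row[f"{label}_{ctx}"] = round(rm.levels[ctx], 6) if rm else np.nan
        rows.append(row)
    cols = ["chrom", "start", "end", "name", "score", "strand", "n_bins",
            "min_p", "direction"] \
        + [f"{s}_{c}" for s in ("a", "b") for c in CONTEXTS]
    return pd.DataFrame(rows, columns=cols)


def write_dmrs_bed(dmrs: Sequence[DMR], path) -> None:
    """BED6+ output: coordinates, -log10 min p as score, levels per context."""
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", header=False, index=False)
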