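"""Per-cytosine methylation samples: report I/O, coverage filter, region levels.

A methylome sample is a coordinate-sorted table of strand-resolved cytosines
with methylated / total read counts (the Bismark cytosine-report substrate).
Methylation of a site is n_meth / n_total; a site enters any statistic only
if it passes the coverage filter (default: at least threefold coverage).

Region-level methylation pools read counts (sum meth / sum total) across the
passing sites of each context — the same count basis the per-bin exact test
uses — rather than averaging per-site levels; a site-averaged mode exists for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genome import CONTEXTS, Genome, classify_context

DEFAULT_MIN_COV = 3  # "at least threefold coverage"

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]


class CytosineSite(NamedTuple):
    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    n_meth: int
    n_total: int


@dataclass
class MethylomeSample:
    """Genotype-labelled, coordinate-sorted collection of cytosine sites."""

    label: str
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sites table missing columns {missing}")
        if (df["n_meth"] < 0).any() or (df["n_total"] < df["n_meth"]).any():
            raise ValueError("require n_total >= n_meth >= 0 at every site")
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort",
                            ignore_index=True)
        if df.duplicated(["chrom", "pos", "strand"]).any():
            dup = df[df.duplicated(["chrom", "pos", "strand"])].iloc[0]
            raise ValueError(
                f"duplicate site {dup['chrom']}:{dup['pos']}({dup['strand']})")
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))


def site_passes_coverage(site, min_cov: int = DEFAULT_MIN_COV) -> bool:
    """True iff the site's total read count meets the coverage floor."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    return site.n_total >= min_cov


def passing_mask(sites: pd.DataFrame, min_cov: int = DEFAULT_MIN_COV) -> np.ndarray:
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    return (sites["n_total"] >= min_cov).to_numpy()


def read_cytosine_report(path, label: str | None = None,
                         genome: Genome | None = None) -> MethylomeSample:
    """Load a Bismark-style cytosine/CX report.

    Tab-separated: chrom, pos (1-based), strand, count methylated, count
    unmethylated, context[, trinucleotide].  If a genome is supplied the
    context column is recomputed from sequence instead of trusted.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str}, na_filter=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=range(6))
    if df.shape[1] < 6 and len(df):
        raise ValueError(f"{path}: expected >= 6 tab-separated columns")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]
    for col in ("pos", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: malformed {col} field at line {line}")
        df[col] = vals.astype(np.int64)
    if not df["strand"].isin(["+", "-"]).all():
        line = int(np.flatnonzero(~df["strand"].isin(["+", "-"]).to_numpy())[0]) + 1
        raise ValueError(f"{path}: bad strand at line {line}")
    df["n_total"] = df["n_meth"] + df["n_unmeth"]
    if genome is not None and len(df):
        df["context"] = [
            classify_context(genome, c, int(p), s).context
            for c, p, s in zip(df["chrom"], df["pos"], df["strand"])
        ]
    sample = MethylomeSample(
        label=label or str(path),
        sites=df[SITE_COLUMNS].copy(),
    )
    return sample


def write_cytosine_report(sample: MethylomeSample, path,
                          genome: Genome | None = None) -> None:
    """Write the Bismark-dialect report (with trinucleotide when genome given)."""
    df = sample.sites
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos"],
        "strand": df["strand"],
        "n_meth": df["n_meth"],
        "n_unmeth": df["n_total"] - df["n_meth"],
        "context": df["context"],
    })
    if genome is not None:
        tri = []
        for chrom, pos, strand in zip(df["chrom"], df["pos"], df["strand"]):
            seq = genome[chrom]
            i = pos - 1
            if strand == "+":
                t = seq[i:i + 3]
            else:
                from .genome import revcomp
                t = revcomp(seq[max(i - 2, 0):i + 1])
            tri.append(t.ljust(3, "N"))
        out["tri"] = tri
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class RegionMethylation:
    """Per-context pooled methylation over one region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    levels: dict[str, float]  # context -> level in [0,1], NaN when no data
    n_meth: dict[str, int]
    n_total: dict[str, int]
    n_sites_passing: dict[str, int]

    def level(self, context: str) -> float:
        return self.levels[context]


def region_methylation(sample: MethylomeSample, chrom: str, start: int, end: int,
                       min_cov: int = DEFAULT_MIN_COV,
                       mode: str = "weighted") -> RegionMethylation:
    """Pooled per-context methylation of [start, end) (0-based half-open).

    ``weighted`` pools read counts (sum meth / sum total); ``site_mean``
    averages per-site levels.  Sites below min_cov are excluded; a context
    with no passing reads has level NaN.
    """
    if end < start:
        raise ValueError("region end < start")
    df = sample.sites
    sel = df[(df["chrom"] == chrom) & (df["pos"] > start) & (df["pos"] <= end)]
    sel = sel[passing_mask(sel, min_cov)]
    levels: dict[str, float] = {}
    n_meth: dict[str, int] = {}
    n_total: dict[str, int] = {}
    n_pass: dict[str, int] = {}
    for ctx in CONTEXTS:
        sub = sel[sel["context"] == ctx]
        m = int(sub["n_meth"].sum())
        t = int(sub["n_total"].sum())
        n_meth[ctx], n_total[ctx], n_pass[ctx] = m, t, len(sub)
        if t == 0:
            levels[ctx] = nan
        elif mode == "weighted":
            levels[ctx] = m / t
        elif mode == "site_mean":
            levels[ctx] = float((sub["n_meth"] / sub["n_total"]).mean())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return RegionMethylation(chrom, start, end, levels, n_meth, n_total, n_pass)
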