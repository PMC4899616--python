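"""DMR genomic composition and gene-body methylation metaprofiles.

Composition assigns each DMR to exactly one of {genic, TE, intergenic} by a
priority rule (genic > TE > intergenic, >= 1 bp overlap), mirroring how
hyper-DMR sets are summarised against the annotation.  Metaprofiles average
per-context methylation over genes scaled to a fixed number of body bins
plus fixed-width 1-kb flanks, with minus-strand genes flipped so upstream
(the TSS side) is always on the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CONTEXTS
from .methylome import DEFAULT_MIN_COV, MethylomeSample, passing_mask

CATEGORIES = ("genic", "TE", "intergenic")


@dataclass
class FeatureAnnotation:
    """Gene (stranded) and TE interval tables, 0-based half-open."""

    genes: pd.DataFrame = field(repr=False)  # chrom, start, end, strand
    tes: pd.DataFrame = field(repr=False)    # chrom, start, end

    def __post_init__(self) -> None:
        for name, df, need in (("genes", self.genes,
                                ["chrom", "start", "end", "strand"]),
                               ("tes", self.tes, ["chrom", "start", "end"])):
            missing = [c for c in need if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table missing {missing}")
            if (df["end"] <= df["start"]).any():
                raise ValueError(f"{name}: end must exceed start")
        if len(self.genes) and not self.genes["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be '+' or '-'")
        self.genes = self.genes.sort_values(["chrom", "start"],
                                            ignore_index=True)
        self.tes = self.tes.sort_values(["chrom", "start"], ignore_index=True)


GENE_TYPES = ("gene",)
TE_TYPES = ("transposable_element", "transposable_element_gene")


def read_gff3(path, gene_types: Sequence[str] = GENE_TYPES,
              te_types: Sequence[str] = TE_TYPES) -> FeatureAnnotation:
    """Pull gene and TE spans from a GFF3 (1-based inclusive -> half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attrs"],
                     dtype={"chrom": str})
    genes = df[df["type"].isin(gene_types)]
    tes = df[df["type"].isin(te_types)]
    return FeatureAnnotation(
        genes=pd.DataFrame({"chrom": genes["chrom"],
                            "start": genes["start"].astype(np.int64) - 1,
                            "end": genes["end"].astype(np.int64),
                            "strand": genes["strand"]}),
        tes=pd.DataFrame({"chrom": tes["chrom"],
                          "start": tes["start"].astype(np.int64) - 1,
                          "end": tes["end"].astype(np.int64)}),
    )


def annotation_from_classmap(classmap) -> FeatureAnnotation:
    """Adapt a simulated region-class map to a FeatureAnnotation."""
    genes = classmap.of_class("gene")[["chrom", "start", "end", "strand"]]
    tes = classmap.of_class("TE")[["chrom", "start", "end"]]
    return FeatureAnnotation(genes=genes.copy(), tes=tes.copy())


@dataclass
class CompositionResult:
    counts: dict[str, int]
    percentages: dict[str, float]
    n_total: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": list(CATEGORIES),
            "count": [self.counts[c] for c in CATEGORIES],
            "percent": [self.percentages[c] for c in CATEGORIES],
        })


def _overlaps_any(chrom: str, start: int, end: int,
                  table: pd.DataFrame) -> bool:
    sub = table[table["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def classify_dmrs(dmrs, annotation: FeatureAnnotation,
                  priority: Sequence[str] = CATEGORIES) -> CompositionResult:
    """Assign each DMR one category by priority with a >= 1 bp overlap rule."""
    if sorted(priority) != sorted(CATEGORIES):
        raise ValueError(f"priority must permute {CATEGORIES}")
    counts = {c: 0 for c in CATEGORIES}
    for d in dmrs:
        chrom, start, end = d.chrom, d.start, d.end
        hit = {
            "genic": _overlaps_any(chrom, start, end, annotation.genes),
            "TE": _overlaps_any(chrom, start, end, annotation.tes),
            "intergenic": True,
        }
        for cat in priority:
            if hit[cat]:
                counts[cat] += 1
                break
    n = sum(counts.values())
    pct = {c: (100.0 * counts[c] / n if n else float("nan"))
           for c in CATEGORIES}
    return CompositionResult(counts, pct, n)


@dataclass
class MetaProfile:
    """Per-context mean methylation over upstream/body/downstream bins."""

    flank_bins: int
    body_bins: int
    values: pd.DataFrame      # index: context, columns: bin 0..u+g+d-1
    occupancy: pd.DataFrame   # pooled read totals per context x bin

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def segment(self, context: str, which: str) -> np.ndarray:
        row = self.values.loc[context].to_numpy()
        u, g = self.flank_bins, self.body_bins
        return {"upstream": row[:u], "body": row[u:u + g],
                "downstream": row[u + g:]}[which]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def gene_metaprofile(sample: MethylomeSample, genes: pd.DataFrame,
                     flank: int = 1000, body_bins: int = 20,
                     flank_bins: int = 10,
                     min_cov: int = DEFAULT_MIN_COV) -> MetaProfile:
    """Average per-context methylation across genes plus 1-kb flanks.

    Each gene body is linearly rescaled to ``body_bins`` bins; flanks use
    fixed-width bins (flank/flank_bins bp).  A site's counts are split
    across body bins by fractional overlap of its 1-bp footprint, so genes
    shorter than body_bins still contribute correctly.  Values are pooled
    counts (sum methylated / sum total) across genes.
    """
    n_bins = 2 * flank_bins + body_bins
    ctx_idx = {c: i for i, c in enumerate(CONTEXTS)}
    meth = np.zeros((len(CONTEXTS), n_bins))
    total = np.zeros((len(CONTEXTS), n_bins))

    df = sample.sites[passing_mask(sample.sites, min_cov)]
    flank_width = flank / flank_bins
    for gene in genes.itertuples(index=False):
        length = gene.end - gene.start
        window = df[(df["chrom"] == gene.chrom)
                    & (df["pos"] > gene.start - flank)
                    & (df["pos"] <= gene.end + flank)]
        if not len(window):
            continue
        pos0 = window["pos"].to_numpy() - 1
        cidx = np.array([ctx_idx[c] for c in window["context"]])
        m = window["n_meth"].to_numpy(dtype=float)
        t = window["n_total"].to_numpy(dtype=float)

        in_body = (pos0 >= gene.start) & (pos0 < gene.end)
        upstream = pos0 < gene.start

        # flanks: fixed-width bins, measured outward from the gene edge
        up_off = gene.start - 1 - pos0[upstream]        # 0 at edge
        down_off = pos0[~in_body & ~upstream] - gene.end
        up_bin = flank_bins - 1 - np.minimum(
            (up_off / flank_width).astype(int), flank_bins - 1)
        down_bin = np.minimum((down_off / flank_width).astype(int),
                              flank_bins - 1) + flank_bins + body_bins

        if gene.strand == "-":
            up_bin = n_bins - 1 - up_bin
            down_bin = n_bins - 1 - down_bin
        for rows, bins in ((upstream, up_bin),
                           (~in_body & ~upstream, down_bin)):
            np.add.at(meth, (cidx[rows], bins), m[rows])
            np.add.at(total, (cidx[rows], bins), t[rows])

        # body: fractional-overlap split of each site's 1-bp footprint
        frac0 = (pos0[in_body] - gene.start) / length * body_bins
        frac1 = (pos0[in_body] - gene.start + 1) / length * body_bins
        b0 = np.minimum(frac0.astype(int), body_bins - 1)
        b1 = np.minimum(np.ceil(frac1).astype(int) - 1, body_bins - 1)
        cb = cidx[in_body]
        mb, tb = m[in_body], t[in_body]
        span = frac1 - frac0
        for site in range(len(b0)):
            lo, hi = b0[site], b1[site]
            for bb in range(lo, hi + 1):
                w = (min(frac1[site], bb + 1) - max(frac0[site], bb)) / span[site]
                col = bb + flank_bins
                if gene.strand == "-":
                    col = n_bins - 1 - col
                meth[cb[site], col] += w * mb[site]
                total[cb[site], col] += w * tb[site]

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(total > 0, meth / np.maximum(total, 1e-300), np.nan)
    cols = list(range(n_bins))
    return MetaProfile(
        flank_bins=flank_bins, body_bins=body_bins,
        values=pd.DataFrame(values, index=list(CONTEXTS), columns=cols),
        occupancy=pd.DataFrame(total, index=list(CONTEXTS), columns=cols),
    )
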