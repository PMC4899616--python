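"""Synthetic paired methylomes with planted hyper-DMRs.

Emulates two-genotype (wild type vs mutant) whole-genome bisulfite data on
a random genome with an Arabidopsis-like layout: heavily CG/CHG-methylated
TE blocks, a low-methylation genic background, and intergenic filler.  The
mutant differs from the wild type only inside planted differentially
methylated regions, where per-context methylation probabilities are raised
by a configurable delta (hypermethylation, mirroring demethylation-mutant
phenotypes; a hypo mode exists but is off by default).

Noise model per cytosine site: depth ~ Poisson(lambda) (or fixed), then
methylated reads ~ Binomial(depth, m) with m set by the site's region class
and context.  Planted regions are placed outside TEs by default — in the
modelled biology hyper-DMRs concentrate in euchromatic, genic territory —
and at least ``planted_min_gap`` apart so distinct truth regions stay
distinct after merging.

Draw order (one generator stream): genome sequence, region blocks, planted
placement, then wild-type depths, wild-type methylated counts, mutant
depths (skipped when depths are paired), mutant methylated counts, each as
one vectorised draw over sites in coordinate order.  Byte-identical output
for identical config and seed is promised within this implementation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CONTEXTS, Genome, cytosine_table
from .methylome import MethylomeSample

CLASSES = ("TE", "gene", "intergenic")


@dataclass
class MethylationProfile:
    """Baseline methylation probability per region class and context."""

    levels: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for cls, per_ctx in self.levels.items():
            for ctx, m in per_ctx.items():
                if not 0.0 <= m <= 1.0:
                    raise ValueError(f"m[{cls}][{ctx}]={m} outside [0,1]")

    def lookup(self) -> np.ndarray:
        """(class, context) matrix in CLASSES x CONTEXTS order."""
        return np.array([[self.levels[cls][ctx] for ctx in CONTEXTS]
                         for cls in CLASSES])


#: Arabidopsis-like defaults: TEs high CG/CHG with moderate CHH (RdDM),
#: genes and intergenic space lowly methylated.
DEFAULT_PROFILE = MethylationProfile({
    "TE": {"CG": 0.80, "CHG": 0.60, "CHH": 0.15},
    "gene": {"CG": 0.05, "CHG": 0.01, "CHH": 0.01},
    "intergenic": {"CG": 0.08, "CHG": 0.03, "CHH": 0.03},
})


@dataclass
class RegionClassMap:
    """Non-overlapping TE/gene/intergenic intervals tiling each chromosome.

    Intervals are 0-based half-open; genes carry a strand, other classes '.'.
    Gaps are filled with intergenic on construction.
    """

    intervals: pd.DataFrame  # chrom, start, end, cls, strand
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        df = self.intervals.sort_values(["chrom", "start"], ignore_index=True)
        filled = []
        for chrom, length in self.chrom_lengths.items():
            sub = df[df["chrom"] == chrom]
            cursor = 0
            for row in sub.itertuples(index=False):
                if row.start < cursor:
                    raise ValueError(f"overlapping intervals on {chrom}")
                if row.start > cursor:
                    filled.append((chrom, cursor, row.start, "intergenic", "."))
                filled.append((chrom, row.start, row.end, row.cls, row.strand))
                cursor = row.end
            if cursor < length:
                filled.append((chrom, cursor, length, "intergenic", "."))
        self.intervals = pd.DataFrame(
            filled, columns=["chrom", "start", "end", "cls", "strand"])

    def class_fraction(self, cls: str) -> float:
        df = self.intervals
        total = sum(self.chrom_lengths.values())
        return float((df.loc[df["cls"] == cls, "end"]
                      - df.loc[df["cls"] == cls, "start"]).sum()) / total

    def class_at(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Class codes (index into CLASSES) for 0-based positions."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        codes = sub["cls"].map({c: i for i, c in enumerate(CLASSES)}).to_numpy()
        idx = np.searchsorted(starts, pos0, side="right") - 1
        return codes[idx]

    def of_class(self, cls: str) -> pd.DataFrame:
        return self.intervals[self.intervals["cls"] == cls].reset_index(drop=True)


@dataclass
class PlantedDMR:
    """Ground-truth hypermethylated region applied to the mutant."""

    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    delta: dict[str, float]  # context -> added methylation probability

    def __post_init__(self) -> None:
        if self.end - self.start < 50:
            raise ValueError("planted DMR must span >= 50 bp")
        if any(d < 0 for d in self.delta.values()):
            raise ValueError("hyper deltas must be >= 0")


DEFAULT_PLANT_DELTA = {"CG": 0.5, "CHG": 0.5, "CHH": 0.3}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated wild-type/mutant pair."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000})
    gc: float = 0.36
    te_fraction: float = 0.15
    gene_fraction: float = 0.45
    arrangement: str = "random"        # or "cassette"
    block_len: tuple[int, int] = (500, 3000)
    cassette: tuple[int, int, int] = (600, 700, 2000)  # intergenic, TE, gene
    profile: MethylationProfile = field(default_factory=lambda: DEFAULT_PROFILE)
    planted: Sequence[PlantedDMR] = ()
    planted_per_mb: float = 30.0
    planted_width: tuple[int, int] = (200, 1000)
    planted_delta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANT_DELTA))
    planted_min_gap: int = 300
    avoid_te: bool = True
    mean_depth: float = 20.0
    fixed_depth: int | None = None
    paired_depth: bool = False
    hypo: bool = False
    labels: tuple[str, str] = ("wt", "mut")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0,1]")
        if self.te_fraction + self.gene_fraction > 1.0 + 1e-9:
            raise ValueError("te_fraction + gene_fraction exceed 1")
        if self.fixed_depth is None and self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[Genome, RegionClassMap]:
    """Random genome at the requested GC plus a TE/gene/intergenic tiling."""
    rng = rng if rng is not None else config.rng()
    p = np.array([(1 - config.gc) / 2, config.gc / 2,
                  config.gc / 2, (1 - config.gc) / 2])
    bases = np.array(list("ACGT"))
    sequences = {
        chrom: "".join(bases[rng.choice(4, size=length, p=p)])
        for chrom, length in config.chrom_lengths.items()
    }
    genome = Genome(sequences)

    rows = []
    targets = {"TE": config.te_fraction, "gene": config.gene_fraction,
               "intergenic": 1.0 - config.te_fraction - config.gene_fraction}
    if config.arrangement == "cassette":
        ig, te, ge = config.cassette
        for chrom, length in config.chrom_lengths.items():
            cursor, flip = 0, False
            while cursor < length:
                unit = [("intergenic", ig), ("TE", te), ("gene", ge), ("TE", te)]
                for cls, w in unit:
                    if cursor >= length:
                        break
                    end = min(cursor + w, length)
                    strand = "."
                    if cls == "gene":
                        strand = "-" if flip else "+"
                        flip = not flip
                    rows.append((chrom, cursor, end, cls, strand))
                    cursor = end
    elif config.arrangement == "random":
        # random block lengths; class chosen greedily toward target fractions
        for chrom, length in config.chrom_lengths.items():
            placed = {cls: 0 for cls in CLASSES}
            cursor = 0
            while cursor < length:
                w = int(rng.integers(config.block_len[0], config.block_len[1] + 1))
                end = min(cursor + w, length)
                done = sum(placed.values()) + (end - cursor)
                deficit = {cls: targets[cls] * done - placed[cls]
                           for cls in CLASSES}
                cls = max(CLASSES, key=lambda c: deficit[c])
                strand = "+" if (cls == "gene" and rng.random() < 0.5) else \
                         ("-" if cls == "gene" else ".")
                rows.append((chrom, cursor, end, cls, strand))
                placed[cls] += end - cursor
                cursor = end
    else:
        raise ValueError(f"unknown arrangement {config.arrangement!r}")
    classmap = RegionClassMap(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "cls", "strand"]),
        dict(config.chrom_lengths))
    return genome, classmap


def plant_dmrs(classmap: RegionClassMap, config: SimulationConfig,
               rng: np.random.Generator | None = None) -> list[PlantedDMR]:
    """Place non-overlapping truth regions, outside TEs when avoid_te is set."""
    rng = rng if rng is not None else config.rng()
    total_mb = sum(classmap.chrom_lengths.values()) / 1e6
    n_target = int(round(config.planted_per_mb * total_mb))
    te = classmap.of_class("TE")
    chroms = list(classmap.chrom_lengths)
    weights = np.array([classmap.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    placed: list[PlantedDMR] = []
    tries = 0
    while len(placed) < n_target and tries < 200 * max(n_target, 1):
        tries += 1
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = classmap.chrom_lengths[chrom]
        width = int(rng.integers(config.planted_width[0],
                                 config.planted_width[1] + 1))
        if width >= length:
            continue
        start = int(rng.integers(0, length - width))
        end = start + width
        if config.avoid_te:
            sub = te[te["chrom"] == chrom]
            if ((sub["start"] < end) & (sub["end"] > start)).any():
                continue
        gap = config.planted_min_gap
        clash = any(p.chrom == chrom and p.start - gap < end and
                    p.end + gap > start for p in placed)
        if clash:
            continue
        placed.append(PlantedDMR(chrom, start, end, dict(config.planted_delta)))
    placed.sort(key=lambda p: (p.chrom, p.start))
    return placed


def simulate_counts(genome: Genome, classmap: RegionClassMap,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    planted: Sequence[PlantedDMR] | None = None
                    ) -> tuple[MethylomeSample, MethylomeSample]:
    """Draw wild-type and mutant read counts for every non-ambiguous cytosine."""
    rng = rng if rng is not None else config.rng()
    planted = config.planted if planted is None else planted

    table = cytosine_table(genome)
    table = table[table["context"] != "ambiguous"].reset_index(drop=True)
    ctx_code = table["context"].astype(str).map(
        {c: i for i, c in enumerate(CONTEXTS)}).to_numpy(dtype=np.int64)

    cls_code = np.empty(len(table), dtype=np.int64)
    for chrom in genome.sequences:
        mask = (table["chrom"] == chrom).to_numpy()
        pos0 = table.loc[mask, "pos"].to_numpy() - 1
        cls_code[mask] = classmap.class_at(chrom, pos0)

    lookup = config.profile.lookup()
    m_wt = lookup[cls_code, ctx_code]
    m_mut = m_wt.copy()
    sign = -1.0 if config.hypo else 1.0
    delta_vec = np.zeros(len(CONTEXTS))
    for region in planted:
        for i, ctx in enumerate(CONTEXTS):
            delta_vec[i] = region.delta.get(ctx, 0.0)
        mask = ((table["chrom"] == region.chrom).to_numpy()
                & (table["pos"].to_numpy() > region.start)
                & (table["pos"].to_numpy() <= region.end))
        m_mut[mask] = np.clip(m_mut[mask] + sign * delta_vec[ctx_code[mask]],
                              0.0, 1.0)

    n = len(table)
    if config.fixed_depth is not None:
        depth_wt = np.full(n, config.fixed_depth, dtype=np.int64)
        depth_mut = depth_wt.copy()
    else:
        depth_wt = rng.poisson(config.mean_depth, size=n)
    meth_wt = rng.binomial(depth_wt, m_wt)
    if config.fixed_depth is None:
        depth_mut = depth_wt if config.paired_depth \
            else rng.poisson(config.mean_depth, size=n)
    meth_mut = rng.binomial(depth_mut, m_mut)

    def build(label: str, meth: np.ndarray, depth: np.ndarray) -> MethylomeSample:
        return MethylomeSample(label, pd.DataFrame({
            "chrom": table["chrom"],
            "pos": table["pos"],
            "strand": table["strand"].astype(str),
            "context": table["context"].astype(str),
            "n_meth": meth.astype(np.int64),
            "n_total": depth.astype(np.int64),
        }))

    return build(config.labels[0], meth_wt, depth_wt), \
        build(config.labels[1], meth_mut, depth_mut)


def simulate_pair(config: SimulationConfig
                  ) -> tuple[Genome, RegionClassMap, list[PlantedDMR],
                             MethylomeSample, MethylomeSample]:
    """One-stop simulation: genome, class map, planted truth, wt and mutant."""
    rng = config.rng()
    genome, classmap = simulate_genome(config, rng)
    planted = list(config.planted) or plant_dmrs(classmap, config, rng)
    wt, mut = simulate_counts(genome, classmap, config, rng, planted)
    return genome, classmap, planted, wt, mut


def write_truth_bed(planted: Sequence[PlantedDMR], path) -> None:
    """Planted regions as BED6 (name=planted_<i>, score 0, strand '.')."""
    with open(path, "w") as fh:
        for i, region in enumerate(planted, start=1):
            fh.write(f"{region.chrom}\t{region.start}\t{region.end}"
                     f"\tplanted_{i}\t0\t.\n")
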