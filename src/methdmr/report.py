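"""Run configuration, percent formatting, and the end-to-end demo pipeline.

``run_pipeline`` strings the stages together in analysis order — simulate
paired methylomes for two mutants against a shared wild type, call
hyper-DMRs, compare the DMR sets (overlap counts, chance expectation,
hypergeometric enrichment), classify their genomic composition, and build
gene metaprofiles — writing every table plus a parameter-echoing summary
under one output directory.  All randomness flows from a single seed, so a
rerun regenerates identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .dmr import DmrParams, call_dmrs, dmrs_to_frame, write_dmrs_bed
from .genome import CONTEXTS
from .overlap import DEFAULT_MIN_OVERLAP, IntervalSet, overlap_enrichment
from .profiles import annotation_from_classmap, classify_dmrs, gene_metaprofile
from .simulate import (PlantedDMR, SimulationConfig, plant_dmrs,
                       simulate_counts, simulate_genome, write_truth_bed)

log = logging.getLogger("methdmr")


def format_percent(numerator: int, denominator: int) -> str:
    """Percent at one decimal, or two decimals below 1%."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    return f"{pct:.2f}%" if pct < 1.0 else f"{pct:.1f}%"


def ratio_report(numerator: int, denominator: int) -> str:
    """Human-readable percent with the underlying counts, e.g. '48.8% (40/82)'.

    Thousands separators appear only in this human-readable form, never in
    machine-readable tables.
    """
    return (f"{format_percent(numerator, denominator)} "
            f"({numerator:,}/{denominator:,})")


@dataclass
class RunConfig:
    """Everything the demo pipeline needs, serialisable and seed-driven."""

    seed: int = 7
    genome_length: int = 400_000
    mean_depth: float = 20.0
    shared_fraction: float = 0.5   # planted truth shared between the mutants
    planted_per_mb: float = 30.0
    dmr: DmrParams = field(default_factory=DmrParams)
    min_overlap: int = DEFAULT_MIN_OVERLAP
    arrangement: str = "cassette"
    labels: tuple[str, str, str] = ("wt", "mutA", "mutB")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _split_planted(planted: list[PlantedDMR], shared_fraction: float,
                   rng) -> tuple[list[PlantedDMR], list[PlantedDMR]]:
    """Partition truth regions into two mutant sets with a shared core."""
    n = len(planted)
    n_shared = int(round(n * shared_fraction))
    idx = rng.permutation(n)
    shared = [planted[i] for i in idx[:n_shared]]
    rest = [planted[i] for i in idx[n_shared:]]
    half = len(rest) // 2
    set_a = sorted(shared + rest[:half], key=lambda p: (p.chrom, p.start))
    set_b = sorted(shared + rest[half:], key=lambda p: (p.chrom, p.start))
    return set_a, set_b


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Simulate, call, compare and profile; return the summary statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(levelname)s %(message)s")
    log.info("pipeline start, seed=%d", config.seed)

    sim = SimulationConfig(
        chrom_lengths={"chr1": config.genome_length},
        arrangement=config.arrangement,
        mean_depth=config.mean_depth,
        planted_per_mb=config.planted_per_mb,
        seed=config.seed,
    )
    rng = sim.rng()
    genome, classmap = simulate_genome(sim, rng)
    planted_all = plant_dmrs(classmap, sim, rng)
    planted_a, planted_b = _split_planted(planted_all,
                                          config.shared_fraction, rng)

    wt, mut_a = simulate_counts(genome, classmap, sim, rng, planted_a)
    _, mut_b = simulate_counts(
        genome, classmap,
        dataclasses.replace(sim, labels=("wt2", config.labels[2])),
        rng, planted_b)
    wt.label, mut_a.label, mut_b.label = config.labels

    write_truth_bed(planted_a, outdir / "truth_mutA.bed")
    write_truth_bed(planted_b, outdir / "truth_mutB.bed")

    lengths = genome.lengths
    n_bins_total = sum((L + config.dmr.bin_size - 1) // config.dmr.bin_size
                      for L in lengths.values())
    dmr_sets = {}
    for label, mut in ((config.labels[1], mut_a), (config.labels[2], mut_b)):
        dmrs = call_dmrs(wt, mut, lengths, config.dmr)
        write_dmrs_bed(dmrs, outdir / f"dmrs_{label}.bed")
        dmr_sets[label] = dmrs
        log.info("%s: %d hyper-DMRs", label, len(dmrs))

    set_a = IntervalSet.from_dmrs(config.labels[1], dmr_sets[config.labels[1]])
    set_b = IntervalSet.from_dmrs(config.labels[2], dmr_sets[config.labels[2]])
    ov_ab = overlap_enrichment(set_a, set_b, n_bins_total, config.min_overlap)
    ov_ba = overlap_enrichment(set_b, set_a, n_bins_total, config.min_overlap)
    import pandas as pd
    pd.DataFrame([dataclasses.asdict(ov_ab),
                  dataclasses.asdict(ov_ba)]).to_csv(
        outdir / "overlap.tsv", sep="\t", index=False)

    annotation = annotation_from_classmap(classmap)
    composition = {}
    for label, dmrs in dmr_sets.items():
        comp = classify_dmrs(dmrs, annotation)
        comp.as_frame().to_csv(outdir / f"composition_{label}.tsv",
                               sep="\t", index=False)
        composition[label] = comp

    profile = gene_metaprofile(wt, annotation.genes,
                               min_cov=config.dmr.min_cov)
    profile.to_tsv(outdir / "metaprofile_wt.tsv")

    summary = {
        "version": __version__,
        "config": config.to_dict(),
        "n_planted": {config.labels[1]: len(planted_a),
                      config.labels[2]: len(planted_b)},
        "n_dmrs": {label: len(d) for label, d in dmr_sets.items()},
        "n_bins_total": n_bins_total,
        "overlap": {
            f"{ov.label_a}_in_{ov.label_b}": {
                "n_overlap": ov.n_overlap_a, "expected": ov.expected,
                "p_value": ov.p_value,
                "report": (ratio_report(ov.n_overlap_a, ov.n_a)
                           if ov.n_a else "0/0"),
            } for ov in (ov_ab, ov_ba)
        },
        "composition": {label: comp.counts
                        for label, comp in composition.items()},
    }
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"methdmr {__version__} demo pipeline (seed {config.seed})\n\n")
        for label in (config.labels[1], config.labels[2]):
            fh.write(f"{label}: {len(dmr_sets[label])} hyper-DMRs called "
                     f"({summary['n_planted'][label]} planted)\n")
        for key, ov in summary["overlap"].items():
            fh.write(f"overlap {key}: {ov['report']}, expected "
                     f"{ov['expected']:.2f}, p={ov['p_value']:.3g}\n")
        for label, comp in composition.items():
            parts = ", ".join(
                f"{cat} {ratio_report(comp.counts[cat], comp.n_total)}"
                if comp.n_total else f"{cat} 0/0"
                for cat in comp.counts)
            fh.write(f"composition {label}: {parts}\n")
    log.info("pipeline done -> %s", outdir)
    return summary
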