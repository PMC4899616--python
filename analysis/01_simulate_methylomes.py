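#!/usr/bin/env python
"""Simulate the study's synthetic methylomes.

Generates one shared wild type plus two demethylation-deficient mutants
(mutA, mutB) on a 400-kb Arabidopsis-like genome at 20x mean depth, with
planted hyper-DMRs partially shared between the mutants, and writes the
genome (FASTA), region classes (BED), planted truth (BED6) and Bismark-
style cytosine reports under results/simulation/.
"""

import dataclasses
from pathlib import Path

from methdmr import SimulationConfig
from methdmr.methylome import write_cytosine_report
from methdmr.report import RunConfig, _split_planted
from methdmr.simulate import (plant_dmrs, simulate_counts, simulate_genome,
                              write_truth_bed)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "simulation"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    run = RunConfig(seed=SEED, genome_length=400_000)
    sim = SimulationConfig(chrom_lengths={"chr1": run.genome_length},
                           arrangement=run.arrangement, seed=run.seed)
    rng = sim.rng()
    genome, classmap = simulate_genome(sim, rng)
    planted = plant_dmrs(classmap, sim, rng)
    planted_a, planted_b = _split_planted(planted, run.shared_fraction, rng)
    wt, mut_a = simulate_counts(genome, classmap, sim, rng, planted_a)
    _, mut_b = simulate_counts(
        genome, classmap, dataclasses.replace(sim, labels=("wt2", "mutB")),
        rng, planted_b)

    with open(OUT / "genome.fa", "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    classmap.intervals.to_csv(OUT / "classes.bed", sep="\t", header=False,
                              index=False)
    write_truth_bed(planted_a, OUT / "truth_mutA.bed")
    write_truth_bed(planted_b, OUT / "truth_mutB.bed")
    for label, sample in (("wt", wt), ("mutA", mut_a), ("mutB", mut_b)):
        write_cytosine_report(sample, OUT / f"{label}.cx")

    shared = len(planted_a) + len(planted_b) - len(planted)
    print(f"simulated {sum(genome.lengths.values()):,} bp genome "
          f"(TE {classmap.class_fraction('TE'):.2f}, "
          f"gene {classmap.class_fraction('gene'):.2f})")
    print(f"planted {len(planted_a)} hyper-DMRs in mutA, {len(planted_b)} "
          f"in mutB ({shared} shared)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
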