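#!/usr/bin/env python
"""Locus-specific clone-based bisulfite summary at one called DMR.

Extracts the strongest called mutA DMR as an amplicon reference, simulates
clone sequencing of wild-type and mutant molecules at the per-context
levels measured there from the whole-genome data, and produces the
per-context clone summary tables (the locus-specific counterpart of the
genome-wide calls).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from methdmr import (AmpliconReference, call_clones, load_genome,
                     region_methylation, simulate_clones, summarize_clones)
from methdmr.clones import conversion_check
from methdmr.methylome import read_cytosine_report

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "simulation"
N_CLONES = 24
SEED = 77


def main() -> None:
    genome = load_genome(SCRATCH / "genome.fa")
    dmrs = pd.read_csv(RESULTS / "dmrs" / "dmrs_mutA.bed", sep="\t",
                       header=None).rename(columns={0: "chrom", 1: "start",
                                                    2: "end", 4: "score"})
    top = dmrs.sort_values("score", ascending=False).iloc[0]
    chrom, start, end = top["chrom"], int(top["start"]), int(top["end"])
    print(f"amplicon: {chrom}:{start}-{end} ({end - start} bp, "
          f"strongest mutA hyper-DMR)")

    reference = AmpliconReference(f"{chrom}_{start}_{end}",
                                  genome[chrom][start:end])
    rng = np.random.default_rng(SEED)
    for label in ("wt", "mutA"):
        sample = read_cytosine_report(SCRATCH / f"{label}.cx",
                                      label)
        rm = region_methylation(sample, chrom, start, end)
        m_vector = np.array([rm.levels.get(ctx, 0.0)
                             if rm.levels.get(ctx) == rm.levels.get(ctx)
                             else 0.0
                             for ctx in reference.cytosines["context"]])
        clones = simulate_clones(reference, m_vector, N_CLONES, rng)
        matrix = call_clones(reference, clones)
        summary = summarize_clones(matrix)
        summary.to_csv(RESULTS / f"clones_{label}.tsv", sep="\t", index=False)
        flagged = conversion_check(matrix)["flagged"].sum()
        levels = {row["context"]: row["level"]
                  for _, row in summary.iterrows()}
        print(f"{label}: {N_CLONES} clones — CG {levels['CG']:.2f}, "
              f"CHG {levels['CHG']:.2f}, CHH {levels['CHH']:.2f} "
              f"({flagged} clones flagged by conversion check)")
    print(f"wrote clone summaries to {RESULTS}")


if __name__ == "__main__":
    main()
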