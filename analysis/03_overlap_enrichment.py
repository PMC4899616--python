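#!/usr/bin/env python
"""Compare the two mutants' hyper-DMR sets.

Counts >=50-bp overlaps between the mutA and mutB DMR sets in both
directions, computes the chance expectation (A*B)/N with N = number of
50-bp genome bins, and the hypergeometric enrichment p-value — the same
statistics used to compare demethylation-mutant DMR sets genome wide.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from methdmr import load_genome, overlap_enrichment, ratio_report
from methdmr.overlap import read_bed

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "simulation"


def main() -> None:
    genome = load_genome(SCRATCH / "genome.fa")
    n_bins = sum((length + 49) // 50 for length in genome.lengths.values())
    set_a = read_bed(RESULTS / "dmrs" / "dmrs_mutA.bed", "mutA")
    set_b = read_bed(RESULTS / "dmrs" / "dmrs_mutB.bed", "mutB")

    rows = []
    for first, second in ((set_a, set_b), (set_b, set_a)):
        result = overlap_enrichment(first, second, n_bins)
        rows.append(dataclasses.asdict(result))
        print(f"{result.label_a} DMRs overlapping {result.label_b}: "
              f"{ratio_report(result.n_overlap_a, result.n_a)}, "
              f"expected by chance {result.expected:.2f}, "
              f"hypergeometric p = {result.p_value:.3g}")
    out = RESULTS / "overlap_enrichment.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
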