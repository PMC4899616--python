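#!/usr/bin/env python
"""Call hyper-DMRs for both mutants against the shared wild type.

Reads the cytosine reports written by 01_simulate_methylomes.py, runs the
50-bp-bin Fisher caller with default thresholds (coverage >= 3, alpha 0.01,
delta >= 0.1, merge gap <= 50 bp), writes BED6+ DMR tables, and scores the
calls against the planted truth.
"""

from pathlib import Path

from methdmr import DmrParams, IntervalSet, call_dmrs, call_overlaps, load_genome
from methdmr.dmr import write_dmrs_bed
from methdmr.methylome import read_cytosine_report
from methdmr.overlap import read_bed, summed_intersection

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "simulation"
SIM = SCRATCH
OUT = RESULTS / "dmrs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = load_genome(SIM / "genome.fa")
    wt = read_cytosine_report(SIM / "wt.cx", "wt")
    params = DmrParams()
    for label in ("mutA", "mutB"):
        mut = read_cytosine_report(SIM / f"{label}.cx", label)
        dmrs = call_dmrs(wt, mut, genome.lengths, params)
        write_dmrs_bed(dmrs, OUT / f"dmrs_{label}.bed")

        truth = read_bed(SIM / f"truth_{label}.bed", "truth")
        called = IntervalSet.from_dmrs(label, dmrs)
        recovered = call_overlaps(truth, called, min_overlap=50)
        inside = int(summed_intersection(called, truth).sum())
        outside_pct = 100 * (called.total_bases() - inside) \
            / max(called.total_bases(), 1)
        print(f"{label}: {len(dmrs)} hyper-DMRs called, "
              f"{recovered}/{len(truth)} planted regions recovered "
              f"(>=50 bp overlap), {outside_pct:.1f}% of called bases "
              f"outside planted truth")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
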