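#!/usr/bin/env python
"""Genomic composition of the called DMRs and gene-body metaprofiles.

Classifies each called hyper-DMR as genic / TE / intergenic (priority
genic > TE at >=1 bp overlap) against the simulated annotation, and builds
per-context methylation metaprofiles over gene bodies with 1-kb flanks for
the wild type, writing tables and a line plot.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from methdmr import classify_dmrs, gene_metaprofile, ratio_report
from methdmr.methylome import read_cytosine_report
from methdmr.overlap import read_bed
from methdmr.profiles import FeatureAnnotation
import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "simulation"


def load_annotation() -> FeatureAnnotation:
    classes = pd.read_csv(SCRATCH / "classes.bed", sep="\t",
                          header=None,
                          names=["chrom", "start", "end", "cls", "strand"])
    return FeatureAnnotation(
        genes=classes[classes["cls"] == "gene"][
            ["chrom", "start", "end", "strand"]].reset_index(drop=True),
        tes=classes[classes["cls"] == "TE"][
            ["chrom", "start", "end"]].reset_index(drop=True))


def main() -> None:
    annotation = load_annotation()
    for label in ("mutA", "mutB"):
        dmrs = read_bed(RESULTS / "dmrs" / f"dmrs_{label}.bed", label)
        records = list(dmrs.intervals.itertuples(index=False))
        comp = classify_dmrs(records, annotation)
        comp.as_frame().to_csv(RESULTS / f"composition_{label}.tsv",
                               sep="\t", index=False)
        genic = ratio_report(comp.counts["genic"], comp.n_total)
        print(f"{label}: {comp.n_total} DMRs — genic {genic}, "
              f"TE {comp.counts['TE']}, intergenic "
              f"{comp.counts['intergenic']}")

    wt = read_cytosine_report(SCRATCH / "wt.cx", "wt")
    profile = gene_metaprofile(wt, annotation.genes)
    profile.to_tsv(RESULTS / "metaprofile_wt.tsv")

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for ctx in ("CG", "CHG", "CHH"):
        ax.plot(profile.values.loc[ctx].to_numpy(), label=ctx)
    u, g = profile.flank_bins, profile.body_bins
    for x in (u - 0.5, u + g - 0.5):
        ax.axvline(x, color="grey", ls=":")
    ax.set_xticks([0, u - 0.5, u + g - 0.5, 2 * u + g - 1])
    ax.set_xticklabels(["-1 kb", "TSS", "TTS", "+1 kb"])
    ax.set_ylabel("methylation level")
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / "metaprofile_wt.png", dpi=120)
    print(f"wrote metaprofile table and plot to {RESULTS}")


if __name__ == "__main__":
    main()
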