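"""DMR genomic composition and gene-body metaprofiles."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from methdmr import (FeatureAnnotation, MethylomeSample, classify_dmrs,
                     gene_metaprofile, read_gff3)
from methdmr.profiles import annotation_from_classmap


def interval(chrom, start, end):
    return SimpleNamespace(chrom=chrom, start=start, end=end)


def annotation(genes=(), tes=()):
    return FeatureAnnotation(
        genes=pd.DataFrame([{"chrom": c, "start": s, "end": e, "strand": st}
                            for c, s, e, st in genes],
                           columns=["chrom", "start", "end", "strand"]),
        tes=pd.DataFrame([{"chrom": c, "start": s, "end": e}
                          for c, s, e in tes],
                         columns=["chrom", "start", "end"]))


class TestComposition:
    def test_priority_genic_over_te(self):
        ann = annotation(genes=[("chr1", 0, 1000, "+")],
                         tes=[("chr1", 500, 1500)])
        result = classify_dmrs([interval("chr1", 600, 900)], ann)
        assert result.counts == {"genic": 1, "TE": 0, "intergenic": 0}

    def test_te_priority_configurable(self):
        ann = annotation(genes=[("chr1", 0, 1000, "+")],
                         tes=[("chr1", 500, 1500)])
        result = classify_dmrs([interval("chr1", 600, 900)], ann,
                               priority=("TE", "genic", "intergenic"))
        assert result.counts["TE"] == 1

    def test_no_overlap_is_intergenic(self):
        ann = annotation(genes=[("chr1", 0, 100, "+")])
        result = classify_dmrs([interval("chr1", 5000, 5100)], ann)
        assert result.counts["intergenic"] == 1

    def test_single_bp_overlap_counts(self):
        ann = annotation(genes=[("chr1", 100, 200, "+")])
        result = classify_dmrs([interval("chr1", 199, 300)], ann)
        assert result.counts["genic"] == 1
        result = classify_dmrs([interval("chr1", 200, 300)], ann)
        assert result.counts["genic"] == 0 and result.counts["intergenic"] == 1

    def test_percentages_sum_to_100(self):
        ann = annotation(genes=[("chr1", 0, 1000, "+")],
                         tes=[("chr1", 2000, 3000)])
        dmrs = [interval("chr1", 100, 200), interval("chr1", 2100, 2200),
                interval("chr1", 5000, 5100)]
        result = classify_dmrs(dmrs, ann)
        assert sum(result.counts.values()) == 3
        assert sum(result.percentages.values()) == pytest.approx(100.0)

    def test_planted_genic_fraction_recovered(self):
        ann = annotation(genes=[("chr1", i * 1000, i * 1000 + 500, "+")
                                for i in range(10)])
        # 7 of 10 DMRs inside genes, 3 in the gaps
        dmrs = [interval("chr1", i * 1000 + 100, i * 1000 + 200)
                for i in range(7)] \
            + [interval("chr1", i * 1000 + 600, i * 1000 + 700)
               for i in range(3)]
        result = classify_dmrs(dmrs, ann)
        assert result.percentages["genic"] == pytest.approx(70.0)

    def test_empty_dmr_set(self):
        result = classify_dmrs([], annotation())
        assert result.n_total == 0
        assert np.isnan(result.percentages["genic"])


def test_gff3_reader_converts_coordinates(tmp_path):
    gff = tmp_path / "ann.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\ttransposable_element\t301\t400\t.\t-\t.\tID=t1\n"
        "chr1\tsrc\texon\t101\t150\t.\t+\t.\tParent=g1\n")
    ann = read_gff3(gff)
    assert list(ann.genes[["start", "end"]].iloc[0]) == [100, 200]
    assert list(ann.tes[["start", "end"]].iloc[0]) == [300, 400]
    assert len(ann.genes) == 1  # exon not pulled in


def uniform_sample(length, level, depth=10, label="s"):
    rows = []
    for pos in range(1, length + 1, 3):
        rows.append(("chr1", pos, "+", ["CG", "CHG", "CHH"][pos % 3],
                     int(round(level * depth)), depth))
    return MethylomeSample(label, pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context",
                       "n_meth", "n_total"]))


class TestMetaprofile:
    def test_constant_field_gives_flat_profile(self):
        sample = uniform_sample(6000, 0.5)
        genes = pd.DataFrame([{"chrom": "chr1", "start": 2000, "end": 4000,
                               "strand": "+"}])
        profile = gene_metaprofile(sample, genes)
        values = profile.values.to_numpy()
        occupied = profile.occupancy.to_numpy() > 0
        assert np.allclose(values[occupied], 0.5)

    def test_upstream_signal_flips_with_strand(self):
        # methylation only 5' of the TSS of a minus-strand gene, i.e. at
        # genomic coordinates greater than the gene end
        rows = [("chr1", pos, "+", "CG", 10 if pos > 4000 else 0, 10)
                for pos in range(1000, 5000, 5)]
        sample = MethylomeSample("s", pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context",
                           "n_meth", "n_total"]))
        genes = pd.DataFrame([{"chrom": "chr1", "start": 2000, "end": 4000,
                               "strand": "-"}])
        profile = gene_metaprofile(sample, genes)
        upstream = profile.segment("CG", "upstream")
        body = profile.segment("CG", "body")
        assert np.nanmean(upstream) == pytest.approx(1.0)
        assert np.nanmean(body) == pytest.approx(0.0)

    def test_short_gene_contributes_by_fractional_weighting(self):
        rows = [("chr1", pos, "+", "CG", 5, 10) for pos in range(95, 106)]
        sample = MethylomeSample("s", pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context",
                           "n_meth", "n_total"]))
        genes = pd.DataFrame([{"chrom": "chr1", "start": 99, "end": 104,
                               "strand": "+"}])  # 5 bp gene, 20 body bins
        profile = gene_metaprofile(sample, genes)
        body = profile.segment("CG", "body")
        occ = profile.occupancy.to_numpy()[0, 10:30]
        assert occ.sum() == pytest.approx(50.0)  # 5 sites x depth 10
        assert np.allclose(body[~np.isnan(body)], 0.5)

    def test_strand_flip_invariance(self, small_pair):
        """Mirroring genome, sample and annotation leaves the profile fixed."""
        genome = small_pair["genome"]
        length = genome.lengths["chr1"]
        wt = small_pair["wt"]
        genes = annotation_from_classmap(small_pair["classmap"]).genes
        genes = genes.head(8)
        profile = gene_metaprofile(wt, genes)

        sites = wt.sites.copy()
        sites["pos"] = length - sites["pos"] + 1
        sites["strand"] = sites["strand"].map({"+": "-", "-": "+"})
        mirrored_sample = MethylomeSample("mirror", sites)
        mirrored_genes = pd.DataFrame({
            "chrom": genes["chrom"],
            "start": length - genes["end"],
            "end": length - genes["start"],
            "strand": genes["strand"].map({"+": "-", "-": "+"}),
        })
        mirrored = gene_metaprofile(mirrored_sample, mirrored_genes)
        np.testing.assert_allclose(profile.values.to_numpy(),
                                   mirrored.values.to_numpy(),
                                   rtol=1e-9, equal_nan=True)
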