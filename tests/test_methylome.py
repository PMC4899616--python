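"""Cytosine-report I/O, the coverage filter, and region-level pooling."""

from math import isnan

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methdmr import (CytosineSite, MethylomeSample, read_cytosine_report,
                     region_methylation, site_passes_coverage)
from methdmr.methylome import passing_mask


def make_sample(rows, label="s"):
    return MethylomeSample(label, pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context",
                       "n_meth", "n_total"]))


class TestReadReport:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "r.cx"
        path.write_text("chr1\t2\t+\t5\t5\tCG\tCGA\n")
        sample = read_cytosine_report(path)
        site = sample.sites.iloc[0]
        assert (site["chrom"], site["pos"], site["strand"]) == ("chr1", 2, "+")
        assert site["context"] == "CG"
        assert (site["n_meth"], site["n_total"]) == (5, 10)

    def test_empty_file_is_valid(self, tmp_path):
        path = tmp_path / "empty.cx"
        path.write_text("")
        assert len(read_cytosine_report(path)) == 0

    def test_negative_count_reports_line(self, tmp_path):
        path = tmp_path / "bad.cx"
        path.write_text("chr1\t2\t+\t5\t5\tCG\nchr1\t3\t+\t-1\t5\tCHH\n")
        with pytest.raises(ValueError, match="line 2"):
            read_cytosine_report(path)

    def test_duplicate_site_fatal(self, tmp_path):
        path = tmp_path / "dup.cx"
        path.write_text("chr1\t2\t+\t1\t1\tCG\nchr1\t2\t+\t2\t0\tCG\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_cytosine_report(path)

    def test_context_recomputed_from_genome(self, tmp_path, write_fasta):
        from methdmr import load_genome
        genome = load_genome(write_fasta([("chr1", "ACGT")]))
        path = tmp_path / "r.cx"
        path.write_text("chr1\t2\t+\t1\t1\tCHH\n")  # wrong context on disk
        sample = read_cytosine_report(path, genome=genome)
        assert sample.sites.iloc[0]["context"] == "CG"


@pytest.mark.parametrize("n_total,passes", [(3, True), (2, False), (0, False),
                                            (10, True)])
def test_threefold_coverage_rule(n_total, passes):
    site = CytosineSite("chr1", 1, "+", "CG", 0, n_total)
    assert site_passes_coverage(site) is passes


def test_coverage_floor_must_be_positive():
    site = CytosineSite("chr1", 1, "+", "CG", 0, 5)
    with pytest.raises(ValueError):
        site_passes_coverage(site, min_cov=0)


class TestRegionMethylation:
    def test_pooling_is_read_weighted(self):
        sample = make_sample([("chr1", 5, "+", "CG", 3, 3),
                              ("chr1", 8, "+", "CG", 0, 3)])
        rm = region_methylation(sample, "chr1", 0, 100)
        assert rm.levels["CG"] == pytest.approx(0.5)
        assert rm.n_meth["CG"] == 3 and rm.n_total["CG"] == 6

    def test_site_mean_mode_differs_under_unequal_depth(self):
        sample = make_sample([("chr1", 5, "+", "CG", 9, 9),
                              ("chr1", 8, "+", "CG", 0, 3)])
        weighted = region_methylation(sample, "chr1", 0, 100)
        site_mean = region_methylation(sample, "chr1", 0, 100,
                                       mode="site_mean")
        assert weighted.levels["CG"] == pytest.approx(0.75)
        assert site_mean.levels["CG"] == pytest.approx(0.5)

    def test_low_coverage_site_filtered_leaves_undefined(self):
        sample = make_sample([("chr1", 5, "+", "CHH", 1, 2)])
        rm = region_methylation(sample, "chr1", 0, 100)
        assert isnan(rm.levels["CHH"])
        assert rm.n_sites_passing["CHH"] == 0

    def test_region_without_cytosines_all_undefined(self):
        sample = make_sample([("chr1", 500, "+", "CG", 1, 5)])
        rm = region_methylation(sample, "chr1", 0, 100)
        assert all(isnan(rm.levels[c]) for c in ("CG", "CHG", "CHH"))

    def test_half_open_region_boundaries(self):
        # pos is 1-based; [start, end) covers 0-based positions
        sample = make_sample([("chr1", 10, "+", "CG", 5, 5),
                              ("chr1", 11, "+", "CG", 0, 5)])
        rm = region_methylation(sample, "chr1", 9, 10)  # only 0-based 9 = pos 10
        assert rm.n_total["CG"] == 5 and rm.levels["CG"] == 1.0


sites_strategy = st.lists(
    st.tuples(st.integers(1, 60), st.sampled_from("+-"),
              st.sampled_from(["CG", "CHG", "CHH"]),
              st.integers(0, 10), st.integers(0, 10)),
    min_size=0, max_size=30, unique_by=lambda t: (t[0], t[1]))


@given(sites_strategy, st.integers(1, 59))
def test_pooling_additivity_over_split_regions(raw, cut):
    sample = make_sample([("chr1", pos, strand, ctx, min(m, t), t)
                          for pos, strand, ctx, m, t in raw])
    whole = region_methylation(sample, "chr1", 0, 60)
    left = region_methylation(sample, "chr1", 0, cut)
    right = region_methylation(sample, "chr1", cut, 60)
    for ctx in ("CG", "CHG", "CHH"):
        assert whole.n_meth[ctx] == left.n_meth[ctx] + right.n_meth[ctx]
        assert whole.n_total[ctx] == left.n_total[ctx] + right.n_total[ctx]


@given(sites_strategy, st.integers(1, 8), st.integers(0, 5))
def test_raising_coverage_floor_never_adds_sites(raw, min_cov, bump):
    sample = make_sample([("chr1", pos, strand, ctx, min(m, t), t)
                          for pos, strand, ctx, m, t in raw])
    low = region_methylation(sample, "chr1", 0, 60, min_cov=min_cov)
    high = region_methylation(sample, "chr1", 0, 60, min_cov=min_cov + bump)
    for ctx in ("CG", "CHG", "CHH"):
        assert high.n_sites_passing[ctx] <= low.n_sites_passing[ctx]


@given(sites_strategy)
def test_context_totals_partition_region_total(raw):
    sample = make_sample([("chr1", pos, strand, ctx, min(m, t), t)
                          for pos, strand, ctx, m, t in raw])
    rm = region_methylation(sample, "chr1", 0, 60, min_cov=1)
    pooled = sample.sites[passing_mask(sample.sites, 1)]
    assert sum(rm.n_total.values()) == pooled["n_total"].sum()
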