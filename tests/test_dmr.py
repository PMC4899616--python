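"""Bin tiling, the per-bin exact test, significance selection and merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methdmr import (DmrParams, GenomicBin, MethylomeSample, bin_methylome,
                     call_dmrs, fisher_bin_test)
from methdmr.dmr import merge_significant_bins, significant_mask, evaluate_bins


def make_sample(rows, label="s"):
    return MethylomeSample(label, pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context",
                       "n_meth", "n_total"]))


class TestBinning:
    def test_terminal_bin_truncated(self):
        sample = make_sample([])
        bins = bin_methylome(sample, {"chr1": 120})
        assert list(zip(bins["start"], bins["end"])) == [
            (0, 50), (50, 100), (100, 120)]

    def test_site_at_pos_50_lands_in_first_bin(self):
        sample = make_sample([("chr1", 50, "+", "CG", 2, 4),
                              ("chr1", 51, "+", "CG", 1, 4)])
        bins = bin_methylome(sample, {"chr1": 120})
        assert bins.loc[0, "n_total"] == 4    # 1-based 50 -> 0-based 49
        assert bins.loc[1, "n_total"] == 4
        assert bins.loc[1, "n_meth"] == 1

    def test_empty_bin_retained_with_zero_counts(self):
        sample = make_sample([("chr1", 110, "+", "CG", 1, 5)])
        bins = bin_methylome(sample, {"chr1": 150})
        assert len(bins) == 3
        assert bins.loc[1, "n_total"] == 0

    def test_coverage_filter_applied_per_site(self):
        sample = make_sample([("chr1", 10, "+", "CG", 1, 2),
                              ("chr1", 20, "+", "CG", 1, 3)])
        bins = bin_methylome(sample, {"chr1": 50})
        assert bins.loc[0, "n_total"] == 3 and bins.loc[0, "n_sites"] == 1

    def test_context_restricted_mode(self):
        sample = make_sample([("chr1", 10, "+", "CG", 3, 3),
                              ("chr1", 20, "+", "CHH", 0, 3)])
        bins = bin_methylome(sample, {"chr1": 50},
                             DmrParams(context="CG"))
        assert bins.loc[0, "n_total"] == 3 and bins.loc[0, "n_meth"] == 3


class TestFisherBin:
    def test_identical_proportions_p_one(self):
        result = fisher_bin_test(GenomicBin("chr1", 0, 50, 5, 10, 5, 10))
        assert result.p_value == 1.0
        assert result.direction == "none" and result.delta == 0.0

    def test_extreme_table_hyper(self):
        result = fisher_bin_test(GenomicBin("chr1", 0, 50, 0, 10, 10, 10))
        assert result.direction == "hyper"
        assert result.p_value == pytest.approx(1.0825088e-05, rel=1e-6)

    def test_untestable_when_one_sample_empty(self):
        result = fisher_bin_test(GenomicBin("chr1", 0, 50, 0, 0, 5, 10))
        assert np.isnan(result.p_value) and result.direction == "none"


def dmr_spans(dmrs):
    return [(d.start, d.end) for d in dmrs]


def paired_samples(sig_bins, length=300, depth=30):
    """Two samples whose significant bins are exactly ``sig_bins`` (by index):
    wt all-unmethylated, mutant fully methylated in the chosen bins."""
    wt_rows, mut_rows = [], []
    n_bins = length // 50
    for b in range(n_bins):
        pos = b * 50 + 25
        wt_rows.append(("chr1", pos, "+", "CG", 0, depth))
        mut_rows.append(("chr1", pos, "+", "CG",
                         depth if b in sig_bins else 0, depth))
    return make_sample(wt_rows, "wt"), make_sample(mut_rows, "mut")


class TestMerging:
    def test_gap_of_50_merges(self):
        wt, mut = paired_samples({0, 2})   # bins [0,50) and [100,150): gap 50
        dmrs = call_dmrs(wt, mut, {"chr1": 300}, annotate_levels=False)
        assert dmr_spans(dmrs) == [(0, 150)]

    def test_gap_of_100_does_not_merge(self):
        wt, mut = paired_samples({0, 3})   # [0,50) and [150,200): gap 100
        dmrs = call_dmrs(wt, mut, {"chr1": 300}, annotate_levels=False)
        assert dmr_spans(dmrs) == [(0, 50), (150, 200)]

    def test_gap_of_51_does_not_merge(self):
        # shifted tiling via raw merge: significant intervals with gap 51
        bins = pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "start": [0, 101], "end": [50, 151]})
        merged = merge_significant_bins(bins, merge_gap=50)
        assert len(merged) == 2

    def test_merging_idempotent_and_order_independent(self):
        bins = pd.DataFrame({"chrom": ["chr1"] * 4,
                             "start": [200, 0, 100, 400],
                             "end": [250, 50, 150, 450]})
        shuffled = bins.sample(frac=1, random_state=1)
        a = merge_significant_bins(bins, 50)
        b = merge_significant_bins(shuffled, 50)
        assert [(c, s, e) for c, s, e, _ in a] \
            == [(c, s, e) for c, s, e, _ in b] \
            == [("chr1", 0, 250), ("chr1", 400, 450)]

    def test_mismatched_chromosomes_fatal(self):
        wt, _ = paired_samples({0})
        other = make_sample([("chrX", 10, "+", "CG", 0, 10)])
        with pytest.raises(ValueError, match="chromosomes"):
            call_dmrs(wt, other, {"chr1": 300})


def test_monotone_in_alpha_and_min_delta(small_pair):
    wt, mut = small_pair["wt"], small_pair["mut"]
    lengths = small_pair["genome"].lengths
    counts = {}
    for alpha, delta in [(0.05, 0.05), (0.01, 0.1), (0.001, 0.2)]:
        params = DmrParams(alpha=alpha, min_delta=delta)
        counts[(alpha, delta)] = len(call_dmrs(wt, mut, lengths, params,
                                               annotate_levels=False))
    assert counts[(0.05, 0.05)] >= counts[(0.01, 0.1)] \
        >= counts[(0.001, 0.2)]


def test_zero_coverage_bins_untestable(small_pair):
    wt, mut = small_pair["wt"], small_pair["mut"]
    lengths = small_pair["genome"].lengths
    params = DmrParams()
    bins_wt = bin_methylome(wt, lengths, params)
    bins_mut = bin_methylome(mut, lengths, params)
    tested = evaluate_bins(bins_wt, bins_mut, params)
    empty = (tested["total_a"] == 0) | (tested["total_b"] == 0)
    assert tested.loc[empty, "p"].isna().all()
    assert not significant_mask(tested, params)[empty.to_numpy()].any()


def test_planted_regions_all_intersected(small_pair):
    """End-to-end on the simulated pair: every planted hyper-DMR is hit."""
    dmrs = call_dmrs(small_pair["wt"], small_pair["mut"],
                     small_pair["genome"].lengths, annotate_levels=False)
    for region in small_pair["planted"]:
        assert any(d.chrom == region.chrom and d.start < region.end
                   and d.end > region.start for d in dmrs), region


def test_dmr_direction_and_levels_annotated(small_pair):
    dmrs = call_dmrs(small_pair["wt"], small_pair["mut"],
                     small_pair["genome"].lengths)
    assert dmrs, "expected at least one call"
    for d in dmrs:
        assert d.direction == "hyper"
        assert d.end - d.start >= 50
        cg_wt, cg_mut = d.meth_a.levels["CG"], d.meth_b.levels["CG"]
        if not (np.isnan(cg_wt) or np.isnan(cg_mut)):
            assert cg_mut > cg_wt
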