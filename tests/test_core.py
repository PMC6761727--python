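import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cortexmeth import core
from cortexmeth.core import (
    ReportParseError,
    annotate_context,
    assign_age_group,
    cluster_positions,
    context_accumulation,
    context_from_trinucleotide,
    filter_by_coverage,
    read_cytosine_report,
    write_cytosine_report,
)


class TestContextRules:
    @pytest.mark.parametrize("tri,ctx", [
        ("CGA", "CpG"), ("CGT", "CpG"), ("CAG", "CHG"), ("CTG", "CHG"),
        ("CAC", "CHH"), ("CAA", "CHH"), ("CTT", "CHH"), ("CCC", "CHH"),
    ])
    def test_context_is_function_of_trinucleotide(self, tri, ctx):
        assert context_from_trinucleotide(tri) == ctx

    @pytest.mark.parametrize("seq,pos,strand,expect", [
        ("TACGAT", 3, "+", ("CpG", "CGA")),
        ("TACAGT", 3, "+", ("CHG", "CAG")),
        ("TACACT", 3, "+", ("CHH", "CAC")),
        # minus strand: G at pos, trinucleotide read on the reverse complement
        ("TTCGAA", 4, "-", ("CpG", "CGA")),
    ])
    def test_annotate_context(self, seq, pos, strand, expect):
        assert annotate_context(seq, pos, strand) == expect

    def test_not_a_c_raises(self):
        with pytest.raises(ValueError, match="not a C"):
            annotate_context("TAAGAT", 3, "+")

    def test_truncated_downstream_raises(self):
        with pytest.raises(ValueError, match="downstream"):
            annotate_context("TACG", 3, "+")

    def test_reverse_complement_context_multiset(self):
        """A sequence and its reverse complement carry the same contexts."""
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 300))
        rc = core.reverse_complement(seq)

        def contexts(s):
            out = []
            for strand in "+-":
                base = "C" if strand == "+" else "G"
                for i, ch in enumerate(s):
                    if ch == base:
                        try:
                            out.append(annotate_context(s, i + 1, strand)[0])
                        except ValueError:
                            pass
            return sorted(out)

        assert contexts(seq) == contexts(rc)


class TestAgeGroups:
    @pytest.mark.parametrize("age,group", [
        (0.0, "infant"), (1.0, "infant"), (1.01, "child"), (10.0, "child"),
        (10.5, "teen"), (17.0, "teen"), (17.1, "adult"), (80.0, "adult"),
    ])
    def test_boundaries(self, age, group):
        assert assign_age_group(age) == group


class TestReportIO:
    def test_single_line_beta(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("chr1\t105\t+\t3\t7\tCpG\tCGA\n")
        mat = read_cytosine_report({"s": p})
        assert mat.n_sites == 1
        assert mat.beta()[0, 0] == pytest.approx(0.3)
        assert mat.sites["context"].iloc[0] == "CpG"

    def test_zero_coverage_retained_and_flagged_missing(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("chr1\t105\t+\t0\t0\tCpG\tCGA\n")
        mat = read_cytosine_report({"s": p})
        assert mat.n_sites == 1
        assert np.isnan(mat.beta()[0, 0])

    def test_three_sample_matrix_matches_hand_built(self, tmp_path, tiny_matrix):
        for s in tiny_matrix.samples:
            write_cytosine_report(tiny_matrix, s, tmp_path / f"{s}.txt")
        back = read_cytosine_report(
            {s: tmp_path / f"{s}.txt" for s in tiny_matrix.samples},
            samples=tiny_matrix.samples,
        )
        assert back.samples == tiny_matrix.samples
        np.testing.assert_array_equal(back.meth, tiny_matrix.meth)
        np.testing.assert_array_equal(back.total, tiny_matrix.total)
        pd.testing.assert_frame_equal(back.sites, tiny_matrix.sites)

    def test_malformed_count_reports_line_number(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("chr1\t10\t+\t1\t1\tCpG\tCGA\nchr1\t20\t+\tx\t1\tCpG\tCGT\n")
        with pytest.raises(ReportParseError, match="line 2"):
            read_cytosine_report({"s": p})

    def test_context_trinucleotide_mismatch_rejected(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("chr1\t10\t+\t1\t1\tCpG\tCAC\n")
        with pytest.raises(ReportParseError, match="context"):
            read_cytosine_report({"s": p})


class TestCoverageFilter:
    def test_site_below_min_cov_in_one_sample_dropped(self, tiny_matrix):
        m = tiny_matrix
        kept = filter_by_coverage(m, 3)
        expect = (m.total >= 3).all(axis=1)
        assert kept.n_sites == expect.sum()

    def test_min_positive_samples_rule(self):
        sites = pd.DataFrame({
            "chrom": ["chr1"], "pos": [10], "strand": ["+"],
            "context": ["CHH"], "trinucleotide": ["CAC"]})
        meth = np.array([[1, 1, 1, 1, 0, 0]])
        total = np.full((1, 6), 10)
        m = core.CytosineMatrix(sites, meth, total, list("abcdef"))
        assert filter_by_coverage(m, 5, min_positive_samples=5).n_sites == 0
        assert filter_by_coverage(m, 5, min_positive_samples=4).n_sites == 1

    def test_matches_brute_force_and_monotone(self, study):
        _, matrix, _, _ = study
        sub = matrix.subset(np.arange(2000))
        kept = filter_by_coverage(sub, 4, min_positive_samples=3)
        beta = sub.beta()
        brute = [
            i for i in range(sub.n_sites)
            if (sub.total[i] >= 4).all()
            and np.nansum(np.nan_to_num(beta[i]) > 0) >= 3
        ]
        np.testing.assert_array_equal(
            kept.sites["pos"].to_numpy(), sub.sites["pos"].to_numpy()[brute])
        # monotone: raising min_cov never adds sites
        assert filter_by_coverage(sub, 6).n_sites <= filter_by_coverage(sub, 4).n_sites


class TestClusterPositions:
    def test_known_gaps(self):
        labels = cluster_positions(np.array([1, 500, 1600, 3000]), 1000)
        np.testing.assert_array_equal(labels, [0, 0, 1, 2])

    def test_singleton(self):
        np.testing.assert_array_equal(cluster_positions(np.array([42]), 1000), [0])

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="increasing"):
            cluster_positions(np.array([5, 3, 10]), 100)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 100_000), min_size=1, max_size=300),
           st.integers(1, 5000))
    def test_matches_brute_force(self, raw, max_gap):
        pos = np.unique(np.asarray(raw))
        labels = cluster_positions(pos, max_gap)
        # O(n^2) oracle: same cluster iff chain of gaps <= max_gap connects
        expect = np.zeros(len(pos), dtype=int)
        for i in range(1, len(pos)):
            expect[i] = expect[i - 1] + (pos[i] - pos[i - 1] > max_gap)
        np.testing.assert_array_equal(labels, expect)

    def test_chromosomes_never_share_labels(self):
        pos = np.array([10, 20, 10, 20])
        chroms = np.array(["chr1", "chr1", "chr2", "chr2"])
        labels = cluster_positions(pos, 1000, chroms)
        assert labels[1] != labels[2]


class TestContextAccumulation:
    def test_known_proportion(self):
        sites = pd.DataFrame({
            "chrom": ["chr1"] * 10, "pos": range(10, 110, 10),
            "strand": ["+"] * 10, "context": ["CHH"] * 10,
            "trinucleotide": ["CAC"] * 10})
        meth = np.array([[3], [2], [0], [0], [0], [0], [0], [0], [0], [0]])
        total = np.full((10, 1), 10)
        m = core.CytosineMatrix(sites, meth, total, ["s"])
        out = context_accumulation(m, threshold=0.10)
        assert out.loc["s", "CAC"] == pytest.approx(0.2)

    def test_all_zero_gives_zero(self, tiny_matrix):
        m = tiny_matrix
        m2 = core.CytosineMatrix(m.sites, np.zeros_like(m.meth),
                                 np.maximum(m.total, 1), m.samples)
        out = context_accumulation(m2)
        assert (out.fillna(0) == 0).all().all()

    def test_neuronal_aging_increases_cac_methylation(self, study):
        """Planted neuronal CpH accumulation: the >10% methylated CAC share
        rises monotonically in age across neuron samples."""
        _, matrix, meta, _ = study
        cph = matrix.select_context("CpH")
        out = context_accumulation(cph, threshold=0.10, classes=["CAC"])
        neurons = meta[meta["cell_fraction"] == "neuron"].sort_values("age")
        series = out.loc[neurons["sample_id"], "CAC"].to_numpy()
        # allow sampling jitter: fit a line, slope must be clearly positive
        slope = np.polyfit(neurons["age"], series, 1)[0]
        assert slope > 0
        assert series[-1] > series[0]
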