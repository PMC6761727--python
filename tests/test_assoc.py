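import numpy as np
import pandas as pd
import pytest

import cortexmeth as cm
from cortexmeth.core import CytosineMatrix
from cortexmeth.assoc import (
    age_confound_check,
    annotate_records,
    cis_scan,
    feature_windows,
    filter_associations,
    filter_expression,
    group_mean_correlation,
    marginal_cpg_rescue,
    summarize_associations,
)


def matrix_from_beta(positions, beta, samples, contexts=None):
    n = len(positions)
    contexts = contexts or ["CpG"] * n
    tri = ["CGA" if c == "CpG" else ("CAG" if c == "CHG" else "CAC")
           for c in contexts]
    sites = pd.DataFrame({"chrom": ["chr1"] * n, "pos": positions,
                          "strand": ["+"] * n, "context": contexts,
                          "trinucleotide": tri})
    total = np.full((n, len(samples)), 10_000)
    meth = np.round(np.asarray(beta) * total).astype(int)
    return CytosineMatrix(sites, meth, total, samples)


class TestFilterExpression:
    def test_gene_mean_boundary_strict(self):
        df = pd.DataFrame({"feature_id": ["a", "b"],
                           "s1": [0.22, 0.23], "s2": [0.22, 0.23]})
        out = filter_expression(df, "gene", ["s1", "s2"])
        assert list(out["feature_id"]) == ["b"]

    def test_exon_transform_applied(self):
        df = pd.DataFrame({"feature_id": ["e"], "s1": [3.0], "s2": [1.0]})
        out = filter_expression(df, "exon", ["s1", "s2"])
        assert out["s1"].iloc[0] == pytest.approx(2.0)   # log2(3+1)

    def test_psi_denominator_rule(self):
        df = pd.DataFrame({"feature_id": ["p", "q"], "min_denominator": [9, 10],
                           "s1": [0.5, 0.5]})
        out = filter_expression(df, "psi", ["s1"])
        assert list(out["feature_id"]) == ["q"]

    def test_brute_force_survivors(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(5)]
        df = pd.DataFrame(rng.exponential(0.3, (10, 5)), columns=cols)
        df.insert(0, "feature_id", [f"g{i}" for i in range(10)])
        out = filter_expression(df, "gene", cols)
        expect = df[df[cols].mean(axis=1) > 0.22]["feature_id"]
        assert list(out["feature_id"]) == list(expect)


class TestCisScan:
    def setup_toy(self, n=22, seed=0, slope=-2.0, r2=0.9):
        rng = np.random.default_rng(seed)
        samples = [f"d{i}" for i in range(n)]
        beta = rng.uniform(0.1, 0.9, (3, n))
        mat = matrix_from_beta([500, 1200, 5000], beta, samples)
        sd = abs(slope) * beta[0].std() * np.sqrt((1 - r2) / r2)
        y = 3 + slope * beta[0] + rng.normal(0, sd, n)
        expr = pd.DataFrame([{"feature_id": "g1", **dict(zip(samples, y))}])
        feats = pd.DataFrame({"feature_id": ["g1"], "gene_id": ["g1"],
                              "chrom": ["chr1"], "start": [300], "end": [800]})
        return mat, expr, feats, samples

    def test_t_matches_correlation_identity(self):
        mat, expr, feats, samples = self.setup_toy()
        out = cis_scan(mat, expr, feats, samples, p_threshold=1.0)
        y = expr[samples].to_numpy(float)[0]
        for _, rec in out.iterrows():
            x = mat.beta()[rec["site_index"]]
            r = np.corrcoef(x, y)[0, 1]
            t_expect = r * np.sqrt((len(x) - 2) / (1 - r**2))
            assert rec["t"] == pytest.approx(t_expect, abs=1e-8)

    def test_window_rule_closed_at_1kb(self):
        mat, expr, feats, samples = self.setup_toy()
        # sites at 500 (inside), 1200 (within 1 kb of end=800), 5000 (outside)
        out = cis_scan(mat, expr, feats, samples, p_threshold=1.0)
        tested = set(out["pos"])
        assert 5000 not in tested and {500, 1200} <= tested
        # a site exactly at distance 1000 from the span edge is included
        mat2, expr2, feats2, s2 = self.setup_toy()
        mat2.sites.loc[2, "pos"] = 1800    # end 800 + 1000, closed boundary
        out2 = cis_scan(mat2, expr2, feats2, s2, p_threshold=1.0)
        assert 1800 in set(out2["pos"])
        mat2.sites.loc[2, "pos"] = 1801
        out3 = cis_scan(mat2, expr2, feats2, s2, p_threshold=1.0)
        assert 1801 not in set(out3["pos"])

    def test_affine_rescaling_of_expression_keeps_t_and_p(self):
        mat, expr, feats, samples = self.setup_toy()
        out = cis_scan(mat, expr, feats, samples, p_threshold=1.0)
        expr2 = expr.copy()
        expr2[samples] = 7.0 * expr2[samples] - 3.0
        out2 = cis_scan(mat, expr2, feats, samples, p_threshold=1.0)
        np.testing.assert_allclose(out["t"], out2["t"], atol=1e-9)
        np.testing.assert_allclose(out["p"], out2["p"], atol=1e-12)
        np.testing.assert_allclose(out2["slope"], 7.0 * out["slope"], rtol=1e-9)

    def test_zero_variance_beta_skipped(self):
        samples = [f"d{i}" for i in range(10)]
        mat = matrix_from_beta([500], np.full((1, 10), 0.5), samples)
        expr = pd.DataFrame([{"feature_id": "g1",
                              **{s: float(i) for i, s in enumerate(samples)}}])
        feats = pd.DataFrame({"feature_id": ["g1"], "gene_id": ["g1"],
                              "chrom": ["chr1"], "start": [300], "end": [800]})
        out = cis_scan(mat, expr, feats, samples, p_threshold=1.0)
        assert len(out) == 0


class TestMarginalRescue:
    def test_no_cpg_in_window_is_exclusive(self):
        samples = [f"d{i}" for i in range(12)]
        rng = np.random.default_rng(1)
        beta = rng.uniform(0.1, 0.9, (1, 12))
        mat = matrix_from_beta([500], beta, samples, contexts=["CHH"])
        y = 2 - 2 * beta[0]
        expr = pd.DataFrame([{"feature_id": "g1", **dict(zip(samples, y))}])
        feats = pd.DataFrame({"feature_id": ["g1"], "gene_id": ["g1"],
                              "chrom": ["chr1"], "start": [300], "end": [800]})
        hits = cis_scan(mat, expr, feats, samples, p_threshold=1.0)
        _, cls = marginal_cpg_rescue(hits, mat, expr, feats, samples)
        assert cls["g1"] == "CpH-exclusive"

    def test_shared_effect_classified_shared(self):
        samples = [f"d{i}" for i in range(12)]
        rng = np.random.default_rng(2)
        b = rng.uniform(0.1, 0.9, 12)
        beta = np.vstack([b, b + rng.normal(0, 0.01, 12)])
        mat = matrix_from_beta([500, 700], np.clip(beta, 0, 1), samples,
                               contexts=["CHH", "CpG"])
        y = 2 - 2 * b
        expr = pd.DataFrame([{"feature_id": "g1", **dict(zip(samples, y))}])
        feats = pd.DataFrame({"feature_id": ["g1"], "gene_id": ["g1"],
                              "chrom": ["chr1"], "start": [300], "end": [800]})
        hits = cis_scan(mat.select_context("CpH"), expr, feats, samples,
                        p_threshold=1.0)
        marg, cls = marginal_cpg_rescue(hits, mat, expr, feats, samples)
        assert cls["g1"] == "shared"
        assert (marg["label"] == "marginal").all()


class TestRecordFilters:
    def records(self):
        return pd.DataFrame({
            "feature_id": ["f1", "f2", "f3"],
            "gene_id": ["g1", "g2", "g3"],
            "n_nonzero_meth": [10, 11, 22],
            "n_nonone_meth": [22, 11, 22],
            "t": [3.0, 4.0, np.inf],
        })

    def test_thresholds_and_infinite_t(self):
        out = filter_associations(self.records())
        assert list(out["feature_id"]) == ["f2"]

    def test_protein_coding_restriction(self):
        feats = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                              "protein_coding": [True, False, True]})
        out = filter_associations(self.records(), feats)
        assert len(out) == 0     # f2 fails coding, others fail counts/t


class TestAgeConfound:
    def build(self, expression_from, n=22, seed=3):
        rng = np.random.default_rng(seed)
        samples = [f"d{i}" for i in range(n)]
        ages = np.linspace(0, 23, n)
        meta = cm.make_sample_meta(samples, ["neuron"] * n, ages)
        if expression_from == "beta":
            b = rng.uniform(0.1, 0.9, n)
            y = 1 - b + rng.normal(0, 0.05, n)
        else:                     # beta is a pure function of age
            b = 0.1 + 0.035 * ages
            y = 0.5 + 0.04 * ages + rng.normal(0, 0.05, n)
        mat = matrix_from_beta([500], b[None, :], samples)
        expr = pd.DataFrame([{"feature_id": "g1", **dict(zip(samples, y))}])
        rec = pd.DataFrame([{"feature_id": "g1", "feature_type": "gene",
                             "site_index": 0}])
        return rec, mat, {"gene": expr}, meta, samples

    def test_independent_beta_not_flagged(self):
        rec, mat, expr, meta, donors = self.build("beta")
        out = age_confound_check(rec, mat, expr, meta, donors)
        assert not out["age_confounded"].iloc[0]

    def test_age_driven_association_flagged(self):
        rec, mat, expr, meta, donors = self.build("age")
        out = age_confound_check(rec, mat, expr, meta, donors)
        assert out["age_confounded"].iloc[0]


class TestGroupMeanCorrelation:
    def test_constructed_anticorrelation(self):
        rng = np.random.default_rng(4)
        n_feat = 15
        samples = [f"d{i}" for i in range(6)]
        ages = [0.5, 0.5, 5, 5, 15, 15]
        meta = cm.make_sample_meta(samples, ["neuron"] * 6, ages)
        positions = np.arange(n_feat) * 10_000 + 1000
        beta = rng.uniform(0.1, 0.9, (n_feat, 6))
        mat = matrix_from_beta(positions, beta, samples)
        feats = pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(n_feat)],
            "start": positions - 100, "end": positions + 100})
        windows = feature_windows(feats.assign(chrom="chr1"), "gene")
        expr = pd.DataFrame(3 - 2 * beta, columns=samples)
        expr.insert(0, "feature_id", feats["feature_id"])
        out = group_mean_correlation(mat, expr, meta, windows, samples)
        body = out[out["window"] == "gene body"].dropna(subset=["rho"])
        assert (body["rho"] < -0.8).all()


class TestSummary:
    def test_summary_matches_brute_force(self):
        rng = np.random.default_rng(5)
        n = 60
        rec = pd.DataFrame({
            "feature_id": [f"f{i%10}" for i in range(n)],
            "feature_type": ["gene"] * n,
            "gene_id": [f"g{i%10}" for i in range(n)],
            "chrom": ["chr1"] * n,
            "pos": rng.integers(0, 10_000, n),
            "context": rng.choice(["CpG", "CHG", "CHH"], n),
            "slope": rng.normal(0, 1, n),
            "n_nonzero_meth": rng.integers(11, 23, n),
            "n_nonone_meth": rng.integers(11, 23, n),
            "expr_change": rng.normal(0, 1, n),
            "annotation": rng.choice(["promoter", "gene body", "flanking"], n),
            "age_confounded": rng.random(n) < 0.2,
        })
        out = summarize_associations(rec)
        grp = out.set_index(["feature_type", "meth_type", "direction"])
        sub = rec[(rec["context"] == "CpG") & (rec["slope"] > 0)]
        if len(sub):
            row = grp.loc[("gene", "CpG", "Up")]
            assert row["n"] == len(sub)
            assert row["prop_promoter"] == pytest.approx(
                (sub["annotation"] == "promoter").mean())
            assert row["mean_expr_change"] == pytest.approx(
                sub["expr_change"].abs().mean())
        # annotation proportions partition to one in every row
        props = out[["prop_promoter", "prop_gene_body", "prop_flanking"]].sum(axis=1)
        np.testing.assert_allclose(props, 1.0)

    def test_all_promoter_toy_set(self):
        rec = pd.DataFrame({
            "feature_id": ["f"], "feature_type": ["gene"], "gene_id": ["g"],
            "chrom": ["chr1"], "pos": [5], "context": ["CpG"], "slope": [-1.0],
            "n_nonzero_meth": [22], "n_nonone_meth": [22],
            "expr_change": [-0.5], "annotation": ["promoter"],
        })
        out = summarize_associations(rec)
        assert out["prop_promoter"].iloc[0] == 1.0


def test_annotate_records_locations():
    genes = pd.DataFrame({"gene_id": ["g"], "start": [10_000], "end": [20_000]})
    rec = pd.DataFrame({
        "gene_id": ["g", "g", "g"],
        "pos": [9_500, 15_000, 22_000],    # promoter, body, flanking (1-based)
    })
    out = annotate_records(rec, genes)
    assert list(out["annotation"]) == ["promoter", "gene body", "flanking"]
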