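import numpy as np
import pandas as pd
import pytest

from cortexmeth.dmr import (
    DesignSpec,
    bumphunt,
    compare_designs,
    fit_sitewise,
    moderated_test,
)


def sites_frame(n, spacing=100):
    return pd.DataFrame({"chrom": ["chr1"] * n,
                         "pos": np.arange(1, n + 1) * spacing})


class TestFitSitewise:
    def test_exact_linear_surface_recovered(self, meta24):
        cell = (meta24["cell_fraction"] == "neuron").to_numpy(float)
        Y = (0.5 + 0.1 * cell)[None, :].repeat(5, axis=0)
        st = fit_sitewise(Y, meta24, DesignSpec("age_plus_cell", "cell"))
        np.testing.assert_allclose(st["coef"], 0.1, atol=1e-12)
        np.testing.assert_allclose(st["s2"], 0.0, atol=1e-20)

    def test_matches_closed_form_normal_equations(self, meta24):
        rng = np.random.default_rng(0)
        sub = meta24.iloc[[0, 1, 2, 12, 13, 14]].reset_index(drop=True)
        Y = rng.random((40, 6))
        des = DesignSpec("age_plus_cell", "cell")
        st = fit_sitewise(Y, sub, des)
        X, names = des.matrix(sub)
        j = names.index("cell")
        expect = (np.linalg.inv(X.T @ X) @ X.T @ Y.T)[j]
        np.testing.assert_allclose(st["coef"], expect, atol=1e-10)

    def test_null_coefficients_center_at_zero(self, meta24):
        rng = np.random.default_rng(1)
        Y = rng.normal(0.5, 0.05, (4000, 24))
        st = fit_sitewise(Y, meta24, DesignSpec("age_plus_cell", "cell"))
        se = st["coef"].std() / np.sqrt(len(st))
        assert abs(st["coef"].mean()) < 4 * se

    def test_rank_deficient_design_names_columns(self, meta24):
        meta = meta24.copy()
        meta["cell_fraction"] = "neuron"     # cell column constant
        with pytest.raises(ValueError, match="cell"):
            fit_sitewise(np.random.default_rng(0).random((5, 24)), meta,
                         DesignSpec("age_plus_cell", "cell"))


@pytest.fixture(scope="module")
def null_stats():
    rng = np.random.default_rng(2)
    import cortexmeth as cm
    ages = list(np.linspace(0, 23, 12))
    meta = cm.make_sample_meta(
        [f"S{i}" for i in range(24)], ["neuron"] * 12 + ["glia"] * 12,
        ages + ages)
    s_true = 0.05 * np.sqrt(4.0 / rng.chisquare(4.0, 5000))
    Y = rng.normal(0.5, s_true[:, None], (5000, 24))
    return fit_sitewise(Y, meta, DesignSpec("age_plus_cell", "cell"))


class TestModeratedTest:

    def test_infinite_prior_df_shrinks_everything_to_prior(self, null_stats):
        out = moderated_test(null_stats, d0=np.inf, s0_2=0.01)
        assert np.allclose(out["s2_post"], 0.01)

    def test_zero_prior_df_recovers_ordinary_t(self, null_stats):
        out = moderated_test(null_stats, d0=0.0, s0_2=123.0)
        ordinary = null_stats["coef"] / (
            null_stats["stdev_unscaled"] * np.sqrt(null_stats["s2"]))
        np.testing.assert_allclose(out["t"], ordinary)

    def test_posterior_variance_between_prior_and_sample(self, null_stats):
        out = moderated_test(null_stats)
        s0 = out.attrs["s0_2"]
        lo = np.minimum(null_stats["s2"], s0)
        hi = np.maximum(null_stats["s2"], s0)
        assert ((out["s2_post"] >= lo - 1e-12) & (out["s2_post"] <= hi + 1e-12)).all()

    def test_q_monotone_in_p(self, null_stats):
        out = moderated_test(null_stats).sort_values("p")
        assert (np.diff(out["q"]) >= -1e-12).all()

    def test_requires_site_ensemble(self, null_stats):
        with pytest.raises(ValueError, match="sites"):
            moderated_test(null_stats.head(10))


class TestBumphunt:
    def make_signal(self, meta24, n=800, bump=slice(300, 310), delta=0.2, seed=0):
        rng = np.random.default_rng(seed)
        cell = (meta24["cell_fraction"] == "neuron").to_numpy(float)
        Y = rng.normal(0.6, 0.05, (n, 24))
        Y[bump] += delta * (cell - 0.5)
        return Y, sites_frame(n)

    def test_planted_bump_detected(self, meta24):
        Y, sites = self.make_signal(meta24)
        out = bumphunt(Y, sites, meta24, DesignSpec("age_plus_cell", "cell"),
                       cutoff=0.1, n_perms=60, seed=3)
        sig = out[out["fwer"] < 0.05]
        assert len(sig) >= 1
        top = sig.iloc[0]
        assert top["index_start"] <= 305 <= top["index_end"]

    def test_sign_flip_symmetry(self, meta24):
        Y, sites = self.make_signal(meta24)
        a = bumphunt(Y, sites, meta24, DesignSpec("age_plus_cell", "cell"),
                     cutoff=0.1, n_perms=40, seed=3)
        b = bumphunt(1 - Y, sites, meta24, DesignSpec("age_plus_cell", "cell"),
                     cutoff=0.1, n_perms=40, seed=3)
        a_top, b_top = a.iloc[0], b.iloc[0]
        assert a_top["index_start"] == b_top["index_start"]
        assert a_top["direction"] == -b_top["direction"]
        assert a_top["area"] == pytest.approx(b_top["area"], rel=1e-9)

    def test_single_cpg_region_is_valid(self, meta24):
        Y, sites = self.make_signal(meta24, bump=slice(300, 301), delta=0.6)
        out = bumphunt(Y, sites, meta24, DesignSpec("age_plus_cell", "cell"),
                       cutoff=0.1, n_perms=60, seed=4)
        sig = out[out["fwer"] < 0.05]
        assert (sig["ncpg"] == 1).any()

    def test_seed_reproducibility_and_fwer_range(self, meta24):
        Y, sites = self.make_signal(meta24)
        des = DesignSpec("age_plus_cell", "cell")
        a = bumphunt(Y, sites, meta24, des, cutoff=0.1, n_perms=40, seed=9)
        b = bumphunt(Y, sites, meta24, des, cutoff=0.1, n_perms=40, seed=9)
        pd.testing.assert_frame_equal(a.drop(columns=[]), b)
        assert ((a["fwer"] >= 0) & (a["fwer"] <= 1)).all()
        # FWER non-increasing in area
        srt = a.sort_values("area")
        assert (np.diff(srt["fwer"]) <= 1e-12).all()

    def test_refuses_too_few_permutations(self, meta24):
        Y, sites = self.make_signal(meta24)
        with pytest.raises(ValueError, match="perm"):
            bumphunt(Y, sites, meta24, DesignSpec("age_plus_cell", "cell"),
                     cutoff=0.1, n_perms=10)

    def test_max_gap_splits_candidates(self, meta24):
        Y, sites = self.make_signal(meta24, bump=slice(300, 310))
        sites.loc[305:, "pos"] += 5000    # gap inside the bump
        out = bumphunt(Y, sites, meta24, DesignSpec("age_plus_cell", "cell"),
                       cutoff=0.1, n_perms=40, seed=5)
        big = out[out["ncpg"] >= 4]
        assert len(big) >= 2              # the bump is split by the cluster gap


class TestCompareDesigns:
    def moderated(self, Y, meta, kind, coef):
        return moderated_test(fit_sitewise(Y, meta, DesignSpec(kind, coef)))

    def test_identical_inputs_concordant(self, meta24):
        rng = np.random.default_rng(6)
        ages = meta24["age"].to_numpy()
        Y = 0.4 + 0.01 * ages[None, :] + rng.normal(0, 0.02, (500, 24))
        ct = self.moderated(Y, meta24, "age_plus_cell", "age")
        rep = compare_designs(ct, ct, p_threshold=1e-4)
        assert rep["coef_correlation"] == pytest.approx(1.0)
        assert rep["missed_fraction"] == 0.0

    def test_opposite_cell_effects_vanish_in_homogenate(self, meta24):
        """Mixture oracle: where neurons gain and glia lose methylation with
        age, a 50/50 homogenate shows no age effect, so cell-type-resolved
        age signal goes undetected in homogenate fits."""
        import cortexmeth as cm
        rng = np.random.default_rng(7)
        ages = np.linspace(0, 23, 12)
        n_sites = 400
        cell_Y = np.empty((n_sites, 24))
        hom_Y = np.empty((n_sites, 12))
        slope = 0.012
        for i in range(n_sites):
            neuron = 0.5 + slope * ages + rng.normal(0, 0.01, 12)
            glia = 0.5 - slope * ages + rng.normal(0, 0.01, 12)
            cell_Y[i] = np.concatenate([neuron, glia])
            hom_Y[i] = (neuron + glia) / 2 + rng.normal(0, 0.01, 12)
        hom_meta = cm.make_sample_meta(
            [f"H{i}" for i in range(12)], ["homogenate"] * 12, ages)
        ct = self.moderated(cell_Y, meta24, "age_by_cell_interaction", "age:cell")
        hm = self.moderated(hom_Y, hom_meta, "age_only", "age")
        rep = compare_designs(ct, hm, p_threshold=1e-4)
        assert rep["missed_fraction"] > 0.9

    def test_empty_intersection_raises(self, meta24):
        rng = np.random.default_rng(8)
        Y = rng.random((200, 24))
        ct = self.moderated(Y, meta24, "age_plus_cell", "age")
        other = ct.copy()
        other.index = other.index + 10_000
        with pytest.raises(ValueError, match="shared"):
            compare_designs(ct, other)
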