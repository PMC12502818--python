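"""Diversity, ordination, PERMANOVA and dispersion-test behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import skbio
from dysbiome.coredata import CountTable, DysbiomeError
from dysbiome.ecostats import (
    DistanceMatrix,
    alpha_diversity,
    dispersion_test,
    dissimilarity,
    nmds,
    pcoa,
    permanova,
)


def _euclid_dm(points, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(np.atleast_2d(points))), ids,
                          "euclidean")


class TestAlphaDiversity:
    def test_chao1_without_rare_taxa_equals_richness(self):
        df = pd.DataFrame([[5, 9, 3]], index=["s"], columns=list("abc"))
        assert alpha_diversity(CountTable(df), "chao1")["s"] == 3

    def test_chao1_plug_in_formula(self):
        # two singletons, no doubletons: 2 + 2*1/(2*1) = 3
        df = pd.DataFrame([[1, 1, 0]], index=["s"], columns=list("abc"))
        assert alpha_diversity(CountTable(df), "chao1")["s"] == pytest.approx(3.0)

    def test_shannon_effective_uniform_equals_richness(self):
        df = pd.DataFrame([[7] * 5], index=["s"], columns=list("abcde"))
        got = alpha_diversity(CountTable(df), "shannon_effective")["s"]
        assert got == pytest.approx(5.0, rel=1e-12)

    def test_empty_sample_flagged_missing(self):
        df = pd.DataFrame([[0, 0], [1, 2]], index=["z", "s"], columns=["a", "b"])
        with pytest.warns(UserWarning):
            out = alpha_diversity(CountTable(df), "chao1")
        assert np.isnan(out["z"]) and not np.isnan(out["s"])


class TestDissimilarity:
    def test_identical_and_disjoint_samples(self):
        df = pd.DataFrame([[2, 0], [2, 0], [0, 3]], index=list("abc"),
                          columns=["x", "y"])
        d = dissimilarity(CountTable(df), "bray_curtis")
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_bray_curtis_known_value(self):
        df = pd.DataFrame([[2, 0], [1, 1]], index=["a", "b"], columns=["x", "y"])
        d = dissimilarity(CountTable(df), "bray_curtis")
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_jaccard_on_presence_absence(self):
        df = pd.DataFrame([[5, 1, 0], [3, 0, 0]], index=["a", "b"],
                          columns=list("xyz"))
        d = dissimilarity(CountTable(df), "jaccard")
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_permutation_equivariance(self, small_cohort):
        d = dissimilarity(small_cohort.counts, "bray_curtis")
        order = list(reversed(small_cohort.counts.sample_ids))
        d2 = dissimilarity(small_cohort.counts.subset_samples(order),
                           "bray_curtis")
        assert np.allclose(d.subset(order).values, d2.values)


class TestOrdination:
    def test_pcoa_recovers_planar_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(15, 2))
        coords, evals = pcoa(_euclid_dm(pts), k=2)
        from scipy.spatial import procrustes
        _, _, disp = procrustes(pts, coords.to_numpy())
        assert disp < 1e-6

    def test_pcoa_eigenvalues_non_increasing(self, small_cohort):
        d = dissimilarity(small_cohort.counts, "bray_curtis")
        _, evals = pcoa(d)
        assert (np.diff(evals) <= 1e-9).all()

    def test_nmds_low_stress_on_embeddable_distances(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(25, 2))
        _, stress = nmds(_euclid_dm(pts), k=2, n_restarts=8, seed=1)
        assert stress < 0.01

    def test_k_must_be_less_than_n(self):
        pts = np.arange(4.0)[:, None]
        with pytest.raises(DysbiomeError):
            pcoa(_euclid_dm(pts), k=4)


class TestPermanova:
    def test_equals_classical_anova_on_univariate_euclidean(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=24)
        g = np.repeat(list("abc"), 8)
        d = _euclid_dm(y[:, None])
        meta = pd.DataFrame({"sample_id": d.ids, "grp": g})
        res = permanova(d, meta, ["grp"], n_perm=99, seed=0)
        f_classic = stats.f_oneway(*[y[g == lv] for lv in "abc"]).statistic
        assert res.pseudo_F["grp"] == pytest.approx(f_classic, rel=1e-10)

    def test_matches_skbio_pseudo_f(self, small_cohort):
        d = dissimilarity(small_cohort.counts, "bray_curtis")
        meta = small_cohort.metadata.data
        groups = meta.set_index("sample_id").loc[d.ids, "diagnosis"]
        mine = permanova(d, meta, ["diagnosis"], n_perm=9, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.ids), groups.to_numpy(),
            permutations=9)
        assert mine.pseudo_F["diagnosis"] == pytest.approx(
            ref["test statistic"], rel=1e-8)

    def test_sequential_ss_sum_to_total_any_order(self, small_cohort):
        d = dissimilarity(small_cohort.counts, "bray_curtis")
        meta = small_cohort.metadata.data
        r1 = permanova(d, meta, ["diagnosis", "sex"], n_perm=9, seed=0)
        r2 = permanova(d, meta, ["sex", "diagnosis"], n_perm=9, seed=0)
        for r in (r1, r2):
            total = sum(r.sum_of_squares.values()) + r.ss_residual
            assert total == pytest.approx(r.ss_total, abs=1e-8)

    def test_single_term_r2_identity(self):
        rng = np.random.default_rng(2)
        d = _euclid_dm(rng.normal(size=(30, 3)))
        meta = pd.DataFrame({"sample_id": d.ids,
                             "grp": np.repeat(["a", "b"], 15)})
        r = permanova(d, meta, ["grp"], n_perm=9, seed=0)
        assert r.R2["grp"] == pytest.approx(1 - r.ss_residual / r.ss_total)

    def test_separated_clusters_reach_minimal_p(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.05, (12, 2)),
                         rng.normal(50, 0.05, (12, 2))])
        d = _euclid_dm(pts)
        meta = pd.DataFrame({"sample_id": d.ids,
                             "grp": np.repeat(["a", "b"], 12)})
        r = permanova(d, meta, ["grp"], n_perm=199, seed=0)
        assert r.p_perm["grp"] == pytest.approx(1 / 200)

    def test_aliased_term_rejected(self):
        rng = np.random.default_rng(6)
        d = _euclid_dm(rng.normal(size=(10, 2)))
        meta = pd.DataFrame({"sample_id": d.ids,
                             "g1": np.repeat(["a", "b"], 5),
                             "g2": np.repeat(["a", "b"], 5)})
        with pytest.raises(DysbiomeError, match="aliased"):
            permanova(d, meta, ["g1", "g2"], n_perm=9)

    def test_conditioning_removes_confounded_signal(self):
        # the response tracks a continuous confounder; the group differs only
        # through that confounder, so conditioning should absorb its signal
        rng = np.random.default_rng(8)
        cov = np.repeat([0.0, 3.0], 20) + rng.normal(0, 0.5, 40)
        x = cov + rng.normal(0, 0.1, 40)
        d = _euclid_dm(x[:, None])
        meta = pd.DataFrame({"sample_id": d.ids,
                             "grp": np.repeat(["a", "b"], 20),
                             "cov": cov})
        plain = permanova(d, meta, ["grp"], n_perm=199, seed=1)
        conditioned = permanova(d, meta, ["grp"], condition=["cov"],
                                n_perm=199, seed=1)
        assert plain.p_perm["grp"] < 0.01
        assert conditioned.p_perm["grp"] > 0.1


class TestDispersion:
    def test_distances_non_negative(self, small_cohort):
        d = dissimilarity(small_cohort.counts, "bray_curtis")
        g = small_cohort.metadata.data.set_index("sample_id").loc[
            d.ids, "diagnosis"]
        res = dispersion_test(d, g, n_perm=99, seed=0)
        assert (res.group_distances >= 0).all()

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 1, (40, 3)),
                         rng.normal(0, 3, (40, 3))])
        d = _euclid_dm(pts)
        g = np.repeat(["tight", "wide"], 40)
        res = dispersion_test(d, g, n_perm=199, seed=0)
        assert res.p_perm <= 0.05
        wide = res.group_distances[res.groups == "wide"].mean()
        tight = res.group_distances[res.groups == "tight"].mean()
        assert wide > tight

    def test_agrees_with_skbio_permdisp_statistic(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(30, 4))
        d = _euclid_dm(pts)
        g = np.repeat(["a", "b", "c"], 10)
        res = dispersion_test(d, g, n_perm=99, seed=0)
        ref = skbio.stats.distance.permdisp(
            skbio.DistanceMatrix(d.values, d.ids), g, test="centroid",
            permutations=9)
        assert res.F == pytest.approx(ref["test statistic"], rel=1e-6)

    def test_singleton_group_excluded_with_warning(self):
        rng = np.random.default_rng(13)
        d = _euclid_dm(rng.normal(size=(9, 2)))
        g = np.array(["a"] * 4 + ["b"] * 4 + ["lonely"])
        with pytest.warns(UserWarning, match="size 1"):
            res = dispersion_test(d, g, n_perm=49, seed=0)
        assert "lonely" not in set(res.groups)
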