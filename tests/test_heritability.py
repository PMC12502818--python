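"""Kinship construction and REML heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from dysbiome.coredata import DysbiomeError
from dysbiome.heritability import (
    KinshipMatrix,
    Pedigree,
    compare_h2_models,
    fit_h2,
    h2_scan_from_cohort,
    kinship_matrix,
)
from dysbiome.synthcohort import SimulationConfig, generate_pedigree, simulate_cohort


def _ped(rows):
    return Pedigree(pd.DataFrame(
        rows, columns=["subject_id", "father_id", "mother_id", "sex",
                       "family_id"]))


class TestKinship:
    def test_textbook_relationships(self):
        ped = _ped([("f", "", "", "M", "A"), ("m", "", "", "F", "A"),
                    ("c1", "f", "m", "M", "A"), ("c2", "f", "m", "F", "A"),
                    ("u", "", "", "M", "B")])
        A = kinship_matrix(ped)
        ix = {s: i for i, s in enumerate(A.subject_ids)}
        assert A.values[ix["f"], ix["c1"]] == pytest.approx(0.5)   # parent-child
        assert A.values[ix["c1"], ix["c2"]] == pytest.approx(0.5)  # full sibs
        assert A.values[ix["c1"], ix["c1"]] == pytest.approx(1.0)  # self
        assert A.values[ix["f"], ix["m"]] == pytest.approx(0.0)    # founders
        assert A.values[ix["u"], ix["c1"]] == pytest.approx(0.0)   # unrelated

    def test_offspring_of_full_sibs_is_inbred(self):
        ped = _ped([("f", "", "", "M", "A"), ("m", "", "", "F", "A"),
                    ("s1", "f", "m", "M", "A"), ("s2", "f", "m", "F", "A"),
                    ("kid", "s1", "s2", "M", "A")])
        A = kinship_matrix(ped)
        i = A.subject_ids.index("kid")
        # Phi(kid,kid) = 0.5 (1 + Phi(s1,s2)) = 0.5 * 1.25 -> A = 1.25
        assert A.values[i, i] == pytest.approx(1.25)

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(DysbiomeError, match="cycle"):
            _ped([("a", "b", "", "M", "A"), ("b", "a", "", "M", "A")])

    def test_children_unsorted_input_handled(self):
        # children listed before parents must still topologically order
        ped = _ped([("c", "f", "m", "M", "A"), ("f", "", "", "M", "A"),
                    ("m", "", "", "F", "A")])
        A = kinship_matrix(ped)
        ix = {s: i for i, s in enumerate(A.subject_ids)}
        assert A.values[ix["c"], ix["f"]] == pytest.approx(0.5)

    def test_matrix_positive_semidefinite(self):
        ped = generate_pedigree(SimulationConfig(seed=4, n_families=30))
        A = kinship_matrix(ped)
        assert np.linalg.eigvalsh(A.values).min() > -1e-10


def _direct_reml_negloglik(h2, y, X, A):
    """Unrotated restricted likelihood oracle (dense solve, no rotation)."""
    n, p = X.shape
    gamma = h2 / (1 - h2)
    V = gamma * A + np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    rss = float(r @ Vi @ r)
    sigma_e2 = rss / (n - p)
    _, logdet_v = np.linalg.slogdet(V)
    _, logdet_x = np.linalg.slogdet(XtViX)
    ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma_e2) + logdet_v
                 + logdet_x + (n - p))
    return -ll


class TestFitH2:
    @pytest.fixture(scope="class")
    def family_kinship(self):
        ped = generate_pedigree(SimulationConfig(
            seed=5, n_families=12, family_size_distribution={2: 1.0}))
        return kinship_matrix(ped)

    def test_matches_unrotated_likelihood_oracle(self, family_kinship):
        A = family_kinship  # 48 subjects
        rng = np.random.default_rng(0)
        n = len(A.subject_ids)
        L = np.linalg.cholesky(A.values + 1e-9 * np.eye(n))
        y = 0.7 * (L @ rng.standard_normal(n)) + 0.7 * rng.standard_normal(n)
        X = np.ones((n, 1))
        est = fit_h2(y, A)
        oracle = minimize_scalar(
            _direct_reml_negloglik, bounds=(1e-6, 1 - 1e-6), method="bounded",
            args=(y, X, A.values), options={"xatol": 1e-10})
        assert est.h2 == pytest.approx(float(oracle.x), abs=1e-5)
        assert est.log_likelihood == pytest.approx(-float(oracle.fun), abs=1e-6)

    def test_scale_invariance(self, family_kinship):
        rng = np.random.default_rng(1)
        n = len(family_kinship.subject_ids)
        y = rng.standard_normal(n)
        a = fit_h2(y, family_kinship)
        b = fit_h2(10 * y, family_kinship)
        # invariance is exact in the model; the residual difference is the
        # optimiser's termination noise on a flat restricted likelihood
        assert a.h2 == pytest.approx(b.h2, abs=1e-7)

    def test_identity_kinship_flagged_unidentifiable(self):
        n = 30
        A = KinshipMatrix(np.eye(n), [f"s{i}" for i in range(n)])
        est = fit_h2(np.random.default_rng(2).standard_normal(n), A)
        assert est.unidentifiable
        assert np.isnan(est.h2)

    def test_pure_noise_phenotype_near_zero(self):
        from dysbiome.heritability import _eigendecompose

        ped = generate_pedigree(SimulationConfig(
            seed=15, n_families=100, family_size_distribution={2: 1.0}))
        A = kinship_matrix(ped)
        eig = _eigendecompose(A.values)
        rng = np.random.default_rng(3)
        n = len(A.subject_ids)
        vals = [fit_h2(rng.standard_normal(n), A, _eigen=eig).h2
                for _ in range(40)]
        assert np.mean(vals) < 0.05


class TestCompareModels:
    def test_confounded_phenotype_shrinks_under_covariates(self):
        ped = generate_pedigree(SimulationConfig(
            seed=6, n_families=100, family_size_distribution={2: 1.0}))
        A = kinship_matrix(ped)
        n = len(A.subject_ids)
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(A.values + 1e-9 * np.eye(n))
        # a family-shared environmental exposure masquerades as heritability
        # unless it is modelled as a fixed covariate
        fam = ped.data["family_id"].to_numpy()
        fam_ibd = {f: rng.random() < 0.5 for f in np.unique(fam)}
        ibd = np.array([fam_ibd[f] for f in fam])
        g = L @ rng.standard_normal(n)
        y = 0.5 * g + 2.0 * ibd + rng.standard_normal(n)
        cov = pd.DataFrame({"ibd": ibd.astype(float)})
        null, full, d_aic = compare_h2_models(y, cov, A)
        assert null.h2 > full.h2
        assert d_aic > 0

    def test_without_covariate_effects_models_agree(self):
        ped = generate_pedigree(SimulationConfig(
            seed=7, n_families=100, family_size_distribution={2: 1.0}))
        A = kinship_matrix(ped)
        n = len(A.subject_ids)
        rng = np.random.default_rng(5)
        L = np.linalg.cholesky(A.values + 1e-9 * np.eye(n))
        y = 0.8 * (L @ rng.standard_normal(n)) + 0.6 * rng.standard_normal(n)
        cov = pd.DataFrame({"junk": rng.standard_normal(n)})
        null, full, _ = compare_h2_models(y, cov, A)
        assert null.h2 == pytest.approx(full.h2, abs=0.05)

    def test_missing_covariates_drop_subjects_from_both_models(self):
        ped = generate_pedigree(SimulationConfig(
            seed=8, n_families=40, family_size_distribution={2: 1.0}))
        A = kinship_matrix(ped)
        n = len(A.subject_ids)
        rng = np.random.default_rng(6)
        y = rng.standard_normal(n)
        cov = pd.DataFrame({"x": rng.standard_normal(n)})
        cov.iloc[:10, 0] = np.nan
        null, full, _ = compare_h2_models(y, cov, A)
        assert null.n == full.n == n - 10


class TestScan:
    def test_prevalence_gate_and_output_columns(self):
        cfg = SimulationConfig(seed=9, n_families=40,
                               heritable_taxa={"ASV-010": 0.5})
        cohort = simulate_cohort(cfg)
        out = h2_scan_from_cohort(cohort.pedigree, cohort.counts,
                                  cohort.metadata, prevalence_cutoff=0.10)
        assert {"taxon_id", "h2_null", "h2_full", "aic_null",
                "aic_full"} <= set(out.columns)
        prevalence = (cohort.counts.values() > 0).mean(axis=0)
        rare = [t for t, pr in zip(cohort.counts.taxon_ids, prevalence)
                if pr < 0.10]
        assert not set(rare) & set(out["taxon_id"])
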