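import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal, norm

import divescaling as dv
from divescaling.inference import (
    Coefficient,
    DesignError,
    FitResult,
    ModelDesign,
    VarianceComponents,
    _v_parts,
    fit_result_table_row,
)
from divescaling.synthetic_data import SimTruth


def make_design(n_species=3, records_per_species=2, seed=0, include_temp=True,
                sigma2_phylo=0.2, sigma2_species=0.1, sigma2_resid=0.15):
    truth = SimTruth(
        n_species=n_species, records_per_species=records_per_species, seed=seed,
        sigma2_phylo=sigma2_phylo, sigma2_species=sigma2_species,
        sigma2_resid=sigma2_resid,
    )
    sim = dv.simulate_dataset(truth)
    return dv.build_design(
        sim.dataset, include_temperature=include_temp, tree=sim.tree
    ), truth


def dense_loglik(design, beta, vc):
    """Brute-force oracle: explicit dense V and scipy's multivariate normal."""
    A, B = _v_parts(design)
    V = (vc.sigma2_phylo * A + vc.sigma2_species * B
         + vc.sigma2_resid * np.eye(design.n_records))
    return multivariate_normal(
        mean=design.fixed_matrix @ beta, cov=V, allow_singular=True
    ).logpdf(design.response)


class TestBuildDesign:
    def test_shapes_with_temperature(self):
        truth = SimTruth(n_species=4, records_per_species=3, seed=1)
        sim = dv.simulate_dataset(truth)
        # keep 10 records
        ds = dv.DiveDataset(frame=sim.dataset.frame.iloc[:10])
        design = dv.build_design(ds, include_temperature=True, tree=sim.tree)
        assert design.fixed_matrix.shape == (10, 3)
        assert design.fixed_names == ("intercept", "ln_mass", "temp_C")
        assert design.phylo_cov.matrix.shape == (4, 4)

    def test_mass_only_design_has_two_columns(self, small_sim):
        design = dv.build_design(
            small_sim.dataset, include_temperature=False, tree=small_sim.tree
        )
        assert design.fixed_matrix.shape[1] == 2
        assert design.fixed_names == ("intercept", "ln_mass")

    def test_single_species_rejected(self, small_sim):
        frame = small_sim.dataset.frame
        one = dv.DiveDataset(frame=frame[frame["species"] == frame["species"].iloc[0]])
        with pytest.raises(DesignError, match="two species"):
            dv.build_design(one, tree=small_sim.tree)

    def test_species_missing_from_tree_dropped(self, small_sim):
        frame = small_sim.dataset.frame.copy()
        frame.loc[frame.index[:3], "species"] = "not_in_tree"
        design = dv.build_design(dv.DiveDataset(frame=frame), tree=small_sim.tree)
        assert design.n_records == len(frame) - 3

    def test_rows_missing_response_dropped(self, small_sim):
        frame = small_sim.dataset.frame.copy()
        frame.loc[frame.index[:5], "median_dive_min"] = np.nan
        design = dv.build_design(dv.DiveDataset(frame=frame), tree=small_sim.tree)
        assert design.n_records == len(frame) - 5

    def test_max_response_uses_max_column(self, small_sim):
        d_med = dv.build_design(small_sim.dataset, "median", tree=small_sim.tree)
        d_max = dv.build_design(small_sim.dataset, "max", tree=small_sim.tree)
        np.testing.assert_allclose(
            d_max.response, d_med.response + np.log(2.0), atol=1e-12
        )

    def test_phylo_cov_aligned_to_species(self, small_sim):
        design = dv.build_design(small_sim.dataset, tree=small_sim.tree)
        assert tuple(design.phylo_cov.labels) == tuple(design.species_labels)
        np.testing.assert_allclose(np.diag(design.phylo_cov.matrix), 1.0)


class TestMarginalLoglik:
    def test_diagonal_case_equals_independent_normals(self):
        design, _ = make_design(seed=3)
        beta = np.array([1.0, 0.2, -0.1])
        vc = VarianceComponents(0.0, 0.0, 0.4)
        r = design.response - design.fixed_matrix @ beta
        expected = norm(0, np.sqrt(0.4)).logpdf(r).sum()
        assert dv.marginal_loglik(design, beta, vc) == pytest.approx(
            expected, abs=1e-10
        )

    def test_toy_tree_matches_brute_force(self):
        """6 records, 3 species on ((A:1,B:1):1,C:2) vs dense evaluation."""
        design, _ = make_design(n_species=3, records_per_species=2, seed=7)
        beta = np.array([0.5, 0.3, -0.05])
        vc = VarianceComponents(0.3, 0.2, 0.25)
        assert dv.marginal_loglik(design, beta, vc) == pytest.approx(
            dense_loglik(design, beta, vc), abs=1e-8
        )

    def test_location_equivariance(self):
        design, _ = make_design(seed=5)
        beta = np.array([1.0, 0.25, -0.12])
        vc = VarianceComponents(0.1, 0.1, 0.2)
        base = dv.marginal_loglik(design, beta, vc)
        shifted = ModelDesign(
            response=design.response + 5.0,
            which_response=design.which_response,
            fixed_matrix=design.fixed_matrix,
            fixed_names=design.fixed_names,
            species_index=design.species_index,
            species_labels=design.species_labels,
            phylo_cov=design.phylo_cov,
        )
        beta_shift = beta + np.array([5.0, 0, 0])
        assert dv.marginal_loglik(shifted, beta_shift, vc) == pytest.approx(
            base, abs=1e-10
        )

    @given(
        seed=st.integers(0, 10_000),
        n_species=st.integers(4, 6),
        rps=st.integers(1, 2),
        s2p=st.floats(0.0, 1.0),
        s2s=st.floats(0.0, 1.0),
        s2e=st.floats(0.05, 1.0),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_oracle_equivalence_small_designs(self, seed, n_species, rps,
                                              s2p, s2s, s2e):
        """Dense multivariate-normal oracle on designs of at most 12 records."""
        design, _ = make_design(n_species=n_species, records_per_species=rps,
                                seed=seed)
        assert design.n_records <= 12
        rng = np.random.default_rng(seed)
        beta = rng.normal(size=3)
        vc = VarianceComponents(s2p, s2s, s2e)
        assert dv.marginal_loglik(design, beta, vc) == pytest.approx(
            dense_loglik(design, beta, vc), abs=1e-8
        )


class TestFitReml:
    def test_zero_variance_data_reduces_to_ols(self):
        design, truth = make_design(
            n_species=20, records_per_species=3, seed=11,
            sigma2_phylo=0, sigma2_species=0, sigma2_resid=0,
        )
        fit = dv.fit_reml(design)
        ols = np.linalg.lstsq(design.fixed_matrix, design.response, rcond=None)[0]
        est = np.array([c.estimate for c in fit.coefficients])
        np.testing.assert_allclose(est, ols, atol=1e-6)

    def test_duplicated_records_same_estimate_smaller_intervals(self):
        """GLS algebra: duplicating every record leaves the point estimate
        unchanged and tightens the Wald intervals (iid-residual model)."""
        design, _ = make_design(
            n_species=15, records_per_species=2, seed=21,
            sigma2_phylo=0, sigma2_species=0, sigma2_resid=0.3,
        )
        dup = ModelDesign(
            response=np.concatenate([design.response] * 2),
            which_response=design.which_response,
            fixed_matrix=np.vstack([design.fixed_matrix] * 2),
            fixed_names=design.fixed_names,
            species_index=np.concatenate([design.species_index] * 2),
            species_labels=design.species_labels,
            phylo_cov=design.phylo_cov,
        )
        f1 = dv.fit_reml(design, components=())
        f2 = dv.fit_reml(dup, components=())
        for c1, c2 in zip(f1.coefficients, f2.coefficients):
            assert c2.estimate == pytest.approx(c1.estimate, abs=1e-6)
            assert (c2.upper95 - c2.lower95) < (c1.upper95 - c1.lower95)

    def test_interval_brackets_estimate(self):
        design, _ = make_design(n_species=10, records_per_species=2, seed=2)
        fit = dv.fit_reml(design)
        for c in fit.coefficients:
            assert c.lower95 <= c.estimate <= c.upper95

    def test_wald_coverage_on_strong_signal(self):
        """True coefficients fall inside the 95% Wald interval in >= 90% of
        seeded replicates."""
        report = dv.run_recovery(
            SimTruth(), n_replicates=100, methods=("reml",), master_seed=7,
        )
        for name in ("intercept", "ln_mass", "temp_C"):
            assert report["summary"]["reml"][name]["coverage"] >= 0.90

    def test_deterministic(self):
        design, _ = make_design(n_species=12, records_per_species=2, seed=30)
        f1, f2 = dv.fit_reml(design), dv.fit_reml(design)
        assert f1.to_json() == f2.to_json()


class TestFitGibbs:
    def test_deterministic_given_seed(self):
        design, _ = make_design(n_species=8, records_per_species=2, seed=3)
        f1 = dv.fit_gibbs(design, n_iter=500, burn_in=100, thin=2, seed=9)
        f2 = dv.fit_gibbs(design, n_iter=500, burn_in=100, thin=2, seed=9)
        assert f1.to_json() == f2.to_json()

    def test_conjugate_toy_matches_closed_form(self):
        """With no random effects the sampler is conjugate Bayesian linear
        regression: the posterior mean of beta is the OLS solution."""
        rng = np.random.default_rng(4)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_true = np.array([1.0, 0.5])
        y = X @ beta_true + 0.3 * rng.normal(size=n)
        cov = dv.bm_covariance(dv.read_newick("(A:1,B:1);"))
        design = ModelDesign(
            response=y,
            which_response="median",
            fixed_matrix=X,
            fixed_names=("intercept", "ln_mass"),
            species_index=rng.integers(0, 2, size=n),
            species_labels=("A", "B"),
            phylo_cov=cov,
        )
        fit = dv.fit_gibbs(
            design, n_iter=21000, burn_in=1000, thin=1, seed=5, components=(),
        )
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        for c, b in zip(fit.coefficients, ols):
            assert c.estimate == pytest.approx(b, abs=1e-2)
        # posterior residual variance close to the REML-style estimate
        resid = y - X @ ols
        s2_hat = resid @ resid / (n - 2)
        assert fit.varcomp.sigma2_resid == pytest.approx(s2_hat, rel=0.15)

    def test_agrees_with_reml_on_strong_signal(self):
        design, _ = make_design(n_species=60, records_per_species=2, seed=17)
        reml = dv.fit_reml(design)
        gibbs = dv.fit_gibbs(design, n_iter=4000, burn_in=1000, thin=3, seed=17)
        mcse = gibbs.diagnostics["mc_se"]
        for name in design.fixed_names:
            tol = max(2 * mcse[name], 0.02)
            assert gibbs.coef(name).estimate == pytest.approx(
                reml.coef(name).estimate, abs=tol
            )

    def test_burn_in_must_be_shorter_than_chain(self):
        design, _ = make_design(seed=1)
        with pytest.raises(ValueError):
            dv.fit_gibbs(design, n_iter=100, burn_in=100)

    def test_low_ess_recorded_in_diagnostics(self):
        design, _ = make_design(n_species=6, records_per_species=2, seed=23)
        fit = dv.fit_gibbs(design, n_iter=300, burn_in=100, thin=1, seed=1,
                           ess_threshold=1e6)
        assert len(fit.diagnostics["low_ess_warning"]) > 0


class TestConditionalR2:
    @staticmethod
    def _manual_fit(beta, vc, design):
        z = [
            Coefficient(n, float(b), float(b) - 1, float(b) + 1)
            for n, b in zip(design.fixed_names, beta)
        ]
        return FitResult(
            coefficients=tuple(z), varcomp=vc, conditional_r2=np.nan,
            n_records=design.n_records, n_species=design.n_species,
            method="reml",
        )

    def test_saturated_when_residual_variance_zero(self):
        design, _ = make_design(seed=2)
        vc = VarianceComponents(0.5, 0.2, 0.0)
        fit = self._manual_fit([1.0, 0.3, -0.1], vc, design)
        assert dv.conditional_r2(fit, design) == pytest.approx(1.0)

    def test_zero_when_no_signal(self):
        design, _ = make_design(seed=2)
        vc = VarianceComponents(0.0, 0.0, 0.7)
        fit = self._manual_fit([0.0, 0.0, 0.0], vc, design)
        assert dv.conditional_r2(fit, design) == pytest.approx(0.0)

    def test_arithmetic_partition(self):
        """var(fixed)=3, random=1, residual=1 gives R2 = 4/5."""
        n = 8
        x = np.arange(n, dtype=float)
        x = x / x.std(ddof=1) * np.sqrt(3)  # sample variance exactly 3
        X = np.column_stack([np.ones(n), x])
        cov = dv.bm_covariance(dv.read_newick("(A:1,B:1);"))
        design = ModelDesign(
            response=np.zeros(n), which_response="median",
            fixed_matrix=X, fixed_names=("intercept", "ln_mass"),
            species_index=np.tile([0, 1], n // 2),
            species_labels=("A", "B"), phylo_cov=cov,
        )
        vc = VarianceComponents(0.5, 0.5, 1.0)
        fit = self._manual_fit([0.0, 1.0], vc, design)
        assert dv.conditional_r2(fit, design) == pytest.approx(0.8)

    def test_invariant_to_response_rescaling(self):
        design, _ = make_design(n_species=25, records_per_species=2, seed=6)
        scaled = ModelDesign(
            response=design.response * 3.0,
            which_response=design.which_response,
            fixed_matrix=design.fixed_matrix,
            fixed_names=design.fixed_names,
            species_index=design.species_index,
            species_labels=design.species_labels,
            phylo_cov=design.phylo_cov,
        )
        r2a = dv.fit_reml(design).conditional_r2
        r2b = dv.fit_reml(scaled).conditional_r2
        assert r2b == pytest.approx(r2a, abs=1e-4)


class TestReporting:
    def test_table_row_layout_with_temperature(self, small_sim):
        design = dv.build_design(small_sim.dataset, tree=small_sim.tree)
        fit = dv.fit_reml(design)
        row = fit_result_table_row(fit, "Ectotherms", "Med.").split("\t")
        assert row[0] == "Ectotherms"
        assert row[1] == "Med."
        assert len(row) == 7  # group, resp, 3 coefficients, R2, N
        assert row[-1].endswith(f"({small_sim.truth.n_species})")

    def test_table_row_layout_mass_only(self, small_sim):
        design = dv.build_design(
            small_sim.dataset, include_temperature=False, tree=small_sim.tree
        )
        fit = dv.fit_reml(design)
        row = fit_result_table_row(fit, "All", "Max.").split("\t")
        assert len(row) == 6

    def test_json_round_trip_keys(self, small_sim):
        import json

        design = dv.build_design(small_sim.dataset, tree=small_sim.tree)
        fit = dv.fit_reml(design)
        payload = json.loads(fit.to_json())
        assert {"method", "coefficients", "varcomp", "conditional_r2",
                "n_records", "n_species"} <= set(payload)
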