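import numpy as np
import pandas as pd
import pytest

from subhealth import (
    build_model,
    default_population,
    implied_covariance,
    lv_covariance,
    parameter_recovery_report,
    sample_cohort,
)
from subhealth.simulate import PopulationError, PopulationModel


class TestPopulationAdmissibility:
    def test_loading_above_one_rejected(self, spec):
        pop = default_population()
        with pytest.raises(PopulationError, match="loading"):
            PopulationModel(
                spec=pop.spec,
                loadings={**pop.loadings, "TC": 1.2},
                formative_weights=pop.formative_weights,
                path_coefficients=pop.path_coefficients,
            )

    def test_overexplained_endogenous_rejected(self):
        spec = build_model(
            [("A", "reflective", ["a1", "a2"]), ("B", "reflective", ["b1", "b2"])],
            [("A", "B")],
        )
        with pytest.raises(PopulationError, match="disturbance"):
            PopulationModel(
                spec=spec,
                loadings={"a1": 0.8, "a2": 0.7, "b1": 0.8, "b2": 0.7},
                path_coefficients={("A", "B"): 1.2},
            )

    def test_bad_grade_marginals_rejected(self):
        pop = default_population()
        with pytest.raises(PopulationError, match="marginals"):
            PopulationModel(
                spec=pop.spec,
                loadings=pop.loadings,
                formative_weights=pop.formative_weights,
                path_coefficients=pop.path_coefficients,
                grade_marginals={"width": (0.5, 0.2, 0.2)},
            )


class TestLatentCovariance:
    def test_default_population_matrix(self, population):
        Phi = lv_covariance(population)
        assert np.allclose(np.diag(Phi), 1.0)
        assert Phi.loc["routine_blood_test", "liver_function"] == pytest.approx(0.468)
        assert Phi.loc["routine_blood_test", "lipid_metabolism"] == pytest.approx(0.225)
        # chain: blood -> lipid -> obesity
        assert Phi.loc["routine_blood_test", "obesity"] == pytest.approx(0.225 * 0.307)

    def test_formative_block_implied_loadings_match_printed(self, population):
        lam = population.block_loadings("obesity")
        assert lam == pytest.approx([0.91, 0.77], abs=0.005)


class TestImpliedCovariance:
    def test_single_construct_two_indicators(self):
        spec = build_model([("A", "reflective", ["a1", "a2"])])
        pop = PopulationModel(spec=spec, loadings={"a1": 0.8, "a2": 0.5})
        Sigma = implied_covariance(pop)
        assert np.allclose(np.diag(Sigma), 1.0)
        # composite population: the common part λ1·λ2 plus the (perfectly
        # anticorrelated) residual term that makes the construct an exact
        # composite of its two indicators
        expected = 0.8 * 0.5 - np.sqrt((1 - 0.8**2) * (1 - 0.5**2))
        assert Sigma.loc["a1", "a2"] == pytest.approx(expected, abs=1e-12)

    def test_unit_loading_block_has_factor_form(self):
        # with a unit loading the indicator IS the construct and the other
        # residuals are independent, so the off-diagonal is exactly λ1·λ2
        spec = build_model([("A", "reflective", ["a1", "a2"])])
        pop = PopulationModel(spec=spec, loadings={"a1": 1.0, "a2": 0.5})
        assert implied_covariance(pop).loc["a1", "a2"] == pytest.approx(0.5, abs=1e-12)

    def test_zero_loadings_give_identity(self):
        spec = build_model([("A", "reflective", ["a1", "a2"])])
        pop = PopulationModel(spec=spec, loadings={"a1": 0.0, "a2": 0.0})
        assert np.allclose(implied_covariance(pop), np.eye(2))

    def test_chain_cross_block_covariance(self):
        spec = build_model(
            [("A", "reflective", ["a1", "a2"]), ("B", "reflective", ["b1", "b2"])],
            [("A", "B")],
        )
        beta = 0.5
        pop = PopulationModel(
            spec=spec,
            loadings={"a1": 0.8, "a2": 0.6, "b1": 0.9, "b2": 0.7},
            path_coefficients={("A", "B"): beta},
        )
        Sigma = implied_covariance(pop)
        for a, la in (("a1", 0.8), ("a2", 0.6)):
            for b, lb in (("b1", 0.9), ("b2", 0.7)):
                assert Sigma.loc[a, b] == pytest.approx(la * beta * lb, abs=1e-12)

    def test_monte_carlo_agreement(self, small_population):
        cohort = sample_cohort(small_population, n=100_000, seed=77)
        emp = np.cov(cohort.indicators.to_numpy(), rowvar=False)
        Sigma = implied_covariance(small_population).to_numpy()
        assert np.abs(emp - Sigma).max() < 0.02


class TestSampler:
    def test_schema_and_determinism(self, population):
        c1 = sample_cohort(population, n=2000, seed=1)
        assert list(c1.indicators.columns) == population.spec.indicator_names
        assert not c1.indicators.isna().any().any()
        assert len(c1.indicators) == 2000
        c2 = sample_cohort(population, n=2000, seed=1)
        assert c1.indicators.equals(c2.indicators)
        assert c1.sv_grades.equals(c2.sv_grades)
        assert c1.symptoms.equals(c2.symptoms)
        c3 = sample_cohort(population, n=2000, seed=2)
        assert not c1.indicators.equals(c3.indicators)

    def test_unit_loadings_reproduce_latent_scores(self):
        spec = build_model([("A", "reflective", ["a1", "a2"])])
        pop = PopulationModel(spec=spec, loadings={"a1": 1.0, "a2": 1.0})
        cohort = sample_cohort(pop, n=100, seed=5)
        lv = cohort.true_lv_scores["A"].to_numpy()
        assert np.allclose(cohort.indicators["a1"], lv)
        assert np.allclose(cohort.indicators["a2"], lv)

    def test_constructs_are_exact_composites(self, population):
        """Reflective blocks without a unit loading admit an exact recovery
        of the construct from the indicators (composite population)."""
        cohort = sample_cohort(population, n=400, seed=6)
        for name in ("lipid_metabolism", "sv_characteristics", "obesity"):
            con = population.spec.construct(name)
            X = cohort.indicators[list(con.indicators)].to_numpy()
            eta = cohort.true_lv_scores[name].to_numpy()
            w, *_ = np.linalg.lstsq(X, eta, rcond=None)
            assert np.allclose(X @ w, eta, atol=1e-8)

    def test_covariance_converges_to_implied(self, population):
        Sigma = implied_covariance(population).to_numpy()
        devs = []
        for n in (1_000, 10_000, 100_000):
            dev = []
            for seed in range(5):
                coh = sample_cohort(population, n=n, seed=300 + seed)
                emp = np.cov(coh.indicators.to_numpy(), rowvar=False)
                dev.append(np.abs(emp - Sigma).max())
            devs.append(np.mean(dev))
        assert devs[0] > devs[1] > devs[2]

    def test_grade_marginals_match(self, population):
        cohort = sample_cohort(population, n=20_000, seed=8)
        for dim, probs in population.grade_marginals.items():
            freq = cohort.sv_grades[dim].value_counts(normalize=True).sort_index()
            assert np.allclose(freq.to_numpy(), probs, atol=0.01)
        l1 = (cohort.sv_grades["trunk_length"] == "L1").mean() * 100
        assert l1 == pytest.approx(68.1, abs=1.0)

    def test_symptom_prevalences_and_severity_rule(self, population):
        cohort = sample_cohort(population, n=20_000, seed=9)
        for symptom, prev in population.symptom_prevalences.items():
            sub = cohort.symptoms[cohort.symptoms["symptom"] == symptom]
            positive = sub["severity"] >= 1
            assert positive.mean() == pytest.approx(prev, abs=0.01)
            n_pos = int(positive.sum())
            assert (sub["severity"] == 2).sum() == n_pos // 2


class TestParameterRecovery:
    def test_report_shape_and_consistency_direction(self, small_population):
        seeds = list(range(30))
        r1 = parameter_recovery_report(small_population, n=300, seeds=seeds)
        r2 = parameter_recovery_report(small_population, n=1200, seeds=seeds)
        assert list(r1.columns) == ["population", "mean_estimate", "bias", "rmse", "rejection_rate"]
        assert (r2["rmse"] < r1["rmse"]).all()
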