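"""Univariate animal model: design assembly, spline, REML, LRT, BIC, h2.

The balanced half-sib design gives a closed-form ANOVA oracle for the
additive variance: with unrelated non-inbred sires and unknown dams,
sigma_a^2 = 4 * (MSB - MSW) / k.
"""

import numpy as np
import pandas as pd
import pytest

from kennelquant.animal_model import (
    AnimalModelFit,
    ModelSpec,
    VarianceComponents,
    bic_backward_elimination,
    build_design,
    heritability_repeatability,
    lrt_random_term,
    reml_fit,
    spline_basis,
)
from kennelquant.mixedmodel import FitResult
from kennelquant.pedigree import Pedigree, PedigreeRecord, compute_inbreeding

from conftest import make_pedigree


def halfsib_data(seed=0, n_sires=40, k=6, sa2=0.8, se2=1.2):
    """Balanced half-sib families; only progeny have records."""
    rng = np.random.default_rng(seed)
    rows = [(f"S{i}", None, None, "male") for i in range(n_sires)]
    rows += [(f"P{i}_{j}", f"S{i}", None) for i in range(n_sires) for j in range(k)]
    ped = compute_inbreeding(make_pedigree(rows))
    sires = rng.normal(size=n_sires) * np.sqrt(sa2)
    recs = []
    y = np.empty((n_sires, k))
    for i in range(n_sires):
        for j in range(k):
            mend = rng.normal() * np.sqrt(0.75 * sa2)
            e = rng.normal() * np.sqrt(se2)
            y[i, j] = 0.5 * sires[i] + mend + e
            recs.append({"dog_id": f"P{i}_{j}", "value": y[i, j],
                         "age_days": 500.0, "sex": "male"})
    return ped, pd.DataFrame(recs), y


class TestBuildDesign:
    def _records(self):
        return pd.DataFrame(
            {
                "dog_id": ["O", "O", "S"],
                "value": [0.1, 0.2, -0.3],
                "age_days": [400.0, 800.0, 600.0],
                "sex": ["male", "male", "male"],
                "assessor": ["A1", "", "A1"],
            }
        )

    def test_repeated_records_share_one_pe_column(self, trio):
        ds = build_design(self._records(), trio, ModelSpec(spline_knots=0))
        zpe = next(f for f in ds.factors if f.name == "permanent_env").Z.toarray()
        col_O = zpe[:, ds.pe_levels.index("O")]
        assert col_O.tolist() == [1.0, 1.0, 0.0]

    def test_missing_assessor_gets_unique_dummy_level(self, trio):
        ds = build_design(self._records(), trio, ModelSpec(spline_knots=0))
        zas = next(f for f in ds.factors if f.name == "assessor").Z.toarray()
        assert zas.shape[1] == 2  # A1 plus one dummy
        assert zas[1].sum() == 1.0 and zas[1, 0] == 0.0

    def test_no_pe_term_when_not_requested(self, trio):
        spec = ModelSpec(random={"assessor"}, spline_knots=0)
        ds = build_design(self._records(), trio, spec)
        assert all(f.name != "permanent_env" for f in ds.factors)

    def test_unknown_dog_errors(self, trio):
        recs = self._records()
        recs.loc[0, "dog_id"] = "nope"
        with pytest.raises(ValueError, match="nope"):
            build_design(recs, trio, ModelSpec())


class TestSplineBasis:
    def test_columns_orthogonal_to_intercept_and_linear(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(300, 3000, size=200)
        S = spline_basis(age, knots=2)
        assert S.shape[1] >= 1
        assert np.abs(S.sum(axis=0)).max() < 1e-8
        assert np.abs(age @ S).max() < 1e-5 * np.abs(age).sum()

    def test_second_derivative_continuous_at_knots(self):
        x = np.linspace(0.0, 10.0, 4001)
        S = spline_basis(x, knots=3)
        h = x[1] - x[0]
        d2 = (S[2:] - 2 * S[1:-1] + S[:-2]) / h**2
        # second differences of a C2 function change smoothly: the jump
        # between adjacent estimates stays O(h)
        assert np.max(np.abs(np.diff(d2, axis=0))) < 50 * h

    def test_too_few_distinct_ages_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            spline_basis(np.array([1.0, 1.0, 2.0]), knots=3)

    def test_linear_response_spline_variance_at_floor(self):
        rng = np.random.default_rng(3)
        n = 300
        rows = [(f"F{i}", None, None) for i in range(n)]
        ped = compute_inbreeding(make_pedigree(rows))
        age = rng.uniform(365, 3000, n)
        y = 0.5 + 0.002 * age + rng.normal(size=n) * 0.3
        recs = pd.DataFrame({"dog_id": [f"F{i}" for i in range(n)], "value": y,
                             "age_days": age, "sex": ["male"] * n})
        spec = ModelSpec(random=set(), spline_knots=6)
        fit = reml_fit(build_design(recs, ped, spec), ped, spec)
        # null smooth: the per-record spline variance collapses to (near)
        # zero, a sliver above the floor from chance smoothness in the noise
        assert fit.spline_variance < 0.01 * np.var(y)


class TestRemlOracles:
    def test_halfsib_reml_equals_anova_estimator(self):
        ped, recs, y = halfsib_data(seed=1)
        n_sires, k = y.shape
        msb = k * np.var(y.mean(axis=1), ddof=1)
        msw = np.mean(np.var(y, axis=1, ddof=1))
        sa2_anova = 4.0 * (msb - msw) / k
        spec = ModelSpec(random=set(), spline_knots=0)
        fit = reml_fit(build_design(recs, ped, spec), ped, spec)
        assert fit.converged
        assert fit.components.sigma2_a == pytest.approx(sa2_anova, abs=1e-6)
        resid_anova = msw - 0.75 * sa2_anova
        assert fit.components.sigma2_e == pytest.approx(resid_anova, abs=1e-6)

    def test_zero_additive_variance_lands_on_floor(self):
        # null data: unrelated families, no sire effect at all
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            ped, recs, _ = halfsib_data(seed=100 + rep, n_sires=25, k=4, sa2=0.0, se2=1.0)
            spec = ModelSpec(random=set(), spline_knots=0)
            fit = reml_fit(build_design(recs, ped, spec), ped, spec)
            if fit.components.sigma2_a < 0.02 * fit.components.sigma2_e:
                hits += 1
        assert hits >= int(0.7 * n_rep)  # most replicates collapse to the floor


class TestLrt:
    def _fit_pair(self):
        ped, recs, _ = halfsib_data(seed=5, n_sires=20, k=4)
        full_spec = ModelSpec(random={"permanent_env"}, spline_knots=0)
        red_spec = ModelSpec(random=set(), spline_knots=0)
        full = reml_fit(build_design(recs, ped, full_spec), ped, full_spec)
        red = reml_fit(build_design(recs, ped, red_spec), ped, red_spec)
        return full, red

    def test_boundary_mixture_p_values(self):
        full, red = self._fit_pair()
        stat, p = lrt_random_term(full, red)
        assert stat >= 0.0
        if stat == 0.0:
            assert p == 0.5
        # quantile identity of the half-half mixture
        from scipy.stats import chi2

        assert 0.5 * chi2.sf(2.706, 1) == pytest.approx(0.05, abs=2e-4)

    def test_equal_likelihood_gives_half(self):
        full, red = self._fit_pair()
        red.reml_loglik = full.reml_loglik
        stat, p = lrt_random_term(full, red)
        assert stat == 0.0 and p == 0.5

    def test_non_nested_specs_error(self):
        full, _ = self._fit_pair()
        with pytest.raises(ValueError, match="nested"):
            lrt_random_term(full, full)


class TestBicElimination:
    def test_junk_covariate_dropped_informative_kept(self):
        rng = np.random.default_rng(21)
        ped, recs, _ = halfsib_data(seed=6, n_sires=30, k=4)
        recs = recs.copy()
        recs["junk"] = rng.normal(size=len(recs))
        recs["signal"] = rng.normal(size=len(recs))
        recs["value"] = recs["value"] + 1.5 * recs["signal"]
        spec = ModelSpec(covariates=["junk", "signal"], random=set(), spline_knots=0)
        final, trace = bic_backward_elimination(recs, ped, spec, ["junk", "signal"])
        assert "junk" not in final.covariates
        assert "signal" in final.covariates
        assert (trace["action"] == "drop").sum() >= 1

    def test_protected_terms_never_candidates(self):
        ped, recs, _ = halfsib_data(seed=7, n_sires=15, k=3)
        spec = ModelSpec(random=set(), spline_knots=0)
        final, _ = bic_backward_elimination(recs, ped, spec, ["sex", "age", "additive"])
        # the protected names are filtered out before any fit is attempted
        assert final.fixed == spec.fixed and final.covariates == spec.covariates


def _fake_fit(sa, se_, spe=None, sas=None):
    names = ["additive[0,0]"]
    if spe is not None:
        names.append("permanent_env[0,0]")
    if sas is not None:
        names.append("assessor[0,0]")
    names.append("residual[0,0]")
    comp = VarianceComponents(sigma2_a=sa, sigma2_e=se_, sigma2_pe=spe, sigma2_as=sas)
    fit = FitResult(
        theta={}, se={}, param_names=names,
        param_values=np.zeros(len(names)), param_cov=0.01 * np.eye(len(names)),
        loglik=0.0, loglik_ml=0.0, beta=np.zeros(1), beta_se=np.ones(1),
        u={}, converged=True, iterations=1,
    )
    return AnimalModelFit(
        components=comp, beta=pd.DataFrame(), spline_variance=None,
        reml_loglik=0.0, ml_loglik=0.0, converged=True, iterations=1,
        fit=fit, design=None, spec=ModelSpec(), model=None,
    )


class TestHeritability:
    def test_assessor_excluded_from_phenotypic_variance(self):
        out = heritability_repeatability(_fake_fit(0.4, 0.4, spe=0.2, sas=0.3))
        assert out["h2"] == pytest.approx(0.4)
        assert out["repeatability"] == pytest.approx(0.6)

    def test_repeatability_absent_without_pe(self):
        out = heritability_repeatability(_fake_fit(0.3, 0.7))
        assert out["h2"] == pytest.approx(0.3)
        assert "repeatability" not in out

    def test_delta_method_se_positive(self):
        out = heritability_repeatability(_fake_fit(0.4, 0.4, spe=0.2, sas=0.3))
        assert out["h2_se"] > 0 and out["repeatability_se"] > 0


def test_parameter_recovery_within_two_se():
    """Full pipeline on one seeded continuous-trait data set."""
    from kennelquant.pedigree import build_a_inverse, trim_to_phenotyped
    from kennelquant.simulate import SimConfig, simulate_pedigree, simulate_phenotypes

    cfg = SimConfig(n_founders=100, n_generations=4, generation_size=200,
                    phenotyped_generations=2, seed=77, category_probs=(None,))
    ped = compute_inbreeding(simulate_pedigree(cfg))
    recs, _ = simulate_phenotypes(ped, cfg)
    recs = recs.assign(liab=recs["value"].astype(float))
    trimmed = compute_inbreeding(trim_to_phenotyped(ped, set(recs["dog_id"])))
    spec = ModelSpec(response="liab", spline_knots=6)
    fit = reml_fit(build_design(recs, trimmed, spec), trimmed, spec)
    hr = heritability_repeatability(fit)
    assert fit.converged
    assert abs(hr["h2"] - 0.45) <= 2 * hr["h2_se"]
    assert abs(hr["repeatability"] - 0.61) <= 2 * hr["repeatability_se"]
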