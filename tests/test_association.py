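"""Cross-sectional OLS and random-intercept mixed model on log lipids."""

import numpy as np
import pandas as pd
import pytest

from lipidtrio import association, scores, sim
from conftest import clean_config

VISITS = (0.0, 3.0, 5.0)


def _noise_free_config(beta=0.02, **kw):
    base = dict(
        n_families=120,
        effect_size_by_age={("TC", a): beta for a in VISITS},
        panel_assignment=None,
        trait_baseline_sd={(t, a): 0.0 for t in sim.TRAITS for a in VISITS},
        residual_sd={(t, a): 0.0 for t in sim.TRAITS for a in VISITS},
        visit_age_sd={a: 0.1 for a in VISITS},
        sex_effect=0.05,
    )
    base.update(kw)
    n_snps = base.pop("n_snps", 10)
    cfg = clean_config(n_snps=n_snps, **{k: v for k, v in base.items() if v is not None})
    if base.get("panel_assignment") is None:
        cfg.panel_assignment = {s: ("TC",) for s in cfg.snp_ids}
    return cfg


def _fit_inputs(cfg):
    cohort = sim.simulate_trios(cfg)
    pheno = association.log_transform(sim.simulate_phenotypes(cohort, cfg))
    gs = scores.genotype_score(cohort.genotypes, cfg.panel_assignment)
    return cohort, pheno, gs


class TestLogTransform:
    def test_values(self):
        df = pd.DataFrame({"iid": ["a", "b"], "visit": [0, 0],
                           "value": [1.0, np.e]})
        out = association.log_transform(df)
        assert out["value"].tolist() == pytest.approx([0.0, 1.0])
        assert out.attrs["transform"] == "ln"

    def test_round_trip(self):
        x = np.abs(np.random.default_rng(0).normal(2, 1, 50)) + 0.1
        df = pd.DataFrame({"iid": range(50), "visit": 0, "value": x})
        assert np.allclose(np.exp(association.log_transform(df)["value"]), x,
                           atol=1e-12)

    def test_non_positive_named(self):
        df = pd.DataFrame({"iid": ["a", "bad"], "visit": [0, 3], "value": [1.0, 0.0]})
        with pytest.raises(ValueError, match="bad"):
            association.log_transform(df)


class TestCrossSectional:
    def test_exact_recovery_noise_free(self):
        cfg = _noise_free_config(beta=0.02)
        _, pheno, gs = _fit_inputs(cfg)
        spec = association.ModelSpec("gs_TC", "TC", 3.0, n_pcs=0)
        res = association.fit_cross_sectional(spec, pheno, gs)
        assert res.beta == pytest.approx(0.02, abs=1e-10)

    def test_beta_equivariance_under_predictor_scaling(self):
        cfg = _noise_free_config(beta=0.02,
                                 residual_sd={(t, a): 0.1 for t in sim.TRAITS for a in VISITS})
        _, pheno, gs = _fit_inputs(cfg)
        spec = association.ModelSpec("gs_TC", "TC", 3.0, n_pcs=0)
        res1 = association.fit_cross_sectional(spec, pheno, gs)
        res2 = association.fit_cross_sectional(spec, pheno, gs.assign(gs_TC=2 * gs["gs_TC"]))
        assert res2.beta == pytest.approx(res1.beta / 2, rel=1e-10)

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        cfg = _noise_free_config(
            beta=0.015, residual_sd={(t, a): 0.2 for t in sim.TRAITS for a in VISITS})
        _, pheno, gs = _fit_inputs(cfg)
        spec = association.ModelSpec("gs_TC", "TC", 5.0, n_pcs=0)
        base = association.fit_cross_sectional(spec, pheno, gs)
        # append a covariate orthogonalized against the full design
        df = association.build_design(spec, pheno, gs)
        x = np.column_stack([np.ones(len(df)), df.drop(columns=["iid", "y"]).to_numpy()])
        rng = np.random.default_rng(1)
        v = rng.normal(size=len(df))
        v -= x @ np.linalg.lstsq(x, v, rcond=None)[0]
        pcs = pd.DataFrame({"PC1": v}, index=pd.Index(df["iid"], name="iid"))
        spec2 = association.ModelSpec("gs_TC", "TC", 5.0, n_pcs=1)
        withc = association.fit_cross_sectional(spec2, pheno, gs, pcs)
        assert withc.beta == pytest.approx(base.beta, abs=1e-8)

    def test_collinear_covariates_identified(self):
        cfg = _noise_free_config()
        _, pheno, gs = _fit_inputs(cfg)
        dup = gs[["gs_TC"]].copy()
        dup["PC1"] = 1.5 * dup["gs_TC"]  # aliased with the predictor
        spec = association.ModelSpec("gs_TC", "TC", 3.0, n_pcs=1)
        with pytest.raises(association.CollinearityError, match="PC1"):
            association.fit_cross_sectional(spec, pheno, gs, dup[["PC1"]])

    def test_constant_age_dropped_with_warning(self):
        cfg = _noise_free_config(visit_age_sd={a: 0.0 for a in VISITS},
                                 residual_sd={(t, a): 0.1 for t in sim.TRAITS for a in VISITS})
        _, pheno, gs = _fit_inputs(cfg)
        spec = association.ModelSpec("gs_TC", "TC", 0.0, n_pcs=0)
        with pytest.warns(UserWarning, match="age"):
            res = association.fit_cross_sectional(spec, pheno, gs)
        assert np.isfinite(res.beta)


class TestLongitudinal:
    def test_boundary_intercept_variance_falls_back_to_pooled_ols(self):
        # anti-correlated within-child residuals push the REML intercept
        # variance to its zero boundary, where the model collapses to OLS
        rng = np.random.default_rng(3)
        n = 120
        x = rng.binomial(2, 0.3, n).astype(float)
        e = rng.normal(0, 0.2, n)
        recs = []
        for i in range(n):
            for j, eps in enumerate((e[i], -e[i])):
                y = 1.0 + 0.05 * x[i] + eps
                recs.append((f"i{i}", float(j), 30.0 + j, "male", "TC", float(np.exp(y))))
        pheno = association.log_transform(pd.DataFrame(
            recs, columns=["iid", "visit", "age", "sex", "trait", "value"]))
        pred = pd.DataFrame({"x": x}, index=pd.Index([f"i{i}" for i in range(n)], name="iid"))
        spec = association.ModelSpec("x", "TC", "pooled", covariates=(), n_pcs=0)
        with pytest.warns(UserWarning, match="zero"):
            lmm = association.fit_longitudinal(spec, pheno, pred)
        ols = association.fit_cross_sectional(spec, pheno, pred)
        assert lmm.model == "ols_fallback"
        assert lmm.beta == pytest.approx(ols.beta, abs=1e-6)

    def test_zero_intercept_simulation_matches_pooled_ols_beta(self):
        # with no true per-child intercept the mixed-model fixed effect and
        # the pooled OLS estimate agree closely (exactly, if the variance
        # estimate hits the boundary)
        cfg = _noise_free_config(
            beta=0.01,
            random_intercept_sd={t: 0.0 for t in sim.TRAITS},
            residual_sd={(t, a): 0.15 for t in sim.TRAITS for a in VISITS},
        )
        _, pheno, gs = _fit_inputs(cfg)
        spec = association.ModelSpec("gs_TC", "TC", "pooled", n_pcs=0)
        lmm = association.fit_longitudinal(spec, pheno, gs)
        ols = association.fit_cross_sectional(spec, pheno, gs)
        assert lmm.beta == pytest.approx(ols.beta, abs=0.2 * ols.se)

    def test_variance_components_match_anova_closed_form(self):
        # balanced two-visit design, intercept-only + group-constant
        # predictor: REML variance components equal the one-way
        # random-effects ANOVA estimators computed on the OLS residuals
        rng = np.random.default_rng(12)
        n, k = 150, 2
        x = rng.binomial(2, 0.4, n).astype(float)
        b = rng.normal(0, 0.3, n)
        recs = []
        for j in range(k):
            y = 1.0 + 0.05 * x + b + rng.normal(0, 0.2, n)
            for i in range(n):
                recs.append((f"i{i}", float(j), 30.0, "male", "TC", float(np.exp(y[i]))))
        pheno = association.log_transform(pd.DataFrame(
            recs, columns=["iid", "visit", "age", "sex", "trait", "value"]))
        pred = pd.DataFrame({"x": x}, index=pd.Index([f"i{i}" for i in range(n)], name="iid"))
        spec = association.ModelSpec("x", "TC", "pooled", covariates=(), n_pcs=0)
        res = association.fit_longitudinal(spec, pheno, pred)

        # closed form: within-group mean square estimates sigma_e^2; the
        # between-group regression mean square estimates sigma_b^2 + sigma_e^2/k
        df_ = pheno.merge(pred, left_on="iid", right_index=True)
        grp = df_.groupby("iid")["value"]
        sse_within = ((df_["value"] - grp.transform("mean")) ** 2).sum()
        sigma_e2 = sse_within / (n * k - n)
        means = grp.mean()
        xm = pred.loc[means.index, "x"].to_numpy()
        design = np.column_stack([np.ones(n), xm])
        resid = means.to_numpy() - design @ np.linalg.lstsq(design, means.to_numpy(), rcond=None)[0]
        ms_between = (resid @ resid) / (n - 2)
        sigma_b2 = ms_between - sigma_e2 / k

        assert res.extra["var_residual"] == pytest.approx(sigma_e2, rel=1e-4)
        assert res.extra["var_intercept"] == pytest.approx(sigma_b2, rel=1e-3)

    def test_parameter_recovery_within_two_se(self):
        cfg = clean_config(
            n_families=400, n_snps=10, seed=21,
            effect_size_by_age={("LDL", a): 0.013 for a in VISITS},
            random_intercept_sd={t: 0.2 for t in sim.TRAITS},
            residual_sd={(t, a): 0.2 for t in sim.TRAITS for a in VISITS},
            visit_age_sd={a: 0.1 for a in VISITS},
        )
        cfg.panel_assignment = {s: ("LDL",) for s in cfg.snp_ids}
        _, pheno, gs = _fit_inputs(cfg)
        spec = association.ModelSpec("gs_LDL", "LDL", "pooled", n_pcs=0)
        res = association.fit_longitudinal(spec, pheno, gs)
        assert res.model == "lmm"
        assert abs(res.beta - 0.013) < 2 * res.se
        assert res.extra["var_intercept"] == pytest.approx(0.04, rel=0.5)

    def test_time_constant_predictor_beta_brackets_per_visit_ols(self):
        cfg = _noise_free_config(
            beta=0.01,
            effect_size_by_age={("TC", 0.0): 0.005, ("TC", 3.0): 0.01, ("TC", 5.0): 0.015},
            random_intercept_sd={t: 0.1 for t in sim.TRAITS},
        )
        _, pheno, gs = _fit_inputs(cfg)
        per_visit = [
            association.fit_cross_sectional(
                association.ModelSpec("gs_TC", "TC", a, covariates=("sex",), n_pcs=0),
                pheno, gs).beta
            for a in VISITS
        ]
        pooled = association.fit_longitudinal(
            association.ModelSpec("gs_TC", "TC", "pooled", covariates=("sex",), n_pcs=0),
            pheno, gs)
        assert min(per_visit) - 1e-9 <= pooled.beta <= max(per_visit) + 1e-9


class TestBonferroni:
    def test_study_threshold(self):
        thr = association.bonferroni_threshold(158, 3)
        assert f"{thr:.3g}" == "0.000105"

    @pytest.mark.parametrize("n_snps,n_t,expected", [(1, 1, 0.05), (100, 2, 2.5e-4)])
    def test_direct_division(self, n_snps, n_t, expected):
        assert association.bonferroni_threshold(n_snps, n_t) == pytest.approx(expected)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            association.bonferroni_threshold(0, 3)


def test_results_table_layout():
    rows = [association.AssociationResult("gs_TC", "TC", 3.0, 0.01, 0.002, 1e-5, 400, True)]
    tab = association.results_table(rows)
    assert list(tab.columns) == ["predictor", "trait", "visit", "beta", "se", "p",
                                 "n", "significant"]
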