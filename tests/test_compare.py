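"""Z-tests, inverse-normal transform, variance explained and power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lipidtrio import compare
from lipidtrio.association import AssociationResult
from lipidtrio.tables import ADULT_CHILD_COMPARISON


class TestZCompare:
    def test_cetp_row(self):
        zc = compare.z_compare(0.241, 0.004, 0.238, 0.052)
        assert zc.z == pytest.approx(0.058, abs=5.1e-4)
        assert zc.p == pytest.approx(0.477, abs=5e-4)

    def test_abca8_row(self):
        zc = compare.z_compare(0.028, 0.004, -0.139, 0.051)
        assert zc.z == pytest.approx(3.264, abs=5.1e-4)
        assert zc.p == pytest.approx(5.48e-4, rel=3e-3)

    @given(st.floats(-0.5, 0.5), st.floats(0.001, 0.2))
    @settings(max_examples=30, deadline=None)
    def test_identical_effects_give_z_zero_p_half(self, b, s):
        zc = compare.z_compare(b, s, b, s)
        assert zc.z == 0.0 and zc.p == pytest.approx(0.5)

    def test_swapping_negates_z_keeps_p(self):
        a = compare.z_compare(0.1, 0.02, 0.05, 0.03)
        b = compare.z_compare(0.05, 0.03, 0.1, 0.02)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_two_sided_doubles(self):
        one = compare.z_compare(0.1, 0.02, 0.0, 0.02)
        two = compare.z_compare(0.1, 0.02, 0.0, 0.02, two_sided=True)
        assert two.p == pytest.approx(2 * one.p)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            compare.z_compare(0.1, 0.0, 0.1, 0.02)


class TestInverseNormal:
    def test_median_maps_to_zero(self):
        out = compare.inverse_normal(np.array([3.0, 1.0, 2.0, 10.0, 4.0]))
        assert out[np.argsort([3.0, 1.0, 2.0, 10.0, 4.0])[2]] == pytest.approx(0.0)

    def test_n4_exact_quantiles(self):
        out = compare.inverse_normal(np.array([10.0, 20.0, 30.0, 40.0]))
        expected = stats.norm.ppf([0.125, 0.375, 0.625, 0.875])
        assert np.allclose(out, expected)

    def test_monotone_transform_invariance(self):
        x = np.random.default_rng(4).normal(size=100)
        assert np.allclose(compare.inverse_normal(x), compare.inverse_normal(np.exp(x)))

    def test_ties_get_average_rank(self):
        out = compare.inverse_normal(np.array([1.0, 1.0, 2.0]))
        assert out[0] == out[1]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            compare.inverse_normal(np.full(10, 3.3))

    def test_output_is_normal_by_shapiro(self):
        x = np.random.default_rng(9).exponential(size=500)
        w = stats.shapiro(compare.inverse_normal(x))
        assert w.pvalue > 0.01


def enumeration_variance(betas, mafs):
    """Oracle: exhaust all genotype combinations under independent HWE."""
    var_terms = []
    k = len(betas)
    combos = list(itertools.product(range(3), repeat=k))
    probs, vals = [], []
    for combo in combos:
        pr = 1.0
        v = 0.0
        for g, b, p in zip(combo, betas, mafs):
            hw = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}[g]
            pr *= hw
            v += b * g
        probs.append(pr)
        vals.append(v)
    probs, vals = np.array(probs), np.array(vals)
    mean = (probs * vals).sum()
    return (probs * (vals - mean) ** 2).sum()


class TestTheoreticalVariance:
    def test_zero_beta(self):
        assert compare.theoretical_variance([0.0], [0.3]) == 0.0

    def test_unit_beta_half_maf(self):
        assert compare.theoretical_variance([1.0], [0.5]) == pytest.approx(50.0)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_enumeration_oracle(self, k):
        rng = np.random.default_rng(k)
        betas = rng.normal(0, 0.1, k)
        mafs = rng.uniform(0.1, 0.9, k)
        expected = 100.0 * enumeration_variance(betas, mafs)
        got = compare.theoretical_variance(betas, mafs)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare.theoretical_variance([0.1, 0.2], [0.3])


class TestEmpiricalVariance:
    def _genotypes(self, n, m, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.binomial(2, 0.3, (n, m)).astype(float),
                            index=[f"i{j}" for j in range(n)],
                            columns=[f"s{j}" for j in range(m)]), rng

    def test_null_phenotype_near_zero(self):
        g, rng = self._genotypes(2000, 40)
        y = pd.Series(rng.normal(size=2000), index=g.index)
        pct, info = compare.empirical_variance(y, g)
        assert pct <= 100 * 40 / 2000 + 2
        assert not info["ridge"]

    def test_noise_free_saturates(self):
        g, rng = self._genotypes(500, 10)
        beta = rng.normal(0, 0.2, 10)
        y = pd.Series(g.to_numpy() @ beta, index=g.index)
        pct, _ = compare.empirical_variance(y, g)
        assert pct == pytest.approx(100.0, abs=1e-6)

    def test_recovers_known_fraction(self):
        g, rng = self._genotypes(5000, 40, seed=3)
        # scale betas for ~5% explained variance
        betas = rng.normal(0, 1.0, 40)
        gvar = np.sum(betas**2 * g.var(axis=0).to_numpy())
        betas *= np.sqrt(0.05 / gvar)
        y = pd.Series(g.to_numpy() @ betas + rng.normal(0, np.sqrt(0.95), 5000),
                      index=g.index)
        pct, _ = compare.empirical_variance(y, g)
        assert 3.0 < pct < 7.0

    def test_undersized_design_uses_ridge(self):
        g, rng = self._genotypes(30, 40)
        y = pd.Series(rng.normal(size=30), index=g.index)
        pct, info = compare.empirical_variance(y, g)
        assert info["ridge"] and 0.0 <= pct <= 100.0


class TestPower:
    def test_zero_beta_power_equals_alpha(self):
        spec = compare.PowerSpec(n=400, maf=0.3, beta=0.0, sigma=0.2, alpha=0.05)
        assert compare.analytic_power(spec) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_n(self):
        powers = [
            compare.analytic_power(
                compare.PowerSpec(n=n, maf=0.2, beta=0.05, sigma=0.2, alpha=0.05))
            for n in (50, 100, 200, 400, 800)
        ]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_min_detectable_beta_inverts_power(self):
        b = compare.min_detectable_beta(361, 0.3, 0.17, alpha=0.05, power=0.8)
        spec = compare.PowerSpec(n=361, maf=0.3, beta=b, sigma=0.17, alpha=0.05)
        assert compare.analytic_power(spec) == pytest.approx(0.8, abs=1e-6)

    def test_order_of_magnitude_matches_study_statement(self):
        # smallest detectable effect ~0.08 on the ln scale at the five-year
        # sample size across common allele frequencies
        sigma = 0.17  # ln-scale SD at five years
        betas = [compare.min_detectable_beta(361, maf, sigma, alpha=0.05, power=0.8)
                 for maf in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert 0.02 < min(betas) and max(betas) < 0.2


class TestCompareAgeEffects:
    def _res(self, beta, se, visit):
        return AssociationResult("gs_TC", "TC", visit, beta, se, 0.5, 400)

    def test_identical_results_give_zero_z(self):
        res = {a: self._res(0.01, 0.003, a) for a in (0.0, 3.0, 5.0)}
        out = compare.compare_age_effects(res)
        assert set(out) == {(0.0, 3.0), (0.0, 5.0), (3.0, 5.0)}
        assert all(zc.z == 0.0 for zc in out.values())

    def test_growing_effect_detected(self):
        res = {0.0: self._res(0.000, 0.003, 0.0), 5.0: self._res(0.02, 0.003, 5.0)}
        out = compare.compare_age_effects(res)
        assert out[(0.0, 5.0)].p < 0.05
        assert "correlation" in out[(0.0, 5.0)].note

    def test_missing_visit_skipped(self):
        res = {0.0: self._res(0.01, 0.003, 0.0)}
        assert compare.compare_age_effects(res) == {}


def test_published_comparison_table_is_internally_consistent():
    """Every complete row of the bundled adult/child table reproduces its own
    printed Z under the implemented convention."""
    tab = ADULT_CHILD_COMPARISON.dropna(subset=["adult_beta", "printed_z"])
    for _, r in tab.iterrows():
        zc = compare.z_compare(r["adult_beta"], r["adult_se"],
                               r["child_beta"], r["child_se"])
        assert zc.z == pytest.approx(r["printed_z"], abs=6e-4), r["rsid"]
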