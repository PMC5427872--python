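"""Effect-size comparison machinery.

Z-tests for effect-size differences (across visit ages within the cohort, or
children vs consortium adults on an inverse-normal trait scale), the
rank-based inverse-normal transform, theoretical and empirical
variance-explained decompositions, and analytic power for an additive
single-SNP test.

The Z-test p-value convention follows the source tables: p = 1 - Phi(|z|),
the upper tail of the absolute statistic.  A genuinely two-sided option
(2 * (1 - Phi(|z|))) is exposed as ``two_sided=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.linear_model import RidgeCV


@dataclass
class ZComparison:
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    z: float
    p: float
    two_sided: bool = False
    note: str = ""


@dataclass
class PowerSpec:
    n: int
    maf: float
    beta: float
    sigma: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1 or not 0 < self.maf < 1 or self.sigma <= 0 or not 0 < self.alpha < 1:
            raise ValueError("invalid power specification")


def z_compare(
    beta_a: float, se_a: float, beta_b: float, se_b: float, two_sided: bool = False
) -> ZComparison:
    """z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2) with p = 1 - Phi(|z|)
    (table convention) or doubled when ``two_sided``."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_a - beta_b) / float(np.hypot(se_a, se_b))
    p = float(stats.norm.sf(abs(z)))
    if two_sided:
        p = min(1.0, 2.0 * p)
    return ZComparison(beta_a, se_a, beta_b, se_b, float(z), p, two_sided)


def inverse_normal(values: np.ndarray | pd.Series, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^-1((rank - offset)/n) with
    average ranks for ties.  Puts traits measured on different scales onto a
    common standard-normal scale for cross-cohort effect comparison."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: all ranks tied, transform undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / len(x))


def theoretical_variance(
    betas: np.ndarray, mafs: np.ndarray, trait_variance: float = 1.0
) -> float:
    """Variance explained by independent HWE SNPs from summary statistics:
    sum of beta_i^2 * 2 * maf_i * (1 - maf_i), as a percentage of
    ``trait_variance``."""
    betas = np.asarray(betas, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if betas.shape != mafs.shape:
        raise ValueError("betas and mafs must have the same length")
    if np.any(mafs <= 0) or np.any(mafs >= 1):
        raise ValueError("mafs must lie strictly inside (0, 1)")
    var = float(np.sum(betas**2 * 2.0 * mafs * (1.0 - mafs)))
    return 100.0 * var / trait_variance


def empirical_variance(
    phenotype: pd.Series,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, dict]:
    """Percent of (covariate-adjusted) trait variance captured jointly by a
    SNP panel.

    The phenotype (already log-transformed) is residualized on the
    covariates plus an intercept; the adjusted R^2 of the joint OLS of the
    residuals on all panel SNPs (mean-imputed) is reported, floored at 0,
    as a percent.  A rank-deficient or undersized design falls back to
    ridge regression with GCV-chosen penalty, flagged in the info dict.
    """
    idx = phenotype.dropna().index.intersection(genotypes.index)
    if covariates is not None:
        idx = idx.intersection(covariates.dropna().index)
    y = phenotype.loc[idx].to_numpy(dtype=float)
    g = genotypes.loc[idx].astype(float)
    g = g.fillna(g.mean(axis=0)).to_numpy()
    n, p = g.shape

    if covariates is not None and covariates.shape[1] > 0:
        c = np.column_stack([np.ones(n), covariates.loc[idx].to_numpy(dtype=float)])
        y = y - c @ np.linalg.lstsq(c, y, rcond=None)[0]
    y = y - y.mean()
    g = g - g.mean(axis=0)

    info: dict = {"n": n, "n_snps": p, "ridge": False}
    tss = float(y @ y)
    if tss == 0:
        return 0.0, info
    rank = np.linalg.matrix_rank(g)
    if n > p + 2 and rank == p:
        coef, _, _, _ = np.linalg.lstsq(g, y, rcond=None)
        rss = float(np.sum((y - g @ coef) ** 2))
        r2 = 1.0 - rss / tss
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        ridge = RidgeCV(alphas=np.logspace(-2, 4, 25), gcv_mode="svd").fit(g, y)
        adj = float(ridge.score(g, y))
        info["ridge"] = True
        info["ridge_alpha"] = float(ridge.alpha_)
    return max(0.0, 100.0 * adj), info


def analytic_power(spec: PowerSpec) -> float:
    """Power of the two-sided level-alpha test of a single additive genotype
    term: noncentrality lambda = n * beta^2 * 2 maf (1-maf) / sigma^2 and
    power = P(|N(sqrt(lambda), 1)| > z_{1-alpha/2})."""
    lam = spec.n * spec.beta**2 * 2.0 * spec.maf * (1.0 - spec.maf) / spec.sigma**2
    zc = stats.norm.isf(spec.alpha / 2.0)
    mu = np.sqrt(lam)
    return float(stats.norm.sf(zc - mu) + stats.norm.cdf(-zc - mu))


def min_detectable_beta(
    n: int, maf: float, sigma: float, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Smallest allelic effect detectable with the given power — the
    inverse of ``analytic_power`` in beta."""
    def gap(beta: float) -> float:
        return analytic_power(PowerSpec(n=n, maf=maf, beta=beta, sigma=sigma, alpha=alpha)) - power

    hi = sigma
    while gap(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(gap, 1e-9, hi))


def compare_age_effects(results_by_visit: dict[float, "object"]) -> dict[tuple[float, float], ZComparison]:
    """Pairwise Z-comparison of per-visit effect estimates of one predictor
    on one trait (pairs 0-3, 3-5, 0-5 with the default schedule).

    The naive Z ignores the between-visit correlation induced by the
    overlapping individuals; each result is annotated accordingly.  Visits
    missing from the input are skipped.
    """
    ages = sorted(results_by_visit)
    out: dict[tuple[float, float], ZComparison] = {}
    for i, a in enumerate(ages):
        for b in ages[i + 1:]:
            ra, rb = results_by_visit[a], results_by_visit[b]
            zc = z_compare(ra.beta, ra.se, rb.beta, rb.se)
            zc.note = (
                "between-visit correlation ignored (overlapping individuals); "
                "test may be conservative or anticonservative"
            )
            out[(a, b)] = zc
    return out


def variance_report(
    per_trait: dict[str, dict],
) -> pd.DataFrame:
    """Assemble the variance-explained reporting table: one row per trait
    with the panel size, the theoretical percent from summary statistics,
    and empirical percents per visit."""
    rows = []
    for trait, d in per_trait.items():
        row = {"trait": trait, "n_snps": d.get("n_snps"),
               "theoretical_pct": d.get("theoretical_pct")}
        for visit, pct in sorted(d.get("empirical_pct", {}).items()):
            row[f"empirical_pct_{visit}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
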