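"""Association models for natural-log lipid traits.

Two model families, matching the longitudinal design:

* per-visit (cross-sectional) ordinary least squares,
      ln(lipid) ~ predictor + sex + age + PC1..PCk [+ parental genotype]
* a pooled random-intercept linear mixed model over all visits,
      ln(lipid) ~ predictor + sex + age + PC1..PCk + (1 | child)
  fitted by REML, which accounts for the within-child correlation of the
  three measurements.

The predictor is either a single SNP dosage (0/1/2 risk-allele copies) or a
trait genotype score.  Significance is labelled at a Bonferroni threshold
that counts markers x measurement times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class ModelSpec:
    """What to regress: one predictor against one trait at one timepoint
    ('pooled' selects the random-intercept mixed model)."""

    predictor: str
    trait: str
    timepoint: float | str = "pooled"
    covariates: tuple[str, ...] = ("sex", "age")
    n_pcs: int = 10
    parental_genotypes: bool = False

    @property
    def pooled(self) -> bool:
        return self.timepoint == "pooled"


@dataclass
class AssociationResult:
    predictor: str
    trait: str
    timepoint: float | str
    beta: float
    se: float
    p: float
    n: int
    significant: bool | None = None
    model: str = "ols"
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "predictor": self.predictor,
            "trait": self.trait,
            "visit": self.timepoint,
            "beta": self.beta,
            "se": self.se,
            "p": self.p,
            "n": self.n,
            "significant": self.significant,
        }


class CollinearityError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


def log_transform(phenotypes: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Natural-log transform the trait values (they are right-skewed on the
    natural scale).  Raises on non-positive values, naming the offender."""
    vals = phenotypes[value_col]
    bad = phenotypes[vals <= 0]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"non-positive trait value for individual {r.get('iid', '?')} "
            f"at visit {r.get('visit', '?')}: {r[value_col]}"
        )
    out = phenotypes.copy()
    out[value_col] = np.log(vals)
    out.attrs["transform"] = "ln"
    return out


def bonferroni_threshold(n_snps: int, n_timepoints: int, alpha: float = 0.05) -> float:
    """alpha / (markers x measurement times); with the study's 158 SNPs and
    3 visits this is 1.05e-4."""
    if n_snps < 1 or n_timepoints < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_snps * n_timepoints)


def _check_collinearity(x: pd.DataFrame) -> None:
    arr = x.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # identify aliased columns incrementally
    aliased, kept = [], []
    for j, name in enumerate(x.columns):
        trial = kept + [j]
        if np.linalg.matrix_rank(arr[:, trial]) == len(trial):
            kept.append(j)
        else:
            aliased.append(name)
    raise CollinearityError(f"aliased design columns: {aliased}")


def build_design(
    model: ModelSpec,
    phenotypes: pd.DataFrame,
    predictors: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    parental: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge phenotype records with predictor and covariate tables into a
    complete-case modelling frame (columns: y, predictor, covariates,
    grouping id).  ``phenotypes`` must already be log-transformed.

    Zero-variance covariates (e.g. age recorded without jitter at a single
    visit) are dropped with a warning rather than breaking the fit.
    """
    df = phenotypes[phenotypes["trait"] == model.trait].copy()
    if not model.pooled:
        df = df[df["visit"] == model.timepoint]
    if df.empty:
        raise ValueError(f"no phenotype records for {model.trait} at {model.timepoint}")
    if model.predictor not in predictors.columns:
        raise KeyError(f"predictor {model.predictor!r} not in predictor table")
    df = df.merge(
        predictors[[model.predictor]].rename(columns={model.predictor: "_x"}),
        left_on="iid", right_index=True, how="inner",
    )
    cov_cols: list[str] = []
    if "sex" in model.covariates:
        df["sex_male"] = (df["sex"] == "male").astype(float)
        cov_cols.append("sex_male")
    if "age" in model.covariates:
        cov_cols.append("age")
    if pcs is not None and model.n_pcs > 0:
        use = [c for c in pcs.columns if c.startswith("PC")][: model.n_pcs]
        df = df.merge(pcs[use], left_on="iid", right_index=True, how="inner")
        cov_cols.extend(use)
    if model.parental_genotypes:
        if parental is None:
            raise ValueError("parental_genotypes=True requires a parental dosage table")
        df = df.merge(parental, left_on="iid", right_index=True, how="inner")
        cov_cols.extend(parental.columns)

    df = df.rename(columns={"value": "y", "_x": "x"})
    keep = ["iid", "y", "x"] + cov_cols
    df = df[keep].dropna()
    for c in list(cov_cols):
        if df[c].nunique() <= 1:
            warnings.warn(f"dropping constant covariate {c!r}", stacklevel=2)
            cov_cols.remove(c)
            df = df.drop(columns=c)
    if df.shape[0] <= len(cov_cols) + 2:
        raise ValueError("too few complete cases for the requested model")
    return df


def _fit_frame_ols(df: pd.DataFrame) -> tuple[sm.regression.linear_model.RegressionResults, pd.DataFrame]:
    x = df.drop(columns=["iid", "y"])
    x = sm.add_constant(x, has_constant="add")
    _check_collinearity(x)
    return sm.OLS(df["y"], x).fit(), x


def fit_cross_sectional(
    model: ModelSpec,
    phenotypes: pd.DataFrame,
    predictors: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    parental: pd.DataFrame | None = None,
    significance_threshold: float | None = None,
) -> AssociationResult:
    """Per-visit OLS of ln(trait) on the predictor plus covariates.

    Returns the predictor's beta, its SE and the two-sided t-test p-value.
    """
    df = build_design(model, phenotypes, predictors, pcs, parental)
    res, _ = _fit_frame_ols(df)
    beta, se, p = res.params["x"], res.bse["x"], res.pvalues["x"]
    return AssociationResult(
        predictor=model.predictor, trait=model.trait, timepoint=model.timepoint,
        beta=float(beta), se=float(se), p=float(p), n=int(res.nobs),
        significant=None if significance_threshold is None else bool(p < significance_threshold),
        model="ols",
        extra={"r2": float(res.rsquared)},
    )


def fit_longitudinal(
    model: ModelSpec,
    phenotypes: pd.DataFrame,
    predictors: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    parental: pd.DataFrame | None = None,
    significance_threshold: float | None = None,
    reml: bool = True,
) -> AssociationResult:
    """Random-intercept linear mixed model pooled over visits, fitted by
    REML.  The returned beta is the predictor's fixed effect with its Wald
    SE and two-sided normal p-value; the estimated intercept and residual
    variances are exposed in ``extra``.

    A singular intercept variance (estimated at zero) triggers an OLS
    fallback with a warning; failure to converge raises
    ``ConvergenceError`` carrying the optimizer trace.
    """
    spec = model if model.pooled else ModelSpec(
        model.predictor, model.trait, "pooled", model.covariates, model.n_pcs,
        model.parental_genotypes,
    )
    df = build_design(spec, phenotypes, predictors, pcs, parental)
    if df.groupby("iid").size().max() < 2:
        raise ValueError("longitudinal model needs >= 2 visits for some individuals")
    x = sm.add_constant(df.drop(columns=["iid", "y"]), has_constant="add")
    _check_collinearity(x)
    mixed = sm.MixedLM(df["y"], x, groups=df["iid"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = mixed.fit(reml=reml)
        except Exception:
            try:
                res = mixed.fit(reml=reml, method="powell")
            except Exception as exc:
                raise ConvergenceError(f"mixed-model fit failed: {exc}") from exc
    var_intercept = float(res.cov_re.iloc[0, 0])
    var_resid = float(res.scale)
    # a singular fit shows up either as a variance estimate at the zero
    # boundary or as the optimizer stalling on its way there
    boundary = var_intercept <= 1e-8 * max(var_resid, 1e-12) or (
        not res.converged and var_intercept < 1e-2 * var_resid
    )
    if not res.converged and not boundary:
        trace = getattr(res, "mle_retvals", None) or getattr(res, "hist", None)
        raise ConvergenceError(f"mixed-model did not converge; optimizer trace: {trace}")
    if boundary:
        warnings.warn(
            "random-intercept variance estimated at zero; falling back to OLS",
            stacklevel=2,
        )
        ols = fit_cross_sectional(spec, phenotypes, predictors, pcs, parental,
                                  significance_threshold)
        ols.model = "ols_fallback"
        return ols
    beta, se = float(res.params["x"]), float(res.bse["x"])
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return AssociationResult(
        predictor=model.predictor, trait=model.trait, timepoint="pooled",
        beta=beta, se=se, p=p, n=int(res.nobs),
        significant=None if significance_threshold is None else bool(p < significance_threshold),
        model="lmm",
        extra={"var_intercept": var_intercept, "var_residual": var_resid,
               "n_groups": int(df["iid"].nunique())},
    )


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Stack association results into the reporting layout
    (predictor, trait, visit, beta, se, p, n, significant)."""
    return pd.DataFrame([r.to_row() for r in results])
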