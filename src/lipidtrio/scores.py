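"""Unweighted trait-specific genotype scores.

A genotype score (GS) for a lipid trait is the per-individual sum of
lipid-increasing allele counts over the trait's SNP panel.  Missing
genotypes are mean-imputed per SNP using the arithmetic average of the
coded genotypes of all successfully genotyped individuals, so the score is
defined for every individual and panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sim import TRAITS


def mean_impute(column: pd.Series) -> pd.Series:
    """Replace missing genotypes in one SNP column by the arithmetic mean of
    the observed genotypes; observed entries are unchanged."""
    col = column.astype(float)
    if col.notna().sum() == 0:
        raise ValueError(f"SNP {column.name!r}: all genotypes missing, cannot impute")
    return col.fillna(col.mean())


def genotype_score(
    genotypes: pd.DataFrame,
    panel_assignment: dict[str, tuple[str, ...]],
    traits: tuple[str, ...] = TRAITS,
    impute_on: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Unweighted genotype scores per individual and trait panel.

    ``genotypes`` rows are the individuals to score; the imputation means
    are computed on ``impute_on`` (default: the same matrix — pass the full
    cohort matrix to impute children with means over children and parents
    pooled).  Returns columns ``gs_<trait>`` and ``n_imputed_<trait>``.
    """
    impute_on = genotypes if impute_on is None else impute_on
    out = {}
    for trait in traits:
        panel = [s for s, ts in panel_assignment.items() if trait in ts]
        missing = [s for s in panel if s not in genotypes.columns]
        if missing:
            raise KeyError(f"panel SNPs absent from genotype matrix: {missing}")
        if not panel:
            out[f"gs_{trait}"] = pd.Series(0.0, index=genotypes.index)
            out[f"n_imputed_{trait}"] = pd.Series(0, index=genotypes.index)
            continue
        sub = genotypes[panel].astype(float)
        means = impute_on[panel].astype(float).mean(axis=0)
        if means.isna().any():
            bad = list(means.index[means.isna()])
            raise ValueError(f"SNPs with no observed genotypes: {bad}")
        filled = sub.fillna(means)
        out[f"gs_{trait}"] = filled.sum(axis=1)
        out[f"n_imputed_{trait}"] = sub.isna().sum(axis=1)
    return pd.DataFrame(out, index=genotypes.index)
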