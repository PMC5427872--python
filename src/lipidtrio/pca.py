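"""EIGENSTRAT-style principal components of the genotype matrix.

Used both as fixed-effect covariates to absorb population structure in the
association models and as a coarse ancestry classifier check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PcScores:
    scores: pd.DataFrame  # individuals x k (columns PC1..PCk)
    eigenvalues: np.ndarray  # length k, non-increasing
    snp_loadings: pd.DataFrame  # SNPs x k


def standardize_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute each SNP column, then scale as (g - 2p)/sqrt(2p(1-p))
    with p the observed allele frequency.  Monomorphic or zero-variance
    SNPs are dropped with a warning."""
    g = genotypes.astype(float)
    p_hat = g.mean(axis=0) / 2.0
    var_ok = (p_hat > 0) & (p_hat < 1) & (g.var(axis=0, ddof=0) > 0)
    if (~var_ok).any():
        warnings.warn(
            f"dropping {int((~var_ok).sum())} monomorphic/zero-variance SNPs before PCA",
            stacklevel=2,
        )
    g = g.loc[:, var_ok]
    p_hat = p_hat[var_ok]
    if g.shape[1] == 0:
        raise ValueError("no SNP with nonzero variance: cannot standardize")
    g = g.fillna(g.mean(axis=0))
    denom = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    return (g - 2.0 * p_hat) / denom


def compute_pcs(genotypes: pd.DataFrame, k: int = 10) -> PcScores:
    """Top-k principal components of the standardized genotype matrix.

    Scores are the projections of individuals on the eigenvectors of the
    individual x individual covariance X X^T / m of the standardized matrix
    X; eigenvalues are returned in non-increasing order.  Sign convention:
    the largest-magnitude SNP loading of each component is positive.
    """
    x = standardize_genotypes(genotypes)
    n, m = x.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} individuals for k={k} components")
    if m < k:
        raise ValueError(f"need at least {k} SNPs with nonzero variance")
    u, s, vt = np.linalg.svd(x.to_numpy(), full_matrices=False)
    u, s, v = u[:, :k], s[:k], vt[:k].T
    # sign convention per component
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    u, v = u * flip, v * flip
    cols = [f"PC{i + 1}" for i in range(k)]
    return PcScores(
        scores=pd.DataFrame(u * s, index=x.index, columns=cols),
        eigenvalues=s**2 / m,
        snp_loadings=pd.DataFrame(v, index=x.columns, columns=cols),
    )
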