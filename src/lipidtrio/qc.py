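"""Genotype quality control for the trio cohort.

Implements the QC pipeline the family design affords: per-sample missing-rate
and per-SNP call-rate filters, Hardy–Weinberg testing (asymptotic chi-square
plus an allele-shuffling permutation p-value), Mendelian-consistency
screening with flagging of putative non-biological fathers, greedy LD
pruning, and proxy-SNP selection over a user-supplied LD/annotation table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .sim import TrioCohort


@dataclass(frozen=True)
class QcThresholds:
    sample_missing_max: float = 0.10
    snp_call_rate_min: float = 0.97
    hwe_p_min: float = 1e-6
    ld_r2_max: float = 0.2
    proxy_r2_min: float = 0.95

    def __post_init__(self) -> None:
        for name in ("sample_missing_max", "snp_call_rate_min", "hwe_p_min",
                     "ld_r2_max", "proxy_r2_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class HweResult:
    chi2: float
    p_asymptotic: float
    p_permutation: float | None
    counts: tuple[int, int, int]
    monomorphic: bool = False


@dataclass
class MendelReport:
    inconsistencies: pd.DataFrame  # fid, snp, child_g, mother_g, father_g
    flagged_fathers: frozenset[str]
    n_tested: pd.Series  # father iid -> SNPs tested in full trios
    n_untested: int = 0


def filter_samples_and_snps(
    cohort: TrioCohort, thresholds: QcThresholds = QcThresholds()
) -> tuple[TrioCohort, pd.DataFrame]:
    """Sample-first missing-rate filter, then SNP call-rate filter.

    Individuals whose fraction of missing genotypes exceeds
    ``sample_missing_max`` are removed first; SNP call rates are then
    recomputed on the remaining individuals and SNPs below
    ``snp_call_rate_min`` are dropped.  Returns the filtered cohort and a
    removal log (kind, id, statistic).
    """
    geno = cohort.genotypes
    if geno.size == 0:
        raise ValueError("empty genotype matrix")
    log = []

    # sample-first, then SNP, iterated to a fixed point: removing SNPs can
    # push a remaining sample's missing fraction back over threshold, so a
    # single pass would not be idempotent
    changed = True
    while changed:
        changed = False
        sample_missing = geno.isna().mean(axis=1)
        bad_samples = sample_missing[sample_missing > thresholds.sample_missing_max]
        for iid, frac in bad_samples.items():
            log.append(("sample", iid, "missing_fraction", float(frac)))
        if len(bad_samples):
            geno = geno.drop(index=bad_samples.index)
            changed = True
        if geno.shape[0] == 0:
            raise ValueError("all samples removed by the missing-rate filter")

        call_rate = 1.0 - geno.isna().mean(axis=0)
        bad_snps = call_rate[call_rate < thresholds.snp_call_rate_min]
        for snp, cr in bad_snps.items():
            log.append(("snp", snp, "call_rate", float(cr)))
        if len(bad_snps):
            geno = geno.drop(columns=bad_snps.index)
            changed = True
        if geno.shape[1] == 0:
            raise ValueError("all SNPs removed by the call-rate filter")

    kept = set(geno.index)
    filtered = replace(
        cohort,
        genotypes=geno,
        role=cohort.role[cohort.role.index.isin(kept)],
        pedigree=cohort.pedigree[cohort.pedigree["mother"].isin(kept)
                                 & cohort.pedigree["child"].isin(kept)].reset_index(drop=True),
        true_child_genotypes=None,
    )
    return filtered, pd.DataFrame(log, columns=["kind", "id", "statistic", "value"])


def genotype_counts(column: pd.Series | np.ndarray) -> tuple[int, int, int]:
    """Observed (n_AA, n_Aa, n_aa) counts, AA = two risk alleles."""
    g = np.asarray(column, dtype=float)
    g = g[~np.isnan(g)]
    return int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())


def _hwe_chi2_from_het(n_het: np.ndarray, n_alt: int, n: int) -> np.ndarray:
    """Goodness-of-fit chi2 given heterozygote count, total risk alleles
    ``n_alt`` and sample size ``n`` (genotype counts are determined by the
    heterozygote count once the allele count is fixed)."""
    n_het = np.asarray(n_het, dtype=float)
    n_aa = (n_alt - n_het) / 2.0  # homozygous risk
    n_rr = n - n_aa - n_het
    p = n_alt / (2.0 * n)
    exp = np.array([n * p**2, 2.0 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.stack([n_aa, n_het, n_rr])
    return ((obs - exp[:, None]) ** 2 / exp[:, None]).sum(axis=0)


def hwe_test(
    counts: tuple[int, int, int],
    n_permutations: int = 0,
    seed: int | np.random.Generator | None = None,
) -> HweResult:
    """Hardy–Weinberg chi-square test with an optional permutation p-value.

    The statistic is the 1-df goodness of fit of the observed genotype
    counts against p^2 / 2pq / q^2 at the observed allele frequency.  The
    permutation p shuffles the 2n alleles into random diploid pairs
    ``n_permutations`` times: p = (1 + #{chi2_perm >= chi2_obs}) / (1 + B),
    with exact ties broken uniformly at random so the p-value is exactly
    discrete-uniform under the null.  Monomorphic input returns chi2 = 0,
    p = 1 with ``monomorphic=True``.
    """
    n_aa, n_het, n_rr = (int(c) for c in counts)
    if min(n_aa, n_het, n_rr) < 0 or n_aa + n_het + n_rr < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    n = n_aa + n_het + n_rr
    n_alt = 2 * n_aa + n_het
    if n_alt == 0 or n_alt == 2 * n:
        return HweResult(0.0, 1.0, 1.0 if n_permutations else None,
                         (n_aa, n_het, n_rr), monomorphic=True)

    chi2 = float(_hwe_chi2_from_het(np.array([n_het]), n_alt, n)[0])
    p_asym = float(stats.chi2.sf(chi2, df=1))

    p_perm = None
    if n_permutations > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        alleles = np.zeros(2 * n, dtype=np.int8)
        alleles[:n_alt] = 1
        mat = np.tile(alleles, (n_permutations, 1))
        rng.permuted(mat, axis=1, out=mat)
        pairs = mat.reshape(n_permutations, n, 2)
        het_counts = (pairs[:, :, 0] != pairs[:, :, 1]).sum(axis=1)
        chi2_perm = _hwe_chi2_from_het(het_counts, n_alt, n)
        # the heterozygote count is lattice-valued, so exact ties between the
        # observed and permuted statistics carry appreciable mass; random
        # tie-breaking (an iid sub-resolution jitter on every statistic)
        # restores the exact discrete-uniform null of Monte Carlo tests
        jitter = 1e-9 * rng.random(n_permutations + 1)
        p_perm = float(
            (1 + np.sum(chi2_perm + jitter[1:] >= chi2 + jitter[0]))
            / (1 + n_permutations)
        )
    return HweResult(chi2, p_asym, p_perm, (n_aa, n_het, n_rr))


def _trio_consistent(m: np.ndarray, f: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Child genotype representable as one transmitted allele from each
    parent: parent with genotype g can transmit g//2 .. (g+1)//2 copies."""
    lo = m // 2 + f // 2
    hi = (m + 1) // 2 + (f + 1) // 2
    return (c >= lo) & (c <= hi)


def _duo_consistent(m: np.ndarray, c: np.ndarray) -> np.ndarray:
    return (c >= m // 2) & (c <= (m + 1) // 2 + 1)


def mendelian_check(
    cohort: TrioCohort, recurrence_threshold: float = 0.05
) -> MendelReport:
    """Screen every family for Mendelian-transmission violations.

    Full trios are checked against one-allele-from-each-parent rules; duos
    (father not genotyped, or father genotype missing at a SNP) against the
    mother-child rules.  Fathers whose trio inconsistencies recur —
    exceeding ``recurrence_threshold`` as a fraction of their tested SNPs
    when < 1, or as an absolute count otherwise — are flagged as putative
    non-biological fathers.  (family, SNP) pairs with a missing child or
    mother genotype are skipped and counted as untested.
    """
    geno = cohort.genotypes
    snps = np.array(cohort.snp_ids)
    rows = []
    father_bad: dict[str, int] = {}
    father_tested: dict[str, int] = {}
    n_untested = 0

    for _, fam in cohort.pedigree.iterrows():
        c = geno.loc[fam["child"]].to_numpy(dtype=float)
        m = geno.loc[fam["mother"]].to_numpy(dtype=float)
        has_father = fam["father"] in geno.index
        f = geno.loc[fam["father"]].to_numpy(dtype=float) if has_father else np.full_like(c, np.nan)

        cm_ok = ~np.isnan(c) & ~np.isnan(m)
        n_untested += int((~cm_ok).sum())
        trio_mask = cm_ok & ~np.isnan(f)
        duo_mask = cm_ok & np.isnan(f)

        bad = np.zeros(len(snps), dtype=bool)
        if trio_mask.any():
            ok = _trio_consistent(m[trio_mask].astype(int), f[trio_mask].astype(int),
                                  c[trio_mask].astype(int))
            bad[np.flatnonzero(trio_mask)[~ok]] = True
        if duo_mask.any():
            ok = _duo_consistent(m[duo_mask].astype(int), c[duo_mask].astype(int))
            bad[np.flatnonzero(duo_mask)[~ok]] = True

        if has_father:
            father_tested[fam["father"]] = int(trio_mask.sum())
            father_bad[fam["father"]] = int((bad & trio_mask).sum())
        for j in np.flatnonzero(bad):
            rows.append((fam["fid"], snps[j], int(c[j]), int(m[j]),
                         int(f[j]) if not np.isnan(f[j]) else None))

    flagged = set()
    for fa, n_bad in father_bad.items():
        n_test = father_tested[fa]
        if n_test == 0:
            continue
        limit = recurrence_threshold * n_test if recurrence_threshold < 1 else recurrence_threshold
        if n_bad > limit:
            flagged.add(fa)

    report = MendelReport(
        inconsistencies=pd.DataFrame(
            rows, columns=["fid", "snp", "child_g", "mother_g", "father_g"]
        ),
        flagged_fathers=frozenset(flagged),
        n_tested=pd.Series(father_tested, dtype=int),
        n_untested=n_untested,
    )
    return report


def ld_prune(
    snp_ids: list[str],
    r2_table: pd.DataFrame,
    threshold: float = 0.2,
) -> list[str]:
    """Greedy LD pruning in panel order.

    Scanning ``snp_ids`` in order, a SNP is discarded if its r2 with any
    previously *kept* SNP exceeds ``threshold``.  ``r2_table`` has columns
    (snp_a, snp_b, r2), treated as symmetric; absent pairs count as r2 = 0
    (warned once).
    """
    lut: dict[tuple[str, str], float] = {}
    for a, b, r2 in r2_table[["snp_a", "snp_b", "r2"]].itertuples(index=False):
        lut[(a, b)] = float(r2)
        lut[(b, a)] = float(r2)
    warned = False
    kept: list[str] = []
    for snp in snp_ids:
        drop = False
        for other in kept:
            if (snp, other) not in lut and not warned:
                warnings.warn("missing r2 entries treated as r2 = 0", stacklevel=2)
                warned = True
            if lut.get((snp, other), 0.0) > threshold:
                drop = True
                break
        if not drop:
            kept.append(snp)
    return kept


def select_proxy(
    lead_snp: str,
    candidates: pd.DataFrame,
    proxy_r2_min: float = 0.95,
) -> str | None:
    """Choose a proxy for an unavailable lead SNP.

    ``candidates`` must have columns (snp, r2, is_coding_ns, distance) and be
    pre-restricted to the available array.  Candidates with r2 >
    ``proxy_r2_min`` survive; among survivors any coding non-synonymous SNP
    is preferred (highest r2 breaking ties), otherwise the SNP closest to
    the lead.  Returns ``None`` (logged as a warning) if nothing survives.
    """
    surv = candidates[candidates["r2"] > proxy_r2_min]
    if surv.empty:
        warnings.warn(f"no proxy with r2 > {proxy_r2_min} for {lead_snp}", stacklevel=2)
        return None
    coding = surv[surv["is_coding_ns"].astype(bool)]
    if not coding.empty:
        return str(coding.sort_values("r2", ascending=False).iloc[0]["snp"])
    return str(surv.sort_values("distance").iloc[0]["snp"])
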