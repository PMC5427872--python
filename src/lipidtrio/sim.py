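"""Synthetic trio-cohort generator.

Emulates a longitudinal parent–child birth cohort: families of one child,
one genotyped mother and a partially genotyped father; a panel of adult
lipid-associated SNPs in four overlapping trait panels; and lognormal lipid
phenotypes (TC, LDL-C, HDL-C, TG) measured at birth, 3 and 5 years, with
additive per-allele effects on the natural-log scale that may grow with age,
a per-child random intercept inducing within-person correlation, genotype
missingness, visit attrition, and optional non-paternity.

Parental genotypes are drawn from Hardy–Weinberg proportions under random
mating; each child allele is transmitted uniformly from the corresponding
parent's two alleles.  Non-paternity replaces the father's *transmitted*
allele with a population draw while leaving the recorded pedigree intact, so
quality control has to discover it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables

TRAITS = ("TC", "LDL", "HDL", "TG")
DEFAULT_VISIT_AGES = (0.0, 3.0, 5.0)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Natural-scale (mean, sd) -> (mu, sigma) of ln(value).

    sd = 0 gives sigma = 0 and mu = ln(mean) exactly.
    """
    if mean <= 0:
        raise ValueError(f"lognormal mean must be positive, got {mean}")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``effect_size_by_age`` maps ``(predictor, visit_age) -> beta`` on the
    natural-log trait scale, where ``predictor`` is either a SNP id (per
    risk-allele effect) or a trait name in ``TRAITS`` (per genotype-score
    unit, applied to the trait's panel score).  ``effect_trait`` names the
    phenotype a predictor acts on; a GS predictor defaults to its own trait,
    a SNP predictor must be listed explicitly.
    """

    n_families: int = 544
    father_genotyped_fraction: float = 352 / 544
    maf: np.ndarray = field(default_factory=lambda: np.full(158, 0.3))
    snp_ids: list[str] | None = None
    panel_assignment: dict[str, tuple[str, ...]] = field(default_factory=dict)
    effect_size_by_age: dict[tuple[str, float], float] = field(default_factory=dict)
    effect_trait: dict[str, str] = field(default_factory=dict)
    trait_baseline_mean: dict[tuple[str, float], float] = field(default_factory=dict)
    trait_baseline_sd: dict[tuple[str, float], float] = field(default_factory=dict)
    random_intercept_sd: dict[str, float] = field(default_factory=dict)
    residual_sd: dict[tuple[str, float], float] = field(default_factory=dict)
    sex_effect: float = 0.0
    age_effect: float = 0.0
    visit_ages: tuple[float, ...] = DEFAULT_VISIT_AGES
    visit_age_mean: dict[float, float] = field(default_factory=dict)
    visit_age_sd: dict[float, float] = field(default_factory=dict)
    visit_attendance: dict[float, float] = field(default_factory=dict)
    genotype_missing_rate: float = 0.0
    nonpaternity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.maf.ndim != 1 or len(self.maf) < 1:
            raise ValueError("maf must be a non-empty 1-D vector")
        if np.any(self.maf <= 0.0) or np.any(self.maf >= 1.0):
            raise ValueError("all maf entries must lie strictly inside (0, 1)")
        for name, value in [
            ("father_genotyped_fraction", self.father_genotyped_fraction),
            ("genotype_missing_rate", self.genotype_missing_rate),
            ("nonpaternity_rate", self.nonpaternity_rate),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{i + 1:04d}" for i in range(len(self.maf))]
        if len(self.snp_ids) != len(self.maf):
            raise ValueError("snp_ids and maf must have the same length")
        for sd in self.random_intercept_sd.values():
            if sd < 0:
                raise ValueError("random_intercept_sd must be >= 0")
        for sd in self.residual_sd.values():
            if sd < 0:
                raise ValueError("residual_sd must be >= 0")
        for age in self.visit_ages:
            self.visit_age_mean.setdefault(age, age)
            self.visit_age_sd.setdefault(age, 0.0)
            self.visit_attendance.setdefault(age, 1.0)
        for trait in TRAITS:
            self.random_intercept_sd.setdefault(trait, 0.0)
            for age in self.visit_ages:
                self.trait_baseline_mean.setdefault((trait, age), 1.0)
                self.trait_baseline_sd.setdefault((trait, age), 0.0)

    @property
    def n_snps(self) -> int:
        return len(self.maf)


@dataclass
class TrioCohort:
    """Genotyped individuals plus the pedigree linking child-mother-father.

    ``genotypes`` is individuals x SNPs, coded 0/1/2 as copies of the
    lipid-increasing allele, ``NaN`` for missing.  The pedigree always
    records the father id; fathers without a genotype row were simply not
    genotyped (mother-child duos for QC purposes).
    """

    genotypes: pd.DataFrame
    pedigree: pd.DataFrame  # columns: fid, child, mother, father
    role: pd.Series  # iid -> {child, mother, father}
    sex: pd.Series  # child iid -> {male, female}
    true_child_genotypes: pd.DataFrame | None = None
    nonpaternal_fathers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        vals = self.genotypes.to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if not np.isin(obs, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotype values must be 0/1/2/missing")
        if not set(self.pedigree["mother"]) <= set(self.genotypes.index):
            raise ValueError("every child must have a genotyped mother record")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def children(self) -> list[str]:
        return list(self.pedigree["child"])


def simulate_trios(config: SimConfig) -> TrioCohort:
    """Draw parental genotypes from Hardy–Weinberg proportions and transmit.

    Each child receives one allele from each parent, chosen uniformly among
    the parent's two alleles.  With probability ``nonpaternity_rate`` (per
    family) the paternal allele is instead drawn from the population at the
    configured allele frequency.  Missingness is applied independently per
    genotype call at ``genotype_missing_rate``.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_families, config.n_snps
    maf = config.maf

    mother_g = rng.binomial(2, maf, size=(n, m)).astype(float)
    father_g = rng.binomial(2, maf, size=(n, m)).astype(float)

    # one allele from each parent: P(transmit risk allele) = g/2
    mat_allele = rng.random((n, m)) < mother_g / 2.0
    pat_allele = rng.random((n, m)) < father_g / 2.0
    nonpat = rng.random(n) < config.nonpaternity_rate
    if nonpat.any():
        pop_allele = rng.random((int(nonpat.sum()), m)) < maf
        pat_allele[nonpat] = pop_allele
    child_g = mat_allele.astype(float) + pat_allele.astype(float)

    fids = [f"F{i + 1:04d}" for i in range(n)]
    child_ids = [f + "_C" for f in fids]
    mother_ids = [f + "_M" for f in fids]
    father_ids = [f + "_D" for f in fids]

    n_geno_fathers = int(round(config.father_genotyped_fraction * n))
    geno_father_idx = np.sort(rng.choice(n, size=n_geno_fathers, replace=False))

    geno = pd.DataFrame(
        np.vstack([child_g, mother_g, father_g[geno_father_idx]]),
        index=child_ids + mother_ids + [father_ids[i] for i in geno_father_idx],
        columns=config.snp_ids,
    )
    if config.genotype_missing_rate > 0:
        mask = rng.random(geno.shape) < config.genotype_missing_rate
        geno = geno.mask(mask)

    pedigree = pd.DataFrame(
        {"fid": fids, "child": child_ids, "mother": mother_ids, "father": father_ids}
    )
    role = pd.Series(
        {**{c: "child" for c in child_ids},
         **{mo: "mother" for mo in mother_ids},
         **{father_ids[i]: "father" for i in geno_father_idx}}
    )
    sex = pd.Series(
        np.where(rng.random(n) < tables.CHILD_SEX_MALE_FRACTION, "male", "female"),
        index=child_ids,
    )
    return TrioCohort(
        genotypes=geno,
        pedigree=pedigree,
        role=role,
        sex=sex,
        true_child_genotypes=pd.DataFrame(child_g, index=child_ids, columns=config.snp_ids),
        nonpaternal_fathers=frozenset(father_ids[i] for i in np.flatnonzero(nonpat)),
    )


def true_genotype_scores(cohort: TrioCohort, config: SimConfig) -> pd.DataFrame:
    """Per-child unweighted panel scores from the complete (pre-missingness)
    genotypes — the causal scores the phenotype generator uses."""
    g = cohort.true_child_genotypes
    if g is None:
        raise ValueError("cohort carries no complete genotype matrix")
    out = {}
    for trait in TRAITS:
        panel = [s for s, traits in config.panel_assignment.items() if trait in traits]
        out[trait] = g[panel].sum(axis=1) if panel else pd.Series(0.0, index=g.index)
    return pd.DataFrame(out)


def simulate_phenotypes(cohort: TrioCohort, config: SimConfig) -> pd.DataFrame:
    """Generate longitudinal lipid phenotypes for the children.

    ln(value) = visit baseline + sum of configured additive genetic effects
    + sex_effect * 1[male] + age_effect * age + per-child random intercept
    + visit residual; the value is returned on the natural scale.  Returns a
    long-format frame (iid, fid, visit, age, sex, trait, value).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    children = cohort.children
    n = len(children)
    gs_true = true_genotype_scores(cohort, config)
    g_true = cohort.true_child_genotypes

    # validate effect table: every predictor must cover every visit and
    # name the trait it acts on
    predictors = {p for p, _ in config.effect_size_by_age}
    target: dict[str, str] = {}
    for p in predictors:
        for age in config.visit_ages:
            if (p, age) not in config.effect_size_by_age:
                raise ValueError(
                    f"effect_size_by_age lacks an entry for predictor {p!r} at visit age {age}"
                )
        if p not in TRAITS and p not in g_true.columns:
            raise ValueError(f"unknown predictor {p!r} in effect_size_by_age")
        target[p] = config.effect_trait.get(p, p if p in TRAITS else None)
        if target[p] not in TRAITS:
            raise ValueError(f"effect_trait must name the target trait for SNP {p!r}")

    intercepts = {
        t: rng.normal(0.0, config.random_intercept_sd[t], size=n) for t in TRAITS
    }
    male = (cohort.sex.loc[children] == "male").to_numpy(dtype=float)

    records = []
    for age in config.visit_ages:
        attend = rng.random(n) < config.visit_attendance[age]
        actual_age = rng.normal(config.visit_age_mean[age], config.visit_age_sd[age], size=n)
        for trait in TRAITS:
            mu, sigma_base = _lognormal_params(
                config.trait_baseline_mean[(trait, age)],
                config.trait_baseline_sd[(trait, age)],
            )
            resid_sd = config.residual_sd.get((trait, age), sigma_base)
            ln_val = mu + config.sex_effect * male + config.age_effect * actual_age
            ln_val = ln_val + intercepts[trait]
            for p in predictors:
                if target[p] != trait:
                    continue
                beta = config.effect_size_by_age[(p, age)]
                if beta == 0.0:
                    continue
                dosage = gs_true[p] if p in TRAITS else g_true[p]
                ln_val = ln_val + beta * dosage.to_numpy()
            ln_val = ln_val + rng.normal(0.0, resid_sd, size=n)
            for i in np.flatnonzero(attend):
                records.append(
                    (children[i], cohort.pedigree["fid"].iloc[i], age,
                     actual_age[i], cohort.sex.iloc[i], trait, math.exp(ln_val[i]))
                )
    pheno = pd.DataFrame(
        records, columns=["iid", "fid", "visit", "age", "sex", "trait", "value"]
    )
    return pheno


def default_panel_assignment(
    snp_ids: list[str], sizes: dict[str, int] | None = None, seed: int = 0
) -> dict[str, tuple[str, ...]]:
    """Assign SNPs to overlapping trait panels with the study's panel sizes.

    Every SNP belongs to at least one panel (the panel list is the union of
    the trait panels); the 241 memberships over 158 SNPs force overlaps,
    mirroring SNPs associated with several lipid traits.
    """
    sizes = dict(sizes or tables.PANEL_SIZES)
    total = sum(sizes.values())
    if total < len(snp_ids):
        raise ValueError("panel sizes too small to cover every SNP")
    rng = np.random.default_rng(seed)
    traits = list(sizes)
    membership: dict[str, set[str]] = {t: set() for t in traits}
    # first pass: give every SNP one primary panel, filling quotas proportionally
    order = rng.permutation(len(snp_ids))
    quota = dict(sizes)
    for idx in order:
        open_traits = [t for t in traits if len(membership[t]) < quota[t]]
        weights = np.array([quota[t] - len(membership[t]) for t in open_traits], float)
        t = rng.choice(open_traits, p=weights / weights.sum())
        membership[t].add(snp_ids[idx])
    # second pass: fill remaining quota with extra memberships
    for t in traits:
        pool = [s for s in snp_ids if s not in membership[t]]
        extra = quota[t] - len(membership[t])
        if extra > 0:
            membership[t].update(rng.choice(pool, size=extra, replace=False))
    out: dict[str, tuple[str, ...]] = {}
    for t in traits:
        for s in membership[t]:
            out.setdefault(s, ())
            out[s] = out[s] + (t,)
    return {s: tuple(sorted(v)) for s, v in out.items()}


def default_study_config(seed: int = 0, **overrides) -> SimConfig:
    """A configuration emulating the study cohort.

    544 families with ~65% of fathers genotyped; 158 SNPs with allele
    frequencies Uniform(0.05, 0.5) in four overlapping panels of sizes
    69/59/73/40; Table-1-scale lognormal baselines; genotype-score effects
    on the natural-log scale growing from birth to 5 years at magnitudes
    matching the cohort's reported estimates; per-visit attendance matching
    the reported per-visit sample sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    n_snps = 158
    maf = rng.uniform(0.05, 0.5, size=n_snps)
    snp_ids = [f"snp{i + 1:04d}" for i in range(n_snps)]
    panels = default_panel_assignment(snp_ids, seed=seed)

    baseline_mean, baseline_sd, residual_sd = {}, {}, {}
    summary = tables.CHILD_PHENOTYPE_SUMMARY.set_index(["trait", "visit"])
    # the intercept SD sets the lipid "tracking" of a child across visits;
    # childhood lipid ranking is strongly persistent, so the intercept takes
    # roughly half of each trait's smallest per-visit ln-scale variance
    ri_sd = {"TC": 0.13, "LDL": 0.19, "HDL": 0.16, "TG": 0.27}
    for trait in TRAITS:
        for age in DEFAULT_VISIT_AGES:
            mean, sd = summary.loc[(trait, int(age)), ["mean", "sd"]]
            baseline_mean[(trait, age)] = float(mean)
            baseline_sd[(trait, age)] = float(sd)

    # per-GS-unit effects on ln(trait), growing with age as reported
    effects = {}
    gs_beta = {
        "TC": {0.0: 0.002, 3.0: 0.009, 5.0: 0.009},
        "LDL": {0.0: 0.003, 3.0: 0.017, 5.0: 0.020},
        "HDL": {0.0: 0.002, 3.0: 0.005, 5.0: 0.007},
        "TG": {0.0: 0.000, 3.0: 0.002, 5.0: 0.002},
    }
    for trait, by_age in gs_beta.items():
        for age, b in by_age.items():
            effects[(trait, age)] = b

    # centre the baselines for the expected genetic and sex contributions so
    # the simulated per-visit means land on the published summaries
    panel_var = {
        t: float(sum(2.0 * maf[i] * (1.0 - maf[i]) for i, s in enumerate(snp_ids)
                     if t in panels[s]))
        for t in TRAITS
    }
    panel_mean = {
        t: float(sum(2.0 * maf[i] for i, s in enumerate(snp_ids) if t in panels[s]))
        for t in TRAITS
    }
    sex_effect = 0.02
    for trait in TRAITS:
        for age in DEFAULT_VISIT_AGES:
            shift = gs_beta[trait][age] * panel_mean[trait] + sex_effect * 0.5
            scale = math.exp(shift)
            baseline_mean[(trait, age)] /= scale
            baseline_sd[(trait, age)] /= scale
            # allocate the published total ln-variance between the random
            # intercept, the genetic term and the visit residual
            _, sigma = _lognormal_params(baseline_mean[(trait, age)],
                                         baseline_sd[(trait, age)])
            g_var = gs_beta[trait][age] ** 2 * panel_var[trait]
            residual_sd[(trait, age)] = math.sqrt(
                max(sigma**2 - ri_sd[trait] ** 2 - g_var, 0.01)
            )

    age_summary = tables.CHILD_PHENOTYPE_SUMMARY.query("trait == 'age'")
    visit_age_mean = {float(v): m for v, m in zip(age_summary["visit"], age_summary["mean"])}
    visit_age_sd = {float(v): s for v, s in zip(age_summary["visit"], age_summary["sd"])}
    attendance = {float(v): n / 544 for v, n in tables.VISIT_SAMPLE_SIZES.items()}

    cfg = dict(
        n_families=544,
        father_genotyped_fraction=352 / 544,
        maf=maf,
        snp_ids=snp_ids,
        panel_assignment=panels,
        effect_size_by_age=effects,
        trait_baseline_mean=baseline_mean,
        trait_baseline_sd=baseline_sd,
        random_intercept_sd=ri_sd,
        residual_sd=residual_sd,
        sex_effect=0.02,
        age_effect=0.0,
        visit_age_mean=visit_age_mean,
        visit_age_sd=visit_age_sd,
        visit_attendance=attendance,
        genotype_missing_rate=0.01,
        nonpaternity_rate=0.0,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
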