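import numpy as np
import pandas as pd
import pytest

from lipidtrio import sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    """A 60-family, 20-SNP cohort with modest effects — fast but non-trivial."""
    rng = np.random.default_rng(42)
    maf = rng.uniform(0.1, 0.5, 20)
    snp_ids = [f"snp{i:02d}" for i in range(20)]
    panels = {s: ("TC",) if i < 10 else ("LDL",) for i, s in enumerate(snp_ids)}
    return sim.SimConfig(
        n_families=60,
        father_genotyped_fraction=0.7,
        maf=maf,
        snp_ids=snp_ids,
        panel_assignment=panels,
        effect_size_by_age={("TC", a): 0.01 for a in (0.0, 3.0, 5.0)},
        trait_baseline_mean={(t, a): 2.0 for t in sim.TRAITS for a in (0.0, 3.0, 5.0)},
        trait_baseline_sd={(t, a): 0.5 for t in sim.TRAITS for a in (0.0, 3.0, 5.0)},
        random_intercept_sd={t: 0.1 for t in sim.TRAITS},
        residual_sd={(t, a): 0.2 for t in sim.TRAITS for a in (0.0, 3.0, 5.0)},
        sex_effect=0.02,
        visit_age_sd={0.0: 0.01, 3.0: 0.1, 5.0: 0.1},
        genotype_missing_rate=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sim.simulate_trios(small_config)


@pytest.fixture(scope="session")
def small_phenotypes(small_config, small_cohort):
    return sim.simulate_phenotypes(small_cohort, small_config)


def clean_config(n_families: int = 100, n_snps: int = 10, seed: int = 1, **kw) -> sim.SimConfig:
    """Error-free cohort: no missingness, no non-paternity, everyone genotyped."""
    rng = np.random.default_rng(seed + 1000)
    base = dict(
        n_families=n_families,
        father_genotyped_fraction=1.0,
        maf=rng.uniform(0.1, 0.5, n_snps),
        genotype_missing_rate=0.0,
        nonpaternity_rate=0.0,
        seed=seed,
    )
    base.update(kw)
    return sim.SimConfig(**base)
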