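"""Association of genotype scores and SNPs with log lipid levels.

Per-visit linear regressions and pooled random-intercept mixed models of
ln(trait) on each trait's genotype score (and a few illustrative SNPs),
adjusted for sex, age and the 10 first principal components; significance
labelled at the Bonferroni threshold 0.05/(158 x 3).  Writes
results/association_gs.tsv and results/association_snps.tsv in the
per-visit + pooled reporting layout.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA_DIR, RESULTS_DIR

from lipidtrio import association, io, scores, sim

VISITS = (0.0, 3.0, 5.0)


def main() -> None:
    pheno = association.log_transform(io.read_phenotypes(DATA_DIR / "phenotypes.tsv"))
    geno = io.read_genotypes_tsv(DATA_DIR / "genotypes.tsv")
    panel = io.panel_assignment_from_table(io.read_panel(DATA_DIR / "panel.tsv"))
    pcs = pd.read_csv(RESULTS_DIR / "pcs.tsv", sep="\t", index_col="iid")
    gs = scores.genotype_score(geno, panel)
    threshold = association.bonferroni_threshold(158, 3)
    print(f"Bonferroni threshold: 0.05/(158 x 3) = {threshold:.3g}")

    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for trait in sim.TRAITS:
            predictor = f"gs_{trait}"
            for visit in VISITS:
                spec = association.ModelSpec(predictor, trait, visit)
                results.append(association.fit_cross_sectional(
                    spec, pheno, gs, pcs, significance_threshold=threshold))
            spec = association.ModelSpec(predictor, trait, "pooled")
            results.append(association.fit_longitudinal(
                spec, pheno, gs, pcs, significance_threshold=threshold))
    gs_table = association.results_table(results)
    gs_table.to_csv(RESULTS_DIR / "association_gs.tsv", sep="\t", index=False)
    print("\ngenotype-score associations (beta on ln scale per GS unit):")
    print(gs_table.round(4).to_string(index=False))

    # a few single-SNP models on the LDL panel for the per-SNP layout
    ldl_snps = [s for s, ts in panel.items() if "LDL" in ts][:5]
    snp_results = []
    dosages = geno[ldl_snps].apply(scores.mean_impute)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for snp in ldl_snps:
            for visit in VISITS:
                spec = association.ModelSpec(snp, "LDL", visit)
                snp_results.append(association.fit_cross_sectional(
                    spec, pheno, dosages, pcs, significance_threshold=threshold))
            snp_results.append(association.fit_longitudinal(
                association.ModelSpec(snp, "LDL", "pooled"), pheno, dosages, pcs,
                significance_threshold=threshold))
    snp_table = association.results_table(snp_results)
    snp_table.to_csv(RESULTS_DIR / "association_snps.tsv", sep="\t", index=False)

    sig = gs_table[gs_table["significant"].astype(bool)]
    print(f"\nsignificant GS associations after Bonferroni: {len(sig)}")
    if len(sig):
        print(sig.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
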