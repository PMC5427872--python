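"""Quality control of the simulated cohort read back from its files.

Sample missing-rate and SNP call-rate filters, Hardy-Weinberg tests on the
founders (asymptotic chi-square plus 999 allele-shuffling permutations),
and the Mendelian trio/duo screen, checking the flagged fathers against the
simulation's truth labels.  Writes results/qc_report.json.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import DATA_DIR, RESULTS_DIR, STUDY_SEED

from lipidtrio import io, qc


def main() -> None:
    cohort = io.load_cohort(DATA_DIR / "genotypes.tsv", DATA_DIR / "pedigree.fam.tsv")
    thresholds = qc.QcThresholds()
    filtered, removal_log = qc.filter_samples_and_snps(cohort, thresholds)
    print(f"filters: removed {(removal_log['kind'] == 'sample').sum()} samples, "
          f"{(removal_log['kind'] == 'snp').sum()} SNPs "
          f"(thresholds: sample missing > {thresholds.sample_missing_max:.0%}, "
          f"call rate < {thresholds.snp_call_rate_min:.0%})")

    founders = filtered.genotypes.loc[
        filtered.role[filtered.role != "child"].index.intersection(filtered.genotypes.index)
    ]
    rng = np.random.default_rng(STUDY_SEED)
    hwe_failures = []
    for snp in filtered.snp_ids:
        res = qc.hwe_test(qc.genotype_counts(founders[snp]), n_permutations=999, seed=rng)
        if res.p_asymptotic < thresholds.hwe_p_min:
            hwe_failures.append((snp, res.p_asymptotic, res.p_permutation))
    print(f"HWE (founders, n={len(founders)}): {len(hwe_failures)} SNPs below "
          f"p = {thresholds.hwe_p_min:g}")

    mendel = qc.mendelian_check(filtered)
    truth = set((DATA_DIR / "nonpaternal_fathers.txt").read_text().split())
    truth &= set(filtered.genotypes.index)  # only genotyped fathers are detectable
    flagged = set(mendel.flagged_fathers)
    print(f"Mendelian screen: {len(mendel.inconsistencies)} inconsistent "
          f"(family, SNP) pairs, {len(flagged)} fathers flagged as non-biological")
    print(f"  truth labels: {len(truth)} genotyped non-paternal fathers; "
          f"recovered exactly: {flagged == truth}")
    residual = mendel.inconsistencies[
        ~mendel.inconsistencies["fid"].isin(
            filtered.pedigree.set_index("father").loc[list(flagged), "fid"]
            if flagged else [])]
    print(f"  residual inconsistencies outside flagged pedigrees: {len(residual)}")

    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    report = {
        "n_samples_removed": int((removal_log["kind"] == "sample").sum()),
        "n_snps_removed": int((removal_log["kind"] == "snp").sum()),
        "n_samples_kept": int(filtered.genotypes.shape[0]),
        "n_snps_kept": int(filtered.genotypes.shape[1]),
        "hwe_failures": [s for s, _, _ in hwe_failures],
        "mendel_inconsistent_pairs": int(len(mendel.inconsistencies)),
        "flagged_fathers": sorted(flagged),
        "flagged_equals_truth": flagged == truth,
    }
    (RESULTS_DIR / "qc_report.json").write_text(json.dumps(report, indent=2))
    print(f"\nwrote {RESULTS_DIR / 'qc_report.json'}")


if __name__ == "__main__":
    main()
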