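"""File formats for cohort exchange.

The native dialect is plain TSV: a genotype matrix (rows = individuals,
columns = SNPs, values 0/1/2/NA coded as risk-allele copies), a PLINK
.fam-style pedigree, a long-format phenotype table, a SNP-panel table and
pairwise r2 / annotation tables.  Genotypes can also be exported to and
read from VCF (GT field, missing as ./.) via pysam/cyvcf2 when those are
available; synthetic SNPs are laid out on a single contig.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sim import TrioCohort


def write_genotypes_tsv(cohort: TrioCohort, path: str | Path) -> None:
    g = cohort.genotypes.copy()
    g.index.name = "iid"
    g.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="iid", na_values="NA")
    df.index.name = None
    return df


def write_pedigree(cohort: TrioCohort, path: str | Path) -> None:
    """PLINK .fam-like table: FID, IID, father, mother, sex (1=male,
    2=female, 0=unknown); one row per individual, parents 0 for founders."""
    rows = []
    sex_code = {"male": 1, "female": 2}
    for _, fam in cohort.pedigree.iterrows():
        child_sex = sex_code.get(cohort.sex.get(fam["child"], ""), 0)
        rows.append((fam["fid"], fam["child"], fam["father"], fam["mother"], child_sex))
        rows.append((fam["fid"], fam["mother"], "0", "0", 2))
        rows.append((fam["fid"], fam["father"], "0", "0", 1))
    pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"]).to_csv(
        path, sep="\t", index=False
    )


def read_pedigree(path: str | Path) -> pd.DataFrame:
    fam = pd.read_csv(path, sep="\t", dtype=str)
    kids = fam[(fam["father"] != "0") | (fam["mother"] != "0")]
    return pd.DataFrame(
        {"fid": kids["fid"], "child": kids["iid"],
         "mother": kids["mother"], "father": kids["father"]}
    ).reset_index(drop=True)


def load_cohort(geno_path: str | Path, ped_path: str | Path) -> TrioCohort:
    """Rebuild a ``TrioCohort`` from a genotype TSV and a .fam-style
    pedigree.  Families whose mother or child lost her genotype row are
    dropped from the pedigree (they are unanalysable for trio QC)."""
    geno = read_genotypes_tsv(geno_path)
    fam = pd.read_csv(ped_path, sep="\t", dtype=str)
    kids = fam[(fam["father"] != "0") | (fam["mother"] != "0")]
    kids = kids[kids["iid"].isin(geno.index) & kids["mother"].isin(geno.index)]
    pedigree = pd.DataFrame(
        {"fid": kids["fid"], "child": kids["iid"],
         "mother": kids["mother"], "father": kids["father"]}
    ).reset_index(drop=True)
    role = pd.Series("father", index=geno.index)
    role[geno.index.isin(pedigree["child"])] = "child"
    role[geno.index.isin(pedigree["mother"])] = "mother"
    sex = pd.Series(
        np.where(kids["sex"].astype(int) == 1, "male", "female"),
        index=kids["iid"].to_numpy(),
    )
    return TrioCohort(genotypes=geno, pedigree=pedigree, role=role, sex=sex)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Panel table columns: snp, trait (comma-joined memberships),
    risk_allele, maf and optional adult summary columns."""
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t")
    if "trait" in panel.columns:
        panel["trait"] = panel["trait"].astype(str)
    return panel


def panel_assignment_from_table(panel: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    return {
        str(r["snp"]): tuple(sorted(str(r["trait"]).split(",")))
        for _, r in panel.iterrows()
    }


def panel_assignment_to_table(
    assignment: dict[str, tuple[str, ...]], maf: dict[str, float] | None = None
) -> pd.DataFrame:
    rows = []
    for snp, traits in assignment.items():
        rows.append({
            "snp": snp,
            "trait": ",".join(traits),
            "risk_allele": "G",
            "maf": None if maf is None else maf.get(snp),
        })
    return pd.DataFrame(rows)


def write_vcf(cohort: TrioCohort, path: str | Path) -> None:
    """Export genotypes as VCF with GT fields (risk allele = ALT)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=1,length=300000000>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = list(cohort.genotypes.index)
    for s in samples:
        header.add_sample(s)
    g = cohort.genotypes.to_numpy(dtype=float)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, snp in enumerate(cohort.snp_ids):
            rec = vcf.new_record(
                contig="1", start=1000 * (j + 1), stop=1000 * (j + 1) + 1,
                alleles=("A", "G"), id=snp,
            )
            for i, s in enumerate(samples):
                v = g[i, j]
                if np.isnan(v):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (1, 1) if v == 2 else ((0, 1) if v == 1 else (0, 0))
            vcf.write(rec)


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a GT-only VCF back into the 0/1/2/NaN risk-allele-dosage
    matrix (rows = individuals, columns = SNP ids)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dosage = np.where(gt == 3, 2.0, gt)
        dosage[gt == 2] = np.nan
        cols[var.ID] = dosage
    return pd.DataFrame(cols, index=samples)
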