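"""Reading and writing the on-disk study layout.

A dataset directory holds:

* ``genotypes.vcf`` — VCF 4.2, biallelic records, GT-only, missing as ``./.``;
  REF is the non-risk allele and ALT the risk allele, so ALT dosage is the
  risk-allele dosage used everywhere downstream.
* ``phenotypes.tsv`` — one row per individual (iid, birth_year, sex, exam_age,
  per-eye sphere/cylinder, afb, neb, parental lifespans, pc1..pc10).
* ``snps.tsv`` — SNP metadata (id, chrom, pos, alleles, baseline frequency,
  recombination rate in cM/Mb).
* ``truth.tsv`` — planted per-SNP parameters (absent for real data).
* ``aging_schedule.tsv`` — age_start, age_end, delta_spe_per_5y.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import CohortDataset, SimulationConfig

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "risk_allele", "other_allele",
                 "baseline_freq", "recomb_rate"]
TRUTH_COLUMNS = ["snp_id", "s_true", "u_true", "beta_afb", "beta_neb", "beta_lifespan"]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=cohortsel
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path: str, dataset: CohortDataset, panel: pd.DataFrame) -> None:
    """Write risk-allele dosages as GT-only VCF (ALT = risk allele)."""
    iids = dataset.phenotypes["iid"].tolist()
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if iids:  # a sample-less VCF is sites-only: no FORMAT column
            cols += ["FORMAT"] + iids
        fh.write("\t".join(cols) + "\n")
        geno = dataset.genotypes
        for j in range(len(panel)):
            row = panel.iloc[j]
            fields = [str(row["chrom"]), str(row["pos"]), str(row["snp_id"]),
                      str(row["other_allele"]), str(row["risk_allele"]),
                      ".", ".", "."]
            if iids:
                fields += ["GT"] + ["./." if np.isnan(g) else _GT[int(g)]
                                    for g in geno[:, j]]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Read a GT-only VCF into (dosage matrix, sample ids, site table).

    Dosage counts the ALT (risk) allele; missing genotypes become NaN.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    dosages, sites = [], []
    for var in vcf:
        if samples:
            gts = np.asarray(var.genotype.array())[:, :2]
            d = gts.sum(axis=1).astype(float)
            d[(gts < 0).any(axis=1)] = np.nan
        else:
            d = np.empty(0)
        dosages.append(d)
        sites.append((var.ID, var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    site_df = pd.DataFrame(sites, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    geno = np.array(dosages).T if dosages else np.empty((len(samples), 0))
    return geno, samples, site_df


def write_dataset(dataset: CohortDataset, panel: pd.DataFrame, directory: str) -> dict[str, str]:
    """Write the full study layout; returns a name->path map.

    A read-back with :func:`read_dataset` reproduces the in-memory genotype
    matrix and phenotype table exactly.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {name: os.path.join(directory, fname) for name, fname in [
        ("vcf", "genotypes.vcf"), ("phenotypes", "phenotypes.tsv"),
        ("snps", "snps.tsv"), ("truth", "truth.tsv"),
        ("aging_schedule", "aging_schedule.tsv"),
    ]}
    write_vcf(paths["vcf"], dataset, panel)
    dataset.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.10g")
    panel[PANEL_COLUMNS].to_csv(paths["snps"], sep="\t", index=False, float_format="%.10g")
    truth_cols = [c for c in TRUTH_COLUMNS if c in panel.columns]
    panel[truth_cols].to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    schedule = dataset.config.aging_schedule if dataset.config is not None else None
    if schedule is not None:
        schedule.to_csv(paths["aging_schedule"], sep="\t", index=False)
    return paths


def read_dataset(directory: str) -> tuple[CohortDataset, pd.DataFrame, pd.DataFrame]:
    """Read a study directory back into (dataset, panel, aging schedule).

    The returned panel includes truth columns when a truth table is present.
    Genotypes are reordered to the panel's SNP order if the VCF differs.
    """
    geno, samples, sites = read_vcf(os.path.join(directory, "genotypes.vcf"))
    pheno = pd.read_csv(os.path.join(directory, "phenotypes.tsv"), sep="\t")
    panel = pd.read_csv(os.path.join(directory, "snps.tsv"), sep="\t",
                        dtype={"chrom": str})
    truth_path = os.path.join(directory, "truth.tsv")
    if os.path.exists(truth_path):
        truth = pd.read_csv(truth_path, sep="\t")
        if len(truth):
            panel = panel.merge(truth, on="snp_id", how="left")
    sched_path = os.path.join(directory, "aging_schedule.tsv")
    schedule = pd.read_csv(sched_path, sep="\t") if os.path.exists(sched_path) else None

    if list(pheno["iid"]) != samples:
        order = {iid: k for k, iid in enumerate(samples)}
        geno = geno[[order[i] for i in pheno["iid"]], :]
    if len(sites) and list(sites["snp_id"]) != list(panel["snp_id"]):
        order = {sid: k for k, sid in enumerate(sites["snp_id"])}
        geno = geno[:, [order[s] for s in panel["snp_id"]]]
    dataset = CohortDataset(genotypes=geno, phenotypes=pheno,
                            snp_ids=list(panel["snp_id"]))
    return dataset, panel, schedule
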