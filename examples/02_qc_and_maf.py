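"""SNP quality control: HWE exact test, missingness and MAF filters.

Writes a small genotype file, reads it back (codes re-oriented to count the
sample-minor allele), and applies the standard GWAS QC cascade.
"""

import tempfile
from pathlib import Path

import numpy as np

from curescan import CohortSpec, simulate_cohort, snp_qc
from curescan.cohort_io import (
    hwe_test,
    genotype_counts,
    ld_r2,
    minor_allele_frequency,
    read_genotypes,
    write_tsv_wide,
)

cohort = simulate_cohort(
    CohortSpec(n=379, maf_list=tuple(np.linspace(0.005, 0.5, 40)), seed=2,
               genotype_missing_rate=0.02)
)
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "genotypes.tsv"
    write_tsv_wide(cohort.genotypes, path)
    matrix = read_genotypes(path)

filtered, report = snp_qc(matrix, hwe_alpha=1e-6, max_missing=0.05, min_maf=0.01)
print(f"input SNPs:            {report.n_input_snps}")
print(f"failed HWE (p<1e-6):   {report.n_failed_hwe}")
print(f"failed missingness:    {report.n_failed_missingness}")
print(f"failed MAF < 1%:       {report.n_failed_maf}")
print(f"retained:              {report.n_retained}")

row = filtered.codes[-1]
print(f"example MAF:           {minor_allele_frequency(row):.3f}")
print(f"example HWE exact p:   {hwe_test(*genotype_counts(row)):.3f}")
print(f"LD r^2 with itself:    {ld_r2(row, row):.1f}")

# Rare SNPs (MAF < 1%) are removed because genotype categories with a
# handful of patients make every downstream survival contrast unstable.
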