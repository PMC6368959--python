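"""Genotype and clinical data input, cohort exclusions and SNP-level QC.

Genotypes are held as minor-allele counts (0/1/2, -1 for missing) in a
SNP x patient matrix. Two on-disk dialects are supported:

* ``tsv-wide`` — one row per SNP with columns ``snp_id``, ``chrom``, ``pos``,
  ``allele1`` (the counted allele), ``allele2``, followed by one column per
  patient holding 0/1/2/NA;
* ``plink-bed`` — the binary PLINK bed/bim/fam triplet (SNP-major, 2-bit
  codes), decoded directly.

Whatever allele the file counts, matrices are re-oriented on read so that
codes count the *minor* allele in this sample (codes flipped 2-x and alleles
swapped when needed).

The clinical table is a CSV with one row per patient; categorical fields use
an explicit ``unknown`` level rather than blanks.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exceptions import DataFormatError, UndefinedInputError

MISSING = -1

_STAGES = {"I", "II", "III", "IV", "unknown"}
_MSI = {"MSI-H", "MSI-L", "MSS", "unknown"}


@dataclass
class SnpMeta:
    """Identity and alleles of one biallelic SNP (1-based GRCh37 positions)."""

    snp_id: str
    chrom: str
    pos: int
    allele_minor: str
    allele_major: str

    def __post_init__(self):
        if self.allele_minor == self.allele_major:
            raise DataFormatError(f"{self.snp_id}: alleles must differ")
        if self.pos < 0:
            raise DataFormatError(f"{self.snp_id}: negative position")


@dataclass
class GenotypeMatrix:
    """Minor-allele count codes, SNP x patient, with -1 marking missing."""

    snps: list
    patients: list
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.snps), len(self.patients)):
            raise DataFormatError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.patients)} patients"
            )
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataFormatError(
                f"invalid genotype code {self.codes[i, j]} at SNP "
                f"{self.snps[i].snp_id}, patient {self.patients[j]}"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise DataFormatError("duplicate SNP identifiers")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            [s for s, k in zip(self.snps, keep) if k] if keep.dtype == bool
            else [self.snps[i] for i in keep],
            self.patients,
            self.codes[keep],
        )

    def subset_patients(self, patient_ids) -> "GenotypeMatrix":
        index = {p: i for i, p in enumerate(self.patients)}
        cols = [index[p] for p in patient_ids]
        return GenotypeMatrix(self.snps, list(patient_ids), self.codes[:, cols])


@dataclass
class ClinicalRecord:
    """One patient's baseline characteristics and time-to-metastasis outcome.

    ``time_years`` is years from diagnosis to metastasis (event=1) or last
    follow-up (event=0); missing outcome data are represented by NaN time or
    event outside {0, 1}.
    """

    patient_id: str
    stage: str = "unknown"
    msi_status: str = "unknown"
    sex: str = "unknown"
    age_group: str = "unknown"
    familial_risk: str = "unknown"
    treatment_5fu: str = "unknown"
    location: str = "unknown"
    histology: str = "unknown"
    vascular_invasion: str = "unknown"
    lymphatic_invasion: str = "unknown"
    braf_v600e: str = "unknown"
    time_years: float = float("nan")
    event: int = -1

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise DataFormatError(f"{self.patient_id}: unknown stage {self.stage!r}")
        if self.msi_status not in _MSI:
            raise DataFormatError(f"{self.patient_id}: unknown MSI status {self.msi_status!r}")
        if np.isfinite(self.time_years) and self.time_years < 0:
            raise DataFormatError(f"{self.patient_id}: negative follow-up time")

    @property
    def outcome_missing(self) -> bool:
        return not np.isfinite(self.time_years) or self.event not in (0, 1)


#: baseline characteristics considered for adjustment, in table order
COVARIATE_FIELDS = [
    "sex",
    "age_group",
    "familial_risk",
    "treatment_5fu",
    "stage",
    "location",
    "histology",
    "vascular_invasion",
    "lymphatic_invasion",
    "braf_v600e",
]


@dataclass
class QcReport:
    """Per-filter tally of a SNP QC pass."""

    n_input_snps: int
    n_failed_hwe: int
    n_failed_missingness: int
    n_failed_maf: int
    n_retained: int
    hwe_alpha: float
    max_missing: float
    min_maf: float


# ---------------------------------------------------------------------------
# readers / writers


def _orient_minor(codes: np.ndarray, a1: str, a2: str):
    """Flip codes so they count the sample-minor allele; returns (codes, minor, major)."""
    obs = codes != MISSING
    n_obs = obs.sum()
    freq = codes[obs].sum() / (2.0 * n_obs) if n_obs else 0.0
    if freq > 0.5:
        flipped = codes.copy()
        flipped[obs] = 2 - flipped[obs]
        return flipped, a2, a1
    return codes, a1, a2


def read_genotypes(path, dialect: str = None) -> GenotypeMatrix:
    """Read a genotype matrix, orienting codes to minor-allele counts.

    ``dialect`` is ``"plink-bed"`` or ``"tsv-wide"``; inferred from the file
    suffix when omitted (``.bed`` vs anything else).
    """
    path = Path(path)
    if dialect is None:
        dialect = "plink-bed" if path.suffix == ".bed" else "tsv-wide"
    if dialect == "plink-bed":
        return _read_plink(path)
    if dialect == "tsv-wide":
        return _read_tsv_wide(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_tsv_wide(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "chrom", "pos", "allele1", "allele2"]
    for col in required:
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    patients = [c for c in df.columns if c not in required]
    if not patients:
        raise DataFormatError(f"{path}: no patient columns")
    cells = df[patients].to_numpy(dtype=object)
    snps, rows = [], []
    for i in range(len(df)):
        snp_id = df.at[i, "snp_id"]
        a1, a2 = str(df.at[i, "allele1"]), str(df.at[i, "allele2"])
        if len(a1) != 1 or len(a2) != 1 or a1 == a2:
            raise DataFormatError(f"{path} line {i + 2}: non-biallelic record {snp_id}")
        raw = np.empty(len(patients), dtype=np.int8)
        for j, cell in enumerate(cells[i]):
            cell = "" if cell is None or cell != cell else str(cell)
            if cell in ("NA", "", "nan"):
                raw[j] = MISSING
            elif cell in ("0", "1", "2"):
                raw[j] = int(cell)
            else:
                raise DataFormatError(
                    f"{path} line {i + 2}: unparseable code {cell!r} "
                    f"for patient {patients[j]}"
                )
        codes, minor, major = _orient_minor(raw, a1, a2)
        snps.append(SnpMeta(snp_id, str(df.at[i, "chrom"]), int(df.at[i, "pos"]), minor, major))
        rows.append(codes)
    return GenotypeMatrix(snps, patients, np.vstack(rows))


def write_tsv_wide(matrix: GenotypeMatrix, path) -> None:
    """Write the wide-TSV dialect (counted allele = allele_minor)."""
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tallele1\tallele2\t" + "\t".join(matrix.patients) + "\n")
        for meta, row in zip(matrix.snps, matrix.codes):
            cells = ["NA" if c == MISSING else str(int(c)) for c in row]
            fh.write(
                f"{meta.snp_id}\t{meta.chrom}\t{meta.pos}\t"
                f"{meta.allele_minor}\t{meta.allele_major}\t" + "\t".join(cells) + "\n"
            )


_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit PLINK codes -> count of the A1 allele (-1 = missing)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def _read_plink(bed_path: Path) -> GenotypeMatrix:
    stem = bed_path.with_suffix("")
    bim = pd.read_csv(
        stem.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype=str,
    )
    fam = pd.read_csv(stem.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    patients = fam[1].tolist()
    n = len(patients)
    m = len(bim)
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise DataFormatError(f"{bed_path}: not a SNP-major PLINK bed file")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise DataFormatError(
            f"{bed_path}: size mismatch ({body.size} bytes for {m} SNPs x {n} samples)"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample-major within byte (LSB first)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes_a1 = _BED_DECODE[two_bit.reshape(m, -1)[:, :n]]
    snps, rows = [], []
    for i, rec in enumerate(bim.itertuples(index=False)):
        if len(rec.a1) != 1 or len(rec.a2) != 1 or rec.a1 == rec.a2:
            raise DataFormatError(f"{stem}.bim record {i + 1}: non-biallelic {rec.snp_id}")
        codes, minor, major = _orient_minor(codes_a1[i], rec.a1, rec.a2)
        snps.append(SnpMeta(rec.snp_id, str(rec.chrom), int(rec.pos), minor, major))
        rows.append(codes)
    return GenotypeMatrix(snps, patients, np.vstack(rows))


def write_plink(matrix: GenotypeMatrix, prefix) -> None:
    """Write a bed/bim/fam triplet (A1 = allele_minor, SNP-major bed)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in matrix.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\t{s.allele_minor}\t{s.allele_major}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for p in matrix.patients:
            fh.write(f"{p}\t{p}\t0\t0\t0\t-9\n")
    n = matrix.n_patients
    bytes_per_snp = (n + 3) // 4
    encode = {0: 0b11, 1: 0b10, 2: 0b00, MISSING: 0b01}
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for row in matrix.codes:
            buf = bytearray(bytes_per_snp)
            for j, c in enumerate(row):
                buf[j // 4] |= encode[int(c)] << (2 * (j % 4))
            fh.write(bytes(buf))


def read_clinical(path) -> list:
    """Read the per-patient clinical CSV into ClinicalRecord objects."""
    df = pd.read_csv(path, dtype=str)
    if "patient_id" not in df.columns:
        raise DataFormatError(f"{path}: missing patient_id column")
    records = []
    valid = {f.name for f in dc_fields(ClinicalRecord)}
    for _, row in df.iterrows():
        kwargs = {}
        for col, val in row.items():
            if col not in valid:
                continue
            if col == "time_years":
                kwargs[col] = float(val) if val not in (None, "", "NA") and val == val else float("nan")
            elif col == "event":
                kwargs[col] = int(val) if val not in (None, "", "NA") and val == val else -1
            else:
                kwargs[col] = "unknown" if val is None or val != val or val == "" else str(val)
        records.append(ClinicalRecord(**kwargs))
    return records


def write_clinical(records, path) -> None:
    cols = [f.name for f in dc_fields(ClinicalRecord)]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort exclusions

EXCLUSION_ORDER = ("stage IV", "unknown MSI", "missing recurrence data", "MSI-H")


def apply_cohort_filters(records) -> tuple[list, dict]:
    """Apply the cohort exclusion cascade for a cure-structure analysis.

    Retains stage I-III patients with MSI-L/MSS tumors and complete
    time/event data. Each excluded patient is tallied under the first
    applicable reason, in the order: stage IV, unknown MSI, missing
    recurrence data, MSI-H. Stage IV tumors are already metastatic, MSI-H
    tumors essentially never metastasize, so neither belongs in a cohort
    modelled as a mixture of cured and susceptible patients.
    """
    tally = {reason: 0 for reason in EXCLUSION_ORDER}
    retained = []
    for rec in records:
        if rec.stage == "IV":
            tally["stage IV"] += 1
        elif rec.msi_status == "unknown":
            tally["unknown MSI"] += 1
        elif rec.outcome_missing:
            tally["missing recurrence data"] += 1
        elif rec.msi_status == "MSI-H":
            tally["MSI-H"] += 1
        elif rec.stage in ("I", "II", "III"):
            retained.append(rec.patient_id)
        else:  # stage unknown: not assignable to I-III
            tally.setdefault("unknown stage", 0)
            tally["unknown stage"] += 1
    return retained, tally


# ---------------------------------------------------------------------------
# per-SNP statistics


def minor_allele_frequency(codes) -> float:
    """Folded allele frequency min(f, 1-f) from 0/1/2 codes, missing excluded."""
    codes = np.asarray(codes)
    obs = codes != MISSING
    n = int(obs.sum())
    if n == 0:
        raise UndefinedInputError("MAF undefined: all genotypes missing")
    f = float(codes[obs].sum()) / (2.0 * n)
    return min(f, 1.0 - f)


def hwe_test(n_major_hom: int, n_het: int, n_minor_hom: int) -> float:
    """Exact Hardy-Weinberg equilibrium test (no mid-p correction).

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts no more likely than the observed one. Monomorphic
    SNPs return 1. Preferred over the chi-square test because rare-genotype
    cells make the asymptotic approximation unreliable.
    """
    for c in (n_major_hom, n_het, n_minor_hom):
        if c < 0:
            raise UndefinedInputError("negative genotype count")
    n = n_major_hom + n_het + n_minor_hom
    if n < 1:
        raise UndefinedInputError("empty genotype table")
    n_rare = 2 * n_minor_hom + n_het
    n_rare = min(n_rare, 2 * n - n_rare)  # symmetry: condition on the rarer allele
    if n_rare == 0:
        return 1.0
    h_values = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - h_values) // 2
    hom_c = n - h_values - hom_r
    valid = hom_c >= 0
    h_values, hom_r, hom_c = h_values[valid], hom_r[valid], hom_c[valid]
    logw = h_values * np.log(2.0) - gammaln(hom_r + 1) - gammaln(h_values + 1) - gammaln(hom_c + 1)
    logw -= logw.max()
    prob = np.exp(logw)
    prob /= prob.sum()
    obs_het = n_het
    p_obs = prob[np.searchsorted(h_values, obs_het)]
    return float(np.minimum(prob[prob <= p_obs * (1 + 1e-12)].sum(), 1.0))


def genotype_counts(codes) -> tuple[int, int, int]:
    """(major hom, het, minor hom) counts, missing excluded."""
    codes = np.asarray(codes)
    return (
        int((codes == 0).sum()),
        int((codes == 1).sum()),
        int((codes == 2).sum()),
    )


def snp_qc(
    matrix: GenotypeMatrix,
    hwe_alpha: float = 1e-6,
    max_missing: float = 0.05,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs failing HWE, missingness or MAF thresholds.

    A SNP is retained iff HWE exact p >= ``hwe_alpha``, missing fraction
    <= ``max_missing`` and MAF >= ``min_maf``. The default ``hwe_alpha`` of
    1e-6 is the conventional GWAS QC choice.
    """
    for thr in (hwe_alpha, max_missing, min_maf):
        if not 0 < thr < 1:
            raise ValueError("QC thresholds must lie in (0, 1)")
    n_patients = matrix.n_patients
    miss_frac = (matrix.codes == MISSING).sum(axis=1) / n_patients
    fail_miss = miss_frac > max_missing
    fail_maf = np.zeros(matrix.n_snps, dtype=bool)
    fail_hwe = np.zeros(matrix.n_snps, dtype=bool)
    for i in range(matrix.n_snps):
        row = matrix.codes[i]
        obs = row != MISSING
        if not obs.any():
            fail_maf[i] = True
            continue
        fail_maf[i] = minor_allele_frequency(row) < min_maf
        fail_hwe[i] = hwe_test(*genotype_counts(row)) < hwe_alpha
    keep = ~(fail_miss | fail_maf | fail_hwe)
    report = QcReport(
        n_input_snps=matrix.n_snps,
        n_failed_hwe=int(fail_hwe.sum()),
        n_failed_missingness=int(fail_miss.sum()),
        n_failed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
        hwe_alpha=hwe_alpha,
        max_missing=max_missing,
        min_maf=min_maf,
    )
    return matrix.subset_snps(keep), report


def ld_r2(codes_a, codes_b) -> float:
    """Squared genotype correlation between two SNPs over shared patients.

    This is the composite (genotype-correlation) definition of LD r-squared,
    not the EM-haplotype definition; the two agree for the near-complete LD
    regimes this package reports.
    """
    a = np.asarray(codes_a, dtype=float)
    b = np.asarray(codes_b, dtype=float)
    if a.shape != b.shape:
        raise UndefinedInputError("LD vectors must cover the same patients")
    obs = (a != MISSING) & (b != MISSING)
    a, b = a[obs], b[obs]
    if a.size < 2 or np.var(a) == 0 or np.var(b) == 0:
        raise UndefinedInputError("LD undefined for constant genotype vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
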