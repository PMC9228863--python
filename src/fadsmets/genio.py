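"""Genotype containers and text-format I/O (PLINK PED/MAP, minimal VCF, cohort TSV).

Genotypes are stored as minor-allele dosages: 0 = major homozygote (AA),
1 = heterozygote (Aa), 2 = minor homozygote (aa), -1 = missing.  The
major/minor designation is carried by :class:`SnpMeta` and is the declared
assignment; it can be re-checked against observed allele counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class SnpMeta:
    """Per-SNP metadata: declared major/minor alleles and map position."""

    snp_id: str
    major: str
    minor: str
    chrom: str = "11"
    pos: int = 0
    gene: str = ""

    def __post_init__(self) -> None:
        if self.major == self.minor:
            raise ValueError(f"{self.snp_id}: major and minor alleles must differ")

    def genotype_string(self, dosage: int) -> str:
        if dosage == MISSING:
            return "0/0"
        if dosage not in (0, 1, 2):
            raise ValueError(f"invalid dosage {dosage}")
        alleles = [self.major] * (2 - dosage) + [self.minor] * dosage
        return "/".join(alleles)


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs unphased diploid calls (minor-allele dosage coding)."""

    subject_ids: list[str]
    snps: list[SnpMeta]
    dosages: np.ndarray  # shape (n_subjects, n_snps), int8

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.subject_ids), len(self.snps)):
            raise ValueError("dosage matrix shape does not match ids/snps")
        bad = ~np.isin(self.dosages, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def subset_loci(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            list(self.subject_ids), [self.snps[i] for i in idx], self.dosages[:, idx]
        )

    def missing_rate(self) -> float:
        return float((self.dosages == MISSING).mean())


# ---------------------------------------------------------------------------
# PLINK PED/MAP text
# ---------------------------------------------------------------------------

def write_ped_map(geno: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write whitespace-delimited PED/MAP; missing alleles coded 0."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for s in geno.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(geno.subject_ids):
            fields = [sid, sid, "0", "0", "0", "0"]
            for j, s in enumerate(geno.snps):
                d = geno.dosages[i, j]
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [s.major] * (2 - d) + [s.minor] * d
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_ped_map(prefix: str | Path, snp_meta: list[SnpMeta] | None = None) -> GenotypeMatrix:
    """Read PED/MAP text.

    When ``snp_meta`` is omitted, the major allele at each locus is the more
    frequent observed allele (ties broken alphabetically).
    """
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            if line.strip():
                chrom, snp_id, _cm, pos = line.split()
                map_rows.append((chrom, snp_id, int(pos)))
    subject_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * len(map_rows):
                raise ValueError("PED row length does not match MAP locus count")
            subject_ids.append(fields[1])
            allele_rows.append(fields[6:])
    snps: list[SnpMeta] = []
    dosages = np.full((len(subject_ids), len(map_rows)), MISSING, dtype=np.int8)
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        if snp_meta is not None:
            meta = next(m for m in snp_meta if m.snp_id == snp_id)
        else:
            counts: dict[str, int] = {}
            for a in a1 + a2:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
            alleles = sorted(counts, key=lambda a: (-counts[a], a))
            if len(alleles) == 1:  # monomorphic: invent a placeholder minor
                alleles.append("N")
            meta = SnpMeta(snp_id, alleles[0], alleles[1], chrom=chrom, pos=pos)
        for i in range(len(subject_ids)):
            pair = (a1[i], a2[i])
            if "0" in pair:
                continue
            for a in pair:
                if a not in (meta.major, meta.minor):
                    raise ValueError(f"{snp_id}: unexpected allele {a!r}")
            dosages[i, j] = sum(a == meta.minor for a in pair)
        snps.append(meta)
    return GenotypeMatrix(subject_ids, snps, dosages)


# ---------------------------------------------------------------------------
# Minimal VCF 4.2 (biallelic, unphased GT only)
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path: str | Path) -> Path:
    path = Path(path)
    gt_code = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in geno.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.subject_ids) + "\n")
        for j, s in enumerate(geno.snps):
            gts = "\t".join(gt_code[int(d)] for d in geno.dosages[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{s.major}\t{s.minor}\t.\t.\t.\tGT\t{gts}\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF via cyvcf2; REF is taken as the major allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    snps: list[SnpMeta] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{var.ID}: only biallelic records supported")
        snps.append(SnpMeta(var.ID, var.REF, var.ALT[0], chrom=str(var.CHROM), pos=var.POS))
        types = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        col = np.full(len(subject_ids), MISSING, dtype=np.int8)
        col[types == 0] = 0
        col[types == 1] = 1
        col[types == 3] = 2
        cols.append(col)
    vcf.close()
    return GenotypeMatrix(subject_ids, snps, np.column_stack(cols))


# ---------------------------------------------------------------------------
# Cohort phenotype table and truth record
# ---------------------------------------------------------------------------

def write_cohort_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_jsonable)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
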