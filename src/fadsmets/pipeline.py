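"""End-to-end pipeline: simulate/load -> FA metrics -> selection -> Ward
clustering -> SNP association -> haplotype analysis, with a run manifest.

Each stage is a plain function over the library types so it can be driven
from the CLI, the numbered analysis scripts, or tests.  The cluster
assignment produced by the Ward stage feeds the association stages as the
grouping variable (MetS1 vs MetS2, CON1 vs CON2, plus the MetS vs CON and
cross contrasts).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_scan
from .cohort import BLOCK_LOCI, GeneratorConfig, default_config, generate_cohort
from .fa import FA_PANEL, add_derived_columns, compare_many
from .genio import (GenotypeMatrix, read_cohort_tsv, read_ped_map, read_vcf,
                    write_cohort_tsv, write_ped_map, write_truth_json, write_vcf)
from .haplotype import block_partition, em_haplotype_frequencies, haplotype_association, ld_matrix
from .stepwise import fit_lda, stepwise_select
from .ward import canonical_labels, cluster_group_chi2, cut_k, ward_linkage

log = logging.getLogger(__name__)

CLINICAL_TRAITS = ["weight_kg", "waist_cm", "glucose_mmol_l", "insulin_mU_l",
                   "tag_mmol_l", "homa_ir"]
DERIVED_COLS = ["sum_sfa", "sum_mfa", "sum_n6", "sum_n3",
                "d9d16", "d9d18", "d6d_n6", "d5d_n6"]


@dataclass
class PipelineConfig:
    outdir: str = "results/run"
    seed: int = 0
    # either a generator config or input paths
    generator: GeneratorConfig | None = None
    phenotype_path: str | None = None
    genotype_path: str | None = None  # PED/MAP prefix or .vcf file
    f_enter_threshold: float = 4.0
    max_vars: int = 6
    k: int = 2
    standardize: bool = False  # raw percent scale, as classical Ward protocols
    n_perm: int = 200
    block_d_prime: float = 0.8
    haplo_loci: list[str] | None = None  # default: largest LD block

    def validate(self) -> None:
        if self.generator is None and self.phenotype_path is None:
            raise ValueError("config needs either a generator or input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            base = default_config(seed=gen.pop("seed", cfg.seed))
            for key, val in gen.items():
                setattr(base, key, val)
            cfg.generator = base
        return cfg

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "generator"}
        if self.generator is not None:
            d["generator"] = {
                "n_mets": self.generator.n_mets, "n_con": self.generator.n_con,
                "seed": self.generator.seed, "n_genotyped": self.generator.n_genotyped,
            }
        return d


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    files: dict = field(default_factory=dict)  # path -> sha256

    def register(self, path: Path) -> None:
        self.files[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, manifest: RunManifest | None = None):
    """Generate a cohort and write phenotype TSV, PED/MAP, VCF and truth JSON."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator or default_config(seed=config.seed)
    table, geno, truth = generate_cohort(gen)
    paths = [write_cohort_tsv(table, out / "cohort.tsv")]
    ped, mp = write_ped_map(geno, out / "genotypes")
    paths += [ped, mp, write_vcf(geno, out / "genotypes.vcf"),
              write_truth_json(truth, out / "truth.json")]
    if manifest is not None:
        for p in paths:
            manifest.register(p)
        manifest.seeds["generator"] = gen.seed
        manifest.row_counts["cohort"] = len(table)
        manifest.row_counts["genotyped"] = geno.n_subjects
    return table, geno, truth


def load_inputs(config: PipelineConfig):
    table = read_cohort_tsv(config.phenotype_path)
    geno = None
    if config.genotype_path:
        gp = str(config.genotype_path)
        geno = read_vcf(gp) if gp.endswith(".vcf") else read_ped_map(gp)
        unknown = set(geno.subject_ids) - set(table["subject_id"].astype(str))
        if unknown:
            raise ValueError(
                f"{len(unknown)} genotyped subjects missing from the phenotype "
                f"table (e.g. {sorted(unknown)[:3]})")
    return table, geno


def stage_metrics(table: pd.DataFrame, config: PipelineConfig,
                  manifest: RunManifest | None = None) -> pd.DataFrame:
    """Derived FA metrics and the group-comparison tables."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    derived = add_derived_columns(table)
    if "homa_ir" not in derived.columns:
        if {"insulin_mU_l", "glucose_mmol_l"} <= set(derived.columns):
            from .fa import homa_ir
            derived["homa_ir"] = homa_ir(derived["insulin_mU_l"], derived["glucose_mmol_l"])
        else:
            msg = "insulin/glucose columns absent; HOMA-IR not computed"
            log.warning(msg)
            if manifest is not None:
                manifest.warnings.append(msg)
    fa_cmp = compare_many(derived, FA_PANEL + DERIVED_COLS, "group", "MetS", "CON")
    p = out / "fa_comparison_MetS_vs_CON.tsv"
    fa_cmp.to_csv(p, sep="\t", index=False)
    clin = [t for t in CLINICAL_TRAITS if t in derived.columns]
    clin_cmp = compare_many(derived, clin, "group", "MetS", "CON")
    p2 = out / "clinical_comparison_MetS_vs_CON.tsv"
    clin_cmp.to_csv(p2, sep="\t", index=False)
    if manifest is not None:
        manifest.register(p)
        manifest.register(p2)
        manifest.row_counts["metrics"] = len(derived)
    return derived


def stage_select(table: pd.DataFrame, config: PipelineConfig,
                 manifest: RunManifest | None = None):
    """Stepwise Wilks-lambda selection of FAs separating MetS from CON."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fa_cols = [c for c in FA_PANEL if c in table.columns]
    trace = stepwise_select(table[fa_cols], table["group"].to_numpy(),
                            f_enter_threshold=config.f_enter_threshold,
                            max_vars=config.max_vars)
    model = None
    if trace.selected:
        model = fit_lda(table, table["group"].to_numpy(), trace.selected)
    p = Path(config.outdir) / "selection_trace.tsv"
    trace.to_frame().to_csv(p, sep="\t", index=False)
    if manifest is not None:
        manifest.register(p)
        manifest.row_counts["selected_variables"] = len(trace.selected)
    return trace, model


def stage_cluster(table: pd.DataFrame, selected: list[str], config: PipelineConfig,
                  manifest: RunManifest | None = None) -> pd.DataFrame:
    """Ward clustering on the selected FAs; returns the table with a
    ``cluster`` column (canonical 1 = case-enriched) and a ``stratum``
    column (MetS1/MetS2/CON1/CON2)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    X = table[selected].to_numpy(float)
    if config.standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    dend = ward_linkage(X)
    assign = cut_k(dend, config.k)
    assign = canonical_labels(assign, table["group"].to_numpy(),
                              dgla=table["20:3n-6"].to_numpy()
                              if "20:3n-6" in table.columns else None)
    result = table.copy()
    result["cluster"] = assign.labels
    result["stratum"] = [f"{g}{c}" for g, c in zip(result["group"], result["cluster"])]
    chi = cluster_group_chi2(assign, table["group"].to_numpy())
    pd.DataFrame(dend.merges, columns=["cluster_a", "cluster_b", "height", "size"]) \
        .to_csv(out / "dendrogram.tsv", sep="\t", index=False)
    result[["subject_id", "group", "cluster", "stratum"]] \
        .to_csv(out / "cluster_assignment.tsv", sep="\t", index=False)
    with open(out / "cluster_group_chi2.json", "w") as fh:
        json.dump({"chi2": chi.chi2, "df": chi.df, "p": chi.p_value,
                   "correction": chi.correction,
                   "observed": chi.observed.tolist()}, fh, indent=1)
    if manifest is not None:
        for name in ("dendrogram.tsv", "cluster_assignment.tsv", "cluster_group_chi2.json"):
            manifest.register(out / name)
        manifest.row_counts["clustered"] = len(result)
    return result


CONTRASTS = [
    ("MetS1", "MetS2"), ("CON1", "CON2"), ("MetS1", "CON1"), ("MetS2", "CON2"),
]


def stage_assoc(clustered: pd.DataFrame, geno: GenotypeMatrix,
                config: PipelineConfig, manifest: RunManifest | None = None) -> dict:
    """Per-SNP association scans for every contrast, plus MetS vs CON."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = clustered.set_index(clustered["subject_id"].astype(str))
    strata = by_id.loc[[str(s) for s in geno.subject_ids], "stratum"].to_numpy()
    groups = by_id.loc[[str(s) for s in geno.subject_ids], "group"].to_numpy()
    scans = {}
    rows = []
    contrasts = CONTRASTS + [("MetS", "CON")]
    for a, b in contrasts:
        sel = groups if a == "MetS" else strata
        mask = np.isin(sel, [a, b])
        if mask.sum() == 0 or len(np.unique(sel[mask])) < 2:
            msg = f"contrast {a} vs {b}: empty stratum, skipped"
            log.warning(msg)
            if manifest is not None:
                manifest.warnings.append(msg)
            continue
        sub = GenotypeMatrix([geno.subject_ids[i] for i in np.where(mask)[0]],
                             geno.snps, geno.dosages[mask])
        scan = association_scan(sub, sel[mask])
        scans[(a, b)] = scan
        for r in scan:
            rows.append({
                "contrast": f"{a}_vs_{b}", "snp": r.snp_id,
                "genotype_chi2": r.genotype.chi2, "genotype_p": r.genotype.p_value,
                "genotype_p_bh": r.genotype.p_adjusted,
                "allele_chi2": r.allele.chi2, "allele_p": r.allele.p_value,
                "allele_p_bh": r.allele.p_adjusted,
                "hwe_p_min": min(h.p_value for h in r.hwe_by_stratum.values()),
            })
    p = out / "snp_association.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    if manifest is not None:
        manifest.register(p)
        manifest.row_counts["association_rows"] = len(rows)
    return scans


def stage_haplo(geno: GenotypeMatrix, grouping, config: PipelineConfig,
                manifest: RunManifest | None = None):
    """LD matrix, block partition, EM frequencies and permutation scan."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ld = ld_matrix(geno, seed=config.seed)
    blocks = block_partition(ld, config.block_d_prime)
    loci = config.haplo_loci
    if loci is None:
        loci = max(blocks, key=lambda b: len(b.snp_ids)).snp_ids if blocks else list(BLOCK_LOCI)
    hapset = em_haplotype_frequencies(geno, loci, seed=config.seed)
    assoc = haplotype_association(geno, grouping, loci,
                                  n_perm=config.n_perm, seed=config.seed)
    pd.DataFrame(ld.d_prime, index=ld.loci, columns=ld.loci) \
        .to_csv(out / "ld_dprime.tsv", sep="\t")
    pd.DataFrame(ld.r2, index=ld.loci, columns=ld.loci) \
        .to_csv(out / "ld_r2.tsv", sep="\t")
    pd.DataFrame([{"start": b.start, "end": b.end, "snps": ",".join(b.snp_ids)}
                  for b in blocks]).to_csv(out / "blocks.tsv", sep="\t", index=False)
    pd.DataFrame({"haplotype": hapset.haplotypes,
                  "frequency": hapset.frequencies}) \
        .to_csv(out / "haplotype_frequencies.tsv", sep="\t", index=False)
    pd.DataFrame([r.__dict__ for r in assoc.rows]) \
        .to_csv(out / "haplotype_association.tsv", sep="\t", index=False)
    if manifest is not None:
        for name in ("ld_dprime.tsv", "ld_r2.tsv", "blocks.tsv",
                     "haplotype_frequencies.tsv", "haplotype_association.tsv"):
            manifest.register(out / name)
    return ld, blocks, hapset, assoc


def run_all(config: PipelineConfig) -> RunManifest:
    config.validate()
    manifest = RunManifest(config=config.echo())
    manifest.seeds["pipeline"] = config.seed
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if config.generator is not None:
            table, geno, _ = stage_simulate(config, manifest)
        else:
            table, geno = load_inputs(config)
        derived = stage_metrics(table, config, manifest)
        trace, model = stage_select(derived, config, manifest)
        selected = trace.selected or [c for c in FA_PANEL if c in derived.columns]
        clustered = stage_cluster(derived, selected, config, manifest)
        if geno is not None:
            stage_assoc(clustered, geno, config, manifest)
            by_id = clustered.set_index(clustered["subject_id"].astype(str))
            strata = by_id.loc[[str(s) for s in geno.subject_ids], "stratum"].to_numpy()
            mets_mask = np.isin(strata, ["MetS1", "MetS2"])
            sub = GenotypeMatrix([geno.subject_ids[i] for i in np.where(mets_mask)[0]],
                                 geno.snps, geno.dosages[mets_mask])
            stage_haplo(sub, strata[mets_mask], config, manifest)
    manifest.warnings.extend(str(w.message) for w in caught)
    if model is not None:
        manifest.row_counts["lda_training_accuracy"] = model.training_accuracy
    out = Path(config.outdir)
    manifest.write(out / "manifest.json")
    return manifest
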