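"""Synthetic cohort generator with the statistical structure of the study design.

The generator emulates a case-control metabolic-syndrome (MetS) cohort in
which a five-SNP *FADS1/FADS2* haplotype block drives membership in one of
two latent fatty-acid phenotypes ("cluster 1" / "cluster 2"), and the
plasma-phospholipid FA panel plus clinical covariates are drawn conditional
on that latent cluster.  The causal chain is

    haplotype pair -> latent cluster -> (FA profile, clinical traits, group label)

so that every downstream stage (discriminant selection, Ward clustering,
SNP/haplotype association) can be exercised against known ground truth.

Defaults are calibrated once to the published study conditions: cohort sizes
188 controls / 166 MetS with 330 genotyped; block haplotype frequencies
66.2/14.9/13.0/4.9% (renormalized to sum to one); complete LD among the
three FADS1 markers (alleles copied); per-cluster FA medians/IQRs at the
published effect sizes; and per-haplotype cluster log-odds chosen so the
major-allele homozygote fraction is ~55% in cluster 1 vs ~32% in cluster 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fa import FA_PANEL, homa_ir
from .genio import GenotypeMatrix, SnpMeta

# SNPs in map order; the first five form the haplotype block.
SNP_ORDER = [
    "rs174537", "rs174545", "rs174546", "rs968567",
    "rs174570", "rs174575", "rs174602", "rs174589",
]
BLOCK_LOCI = SNP_ORDER[:5]

_SNP_DEFS = {
    # snp_id: (major, minor, pos, gene); positions approximate, map order correct
    "rs174537": ("G", "T", 61785208, "FADS1"),
    "rs174545": ("G", "C", 61802631, "FADS1"),
    "rs174546": ("G", "A", 61803311, "FADS1"),
    "rs968567": ("C", "T", 61817418, "FADS2"),
    "rs174570": ("C", "T", 61826566, "FADS2"),
    "rs174575": ("C", "G", 61832161, "FADS2"),
    "rs174602": ("T", "C", 61843176, "FADS2"),
    "rs174589": ("C", "G", 61851256, "FADS2"),
}

# Published five-SNP block haplotypes (rs174537-rs174545-rs174546-rs968567-
# rs174570) with frequencies renormalized from 66.2/14.9/13.0/4.9 (sum 99.0).
CORE_HAPLOTYPES = {
    "GGGCC": 0.662 / 0.990,
    "TCATC": 0.149 / 0.990,
    "TCACT": 0.130 / 0.990,
    "TCACC": 0.049 / 0.990,
}

# Conditional minor-allele probabilities for the three non-block SNPs
# (rs174575, rs174602, rs174589) given the core haplotype.  Calibrated so the
# marginal minor-allele frequencies approximate the published stratum tables
# (~0.235, ~0.176, ~0.180) while keeping D' with the block well below the
# block-defining threshold.
TAIL_CONDITIONALS = {
    "GGGCC": (0.18, 0.12, 0.13),
    "TCATC": (0.40, 0.30, 0.28),
    "TCACT": (0.30, 0.28, 0.28),
    "TCACC": (0.30, 0.28, 0.28),
}

# Per-cluster FA (location, spread) on the percent scale.  Spread is an IQR;
# rows published as mean +/- SD were converted with IQR = 1.349 * SD.
_FA_PARAMS = {
    1: {
        "14:0": (0.268, 0.110), "16:0": (29.752, 1.903), "16:1n-9": (0.105, 0.041),
        "16:1n-7": (0.634, 0.284), "18:0": (14.59, 1.807), "18:1n-9": (10.154, 1.945),
        "18:1n-7": (1.556, 0.467), "18:2n-6": (20.17, 2.792), "18:3n-6": (0.089, 0.053),
        "18:3n-3": (0.198, 0.081), "20:2n-6": (0.408, 0.149), "20:3n-6": (3.363, 0.708),
        "20:4n-6": (11.34, 2.738), "20:5n-3": (1.091, 0.492), "22:4n-6": (0.312, 0.103),
        "22:5n-6": (0.199, 0.075), "22:5n-3": (0.909, 0.192), "22:6n-3": (3.574, 1.251),
    },
    2: {
        "14:0": (0.264, 0.105), "16:0": (29.091, 2.072), "16:1n-9": (0.098, 0.037),
        "16:1n-7": (0.484, 0.183), "18:0": (14.16, 1.511), "18:1n-9": (8.930, 1.453),
        "18:1n-7": (1.382, 0.291), "18:2n-6": (25.31, 2.536), "18:3n-6": (0.074, 0.036),
        "18:3n-3": (0.186, 0.078), "20:2n-6": (0.381, 0.121), "20:3n-6": (3.036, 0.893),
        "20:4n-6": (10.34, 2.631), "20:5n-3": (0.801, 0.284), "22:4n-6": (0.284, 0.098),
        "22:5n-6": (0.181, 0.072), "22:5n-3": (0.818, 0.164), "22:6n-3": (3.018, 0.973),
    },
}

# Clinical traits per (group, cluster): (location, spread, distribution).
# "lognormal" entries are median/IQR, "normal" entries mean/SD.
_CLINICAL_PARAMS = {
    ("MetS", 1): {
        "weight_kg": (90.0, 19.0, "lognormal"), "waist_cm": (105.0, 11.0, "normal"),
        "glucose_mmol_l": (5.7, 1.8, "lognormal"), "insulin_mU_l": (11.75, 7.17, "lognormal"),
        "tag_mmol_l": (2.86, 3.09, "lognormal"),
    },
    ("MetS", 2): {
        "weight_kg": (85.8, 20.3, "lognormal"), "waist_cm": (101.0, 9.0, "normal"),
        "glucose_mmol_l": (5.3, 1.1, "lognormal"), "insulin_mU_l": (9.40, 5.83, "lognormal"),
        "tag_mmol_l": (2.43, 1.60, "lognormal"),
    },
    ("CON", 1): {
        "weight_kg": (80.6, 23.8, "lognormal"), "waist_cm": (95.5, 12.3, "normal"),
        "glucose_mmol_l": (5.00, 0.60, "lognormal"), "insulin_mU_l": (8.59, 6.00, "lognormal"),
        "tag_mmol_l": (1.57, 1.10, "lognormal"),
    },
    ("CON", 2): {
        "weight_kg": (73.7, 15.7, "lognormal"), "waist_cm": (88.9, 10.6, "normal"),
        "glucose_mmol_l": (4.90, 0.80, "lognormal"), "insulin_mU_l": (7.43, 5.30, "lognormal"),
        "tag_mmol_l": (1.27, 0.70, "lognormal"),
    },
}


def snp_metadata() -> list[SnpMeta]:
    """Default metadata for the eight studied SNPs, in map order."""
    return [
        SnpMeta(sid, *(_SNP_DEFS[sid][:2]), chrom="11",
                pos=_SNP_DEFS[sid][2], gene=_SNP_DEFS[sid][3])
        for sid in SNP_ORDER
    ]


@dataclass
class GeneratorConfig:
    n_mets: int = 166
    n_con: int = 188
    seed: int = 0
    n_genotyped: int = 330
    # list of (8-allele haplotype string in SNP_ORDER, frequency)
    haplotype_pool: list[tuple[str, float]] = field(default_factory=list)
    cluster_intercept: float = -0.25
    # per-haplotype additive effect on the log-odds of cluster-1 membership
    cluster_logit: dict[str, float] = field(default_factory=dict)
    # P(MetS | cluster); defaults are the published cluster compositions
    group_given_cluster: dict[int, float] = field(
        default_factory=lambda: {1: 109 / 180, 2: 57 / 174}
    )
    # cluster -> FA -> (location, IQR) on the percent scale
    fa_params: dict[int, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {c: dict(v) for c, v in _FA_PARAMS.items()}
    )
    clinical_params: dict[tuple[str, int], dict[str, tuple[float, float, str]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _CLINICAL_PARAMS.items()}
    )
    panel_total: float | None = None  # None: sum of the cluster FA locations
    age_mean: float = 55.0
    age_sd: float = 11.0
    p_male: float = 0.56

    def validate(self) -> None:
        if self.n_mets < 0 or self.n_con < 0 or self.n_mets + self.n_con < 1:
            raise ValueError("cohort must contain at least one subject")
        if not self.haplotype_pool:
            raise ValueError("empty haplotype pool")
        freqs = np.array([f for _, f in self.haplotype_pool])
        if (freqs < 0).any():
            raise ValueError("negative haplotype frequency")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {freqs.sum()}, not 1")
        meta = snp_metadata()
        for hap, _ in self.haplotype_pool:
            if len(hap) != len(SNP_ORDER):
                raise ValueError(f"haplotype {hap!r} has wrong length")
            for allele, m in zip(hap, meta):
                if allele not in (m.major, m.minor):
                    raise ValueError(f"haplotype {hap!r}: allele {allele!r} invalid at {m.snp_id}")
        for hap, _ in self.haplotype_pool:
            if hap not in self.cluster_logit:
                raise ValueError(f"cluster_logit missing for haplotype {hap!r}")
        for c in (1, 2):
            missing = set(FA_PANEL) - set(self.fa_params[c])
            if missing:
                raise ValueError(f"fa_params cluster {c} missing {sorted(missing)}")
            for fa, (loc, iqr) in self.fa_params[c].items():
                if loc <= 0 or iqr < 0:
                    raise ValueError(f"fa_params[{c}][{fa!r}]: location must be > 0, IQR >= 0")


def default_config(seed: int = 0) -> GeneratorConfig:
    """Study-condition defaults (see module docstring for the calibration)."""
    pool: list[tuple[str, float]] = []
    logit: dict[str, float] = {}
    for core, core_freq in CORE_HAPLOTYPES.items():
        probs = TAIL_CONDITIONALS[core]
        tails_meta = [_SNP_DEFS[s] for s in SNP_ORDER[5:]]
        for bits in range(8):
            alleles = []
            p = 1.0
            for k, (major, minor, _, _) in enumerate(tails_meta):
                if (bits >> k) & 1:
                    alleles.append(minor)
                    p *= probs[k]
                else:
                    alleles.append(major)
                    p *= 1.0 - probs[k]
            hap = core + "".join(alleles)
            pool.append((hap, core_freq * p))
            logit[hap] = 0.45 if core == "GGGCC" else -0.45
    cfg = GeneratorConfig(seed=seed, haplotype_pool=pool, cluster_logit=logit)
    cfg.validate()
    return cfg


def draw_haplotype_pairs(
    config: GeneratorConfig, n: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Draw two independent haplotypes per subject (random mating, hence HWE)."""
    if not config.haplotype_pool:
        raise ValueError("empty haplotype pool")
    haps = [h for h, _ in config.haplotype_pool]
    freqs = np.array([f for _, f in config.haplotype_pool], dtype=float)
    freqs = freqs / freqs.sum()
    idx = rng.choice(len(haps), size=(n, 2), p=freqs)
    return [(haps[i], haps[j]) for i, j in idx]


def collapse_to_genotypes(
    pairs: list[tuple[str, str]],
    snp_metadata_list: list[SnpMeta],
    subject_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Discard phase: emit minor-allele dosages per subject per SNP."""
    n = len(pairs)
    if subject_ids is None:
        subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    dosages = np.zeros((n, len(snp_metadata_list)), dtype=np.int8)
    for i, (h1, h2) in enumerate(pairs):
        for j, meta in enumerate(snp_metadata_list):
            d = 0
            for hap in (h1, h2):
                a = hap[j]
                if a == meta.minor:
                    d += 1
                elif a != meta.major:
                    raise ValueError(f"allele {a!r} not valid for {meta.snp_id}")
            dosages[i, j] = d
    return GenotypeMatrix(subject_ids, list(snp_metadata_list), dosages)


def assign_cluster_labels(
    pairs: list[tuple[str, str]], config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """P(cluster 1) = logistic(intercept + effect(h1) + effect(h2))."""
    logits = np.array(
        [
            config.cluster_intercept
            + config.cluster_logit[h1]
            + config.cluster_logit[h2]
            for h1, h2 in pairs
        ]
    )
    from scipy.special import expit

    p1 = expit(logits)
    return np.where(rng.random(len(pairs)) < p1, 1, 2).astype(int)


def _lognormal_sigma(location: float, iqr: float) -> float:
    # IQR of a log-normal with median m: m*(e^{zs} - e^{-zs}), z = 0.6745
    return math.asinh(iqr / (2.0 * location)) / 0.6745


def generate_fa_profiles(
    labels: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-subject 18-FA vectors (log-normal, renormalized to the panel total)."""
    n = len(labels)
    out = np.empty((n, len(FA_PANEL)))
    totals = {
        c: (config.panel_total if config.panel_total is not None
            else sum(loc for loc, _ in config.fa_params[c].values()))
        for c in (1, 2)
    }
    z = rng.standard_normal((n, len(FA_PANEL)))
    for c in (1, 2):
        mask = labels == c
        if not mask.any():
            continue
        locs = np.array([config.fa_params[c][fa][0] for fa in FA_PANEL])
        iqrs = np.array([config.fa_params[c][fa][1] for fa in FA_PANEL])
        if (locs <= 0).any():
            raise ValueError("FA location parameters must be positive")
        sig = np.array([_lognormal_sigma(l, q) for l, q in zip(locs, iqrs)])
        vals = locs * np.exp(sig * z[mask])
        vals *= (totals[c] / vals.sum(axis=1))[:, None]
        out[mask] = vals
    return pd.DataFrame(out, columns=FA_PANEL)


def _draw_clinical(
    groups: np.ndarray, labels: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    traits = list(next(iter(config.clinical_params.values())))
    n = len(groups)
    z = rng.standard_normal((n, len(traits)))
    out = np.empty((n, len(traits)))
    for i in range(n):
        params = config.clinical_params[(groups[i], int(labels[i]))]
        for j, t in enumerate(traits):
            loc, spread, dist = params[t]
            if dist == "normal":
                out[i, j] = loc + spread * z[i, j]
            else:
                out[i, j] = loc * math.exp(_lognormal_sigma(loc, spread) * z[i, j])
    return pd.DataFrame(out, columns=traits)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, GenotypeMatrix, dict]:
    """End-to-end generation.

    Returns the phenotype table (all subjects), the genotype matrix
    (genotyped subset only) and a truth record with the per-subject haplotype
    pairs and latent cluster labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_mets + config.n_con
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]

    pairs = draw_haplotype_pairs(config, n, rng)
    clusters = assign_cluster_labels(pairs, config, rng)

    # Exact group sizes with the configured conditional composition: the MetS
    # total is split between the clusters in proportion to n_c * P(MetS|c),
    # then subjects are picked uniformly within each cluster.
    groups = np.array(["CON"] * n, dtype=object)
    if config.n_mets > 0:
        idx1 = np.where(clusters == 1)[0]
        idx2 = np.where(clusters == 2)[0]
        w1 = len(idx1) * config.group_given_cluster[1]
        w2 = len(idx2) * config.group_given_cluster[2]
        m1 = config.n_mets if w1 + w2 <= 0 else round(config.n_mets * w1 / (w1 + w2))
        m1 = int(np.clip(m1, max(0, config.n_mets - len(idx2)), min(len(idx1), config.n_mets)))
        mets_idx = np.concatenate([
            rng.choice(idx1, size=m1, replace=False),
            rng.choice(idx2, size=config.n_mets - m1, replace=False),
        ])
        groups[mets_idx] = "MetS"

    fa = generate_fa_profiles(clusters, config, rng)
    clinical = _draw_clinical(groups, clusters, config, rng)
    sex = np.where(rng.random(n) < config.p_male, "M", "F")
    age = np.round(config.age_mean + config.age_sd * rng.standard_normal(n), 1)

    if not 0 <= config.n_genotyped <= n:
        raise ValueError("n_genotyped out of range")
    geno_idx = np.sort(rng.choice(n, size=config.n_genotyped, replace=False))
    genotyped = np.zeros(n, dtype=bool)
    genotyped[geno_idx] = True

    table = pd.DataFrame({"subject_id": subject_ids, "group": groups,
                          "sex": sex, "age": age})
    table = pd.concat([table, clinical, fa], axis=1)
    table["homa_ir"] = homa_ir(table["insulin_mU_l"], table["glucose_mmol_l"])
    table["genotyped"] = genotyped

    meta = snp_metadata()
    geno = collapse_to_genotypes(
        [pairs[i] for i in geno_idx], meta, [subject_ids[i] for i in geno_idx]
    )

    truth = {
        "haplotype_pairs": {sid: list(pairs[i]) for i, sid in enumerate(subject_ids)},
        "cluster": {sid: int(clusters[i]) for i, sid in enumerate(subject_ids)},
        "config": {
            "n_mets": config.n_mets, "n_con": config.n_con, "seed": config.seed,
            "n_genotyped": config.n_genotyped,
            "cluster_intercept": config.cluster_intercept,
            "haplotype_pool": [[h, float(f)] for h, f in config.haplotype_pool],
            "cluster_logit": {h: float(v) for h, v in config.cluster_logit.items()},
            "group_given_cluster": {str(k): float(v) for k, v in config.group_given_cluster.items()},
        },
    }
    return table, geno, truth


def core_haplotype_frequencies(config: GeneratorConfig) -> dict[str, float]:
    """Marginal frequencies of the five-SNP block haplotypes in the pool."""
    core: dict[str, float] = {}
    for hap, f in config.haplotype_pool:
        core[hap[:5]] = core.get(hap[:5], 0.0) + f
    return core
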