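"""Generator tests: pool construction, HWE, cluster effects, FA profiles."""

import numpy as np
import pandas as pd
import pytest

from fadsmets import GeneratorConfig, default_config, generate_cohort
from fadsmets.association import hwe_test
from fadsmets.cohort import (assign_cluster_labels, collapse_to_genotypes,
                             core_haplotype_frequencies, draw_haplotype_pairs,
                             generate_fa_profiles, snp_metadata, SNP_ORDER)
from fadsmets.fa import FA_PANEL


class TestDefaultConfig:
    def test_core_frequencies_renormalized(self):
        core = core_haplotype_frequencies(default_config())
        assert core["GGGCC"] == pytest.approx(0.662 / 0.990, abs=1e-12)
        assert core["TCATC"] == pytest.approx(0.149 / 0.990, abs=1e-12)
        assert core["TCACT"] == pytest.approx(0.130 / 0.990, abs=1e-12)
        assert core["TCACC"] == pytest.approx(0.049 / 0.990, abs=1e-12)

    def test_pool_frequencies_sum_to_one(self):
        cfg = default_config()
        assert sum(f for _, f in cfg.haplotype_pool) == pytest.approx(1.0, abs=1e-9)

    def test_fads1_alleles_copied(self):
        """rs174545/rs174546 states are deterministic copies of rs174537."""
        cfg = default_config()
        meta = snp_metadata()
        for hap, _ in cfg.haplotype_pool:
            minor37 = hap[0] == meta[0].minor
            assert (hap[1] == meta[1].minor) == minor37
            assert (hap[2] == meta[2].minor) == minor37

    def test_validation_rejects_bad_pool(self):
        cfg = default_config()
        cfg.haplotype_pool[0] = ("XXXXXXXX", cfg.haplotype_pool[0][1])
        with pytest.raises(ValueError, match="invalid"):
            cfg.validate()


class TestDrawHaplotypePairs:
    def test_degenerate_pool(self, rng):
        cfg = default_config()
        hap = cfg.haplotype_pool[0][0]
        cfg.haplotype_pool = [(hap, 1.0)]
        cfg.cluster_logit = {hap: 0.0}
        pairs = draw_haplotype_pairs(cfg, 5, rng)
        assert pairs == [(hap, hap)] * 5

    def test_heterozygote_fraction_binomial(self, rng):
        """Two equifrequent haplotypes: het fraction ~ Binomial(n, 1/2)."""
        cfg = default_config()
        h1, h2 = cfg.haplotype_pool[0][0], cfg.haplotype_pool[-1][0]
        cfg.haplotype_pool = [(h1, 0.5), (h2, 0.5)]
        n = 10_000
        pairs = draw_haplotype_pairs(cfg, n, rng)
        het = sum(a != b for a, b in pairs) / n
        sd = np.sqrt(0.25 / n)
        assert abs(het - 0.5) < 3 * sd

    def test_seed_determinism(self):
        cfg = default_config()
        p1 = draw_haplotype_pairs(cfg, 100, np.random.default_rng(7))
        p2 = draw_haplotype_pairs(cfg, 100, np.random.default_rng(7))
        assert p1 == p2

    def test_empty_pool_rejected(self, rng):
        cfg = default_config()
        cfg.haplotype_pool = []
        with pytest.raises(ValueError, match="empty"):
            draw_haplotype_pairs(cfg, 3, rng)


class TestCollapseToGenotypes:
    def test_heterozygote_and_homozygote(self):
        meta = snp_metadata()
        g = collapse_to_genotypes(
            [("GGGCCCTC", "TCATCCTC"), ("GGGCCCTC", "GGGCCCTC")], meta
        )
        # subject 1 heterozygous at the first four loci, subject 2 all major
        assert list(g.dosages[0, :5]) == [1, 1, 1, 1, 0]
        assert list(g.dosages[1]) == [0] * 8
        assert g.snps[0].genotype_string(1) == "G/T"

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError, match="allele"):
            collapse_to_genotypes([("ZGGCCCTC", "GGGCCCTC")], snp_metadata())

    def test_default_cohort_shape(self, default_cohort):
        _, geno, _ = default_cohort
        assert geno.dosages.shape == (330, 8)
        assert geno.missing_rate() == 0.0


class TestAssignClusterLabels:
    def test_null_effects_balanced(self, rng):
        cfg = default_config()
        cfg.cluster_intercept = 0.0
        cfg.cluster_logit = {h: 0.0 for h, _ in cfg.haplotype_pool}
        pairs = draw_haplotype_pairs(cfg, 10_000, rng)
        labels = assign_cluster_labels(pairs, cfg, rng)
        assert abs((labels == 1).mean() - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_extreme_intercept_forces_cluster2(self, rng):
        cfg = default_config()
        cfg.cluster_intercept = -1e9
        pairs = draw_haplotype_pairs(cfg, 200, rng)
        assert (assign_cluster_labels(pairs, cfg, rng) == 2).all()

    def test_major_homozygote_enrichment(self, rng):
        """GGGCC-core effects put major-allele homozygotes mostly in cluster 1;
        the realized odds ratio matches the configured logistic model."""
        cfg = default_config()
        pairs = draw_haplotype_pairs(cfg, 10_000, rng)
        labels = assign_cluster_labels(pairs, cfg, rng)
        gg = np.array([a[:5] == "GGGCC" and b[:5] == "GGGCC" for a, b in pairs])
        p_gg = (labels[gg] == 1).mean()
        p_tt = (labels[~gg & np.array(
            [a[:5] != "GGGCC" and b[:5] != "GGGCC" for a, b in pairs])] == 1).mean()
        # configured: logistic(-0.25+0.9) vs logistic(-0.25-0.9)
        assert p_gg == pytest.approx(1 / (1 + np.exp(-0.65)), abs=0.03)
        assert p_tt == pytest.approx(1 / (1 + np.exp(1.15)), abs=0.03)
        assert p_gg > p_tt


class TestGenerateFaProfiles:
    def test_zero_variance_yields_cluster_locations(self, rng):
        cfg = default_config()
        for c in (1, 2):
            cfg.fa_params[c] = {fa: (loc, 0.0) for fa, (loc, _) in cfg.fa_params[c].items()}
        prof = generate_fa_profiles(np.array([1, 2]), cfg, rng)
        for c, row in zip((1, 2), prof.to_numpy()):
            expected = np.array([cfg.fa_params[c][fa][0] for fa in FA_PANEL])
            np.testing.assert_allclose(row, expected, rtol=1e-12)

    def test_rows_sum_to_panel_total(self, rng):
        cfg = default_config()
        cfg.panel_total = 100.0
        prof = generate_fa_profiles(np.array([1] * 20 + [2] * 20), cfg, rng)
        np.testing.assert_allclose(prof.sum(axis=1), 100.0, atol=1e-9)

    def test_linoleic_acid_lower_in_cluster1(self, rng):
        labels = np.array([1] * 500 + [2] * 500)
        prof = generate_fa_profiles(labels, default_config(), rng)
        assert (prof["18:2n-6"][labels == 1].median()
                < prof["18:2n-6"][labels == 2].median())

    def test_nonpositive_location_rejected(self, rng):
        cfg = default_config()
        cfg.fa_params[1]["14:0"] = (0.0, 0.1)
        with pytest.raises(ValueError):
            cfg.validate()


class TestGenerateCohort:
    def test_default_sizes(self, default_cohort):
        table, geno, truth = default_cohort
        assert len(table) == 354
        assert table["group"].value_counts().to_dict() == {"CON": 188, "MetS": 166}
        assert geno.n_subjects == 330
        assert int(table["genotyped"].sum()) == 330

    def test_truth_collapses_to_genotypes(self, default_cohort):
        table, geno, truth = default_cohort
        meta = snp_metadata()
        re_collapsed = collapse_to_genotypes(
            [tuple(truth["haplotype_pairs"][s]) for s in geno.subject_ids],
            meta, list(geno.subject_ids))
        np.testing.assert_array_equal(re_collapsed.dosages, geno.dosages)

    def test_con_only_cohort(self):
        cfg = default_config(seed=2)
        cfg.n_mets, cfg.n_con, cfg.n_genotyped = 0, 50, 40
        table, _, _ = generate_cohort(cfg)
        assert (table["group"] == "CON").all()

    def test_seed_reproducibility(self):
        t1, g1, r1 = generate_cohort(default_config(seed=42))
        t2, g2, r2 = generate_cohort(default_config(seed=42))
        pd.testing.assert_frame_equal(t1, t2)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert r1 == r2


def test_hwe_rejection_rate_is_nominal():
    """Random-mating sampling: per-cohort HWE test rejects at ~alpha."""
    cfg = default_config()
    meta = snp_metadata()
    rej = 0
    n_rep = 120
    for rep in range(n_rep):
        rng = np.random.default_rng(900 + rep)
        pairs = draw_haplotype_pairs(cfg, 300, rng)
        geno = collapse_to_genotypes(pairs, meta)
        col = geno.column("rs174537")
        counts = [(col == d).sum() for d in (0, 1, 2)]
        if hwe_test(counts).p_value < 0.05:
            rej += 1
    sd = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rej / n_rep - 0.05) < 3.5 * sd
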