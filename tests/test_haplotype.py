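"""EM estimator vs brute-force likelihood, LD algebra, blocks, phase, scan."""

import itertools

import numpy as np
import pytest

from fadsmets.cohort import BLOCK_LOCI, default_config
from fadsmets import generate_cohort
from fadsmets.genio import GenotypeMatrix, SnpMeta
from fadsmets.haplotype import (HaplotypeSet, assign_phase, block_partition,
                                em_haplotype_frequencies, haplotype_association,
                                ld_from_two_locus_freqs, ld_matrix, pairwise_ld)


def _toy_geno(dosages, n_loci=2):
    snps = [SnpMeta(f"rs{k}", "A", "B") if k == 0 else SnpMeta(f"rs{k}", "C", "D")
            for k in range(n_loci)]
    dosages = np.asarray(dosages)
    ids = [f"s{i}" for i in range(len(dosages))]
    return GenotypeMatrix(ids, snps, dosages)


def _grid_loglik_max(dosages, step=0.02):
    """Brute-force oracle: maximize the two-locus likelihood on a simplex
    grid (haplotypes 00, 01, 10, 11 in minor-allele coding)."""
    ticks = int(round(1 / step))
    pts = []
    for i, j, k in itertools.product(range(ticks + 1), repeat=3):
        if i + j + k <= ticks:
            pts.append((i, j, k, ticks - i - j - k))
    F = np.asarray(pts, dtype=float) / ticks  # (n_grid, 4)

    def pair_prob(F, a, b):
        return (2 - (a == b)) * F[:, a] * F[:, b]

    ll = np.zeros(len(F))
    for d in np.asarray(dosages):
        compat = []
        # haplotype index = 2*allele_at_locus0 + allele_at_locus1
        for a0, b0 in {0: [(0, 0)], 1: [(0, 1)], 2: [(1, 1)]}[d[0]]:
            for a1, b1 in {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}[d[1]]:
                pair = tuple(sorted((2 * a0 + a1, 2 * b0 + b1)))
                if pair not in compat:
                    compat.append(pair)
        p = np.zeros(len(F))
        for a, b in compat:
            p += pair_prob(F, a, b)
        ll += np.log(np.maximum(p, 1e-300))
    best = np.argmax(ll)
    return float(ll[best]), F[best]


class TestEmHaplotypeFrequencies:
    def test_single_double_homozygote(self):
        hs = em_haplotype_frequencies(_toy_geno([[0, 0]]))
        assert hs.as_dict() == {"AC": pytest.approx(1.0)}

    def test_homozygote_plus_double_het_prefers_coupling(self):
        """One AC/AC homozygote plus one double heterozygote: the coupling
        resolution dominates and matches the grid-search optimum."""
        hs = em_haplotype_frequencies(_toy_geno([[0, 0], [1, 1]]))
        ll_grid, f_grid = _grid_loglik_max([[0, 0], [1, 1]], step=0.01)
        assert hs.log_likelihood >= ll_grid - 1e-4
        d = hs.as_dict()
        assert d.get("AC", 0.0) == pytest.approx(f_grid[0], abs=0.01)
        assert d.get("AC", 0.0) > 0.70  # coupling-biased solution

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_grid(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 7))
        dosages = r.integers(0, 3, size=(n, 2))
        hs = em_haplotype_frequencies(_toy_geno(dosages), tol=1e-10, seed=seed)
        ll_grid, _ = _grid_loglik_max(dosages)
        assert hs.log_likelihood >= ll_grid - 1e-3

    def test_loglik_nondecreasing(self, default_cohort):
        _, geno, _ = default_cohort
        hs = em_haplotype_frequencies(geno, list(BLOCK_LOCI))
        trace = np.asarray(hs.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()
        assert hs.converged

    def test_recovers_generator_frequencies(self):
        cfg = default_config(seed=21)
        cfg.n_mets, cfg.n_con, cfg.n_genotyped = 1000, 1000, 2000
        _, geno, _ = generate_cohort(cfg)
        hs = em_haplotype_frequencies(geno, list(BLOCK_LOCI))
        est = hs.common()
        truth = {"GGGCC": 0.662 / 0.990, "TCATC": 0.149 / 0.990,
                 "TCACT": 0.130 / 0.990, "TCACC": 0.049 / 0.990}
        assert set(est) == set(truth)
        for h, f in truth.items():
            assert est[h] == pytest.approx(f, abs=0.02)

    def test_no_complete_subject_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            em_haplotype_frequencies(_toy_geno([[-1, 0]]))


class TestPairwiseLd:
    def test_perfect_coupling(self):
        d, dp, r2 = ld_from_two_locus_freqs(0.5, 0.0, 0.0, 0.5)
        assert dp == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_loci(self):
        d, dp, r2 = ld_from_two_locus_freqs(0.36, 0.24, 0.24, 0.16)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        d, dp, r2 = ld_from_two_locus_freqs(0.5, 0.1, 0.1, 0.3)
        assert d == pytest.approx(0.14, abs=1e-12)
        assert dp == pytest.approx(0.14 / 0.24, abs=1e-9)
        assert r2 == pytest.approx(0.14**2 / (0.6 * 0.4 * 0.6 * 0.4), abs=1e-9)

    def test_duplicated_column_r2_one(self, default_cohort):
        _, geno, _ = default_cohort
        pair = pairwise_ld(geno, "rs174537", "rs174545")
        assert pair.r2 == pytest.approx(1.0, abs=1e-9)
        assert pair.d_prime == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def default_ld():
    cfg = default_config(seed=13)
    _, geno, _ = generate_cohort(cfg)
    return ld_matrix(geno)


class TestLdMatrixAndBlocks:
    def test_entries_bounded(self, default_ld):
        finite_dp = default_ld.d_prime[np.isfinite(default_ld.d_prime)]
        finite_r2 = default_ld.r2[np.isfinite(default_ld.r2)]
        assert ((finite_dp >= -1e-9) & (finite_dp <= 1 + 1e-9)).all()
        assert ((finite_r2 >= -1e-9) & (finite_r2 <= 1 + 1e-9)).all()

    def test_r2_one_implies_dprime_one(self, default_ld):
        iu = np.triu_indices(len(default_ld.loci), 1)
        near_one = default_ld.r2[iu] > 1 - 1e-6
        assert (default_ld.d_prime[iu][near_one] > 1 - 1e-6).all()

    def test_block_contains_fads1_triplet(self, default_ld):
        blocks = block_partition(default_ld, 0.8)
        members = {s for b in blocks for s in b.snp_ids}
        assert {"rs174537", "rs174545", "rs174546"} <= members

    def test_degenerate_thresholds(self, default_ld):
        one = ld_matrix_like(default_ld, 1.0)
        assert [b.snp_ids for b in block_partition(one, 0.8)] == [one.loci]
        zero = ld_matrix_like(default_ld, 0.0)
        assert block_partition(zero, 0.8) == []


def ld_matrix_like(ld, value):
    from fadsmets.haplotype import LdMatrix
    m = len(ld.loci)
    dp = np.full((m, m), value)
    np.fill_diagonal(dp, 1.0)
    return LdMatrix(loci=list(ld.loci), d=np.zeros((m, m)), d_prime=dp,
                    r2=np.full((m, m), value))


class TestAssignPhase:
    def _hapset(self, freqs):
        haps = list(freqs)
        return HaplotypeSet(loci=["rs0", "rs1"], haplotypes=haps,
                            frequencies=np.array([freqs[h] for h in haps]),
                            log_likelihood=0.0, n_iterations=0, converged=True,
                            n_subjects=0)

    def test_double_homozygote_certain(self):
        hs = self._hapset({"AC": 0.7, "BD": 0.3})
        res = assign_phase(hs, [0, 0])
        assert res.pair == ("AC", "AC")
        assert res.posterior == 1.0

    def test_coupling_posterior_two_term_bayes(self):
        hs = self._hapset({"AC": 0.6, "BD": 0.3, "AD": 0.06, "BC": 0.04})
        res = assign_phase(hs, [1, 1])
        # P(coupling) = 2*0.6*0.3 / (2*0.6*0.3 + 2*0.06*0.04)
        want = (0.6 * 0.3) / (0.6 * 0.3 + 0.06 * 0.04)
        assert res.pair == ("AC", "BD")
        assert res.posterior == pytest.approx(want, rel=1e-9)

    def test_symmetric_tie_break(self):
        hs = self._hapset({"AC": 0.25, "AD": 0.25, "BC": 0.25, "BD": 0.25})
        res = assign_phase(hs, [1, 1])
        assert res.posterior == pytest.approx(0.5)
        assert res.pair == ("AC", "BD")  # lexicographically first

    def test_incompatible_genotype_flagged(self):
        hs = self._hapset({"AC": 1.0})
        res = assign_phase(hs, [2, 2])
        assert res.flagged


class TestHaplotypeAssociation:
    def test_perfect_association_hits_permutation_floor(self):
        r = np.random.default_rng(0)
        n = 120
        carrier = r.random(n) < 0.4
        dosages = np.zeros((n, 2), dtype=int)
        dosages[carrier] = [1, 1]  # carriers are double heterozygotes
        geno = _toy_geno(dosages)
        groups = np.where(carrier, "case", "control")
        res = haplotype_association(geno, groups, n_perm=199, seed=3)
        best = min(res.rows, key=lambda row: row.p_corrected)
        assert best.p_corrected == pytest.approx(1 / 200, abs=1e-12)

    def test_correction_dominates_single_test(self, small_cohort):
        _, geno, truth = small_cohort
        groups = np.array([truth["cluster"][s] for s in geno.subject_ids])
        res = haplotype_association(geno, groups, list(BLOCK_LOCI),
                                    n_perm=100, seed=4)
        for row in res.rows:
            assert row.p_corrected >= row.p_perm - 1e-12

    def test_effect_haplotypes_rank_first(self):
        """With the default cluster effects, the two most frequent block
        haplotypes (opposite effect signs) carry the association signal."""
        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = default_config(seed=200 + seed)
            _, geno, truth = generate_cohort(cfg)
            groups = np.array([truth["cluster"][s] for s in geno.subject_ids])
            res = haplotype_association(geno, groups, list(BLOCK_LOCI),
                                        n_perm=300, seed=seed)
            rows = {r.haplotype: r for r in res.rows}
            others = [r.p_corrected for h, r in rows.items()
                      if h not in ("GGGCC", "TCATC")]
            if rows["GGGCC"].p_corrected <= min(others) + 1e-12:
                wins += 1
        assert wins >= n_seeds - 1

    def test_seed_reproducibility(self, small_cohort):
        _, geno, truth = small_cohort
        groups = np.array([truth["cluster"][s] for s in geno.subject_ids])
        r1 = haplotype_association(geno, groups, list(BLOCK_LOCI), n_perm=50, seed=9)
        r2 = haplotype_association(geno, groups, list(BLOCK_LOCI), n_perm=50, seed=9)
        assert [(a.haplotype, a.p_corrected) for a in r1.rows] == \
               [(a.haplotype, a.p_corrected) for a in r2.rows]
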