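"""EM haplotype-frequency estimation, pairwise LD, blocks and association.

The estimator is the classical EM for multilocus haplotype frequencies from
unphased genotypes (Excoffier-Slatkin style): the E-step distributes each
ambiguous genotype over its compatible haplotype pairs in proportion to the
current pair probabilities (2 f_a f_b for a != b, f_a^2 otherwise); the
M-step re-estimates frequencies from the expected pair counts.  Haplotypes
are encoded as bitmasks of minor alleles, so the per-subject compatible
pairs can be enumerated once and the EM iterations run as vectorized
segment sums.

Block partitioning is a documented substitute for likelihood-based block
finders: maximal contiguous runs of loci in which every within-run pair has
D' at or above a threshold (default 0.8).

The haplotype-cluster association scan tests each common haplotype's
EM-expected allele counts in a 2x2 chi-square against the pooled remainder
and corrects for multiplicity with a max-statistic label permutation:
per-group EM is re-run for every permuted labeling (the candidate haplotype
list, which depends only on the genotypes, stays fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .genio import MISSING, GenotypeMatrix

MAX_LOCI = 12


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------

@dataclass
class _PairTable:
    """Flattened per-subject compatible haplotype pairs.

    ``subj``, ``a``, ``b`` are parallel arrays over all (subject, pair)
    rows; ``a``/``b`` index the haplotype registry; ``mult`` is 2 for
    heterozygous pairs and 1 for homozygous ones.
    """

    n_subjects: int
    n_haplotypes: int
    subj: np.ndarray
    a: np.ndarray
    b: np.ndarray
    mult: np.ndarray
    codes: np.ndarray  # registry index -> haplotype bitmask

    def subset(self, subject_mask: np.ndarray) -> "_PairTable":
        keep = subject_mask[self.subj]
        new_index = np.cumsum(subject_mask) - 1
        return _PairTable(
            n_subjects=int(subject_mask.sum()),
            n_haplotypes=self.n_haplotypes,
            subj=new_index[self.subj[keep]],
            a=self.a[keep], b=self.b[keep], mult=self.mult[keep],
            codes=self.codes,
        )


def _enumerate_pairs(dosages: np.ndarray) -> _PairTable:
    """Enumerate compatible unordered haplotype pairs per complete subject."""
    n, L = dosages.shape
    registry: dict[int, int] = {}

    def reg(code: int) -> int:
        if code not in registry:
            registry[code] = len(registry)
        return registry[code]

    subj, aa, bb, mult = [], [], [], []
    for i in range(n):
        d = dosages[i]
        base = 0
        hets = []
        for k in range(L):
            if d[k] == 2:
                base |= 1 << k
            elif d[k] == 1:
                hets.append(k)
        hm = 0
        for k in hets:
            hm |= 1 << k
        if not hets:
            subj.append(i); aa.append(reg(base)); bb.append(reg(base)); mult.append(1)
            continue
        rest = hets[1:]
        for bits in range(1 << len(rest)):
            s = 0
            for idx, k in enumerate(rest):
                if (bits >> idx) & 1:
                    s |= 1 << k
            a = base | s
            b = base | (hm ^ s)
            subj.append(i); aa.append(reg(a)); bb.append(reg(b)); mult.append(2)
    codes = np.empty(len(registry), dtype=np.int64)
    for code, idx in registry.items():
        codes[idx] = code
    return _PairTable(
        n_subjects=n, n_haplotypes=len(registry),
        subj=np.asarray(subj, dtype=np.int64), a=np.asarray(aa, dtype=np.int64),
        b=np.asarray(bb, dtype=np.int64), mult=np.asarray(mult, dtype=np.float64),
        codes=codes,
    )


def _em(pairs: _PairTable, init: np.ndarray, tol: float, max_iter: int):
    """Run EM from ``init``; returns (freqs, loglik_trace, converged)."""
    p = init / init.sum()
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        w = pairs.mult * p[pairs.a] * p[pairs.b]
        denom = np.bincount(pairs.subj, weights=w, minlength=pairs.n_subjects)
        trace.append(float(np.log(np.maximum(denom, 1e-300)).sum()))
        wn = w / np.maximum(denom[pairs.subj], 1e-300)
        counts = (np.bincount(pairs.a, weights=wn, minlength=pairs.n_haplotypes)
                  + np.bincount(pairs.b, weights=wn, minlength=pairs.n_haplotypes))
        p_new = counts / (2.0 * pairs.n_subjects)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    w = pairs.mult * p[pairs.a] * p[pairs.b]
    denom = np.bincount(pairs.subj, weights=w, minlength=pairs.n_subjects)
    trace.append(float(np.log(np.maximum(denom, 1e-300)).sum()))
    return p, trace, converged


def _marginal_init(pairs: _PairTable, dosages: np.ndarray) -> np.ndarray:
    L = dosages.shape[1]
    maf = dosages.mean(axis=0) / 2.0
    maf = np.clip(maf, 1e-6, 1 - 1e-6)
    init = np.empty(pairs.n_haplotypes)
    for idx, code in enumerate(pairs.codes):
        prod = 1.0
        for k in range(L):
            prod *= maf[k] if (code >> k) & 1 else 1.0 - maf[k]
        init[idx] = prod
    return init


@dataclass
class HaplotypeSet:
    loci: list[str]
    haplotypes: list[str]           # allele strings, aligned with frequencies
    frequencies: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_subjects: int
    reporting_floor: float = 0.01
    loglik_trace: list[float] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.haplotypes, map(float, self.frequencies)))

    def common(self) -> dict[str, float]:
        """Haplotypes at or above the reporting floor (default 1%)."""
        return {h: f for h, f in self.as_dict().items() if f >= self.reporting_floor}


def _codes_to_strings(codes: np.ndarray, snps) -> list[str]:
    out = []
    for code in codes:
        out.append("".join(
            s.minor if (int(code) >> k) & 1 else s.major for k, s in enumerate(snps)
        ))
    return out


def em_haplotype_frequencies(
    geno: GenotypeMatrix,
    loci: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 3,
    seed: int = 0,
    reporting_floor: float = 0.01,
) -> HaplotypeSet:
    """EM haplotype frequencies over ``loci`` (default: all SNPs).

    Subjects incomplete on the requested loci are excluded.  The run is
    restarted ``n_restarts`` times (product-of-marginals start, then
    seeded Dirichlet draws) and the best-likelihood solution kept.
    """
    sub = geno.subset_loci(loci) if loci is not None else geno
    loci_ids = sub.snp_ids
    if len(loci_ids) > MAX_LOCI:
        raise ValueError(f"more than {MAX_LOCI} loci requested")
    complete = ~(sub.dosages == MISSING).any(axis=1)
    if not complete.any():
        raise ValueError("no subject with complete data on the requested loci")
    dosages = sub.dosages[complete].astype(np.int64)
    pairs = _enumerate_pairs(dosages)

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        init = (_marginal_init(pairs, dosages) if r == 0
                else rng.dirichlet(np.ones(pairs.n_haplotypes)))
        p, trace, converged = _em(pairs, init, tol, max_iter)
        if best is None or trace[-1] > best[1][-1]:
            best = (p, trace, converged)
    p, trace, converged = best

    order = np.argsort(-p)
    return HaplotypeSet(
        loci=loci_ids,
        haplotypes=_codes_to_strings(pairs.codes[order], sub.snps),
        frequencies=p[order],
        log_likelihood=trace[-1],
        n_iterations=len(trace) - 1,
        converged=converged,
        n_subjects=pairs.n_subjects,
        reporting_floor=reporting_floor,
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LdPair:
    snp_i: str
    snp_j: str
    d: float
    d_prime: float
    r2: float
    defined: bool = True


def ld_from_two_locus_freqs(f_ab, f_aB, f_Ab, f_AB) -> tuple[float, float, float]:
    """(D, D', r2) from two-locus haplotype frequencies.

    Arguments are the frequencies of (major,major), (major,minor),
    (minor,major) and (minor,minor) haplotypes; D is defined on the major
    alleles, D = f(AB) - f(A) f(B).
    """
    total = f_ab + f_aB + f_Ab + f_AB
    if abs(total - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must sum to 1")
    pA = f_ab + f_aB      # major at locus i
    pB = f_ab + f_Ab      # major at locus j
    qA, qB = 1 - pA, 1 - pB
    if min(pA, qA, pB, qB) <= 0:
        return float("nan"), float("nan"), float("nan")
    d = f_ab - pA * pB
    if d >= 0:
        dmax = min(pA * qB, qA * pB)
    else:
        dmax = min(pA * pB, qA * qB)
    d_prime = abs(d) / dmax if dmax > 0 else float("nan")
    r2 = d * d / (pA * qA * pB * qB)
    return d, d_prime, r2


def pairwise_ld(source, snp_i: str, snp_j: str, seed: int = 0) -> LdPair:
    """LD between two biallelic loci.

    ``source`` is either a :class:`GenotypeMatrix` (two-locus EM estimates
    the haplotype frequencies) or a two-locus :class:`HaplotypeSet`.
    """
    if isinstance(source, HaplotypeSet):
        hs = source
        if len(hs.loci) != 2 or [snp_i, snp_j] != hs.loci:
            raise ValueError("HaplotypeSet loci do not match the requested pair")
    else:
        hs = em_haplotype_frequencies(source, [snp_i, snp_j], tol=1e-8,
                                      n_restarts=1, seed=seed)
    freqs = {"ab": 0.0, "aB": 0.0, "Ab": 0.0, "AB": 0.0}
    # reconstruct minor-allele pattern from string vs SnpMeta is not needed:
    # HaplotypeSet haplotypes are ordered allele strings over the two loci.
    majors = _majors_for(hs)
    for hap, f in hs.as_dict().items():
        key = ("a" if hap[0] == majors[0] else "A") + ("b" if hap[1] == majors[1] else "B")
        freqs[{"ab": "ab", "aB": "aB", "Ab": "Ab", "AB": "AB"}[key]] += f
    d, dp, r2 = ld_from_two_locus_freqs(freqs["ab"], freqs["aB"], freqs["Ab"], freqs["AB"])
    defined = np.isfinite(d)
    return LdPair(snp_i, snp_j, d, dp, r2, defined=bool(defined))


def _majors_for(hs: HaplotypeSet) -> list[str]:
    # major allele per locus = allele of the most frequent haplotype... not
    # robust; recover from frequency-weighted allele counts instead.
    majors = []
    for k in range(len(hs.loci)):
        counts: dict[str, float] = {}
        for hap, f in zip(hs.haplotypes, hs.frequencies):
            counts[hap[k]] = counts.get(hap[k], 0.0) + float(f)
        majors.append(sorted(counts, key=lambda a: (-counts[a], a))[0])
    return majors


@dataclass
class LdMatrix:
    loci: list[str]
    d: np.ndarray
    d_prime: np.ndarray
    r2: np.ndarray


def ld_matrix(geno: GenotypeMatrix, loci: list[str] | None = None, seed: int = 0) -> LdMatrix:
    if loci is None:
        loci = geno.snp_ids
    m = len(loci)
    D = np.full((m, m), np.nan)
    DP = np.full((m, m), np.nan)
    R2 = np.full((m, m), np.nan)
    np.fill_diagonal(DP, 1.0)
    np.fill_diagonal(R2, 1.0)
    np.fill_diagonal(D, 0.0)
    for i in range(m):
        for j in range(i + 1, m):
            pair = pairwise_ld(geno, loci[i], loci[j], seed=seed)
            D[i, j] = D[j, i] = pair.d
            DP[i, j] = DP[j, i] = pair.d_prime
            R2[i, j] = R2[j, i] = pair.r2
    return LdMatrix(loci=list(loci), d=D, d_prime=DP, r2=R2)


@dataclass
class Block:
    start: int
    end: int  # inclusive
    snp_ids: list[str]


def block_partition(ld: LdMatrix, d_prime_threshold: float = 0.8) -> list[Block]:
    """Greedy maximal contiguous runs with every within-run D' >= threshold."""
    m = len(ld.loci)
    blocks: list[Block] = []
    i = 0
    while i < m:
        j = i
        while j + 1 < m and np.all(
            ld.d_prime[i : j + 2, i : j + 2][np.triu_indices(j + 2 - i, 1)]
            >= d_prime_threshold
        ):
            j += 1
        if j > i:
            blocks.append(Block(start=i, end=j, snp_ids=ld.loci[i : j + 1]))
        i = j + 1
    return blocks


# ---------------------------------------------------------------------------
# Phase assignment
# ---------------------------------------------------------------------------

@dataclass
class PhaseAssignment:
    pair: tuple[str, str]
    posterior: float
    flagged: bool = False  # True when no positive-frequency pair was compatible


def assign_phase(hapset: HaplotypeSet, subject_dosages) -> PhaseAssignment:
    """Most probable haplotype pair for one subject under ``hapset``."""
    d = np.asarray(subject_dosages, dtype=np.int64)
    if d.ndim != 1 or len(d) != len(hapset.loci):
        raise ValueError("dosage vector does not match the haplotype loci")
    if (d == MISSING).any():
        raise ValueError("subject must be complete on the haplotype loci")
    pairs = _enumerate_pairs(d[None, :])
    strings = _PhaseStrings(hapset)
    cand: list[tuple[str, str]] = []
    probs: list[float] = []
    for a, b, mult in zip(pairs.a, pairs.b, pairs.mult):
        ha = strings.from_code(int(pairs.codes[a]))
        hb = strings.from_code(int(pairs.codes[b]))
        ha, hb = sorted((ha, hb))
        fa = hapset.as_dict().get(ha, 0.0)
        fb = hapset.as_dict().get(hb, 0.0)
        cand.append((ha, hb))
        probs.append(mult * fa * fb)
    probs_arr = np.asarray(probs)
    flagged = False
    if probs_arr.sum() <= 0:
        probs_arr = np.ones_like(probs_arr)
        flagged = True
    probs_arr = probs_arr / probs_arr.sum()
    order = sorted(range(len(cand)), key=lambda k: (-probs_arr[k], cand[k]))
    best = order[0]
    return PhaseAssignment(pair=cand[best], posterior=float(probs_arr[best]),
                           flagged=flagged)


class _PhaseStrings:
    def __init__(self, hapset: HaplotypeSet):
        # alleles per locus: infer (major, minor) from frequency-weighted counts
        self._majors = _majors_for(hapset)
        self._minors = []
        for k in range(len(hapset.loci)):
            alleles = {h[k] for h in hapset.haplotypes}
            alleles.discard(self._majors[k])
            self._minors.append(alleles.pop() if alleles else "N")

    def from_code(self, code: int) -> str:
        return "".join(
            self._minors[k] if (code >> k) & 1 else self._majors[k]
            for k in range(len(self._majors))
        )


# ---------------------------------------------------------------------------
# Haplotype association with max-statistic permutation correction
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAssociationRow:
    haplotype: str
    freq_all: float
    freq_a: float
    freq_b: float
    chi2: float
    p_raw: float            # asymptotic chi-square p on EM-expected counts
    p_perm: float           # single-haplotype permutation p
    p_corrected: float      # max-statistic family-wise corrected p


@dataclass
class HaplotypeAssociation:
    loci: list[str]
    levels: list
    rows: list[HaplotypeAssociationRow]
    n_perm: int
    seed: int


def _group_freqs(pairs: _PairTable, mask: np.ndarray, dosages: np.ndarray,
                 tol: float, max_iter: int) -> np.ndarray:
    sub = pairs.subset(mask)
    init = _marginal_init(sub, dosages[mask])
    p, _, _ = _em(sub, init, tol, max_iter)
    return p


def _hap_chi2(f1: np.ndarray, f2: np.ndarray, n1: int, n2: int,
              hap_idx: np.ndarray) -> np.ndarray:
    """Per-haplotype 2x2 chi-square on EM-expected allele counts (this
    haplotype vs all others, by group), counts rounded to 0.01."""
    stats = np.empty(len(hap_idx))
    for out_i, h in enumerate(hap_idx):
        c1 = round(2 * n1 * float(f1[h]), 2)
        c2 = round(2 * n2 * float(f2[h]), 2)
        table = np.array([[c1, 2 * n1 - c1], [c2, 2 * n2 - c2]], dtype=float)
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        if (row <= 0).any() or (col <= 0).any():
            stats[out_i] = 0.0
            continue
        exp = np.outer(row, col) / table.sum()
        stats[out_i] = float(((table - exp) ** 2 / exp).sum())
    return stats


def haplotype_association(
    geno: GenotypeMatrix,
    grouping,
    loci: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    reporting_floor: float = 0.01,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> HaplotypeAssociation:
    """Case-control haplotype scan with max-statistic permutation correction."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sub = geno.subset_loci(loci) if loci is not None else geno
    groups = np.asarray(grouping)
    if len(groups) != sub.n_subjects:
        raise ValueError("grouping length does not match genotype matrix")
    complete = ~(sub.dosages == MISSING).any(axis=1)
    dosages = sub.dosages[complete].astype(np.int64)
    groups = groups[complete]
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"grouping must have two levels, got {levels}")
    mask_a = groups == levels[0]
    n1, n2 = int(mask_a.sum()), int((~mask_a).sum())
    if min(n1, n2) < 2:
        raise ValueError("degenerate group sizes")

    pairs = _enumerate_pairs(dosages)
    init = _marginal_init(pairs, dosages)
    pooled, _, _ = _em(pairs, init, tol=1e-6, max_iter=1000)
    hap_idx = np.where(pooled >= reporting_floor)[0]
    hap_strings = _codes_to_strings(pairs.codes[hap_idx], sub.snps)

    f1 = _group_freqs(pairs, mask_a, dosages, tol, max_iter)
    f2 = _group_freqs(pairs, ~mask_a, dosages, tol, max_iter)
    obs = _hap_chi2(f1, f2, n1, n2, hap_idx)

    rng = np.random.default_rng(seed)
    exceed_single = np.zeros(len(hap_idx))
    exceed_max = np.zeros(len(hap_idx))
    for _ in range(n_perm):
        perm = rng.permutation(mask_a)
        g1 = _group_freqs(pairs, perm, dosages, tol, max_iter)
        g2 = _group_freqs(pairs, ~perm, dosages, tol, max_iter)
        stats = _hap_chi2(g1, g2, n1, n2, hap_idx)
        exceed_single += stats >= obs
        exceed_max += stats.max() >= obs
    p_perm = (1.0 + exceed_single) / (n_perm + 1.0)
    p_corr = (1.0 + exceed_max) / (n_perm + 1.0)

    rows = [
        HaplotypeAssociationRow(
            haplotype=hap_strings[i],
            freq_all=float(pooled[hap_idx[i]]),
            freq_a=float(f1[hap_idx[i]]),
            freq_b=float(f2[hap_idx[i]]),
            chi2=float(obs[i]),
            p_raw=float(chi2_dist.sf(obs[i], 1)),
            p_perm=float(p_perm[i]),
            p_corrected=float(p_corr[i]),
        )
        for i in np.argsort(-pooled[hap_idx])
    ]
    return HaplotypeAssociation(loci=sub.snp_ids, levels=levels, rows=rows,
                                n_perm=n_perm, seed=seed)
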