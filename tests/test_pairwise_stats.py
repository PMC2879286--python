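"""IBS/kinship and two-locus LD against brute-force and likelihood oracles."""

import numpy as np
import pytest

from parallgwa.errors import EmptyDataError, ParameterError
from parallgwa.pairwise_stats import (
    em_haplotype_freqs,
    ibs_matrix,
    ibs_pair,
    ld_matrix,
    ld_pair,
)
from parallgwa.snp_stats import alt_allele_freqs
from parallgwa.synthetic_data import SimSpec, simulate_genotypes
from conftest import make_matrix


def genotype_pair_probs(f):
    """Oracle: 3x3 genotype-pair probabilities from haplotype freqs under
    random union of gametes."""
    haps = {(0, 0): f[0], (0, 1): f[1], (1, 0): f[2], (1, 1): f[3]}
    P = np.zeros((3, 3))
    for (a1, b1), p1 in haps.items():
        for (a2, b2), p2 in haps.items():
            P[a1 + a2, b1 + b2] += p1 * p2
    return P


def table_loglik(counts, f):
    P = genotype_pair_probs(f)
    keep = counts > 0
    with np.errstate(divide="ignore"):
        lp = np.log(P)
    if np.any(keep & ~np.isfinite(lp)):
        return -np.inf
    return float((counts[keep] * lp[keep]).sum())


def random_count_table(rng, n=120):
    f = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
    P = genotype_pair_probs(f)
    draws = rng.multinomial(n, P.ravel()).reshape(3, 3)
    return draws.astype(float)


class TestIBSPair:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        val, n = ibs_pair(g, g)
        assert val == 1.0 and n == 5

    def test_opposite_homozygotes(self):
        a = np.zeros(6, dtype=np.int8)
        b = np.full(6, 2, dtype=np.int8)
        val, _ = ibs_pair(a, b)
        assert val == 0.0

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = rng.choice([-1, 0, 1, 2], size=40).astype(np.int8)
            b = rng.choice([-1, 0, 1, 2], size=40).astype(np.int8)
            val, n = ibs_pair(a, b)
            acc, cnt = 0.0, 0
            for x, y in zip(a, b):
                if x >= 0 and y >= 0:
                    acc += 1.0 - abs(int(x) - int(y)) / 2.0
                    cnt += 1
            assert n == cnt
            if cnt:
                assert val == pytest.approx(acc / cnt, abs=1e-12)
            else:
                assert np.isnan(val)

    def test_zero_shared_flagged(self):
        a = np.array([-1, 0], dtype=np.int8)
        b = np.array([1, -1], dtype=np.int8)
        val, n = ibs_pair(a, b)
        assert np.isnan(val) and n == 0

    def test_kinship_brute_force(self, sim_gm):
        freqs = alt_allele_freqs(sim_gm)
        rng = np.random.default_rng(6)
        for _ in range(10):
            i, k = rng.choice(sim_gm.n_samples, size=2, replace=False)
            val, n = ibs_pair(sim_gm.codes[i], sim_gm.codes[k], weight="freq", freqs=freqs)
            acc, cnt = 0.0, 0
            for j in range(sim_gm.n_snps):
                gi, gk, p = sim_gm.codes[i, j], sim_gm.codes[k, j], freqs[j]
                if gi >= 0 and gk >= 0 and 0 < p < 1:
                    acc += (gi / 2 - p) * (gk / 2 - p) / (p * (1 - p))
                    cnt += 1
            assert n == cnt
            assert val == pytest.approx(acc / cnt, abs=1e-12)


class TestIBSMatrix:
    def test_duplicated_individual_hits_one(self):
        G = make_matrix([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        m = ibs_matrix(G)
        assert m.values[0, 1] == 1.0

    def test_symmetry_and_bounds(self, sim_gm):
        m = ibs_matrix(sim_gm)
        assert np.array_equal(m.values, m.values.T)
        off = m.values[np.triu_indices(sim_gm.n_samples, k=1)]
        assert np.all((off >= 0.0) & (off <= 1.0))
        assert np.all(np.diag(m.values) == 1.0)

    def test_invariant_to_snp_order(self, sim_gm):
        perm = np.random.default_rng(2).permutation(sim_gm.n_snps)
        m1 = ibs_matrix(sim_gm)
        m2 = ibs_matrix(sim_gm.subset_snps(perm))
        assert np.allclose(m1.values, m2.values, atol=1e-12)

    def test_kinship_diagonal_is_half_one_plus_F(self, sim_gm):
        from parallgwa.ind_stats import homozygosity

        m = ibs_matrix(sim_gm, weight="freq")
        F = homozygosity(sim_gm)["F"].to_numpy()
        assert np.allclose(np.diag(m.values), 0.5 * (1 + F), atol=1e-12)


class TestEMHaplotypeFreqs:
    def test_no_double_heterozygotes_closed_form(self):
        counts = np.array([[10, 4, 1], [6, 0, 2], [2, 3, 8]], dtype=float)
        f = em_haplotype_freqs(counts)
        total2 = 2 * counts.sum()
        want_AB = (2 * 10 + 4 + 6) / total2
        want_Ab = (2 * 1 + 4 + 2) / total2
        want_aB = (2 * 2 + 3 + 6) / total2
        want_ab = (2 * 8 + 3 + 2) / total2
        assert f.f_AB == pytest.approx(want_AB, abs=1e-12)
        assert f.f_Ab == pytest.approx(want_Ab, abs=1e-12)
        assert f.f_aB == pytest.approx(want_aB, abs=1e-12)
        assert f.f_ab == pytest.approx(want_ab, abs=1e-12)

    def test_duplicated_locus_complete_ld(self):
        g = np.array([0, 0, 1, 1, 2, 2, 1, 0], dtype=np.int8)
        counts = np.zeros((3, 3))
        for c in g:
            counts[c, c] += 1
        f = em_haplotype_freqs(counts)
        assert f.f_AB + f.f_ab == pytest.approx(1.0, abs=1e-9)
        assert f.f_Ab == pytest.approx(0.0, abs=1e-9)
        assert f.f_aB == pytest.approx(0.0, abs=1e-9)

    def test_loglik_beats_constrained_grid(self):
        # EM solution must dominate a fine 1-D grid over the free haplotype
        # frequency (margins are fixed at the observed allele frequencies,
        # which the EM preserves exactly)
        rng = np.random.default_rng(77)
        for _ in range(15):
            counts = random_count_table(rng)
            try:
                f = em_haplotype_freqs(counts)
            except ParameterError:
                continue  # monomorphic draw
            fv = np.array([f.f_AB, f.f_Ab, f.f_aB, f.f_ab])
            pA = fv[0] + fv[1]
            pB = fv[0] + fv[2]
            ll_em = table_loglik(counts, fv)
            lo = max(0.0, pA + pB - 1.0)
            hi = min(pA, pB)
            grid = np.arange(lo, hi + 1e-12, 0.001)
            for fab in grid:
                cand = np.array([fab, pA - fab, pB - fab, 1 - pA - pB + fab])
                if cand.min() < 0:
                    continue
                assert ll_em + 1e-9 >= table_loglik(counts, cand)

    def test_loglik_beats_coarse_full_simplex_grid(self):
        rng = np.random.default_rng(78)
        counts = random_count_table(rng, n=200)
        f = em_haplotype_freqs(counts)
        fv = np.array([f.f_AB, f.f_Ab, f.f_aB, f.f_ab])
        ll_em = table_loglik(counts, fv)
        step = 0.05
        vals = np.arange(step, 1.0, step)
        for a in vals:
            for b in vals:
                for c in vals:
                    d = 1.0 - a - b - c
                    if d <= 0:
                        continue
                    assert ll_em + 1e-9 >= table_loglik(counts, np.array([a, b, c, d]))

    def test_expected_table_is_a_distribution(self):
        rng = np.random.default_rng(79)
        counts = random_count_table(rng)
        f = em_haplotype_freqs(counts)
        P = genotype_pair_probs([f.f_AB, f.f_Ab, f.f_aB, f.f_ab])
        # reconstructed expected counts sum to the observed total
        assert (P * counts.sum()).sum() == pytest.approx(counts.sum(), abs=1e-9)

    def test_monomorphic_rejected(self):
        counts = np.zeros((3, 3))
        counts[0, 0] = 5
        counts[0, 2] = 5
        with pytest.raises(ParameterError):
            em_haplotype_freqs(counts)


class TestLDPair:
    def test_duplicated_snp_perfect_ld(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=np.int8)
        res = ld_pair(g, g.copy())
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.Dprime == pytest.approx(1.0, abs=1e-9)
        assert res.rho == pytest.approx(1.0, abs=1e-12)

    def test_product_table_gives_zero_d(self):
        # counts that factorize exactly as independent HWE loci: the EM
        # fixed point is the product distribution, so D = r2 = D' = 0
        hw = np.array([0.25, 0.5, 0.25])
        counts = 64 * np.outer(hw, hw)
        f = em_haplotype_freqs(counts)
        from parallgwa.pairwise_stats import ld_from_freqs

        D, dprime, r2 = ld_from_freqs(f)
        assert D == pytest.approx(0.0, abs=1e-9)
        assert dprime == pytest.approx(0.0, abs=1e-6)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_phase_unambiguous_r2_equals_haplotype_count_r2(self):
        # no double heterozygotes: haplotypes are countable directly
        rng = np.random.default_rng(91)
        h_a = rng.integers(0, 2, size=200)
        h_b = np.where(rng.random(200) < 0.8, h_a, rng.integers(0, 2, size=200))
        # build individuals from identical gamete pairs -> g in {0,2}
        g1 = (2 * h_a).astype(np.int8)
        g2 = (2 * h_b).astype(np.int8)
        res = ld_pair(g1, g2)
        r_hap = np.corrcoef(np.repeat(h_a, 2), np.repeat(h_b, 2))[0, 1]
        assert res.r2 == pytest.approx(r_hap**2, abs=1e-9)

    def test_monomorphic_flagged(self):
        g1 = np.zeros(20, dtype=np.int8)
        g2 = np.array([0, 1, 2, 1] * 5, dtype=np.int8)
        res = ld_pair(g1, g2)
        assert res.is_flagged and res.n == 20

    def test_rho_is_genotype_correlation(self):
        rng = np.random.default_rng(92)
        g1 = rng.choice([0, 1, 2], size=100).astype(np.int8)
        g2 = rng.choice([0, 1, 2], size=100).astype(np.int8)
        res = ld_pair(g1, g2)
        assert res.rho == pytest.approx(np.corrcoef(g1, g2)[0, 1], abs=1e-12)
        assert res.rho**2 <= 1.0


class TestLDMatrix:
    def test_equals_pairwise_loop(self):
        G = simulate_genotypes(
            SimSpec(n_ind=60, n_snp=30, mafs=0.3, ld_rho=0.5, missing_rate=0.05, seed=44)
        )
        mats = ld_matrix(G, min_shared=5)
        for a in range(0, 30, 7):
            for b in range(a, 30, 5):
                res = ld_pair(G.codes[:, a], G.codes[:, b])
                if res.n >= 5 and not res.is_flagged:
                    assert mats["r2"].values[a, b] == pytest.approx(res.r2, abs=1e-12)
                    assert mats["dprime"].values[a, b] == pytest.approx(res.Dprime, abs=1e-12)
                    assert mats["rho"].values[a, b] == pytest.approx(res.rho, abs=1e-12)

    def test_symmetric(self):
        G = simulate_genotypes(SimSpec(n_ind=50, n_snp=12, mafs=0.4, seed=45))
        m = ld_matrix(G)["r2"].values
        assert np.array_equal(m, m.T)

    def test_window_excludes_distant_pairs(self):
        # SNPs are 1000 bp apart; a 500 bp window leaves only the diagonal
        G = simulate_genotypes(SimSpec(n_ind=80, n_snp=6, mafs=0.4, seed=46))
        m = ld_matrix(G, max_bp_window=500)["r2"].values
        off = m[np.triu_indices(6, k=1)]
        assert np.all(np.isnan(off))
        # self-pair LD stays defined (EM may stop a hair under exactly 1)
        assert np.allclose(np.diag(m), 1.0, atol=1e-9)

    def test_min_shared_floor_flags_pairs(self):
        G = simulate_genotypes(
            SimSpec(n_ind=12, n_snp=8, mafs=0.4, missing_rate=0.4, seed=47)
        )
        m = ld_matrix(G, min_shared=12)
        assert np.all(np.isnan(m["r2"].values))

    def test_empty_subset_rejected(self):
        G = simulate_genotypes(SimSpec(n_ind=10, n_snp=5, mafs=0.3, seed=48))
        with pytest.raises((EmptyDataError, ParameterError)):
            ld_matrix(G, snp_subset=[0])
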