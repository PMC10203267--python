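"""Windowed statistics against independently coded oracles and hand-worked
examples: π, Tajima's D, Weir-Cockerham Fst, folded SFS, LD, and the
sex-association / female-specific-SNP detectors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from zwscan.genotypes import MISSING
from zwscan.intervals import GenomicInterval
from zwscan.popgen_core import (
    female_specific_snps,
    filter_variants,
    folded_sfs,
    fst_weir_cockerham,
    fst_weir_cockerham_sites,
    ld_half_decay,
    ld_r2,
    nucleotide_diversity,
    sex_association,
    tajima_constants,
    tajimas_d,
)
from zwscan.synthetic_data import _assign_exact, _folded_spectrum_counts
from tests.conftest import make_gm


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pi_bruteforce(dosage_col: np.ndarray) -> float:
    """π at one site by direct double loop over all allele pairs."""
    alleles = []
    for d in dosage_col:
        if d == MISSING:
            continue
        alleles += [1] * int(d) + [0] * (2 - int(d))
    n = len(alleles)
    if n < 2:
        return 0.0
    diff = sum(
        alleles[i] != alleles[j] for i in range(n) for j in range(i + 1, n)
    )
    return diff / (n * (n - 1) / 2)


def wc_fst_formula(n1, n2, p1, p2, h1, h2):
    """Scalar Weir & Cockerham (1984) two-population estimator, coded
    directly from the published component formulas."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def tajima_d_oracle(n: int, S: int, pi_sum: float) -> float:
    """Tajima's D from the 1989 constants, recomputed from scratch."""
    i = np.arange(1, n)
    a1 = (1 / i).sum()
    a2 = (1 / i**2).sum()
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilterVariants:
    def _toy(self):
        # 10 sites over 20 diploids; 4 sites each violating one distinct rule
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 2, size=(20, 10)).astype(np.int8)
        dosage[:10, :] = 1  # every site has MAF >= ~0.25
        dp = np.full(10, 20.0)
        qual = np.full(10, 50.0)
        dp[0] = 1.0          # DP < 2
        dp[1] = 41.0         # DP > 40
        qual[2] = 10.0       # quality < 20
        dosage[0:5, 3] = MISSING  # 25% missing > 20%
        return make_gm(dosage, dp=dp, qual=qual)

    def test_toy_counts(self):
        gm = filter_variants(self._toy())
        assert gm.n_sites == 6

    def test_identity_when_all_pass(self):
        gm = make_gm(np.ones((20, 5), dtype=np.int8))
        out = filter_variants(gm)
        assert out.n_sites == 5

    def test_maf_exactly_at_threshold_retained(self):
        # 20 diploids, ac = 2 of 40 alleles -> MAF exactly 0.05
        dosage = np.zeros((20, 1), dtype=np.int8)
        dosage[0, 0] = 1
        dosage[1, 0] = 1
        assert filter_variants(make_gm(dosage)).n_sites == 1
        # one copy fewer -> MAF 0.025 < 5% -> removed, leaving nothing
        dosage[1, 0] = 0
        with pytest.raises(ValueError):
            # removing the only site means the next call sees nothing; the
            # filter itself returns an empty matrix
            filter_variants(filter_variants(make_gm(dosage)))

    def test_idempotent(self):
        gm = self._toy()
        once = filter_variants(gm)
        twice = filter_variants(once)
        assert np.array_equal(once.dosage, twice.dosage)

    def test_empty_matrix_rejected(self):
        gm = make_gm(np.ones((4, 1), dtype=np.int8))
        empty = gm.take_sites(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            filter_variants(empty)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

class TestPi:
    def test_single_site_unbiased_estimator(self):
        # allele counts 2/2 among n = 4 alleles -> per-site pi = 2/3
        gm = make_gm([[1], [1]], pos=[1])
        df = nucleotide_diversity(gm, {"chr1": 1}, window=1, step=1)
        assert df.value.iloc[0] == pytest.approx(2 / 3, abs=1e-12)

    def test_monomorphic_window_zero(self):
        gm = make_gm(np.full((4, 5), 2, dtype=np.int8))
        df = nucleotide_diversity(gm, {"chr1": 1000}, window=1000, step=1000)
        assert df.value.iloc[0] == 0.0

    def test_two_haplotypes_three_diffs(self):
        # one diploid heterozygous at 3 of 1000 positions: pi = 0.003
        dosage = np.zeros((1, 3), dtype=np.int8) + 1
        gm = make_gm(
            np.vstack([dosage]), pos=[10, 20, 30]
        )
        df = nucleotide_diversity(
            gm, {"chr1": 1000}, window=1000, step=1000
        )
        assert df.value.iloc[0] == pytest.approx(0.003, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        dosage = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.1] = MISSING
        pos = np.sort(rng.choice(np.arange(1, 5001), 40, replace=False))
        gm = make_gm(dosage, pos=pos)
        df = nucleotide_diversity(gm, {"chr1": 5000}, window=5000, step=5000)
        expected = sum(pi_bruteforce(dosage[:, j]) for j in range(40)) / 5000
        assert df.value.iloc[0] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

class TestTajimasD:
    def test_hand_computed_constants(self):
        c = tajima_constants(4)
        assert c["a1"] == pytest.approx(1.8333, abs=1e-4)
        assert c["e1"] == pytest.approx(0.005510, abs=5e-6)

    def test_n4_single_site_balanced(self):
        # n=4 alleles, S=1, allele counts 2/2 -> D = 1.63
        gm = make_gm([[1], [1]], pos=[100])
        df = tajimas_d(gm, {"chr1": 1000}, window=1000, step=1000)
        assert df.value.iloc[0] == pytest.approx(1.63, abs=0.01)

    def test_zero_when_pi_equals_theta(self):
        # with S=1 and pi contribution exactly 1/a1 the numerator vanishes;
        # engineered via n=2 alleles is excluded (needs n>=4), so check the
        # formula directly through the oracle instead
        n, S = 10, 3
        pi_sum = S / tajima_constants(n)["a1"]
        assert tajima_d_oracle(n, S, pi_sum) == pytest.approx(0.0, abs=1e-12)

    def test_excess_singletons_negative(self):
        # 20 sites, each a singleton among 10 diploids -> D < 0
        dosage = np.zeros((10, 20), dtype=np.int8)
        dosage[0, :] = 1
        gm = make_gm(dosage, pos=np.arange(1, 21) * 10)
        df = tajimas_d(gm, {"chr1": 1000}, window=1000, step=1000)
        assert df.value.iloc[0] < 0

    def test_no_segregating_sites_is_na(self):
        gm = make_gm(np.full((4, 3), 2, dtype=np.int8))
        df = tajimas_d(gm, {"chr1": 1000}, window=1000, step=1000)
        assert np.isnan(df.value.iloc[0])

    def test_matches_oracle_on_random_toys(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_dip = int(rng.integers(2, 12))
            n_sites = int(rng.integers(1, 30))
            dosage = rng.integers(0, 3, size=(n_dip, n_sites)).astype(np.int8)
            gm = make_gm(dosage, pos=np.arange(1, n_sites + 1) * 7)
            df = tajimas_d(gm, {"chr1": 1000}, window=1000, step=1000)
            n = 2 * n_dip
            ac = dosage.sum(axis=0)
            seg = (ac > 0) & (ac < n)
            S = int(seg.sum())
            if S == 0:
                assert np.isnan(df.value.iloc[0])
                continue
            p = ac[seg] / n
            pi_sum = (2 * p * (1 - p) * n / (n - 1)).sum()
            assert df.value.iloc[0] == pytest.approx(
                tajima_d_oracle(n, S, pi_sum), abs=1e-10
            )


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

class TestFst:
    def test_fixed_difference_gives_one(self):
        dosage = np.array([[2]] * 5 + [[0]] * 5, dtype=np.int8)
        gm = make_gm(dosage, pos=[100])
        a = np.arange(10) < 5
        df = fst_weir_cockerham(gm, a, ~a, {"chr1": 1000}, 1000, 1000)
        assert df.value.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_frequencies_not_positive(self):
        dosage = np.array([[1]] * 10, dtype=np.int8)
        gm = make_gm(dosage, pos=[100])
        a = np.arange(10) < 5
        df = fst_weir_cockerham(gm, a, ~a, {"chr1": 1000}, 1000, 1000)
        assert df.value.iloc[0] <= 0

    def test_formula_value_at_published_example(self):
        # n1=n2=10 diploids, p1=0.8, p2=0.2, observed het 0.32 -> 0.5033
        assert wc_fst_formula(10, 10, 0.8, 0.2, 0.32, 0.32) == pytest.approx(
            0.5033, abs=2e-4
        )

    def test_matches_formula_oracle_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 10)), int(rng.integers(2, 10))
            d1 = rng.integers(0, 3, size=(n1, 1)).astype(np.int8)
            d2 = rng.integers(0, 3, size=(n2, 1)).astype(np.int8)
            p1, p2 = d1.mean() / 2, d2.mean() / 2
            h1, h2 = (d1 == 1).mean(), (d2 == 1).mean()
            if p1 == p2 == 0 or p1 == p2 == 1:
                continue
            gm = make_gm(np.vstack([d1, d2]), pos=[50])
            mask = np.arange(n1 + n2) < n1
            df = fst_weir_cockerham(gm, mask, ~mask, {"chr1": 100}, 100, 100)
            expected = wc_fst_formula(n1, n2, p1, p2, h1, h2)
            assert df.value.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_all_missing_group_window_is_na(self):
        dosage = np.array([[1], [1], [MISSING], [MISSING]], dtype=np.int8)
        gm = make_gm(dosage, pos=[100])
        a = np.array([True, True, False, False])
        df = fst_weir_cockerham(gm, a, ~a, {"chr1": 1000}, 1000, 1000)
        assert np.isnan(df.value.iloc[0])


# ---------------------------------------------------------------------------
# folded SFS
# ---------------------------------------------------------------------------

class TestFoldedSfs:
    def test_minor_count_class(self):
        # 4 diploids = 8 alleles; alt count 3 -> class 3
        dosage = np.array([[2], [1], [0], [0]], dtype=np.int8)
        sfs = folded_sfs(make_gm(dosage))
        assert sfs.tolist() == [0, 0, 1, 0]

    def test_folding_high_count(self):
        # alt count 6 of 8 folds to class 2
        dosage = np.array([[2], [2], [2], [0]], dtype=np.int8)
        sfs = folded_sfs(make_gm(dosage))
        assert sfs.tolist() == [0, 1, 0, 0]

    def test_monomorphic_only_is_zero_vector(self):
        sfs = folded_sfs(make_gm(np.zeros((4, 3), dtype=np.int8)))
        assert sfs.sum() == 0

    def test_neutral_spectrum_goodness_of_fit(self):
        # exact-count assignment from the folded neutral spectrum must pass
        # a chi-square GOF against eta_k ∝ 1/k + 1/(n-k)
        rng = np.random.default_rng(5)
        n_dip, n_sites = 20, 20_000
        n = 2 * n_dip
        k = _folded_spectrum_counts(rng, n, n_sites)
        slots = _assign_exact(rng, n, k)
        dosage = (slots[:, ::2].astype(np.int8) + slots[:, 1::2].astype(np.int8)).T
        gm = make_gm(dosage, pos=np.arange(1, n_sites + 1))
        sfs = folded_sfs(gm)
        ks = np.arange(1, n // 2 + 1)
        w = 1 / ks + 1 / (n - ks)
        w[ks == n - ks] /= 2
        expected = sfs.sum() * w / w.sum()
        stat = ((sfs - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(stat, df=len(ks) - 1)
        assert p > 0.01


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

class TestLd:
    def test_duplicated_site_r2_one(self):
        dosage = np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8)
        df = ld_r2(make_gm(dosage, pos=[100, 200]), max_dist=1000)
        assert df.r2.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_repulsion_phase_r2_one(self):
        x = np.array([0, 1, 2, 1, 0])
        dosage = np.stack([x, 2 - x], axis=1).astype(np.int8)
        df = ld_r2(make_gm(dosage, pos=[100, 200]), max_dist=1000)
        assert df.r2.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_sites_sampling_bias(self):
        # E[r²] between independent sites ≈ 1/n
        rng = np.random.default_rng(9)
        n = 200
        dosage = rng.binomial(2, 0.4, size=(n, 60)).astype(np.int8)
        df = ld_r2(make_gm(dosage, pos=np.arange(1, 61) * 10), max_dist=1000)
        assert 0.5 / n < df.r2.mean() < 2.0 / n

    def test_half_decay_exponential_closed_form(self):
        # r²(d) = exp(-d / 10 kb) halves at 10·ln2 ≈ 6.93 kb; distances start
        # near zero so the maximum bin sits at the curve's origin
        d = np.arange(10, 30_000, 20)
        df = pd.DataFrame({"chrom": "c", "pos1": 0, "pos2": d, "dist": d,
                           "r2": np.exp(-d / 10_000)})
        est = ld_half_decay(df, bin_size=100)
        assert est == pytest.approx(6_931, rel=0.02)

    def test_half_decay_scale_invariant(self):
        d = np.arange(100, 30_000, 50)
        base = pd.DataFrame({"chrom": "c", "pos1": 0, "pos2": d, "dist": d,
                             "r2": np.exp(-d / 10_000)})
        scaled = base.assign(r2=base.r2 * 0.37)
        assert ld_half_decay(base, 100) == pytest.approx(
            ld_half_decay(scaled, 100), abs=1e-9
        )

    def test_constant_r2_is_na(self):
        d = np.arange(100, 10_000, 100)
        df = pd.DataFrame({"chrom": "c", "pos1": 0, "pos2": d, "dist": d,
                           "r2": 0.4})
        with pytest.warns(UserWarning):
            assert np.isnan(ld_half_decay(df, 100))


# ---------------------------------------------------------------------------
# sex association
# ---------------------------------------------------------------------------

class TestSexAssociation:
    def _panel(self, dosage):
        n = dosage.shape[0]
        sex = ["F"] * (n // 2) + ["M"] * (n - n // 2)
        return make_gm(dosage, sex=sex)

    def test_fully_penetrant_w_site_chi2(self):
        # allele counts 22/44 in F vs 0/44 in M -> chi2 = 29.33
        dosage = np.array([[1]] * 22 + [[0]] * 22, dtype=np.int8)
        df = sex_association(self._panel(dosage))
        assert df.chi2.iloc[0] == pytest.approx(29.33, abs=0.01)

    def test_balanced_site_near_zero(self):
        dosage = np.array([[1]] * 44, dtype=np.int8)
        df = sex_association(self._panel(dosage))
        assert df.chi2.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        gm = self._panel(dosage)
        swapped = make_gm(
            dosage, sex=["M"] * 10 + ["F"] * 10
        )
        a = sex_association(gm)
        b = sex_association(swapped)
        assert np.allclose(a.chi2, b.chi2)

    def test_monomorphic_site_zero(self):
        dosage = np.zeros((10, 1), dtype=np.int8)
        df = sex_association(self._panel(dosage))
        assert df.chi2.iloc[0] == 0.0

    def test_type_one_error_calibration(self):
        # under the null (allele independent of sex), P(p < 1e-3) must be
        # within 3 standard errors of 1e-3
        rng = np.random.default_rng(12)
        n_sites, n_dip = 60_000, 22 + 22
        k = _folded_spectrum_counts(rng, 2 * n_dip, n_sites)
        slots = _assign_exact(rng, 2 * n_dip, k)
        dosage = (slots[:, ::2].astype(np.int8) + slots[:, 1::2].astype(np.int8)).T
        df = sex_association(self._panel(dosage))
        alpha = 1e-3
        rate = (df.neg_log10_p >= 3).mean()
        se = np.sqrt(alpha * (1 - alpha) / n_sites)
        # the chi-square is conservative for rare alleles, so bound above
        assert rate < alpha + 3 * se


# ---------------------------------------------------------------------------
# female-specific SNPs
# ---------------------------------------------------------------------------

class TestFemaleSpecific:
    def test_planted_sites_all_flagged(self):
        dosage = np.vstack(
            [np.ones((22, 15), dtype=np.int8), np.zeros((22, 15), dtype=np.int8)]
        )
        gm = make_gm(dosage, sex=["F"] * 22 + ["M"] * 22,
                     pos=np.arange(1, 16) * 50_000)
        flagged, blocks = female_specific_snps(gm)
        assert len(flagged) == 15
        assert len(blocks) == 1
        assert blocks[0] == GenomicInterval("chr1", 50_000, 750_000)

    def test_autosomal_null_rarely_flagged(self):
        rng = np.random.default_rng(21)
        n_sites = 5_000
        k = _folded_spectrum_counts(rng, 88, n_sites)
        slots = _assign_exact(rng, 88, k)
        dosage = (slots[:, ::2].astype(np.int8) + slots[:, 1::2].astype(np.int8)).T
        gm = make_gm(dosage, sex=["F"] * 22 + ["M"] * 22,
                     pos=np.arange(1, n_sites + 1) * 10)
        flagged, _ = female_specific_snps(gm)
        assert len(flagged) / n_sites < 1e-3

    def test_block_rule_spacing(self):
        # 12 flagged sites spaced 50 kb -> one block spanning them
        dosage = np.vstack(
            [np.ones((10, 12), dtype=np.int8), np.zeros((10, 12), dtype=np.int8)]
        )
        gm = make_gm(dosage, sex=["F"] * 10 + ["M"] * 10,
                     pos=np.arange(12) * 50_000 + 1)
        _, blocks = female_specific_snps(gm)
        assert len(blocks) == 1
        assert blocks[0].start == 1 and blocks[0].end == 11 * 50_000 + 1
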