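"""Diversity/differentiation estimators against brute-force oracles."""

import itertools

import numpy as np
import pytest

from ploidyscan import popgen_stats as pg
from ploidyscan import variants_io as vio
from ploidyscan.variants_io import MISSING

from conftest import make_gm


class TestNucleotideDiversity:
    def test_single_difference_two_chromosomes(self):
        assert pg.nucleotide_diversity([1], [2], 1000) == pytest.approx(0.001)

    def test_monomorphic_is_zero(self):
        assert pg.nucleotide_diversity([0, 0, 0], [8, 8, 8], 100) == 0.0

    def test_matches_pairwise_hamming_oracle(self):
        # n=8 chromosomes, k=3 derived at one site, 100-bp window: compare
        # against the mean pairwise difference over all C(8,2) haplotype pairs
        haplotypes = [1, 1, 1, 0, 0, 0, 0, 0]
        pairs = list(itertools.combinations(haplotypes, 2))
        mean_diff = sum(a != b for a, b in pairs) / len(pairs)
        assert pg.nucleotide_diversity([3], [8], 100) == pytest.approx(mean_diff / 100)

    def test_multisite_window_oracle(self):
        rng = np.random.default_rng(0)
        hap = rng.integers(0, 2, size=(12, 30))  # 12 haplotypes, 30 SNPs in 500 bp
        k = hap.sum(axis=0)
        total = 0.0
        n_pairs = 0
        for a, b in itertools.combinations(range(12), 2):
            total += (hap[a] != hap[b]).sum()
            n_pairs += 1
        assert pg.nucleotide_diversity(k, np.full(30, 12), 500) == pytest.approx(
            total / n_pairs / 500
        )

    def test_sites_below_two_chromosomes_skipped(self):
        assert pg.nucleotide_diversity([1, 1], [2, 1], 100) == pytest.approx(
            pg.nucleotide_diversity([1], [2], 100)
        )


class TestTajimasD:
    def test_excess_singletons_negative(self):
        n, S = 6, 5
        pi_sum = S * 2 * 1 * (n - 1) / (n * (n - 1))
        assert pg.tajimas_d(S, pi_sum, n) < 0

    def test_constructed_zero(self):
        n, S = 10, 16
        a1 = sum(1 / i for i in range(1, n))
        assert pg.tajimas_d(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)

    def test_formula_oracle(self):
        # frozen value from an independent evaluation of the 1989 constants
        assert pg.tajimas_d(16, 3.888, 10) == pytest.approx(-1.4468996210899197)

    def test_no_segregating_sites_undefined(self):
        assert np.isnan(pg.tajimas_d(0, 0.0, 10))

    def test_small_n_fatal(self):
        with pytest.raises(ValueError):
            pg.tajima_constants(3)


def wc_oracle(kA, nA, kB, nB):
    """Brute-force one-way ANOVA on explicit 0/1 allele copies."""
    copies = [1] * kA + [0] * (nA - kA) + [1] * kB + [0] * (nB - kB)
    groups = [0] * nA + [1] * nB
    copies = np.array(copies, float)
    groups = np.array(groups)
    grand = copies.mean()
    msa = sum(
        (groups == g).sum() * (copies[groups == g].mean() - grand) ** 2 for g in (0, 1)
    )
    msw = sum(((copies[groups == g] - copies[groups == g].mean()) ** 2).sum() for g in (0, 1)) / (
        nA + nB - 2
    )
    N = nA + nB
    nc = N - (nA**2 + nB**2) / N
    a = (msa - msw) / nc
    return a, a + msw


class TestWcFst:
    def test_equal_frequencies_reported_zero(self):
        num, den, fst = pg.wc_fst([5], [10], [5], [10])
        assert num[0] <= 0
        assert max(fst, 0.0) == 0.0

    def test_fixed_difference_is_one(self):
        assert pg.wc_fst([0], [10], [10], [10])[2] == pytest.approx(1.0)

    @pytest.mark.parametrize("kA,nA,kB,nB", [(2, 10, 8, 10), (1, 6, 9, 12), (0, 8, 3, 10)])
    def test_matches_anova_oracle(self, kA, nA, kB, nB):
        num, den, _ = pg.wc_fst([kA], [nA], [kB], [nB])
        a, total = wc_oracle(kA, nA, kB, nB)
        assert num[0] == pytest.approx(a)
        assert den[0] == pytest.approx(total)

    def test_empty_population_gives_nan(self):
        num, den, fst = pg.wc_fst([0], [0], [5], [10])
        assert np.isnan(num[0]) and np.isnan(fst)


def rho_oracle(dosA, dosB, pA, pB):
    """Identity-probability Rho from explicit between-individual pairs."""
    yA = [d / pA for d in dosA if d != MISSING]
    yB = [d / pB for d in dosB if d != MISSING]

    def hw(ys):
        # ordered pairs double-count each unordered pair, so the plain mean
        # of P(two copies differ) over ordered pairs is the pair average
        pairs = [(a, b) for i, a in enumerate(ys) for j, b in enumerate(ys) if i != j]
        return sum(a * (1 - b) + b * (1 - a) for a, b in pairs) / len(pairs)

    h_w = (hw(yA) + hw(yB)) / 2
    pa, pb = np.mean(yA), np.mean(yB)
    h_b = pa * (1 - pb) + pb * (1 - pa)
    return h_b - h_w, h_b


class TestRho:
    def test_identical_populations_reported_zero(self):
        dos = np.array([[1, 1, 0, 2, 1, 1, 0, 2]], dtype=np.int16)
        num, den, value = pg.rho(dos[:, :4], dos[:, 4:], 2, 2)
        assert max(value, 0.0) == pytest.approx(0.0)

    def test_fixed_alternative_homozygotes_is_one(self):
        a = np.full((1, 5), 2, dtype=np.int16)
        b = np.zeros((1, 5), dtype=np.int16)
        assert pg.rho(a, b, 2, 2)[2] == pytest.approx(1.0)
        a4 = np.full((1, 5), 4, dtype=np.int16)
        b4 = np.zeros((1, 5), dtype=np.int16)
        assert pg.rho(a4, b4, 4, 4)[2] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "dosA,dosB,pA,pB",
        [
            ([1, 2, 0, 1], [2, 2, 1, 0], 2, 2),
            ([3, 1, 4, 0], [0, 1, 2, 1], 4, 4),
            ([1, 0, 2, MISSING], [3, 4, 1, 2], 2, 4),
        ],
    )
    def test_matches_pairwise_identity_oracle(self, dosA, dosB, pA, pB):
        num, den = pg.rho_components(
            np.array([dosA], dtype=np.int16), np.array([dosB], dtype=np.int16), pA, pB
        )
        o_num, o_den = rho_oracle(dosA, dosB, pA, pB)
        assert num[0] == pytest.approx(o_num)
        assert den[0] == pytest.approx(o_den)

    def test_single_individual_population_dropped(self):
        a = np.array([[2, MISSING, MISSING]], dtype=np.int16)
        b = np.array([[0, 0, 0]], dtype=np.int16)
        num, den = pg.rho_components(a, b, 2, 2)
        assert np.isnan(num[0])

    def test_ploidy_comparability_small(self):
        """Diploid and tetraploid pairs with identical population-frequency
        divergence give matching windowed Rho despite different raw
        heterozygosity."""
        rng = np.random.default_rng(3)
        n_snps, n_ind = 4000, 8
        pa = rng.beta(2, 2, n_snps)
        delta = rng.beta(8, 8, n_snps)  # shared divergence pattern
        pb = np.clip(pa + (delta - 0.5) * 0.5, 0, 1)
        dos2a = rng.binomial(2, pa[:, None], (n_snps, n_ind)).astype(np.int16)
        dos2b = rng.binomial(2, pb[:, None], (n_snps, n_ind)).astype(np.int16)
        dos4a = rng.binomial(4, pa[:, None], (n_snps, n_ind)).astype(np.int16)
        dos4b = rng.binomial(4, pb[:, None], (n_snps, n_ind)).astype(np.int16)
        r2 = pg.rho(dos2a, dos2b, 2, 2)[2]
        r4 = pg.rho(dos4a, dos4b, 4, 4)[2]
        assert r2 == pytest.approx(r4, abs=0.02)
        het2 = np.mean(dos2a == 1)
        het4 = np.mean((dos4a > 0) & (dos4a < 4))
        assert het4 > het2  # raw heterozygosity differs while Rho agrees


class TestDownsample:
    def test_population_of_exactly_four_is_identity(self):
        dosage = np.array([[1, 2, 0, 1]], dtype=np.int16)
        gm = make_gm(dosage, [2] * 4, ["p1"] * 4)
        out = pg.downsample_individuals(gm, 4, seed=0)
        assert np.array_equal(out.dosage, dosage)

    def test_undersized_population_dropped_at_site(self):
        dosage = np.array([[1, 2, MISSING]], dtype=np.int16)
        gm = make_gm(dosage, [2] * 3, ["p1"] * 3)
        out = pg.downsample_individuals(gm, 3, seed=0)
        assert (out.dosage[0] == MISSING).all()

    def test_twelve_chromosomes_from_six_diploids_exhaustive(self):
        dosage = np.array([[1, 2, 0, 1, 1, 2]], dtype=np.int16)
        gm = make_gm(dosage, [2] * 6, ["p1"] * 6)
        freqs = vio.population_frequencies(gm)
        down = pg.downsample_chromosomes(freqs, 12, seed=0)
        assert down.freq[0, 0] == pytest.approx(7 / 12)
        assert down.chroms[0, 0] == 12

    def test_chromosome_draw_unbiased(self):
        dosage = np.array([[2, 1, 1, 0, 2, 1, 0, 1]], dtype=np.int16)
        gm = make_gm(dosage, [2] * 8, ["p1"] * 8)
        freqs = vio.population_frequencies(gm)
        p_true = freqs.freq[0, 0]
        draws = np.array(
            [pg.downsample_chromosomes(freqs, 12, seed=s).freq[0, 0] for s in range(400)]
        )
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - p_true) < 3 * se

    def test_both_modes_requested_fatal(self):
        with pytest.raises(ValueError):
            pg.downsample(n_individuals=4, n_chromosomes=12)


def test_window_statistics_invariant_to_site_order():
    rng = np.random.default_rng(5)
    num = rng.normal(size=50)
    den = np.abs(rng.normal(size=50)) + 0.1
    widx = rng.integers(0, 5, size=50)
    base = pg.window_ratio_of_sums(num, den, widx, 5)
    perm = rng.permutation(50)
    shuffled = pg.window_ratio_of_sums(num[perm], den[perm], widx[perm], 5)
    np.testing.assert_allclose(base, shuffled)


def test_fst_and_rho_coincide_for_random_mating_diploids():
    """For diploids under Hardy-Weinberg sampling the allele-count F_ST and
    the between-individual Rho estimate the same quantity."""
    rng = np.random.default_rng(9)
    n_snps, n_ind = 6000, 10
    pa = rng.beta(1, 1, n_snps)
    pb = np.clip(pa + rng.normal(0, 0.15, n_snps), 0, 1)
    dosA = rng.binomial(2, pa[:, None], (n_snps, n_ind)).astype(np.int16)
    dosB = rng.binomial(2, pb[:, None], (n_snps, n_ind)).astype(np.int16)
    kA, kB = dosA.sum(axis=1), dosB.sum(axis=1)
    n = np.full(n_snps, 2 * n_ind)
    fst = pg.wc_fst(kA, n, kB, n)[2]
    r = pg.rho(dosA, dosB, 2, 2)[2]
    assert fst == pytest.approx(r, abs=0.02)
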