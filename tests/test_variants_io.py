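"""VCF parsing, site filters, paralog/depth masks and polarization."""

import numpy as np
import pandas as pd
import pytest

from ploidyscan import variants_io as vio
from ploidyscan.variants_io import MISSING

from conftest import make_gm

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=s1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tdip1\ttet1
s1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP\t0/1:20\t0/0/0/1:22
s1\t200\t.\tC\tG\t.\tPASS\t.\tGT:DP\t./.:5\t./0/0/1:9
s1\t300\t.\tG\tA,C\t.\tPASS\t.\tGT:DP\t0/1:20\t0/0/1/2:20
s1\t400\t.\tT\tC\t.\tPASS\t.\tGT:DP\t1/1:31\t1/1/1/1:28
"""


@pytest.fixture()
def two_sample_table():
    return pd.DataFrame(
        {
            "sample_id": ["dip1", "tet1"],
            "population": ["p1", "p2"],
            "ploidy": [2, 4],
            "lineage": ["L1", "L2"],
        }
    )


def test_mixed_ploidy_gt_parsing(tmp_path, two_sample_table):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TEXT)
    gm = vio.read_vcf(path, two_sample_table)
    # multi-allelic record at pos 300 dropped
    assert gm.sites["pos"].tolist() == [100, 200, 400]
    assert gm.log["multiallelic_dropped"] == 1
    assert gm.dosage[0].tolist() == [1, 1]  # 0/1 and 0/0/0/1
    assert gm.dosage[1].tolist() == [MISSING, MISSING]  # ./., half-call
    assert gm.dosage[2].tolist() == [2, 4]
    assert gm.depth[0].tolist() == [20, 22]


def test_gt_arity_mismatch_is_reported(tmp_path, two_sample_table):
    bad = VCF_TEXT.replace("0/0/0/1", "0/1")
    path = tmp_path / "bad.vcf"
    path.write_text(bad)
    with pytest.raises(ValueError, match="tet1"):
        vio.read_vcf(path, two_sample_table)


def test_missing_sample_metadata_fatal(tmp_path, two_sample_table):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TEXT)
    with pytest.raises(ValueError, match="tet1"):
        vio.read_vcf(path, two_sample_table.iloc[:1])


def test_sample_table_invariants():
    bad = pd.DataFrame(
        {
            "sample_id": ["a", "b"],
            "population": ["p", "p"],
            "ploidy": [2, 4],  # mixed ploidy in one population
            "lineage": ["L1", "L1"],
        }
    )
    with pytest.raises(ValueError, match="ploidy"):
        vio.validate_sample_table(bad)


class TestFilterSites:
    def test_low_depth_cell_set_missing(self):
        gm = make_gm([[1, 1]], [2, 2], ["p1", "p1"], depth=[[7, 9]])
        out = vio.filter_sites(gm, min_depth=8, max_missing_fraction=1.0)
        assert out.dosage[0].tolist() == [MISSING, 1]

    def test_majority_missing_site_removed(self):
        dosage = np.ones((1, 10), dtype=np.int16)
        dosage[0, :6] = MISSING
        gm = make_gm(dosage, [2] * 10, ["p1"] * 10)
        out = vio.filter_sites(gm, min_depth=0, max_missing_fraction=0.5)
        assert out.n_sites == 0  # 0.6 > 0.5

    def test_exact_boundary_kept(self):
        dosage = np.ones((1, 10), dtype=np.int16)
        dosage[0, :5] = MISSING
        gm = make_gm(dosage, [2] * 10, ["p1"] * 10)
        assert vio.filter_sites(gm, min_depth=0, max_missing_fraction=0.5).n_sites == 1

    def test_survivors_match_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        n_sites, n_samples = 20, 10
        dosage = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int16)
        dosage[rng.random(dosage.shape) < 0.2] = MISSING
        depth = rng.integers(2, 20, size=dosage.shape)
        gm = make_gm(dosage, [2] * n_samples, ["p1"] * n_samples, depth=depth)
        out = vio.filter_sites(gm, min_depth=8, max_missing_fraction=0.5, maf=0.1)

        expected = []
        for r in range(n_sites):
            cells = [
                dosage[r, c] if depth[r, c] >= 8 and dosage[r, c] != MISSING else None
                for c in range(n_samples)
            ]
            missing_frac = sum(c is None for c in cells) / n_samples
            if missing_frac > 0.5:
                continue
            tot = 2 * sum(c is not None for c in cells)
            alt = sum(c for c in cells if c is not None)
            p = alt / tot
            if min(p, 1 - p) < 0.1:
                continue
            expected.append(r + 1)
        assert out.sites["pos"].tolist() == expected


class TestParalogMask:
    def _gene(self):
        return pd.DataFrame(
            {"gene_id": ["g1"], "scaffold": ["s1"], "start": [1], "end": [10], "strand": ["+"]}
        )

    def test_five_fixed_het_snps_in_two_pops_masks_gene(self):
        # 6 sites in gene, 5 of them all-heterozygous in both diploid pops
        dosage = np.ones((6, 4), dtype=np.int16)
        dosage[5] = [0, 0, 2, 2]
        gm = make_gm(dosage, [2] * 4, ["p1", "p1", "p2", "p2"])
        mask = vio.mask_paralog_genes(gm, self._gene())
        assert mask.all()

    def test_four_snps_not_enough(self):
        dosage = np.ones((4, 4), dtype=np.int16)
        gm = make_gm(dosage, [2] * 4, ["p1", "p1", "p2", "p2"])
        assert not vio.mask_paralog_genes(gm, self._gene()).any()

    def test_one_population_not_enough(self):
        dosage = np.ones((5, 4), dtype=np.int16)
        dosage[:, 2:] = 0  # second pop homozygous
        gm = make_gm(dosage, [2] * 4, ["p1", "p1", "p2", "p2"])
        assert not vio.mask_paralog_genes(gm, self._gene()).any()

    def test_tetraploid_dosage_two_is_fixed_het(self):
        dosage = np.full((5, 4), 2, dtype=np.int16)
        gm = make_gm(dosage, [4] * 4, ["p1", "p1", "p2", "p2"])
        assert vio.mask_paralog_genes(gm, self._gene()).all()


class TestExcessDepthMask:
    def test_uniform_depth_masks_nothing(self):
        gm = make_gm(
            np.zeros((50, 30), dtype=np.int16), [2] * 30, ["p1"] * 30,
            depth=np.full((50, 30), 25),
        )
        assert not vio.mask_excess_depth(gm, min_individuals=20).any()

    def test_spike_site_masked(self):
        rng = np.random.default_rng(1)
        depth = rng.integers(20, 30, size=(50, 30))
        depth[10, :21] = 500  # spike in 21 of 30 samples
        gm = make_gm(np.zeros((50, 30), dtype=np.int16), [2] * 30, ["p1"] * 30, depth=depth)
        mask = vio.mask_excess_depth(gm, min_individuals=20)
        assert mask[10]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        depth = rng.poisson(25, size=(50, 30))
        depth[rng.random(depth.shape) < 0.02] *= 10
        gm = make_gm(np.zeros((50, 30), dtype=np.int16), [2] * 30, ["p1"] * 30, depth=depth)
        mask = vio.mask_excess_depth(gm, sd_multiplier=2, min_individuals=5)
        for r in range(50):
            n_exceed = sum(
                depth[r, c] > depth[:, c].mean() + 2 * depth[:, c].std()
                for c in range(30)
            )
            assert mask[r] == (n_exceed >= 5)


class TestPolarize:
    def _gm(self):
        return make_gm([[1, 3], [2, 0], [0, 4]], [2, 4], ["p1", "p2"],
                       positions=[10, 20, 30])

    def _key(self, probs):
        return pd.DataFrame(
            {"scaffold": "s1", "pos": [10, 20, 30], "p_anc_ref": probs}
        )

    def test_threshold_and_flip(self):
        out = vio.polarize(self._gm(), self._key([0.9, 0.69, 0.2]))
        assert out.sites["ancestral"].tolist() == ["ref", "unknown", "alt"]
        assert out.dosage[0].tolist() == [1, 3]  # ref ancestral: unchanged
        assert out.dosage[1].tolist() == [2, 0]  # unknown: untouched
        assert out.dosage[2].tolist() == [2, 0]  # flipped to ploidy - dosage

    def test_involution(self):
        gm = self._gm()
        once = vio.polarize(gm, self._key([0.1, 0.1, 0.1]))
        # flipping twice restores original dosages
        twice = vio.polarize(once, self._key([0.1, 0.1, 0.1]))
        assert np.array_equal(twice.dosage, gm.dosage)

    def test_missing_preserved_and_bad_probability_fatal(self):
        gm = make_gm([[MISSING, 2]], [2, 4], ["p1", "p2"], positions=[10])
        out = vio.polarize(gm, self._key([0.0, 0.5, 0.5]).iloc[:1])
        assert out.dosage[0].tolist() == [MISSING, 2]
        with pytest.raises(ValueError):
            vio.polarize(gm, pd.DataFrame({"scaffold": ["s1"], "pos": [10], "p_anc_ref": [1.2]}))

    def test_derived_dosage_uses_polarity(self):
        gm = self._gm()
        out = vio.polarize(gm, self._key([0.9, 0.69, 0.2]))
        dd = out.derived_dosage()
        assert dd[0].tolist() == [1, 3]
        assert np.isnan(dd[1]).all()  # unknown excluded
        assert dd[2].tolist() == [2, 0]


class TestPopulationFrequencies:
    def test_basic_and_tetraploid(self):
        gm = make_gm([[1, 1, 3]], [2, 2, 4], ["p1", "p1", "p2"])
        freqs = vio.population_frequencies(gm)
        assert freqs.freq[freqs.pop_index("p1"), 0] == pytest.approx(0.5)
        assert freqs.freq[freqs.pop_index("p2"), 0] == pytest.approx(0.75)
        assert freqs.chroms[freqs.pop_index("p1"), 0] == 4

    def test_all_missing_is_nan_not_zero(self):
        gm = make_gm([[MISSING, MISSING]], [2, 2], ["p1", "p1"])
        freqs = vio.population_frequencies(gm)
        assert np.isnan(freqs.freq[0, 0])
        assert freqs.chroms[0, 0] == 0
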