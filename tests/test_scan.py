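"""Window grid, outlier calling, gene annotation and set-level tests."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ploidyscan import scan


def sites_at(positions, scaffold="s1"):
    return pd.DataFrame({"scaffold": scaffold, "pos": positions})


class TestBuildWindows:
    def test_ten_snps_make_one_window(self):
        windows, widx = scan.build_windows(sites_at(range(1, 11)))
        assert len(windows) == 1
        assert windows.iloc[0][["start", "end"]].tolist() == [1, 1000]
        assert (widx == 0).all()

    def test_nine_snps_discarded(self):
        windows, widx = scan.build_windows(sites_at(range(1, 10)))
        assert len(windows) == 0
        assert (widx == -1).all()

    def test_grid_boundary(self):
        windows, widx = scan.build_windows(
            sites_at([1000] * 10 + [1001] * 10), 1000, 10
        )
        assert windows[["start", "end"]].values.tolist() == [[1, 1000], [1001, 2000]]
        assert widx[0] != widx[10]


class TestOutlierWindows:
    def _windows(self, values):
        return pd.DataFrame(
            {"scaffold": "s1", "start": 1, "end": 1000, "fst": values}
        )

    def test_one_percent_of_thousand(self):
        out = scan.outlier_windows(self._windows(np.linspace(0, 1, 1000)))
        assert len(out) == 10

    def test_ceiling_rule(self):
        out = scan.outlier_windows(self._windows(np.linspace(0, 1, 250)))
        assert len(out) == 3  # ceil(2.5)

    def test_ties_at_cutoff_included(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.uniform(0, 0.5, 995), np.full(10, 0.9)])
        out = scan.outlier_windows(self._windows(values), quantile=0.008)
        # nominal ceil(0.008 * 1005) = 9, but all ten windows tied at the
        # cutoff value 0.9 are included
        assert len(out) == 10 and (out["fst"] == 0.9).all()

    def test_too_few_windows_fatal(self):
        with pytest.raises(ValueError, match="quantile"):
            scan.outlier_windows(self._windows(np.linspace(0, 1, 99)))

    def test_all_equal_fatal(self):
        with pytest.raises(ValueError, match="equal"):
            scan.outlier_windows(self._windows(np.full(200, 0.3)))


class TestAnnotateGenes:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])

    def test_two_bp_overlap_is_hit(self):
        genes = self._genes([("g1", "s1", 999, 1500, "+")])
        windows = pd.DataFrame({"scaffold": ["s1"], "start": [1], "end": [1000]})
        assert scan.annotate_genes(windows, genes) == {"g1"}

    def test_adjacent_no_overlap(self):
        genes = self._genes([("g1", "s1", 1001, 1500, "+")])
        windows = pd.DataFrame({"scaffold": ["s1"], "start": [1], "end": [1000]})
        assert scan.annotate_genes(windows, genes) == set()

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        genes = self._genes(
            [
                (f"g{i}", "s1", int(s), int(s + rng.integers(100, 3000)), "+")
                for i, s in enumerate(rng.integers(1, 50_000, 40))
            ]
        )
        starts = rng.integers(1, 50_000, 30)
        windows = pd.DataFrame(
            {"scaffold": "s1", "start": starts, "end": starts + 999}
        )
        expected = {
            g["gene_id"]
            for _, g in genes.iterrows()
            for _, w in windows.iterrows()
            if w["start"] <= g["end"] and w["end"] >= g["start"]
        }
        assert scan.annotate_genes(windows, genes) == expected


class TestParallelCandidates:
    def test_distinct_lineages_required(self):
        lineages = {"p1": "L1", "p2": "L1", "p3": "L2"}
        sets = {"p1": {"gA", "gB"}, "p2": {"gA"}, "p3": {"gB"}}
        out = scan.parallel_candidates(sets, lineages)
        # gA supported by p1+p2 (same lineage) -> excluded;
        # gB by p1+p3 (L1, L2) -> retained
        assert out.gene_ids() == {"gB"}

    def test_extra_same_lineage_pair_still_counts(self):
        lineages = {"p1": "L1", "p2": "L1", "p3": "L2"}
        sets = {"p1": {"g"}, "p2": {"g"}, "p3": {"g"}}
        assert scan.parallel_candidates(sets, lineages).gene_ids() == {"g"}

    def test_single_lineage_warns_empty(self):
        lineages = {"p1": "L1", "p2": "L1"}
        sets = {"p1": {"g"}, "p2": {"g"}}
        assert scan.parallel_candidates(sets, lineages).gene_ids() == set()


class TestTopCandidates:
    def _parallel(self):
        cs = scan.CandidateSet()
        for g in ("gA", "gB", "gC"):
            cs.genes[g] = {"pairs": {"p1", "p2"}, "methods": {"fst_scan"}, "lineages": {"L1", "L2"}}
        return cs

    def test_intersection_rule(self):
        out = scan.top_candidates(self._parallel(), {"gA"}, {"gB", "gZ"})
        assert out.gene_ids() == {"gA", "gB"}
        assert out.genes["gA"]["methods"] == {"fst_scan", "repeatability"}
        # gZ only in assoc, not in the F_ST scan -> never a top candidate
        assert "gZ" not in out.gene_ids()

    def test_subset_invariant(self):
        out = scan.top_candidates(self._parallel(), {"gA", "gB", "gC"}, set())
        assert out.gene_ids() <= self._parallel().gene_ids()


class TestOverlapTest:
    def test_zero_overlap_is_one(self):
        assert scan.overlap_test({"a", "b"}, {"c", "d"}, 100) == pytest.approx(1.0)

    def test_matches_exact_sum(self):
        A = {f"a{i}" for i in range(10)}
        B = {f"a{i}" for i in range(5)} | {f"b{i}" for i in range(5)}
        expected = sum(
            comb(10, k) * comb(90, 10 - k) / comb(100, 10) for k in range(5, 11)
        )
        assert scan.overlap_test(A, B, 100) == pytest.approx(expected)

    def test_complete_overlap_single_term(self):
        A = {"a", "b"}
        B = {"a", "b", "c"}
        expected = comb(2, 2) * comb(2, 1) / comb(4, 3)
        assert scan.overlap_test(A, B, 4) == pytest.approx(expected)

    def test_undersized_universe_fatal(self):
        with pytest.raises(ValueError):
            scan.overlap_test({"a", "b"}, {"c"}, 2)


class TestRecombinationPermutation:
    def _rates(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "rate": rng.lognormal(0, 0.5, n)}
        )

    def test_all_genes_gives_p_one(self):
        rates = self._rates()
        res = scan.recombination_permutation_test(set(rates["gene_id"]), rates, 500, seed=1)
        assert res["p"] == pytest.approx(1.0)

    def test_top_rate_genes_hit_floor(self):
        rates = self._rates()
        top = set(rates.nlargest(3, "rate")["gene_id"])
        res = scan.recombination_permutation_test(top, rates, n_perm=1000, seed=1)
        # at the permutation floor except for rare draws of the same top set
        assert res["p"] <= 3 / 1001

    def test_empty_candidates_fatal(self):
        with pytest.raises(ValueError):
            scan.recombination_permutation_test(set(), self._rates())

    def test_null_pvalues_roughly_uniform(self):
        rates = self._rates(n=80, seed=2)
        rng = np.random.default_rng(10)
        pvals = []
        for rep in range(300):
            cand = set(rng.choice(rates["gene_id"], size=8, replace=False))
            pvals.append(
                scan.recombination_permutation_test(cand, rates, n_perm=199, seed=4000 + rep)["p"]
            )
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
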