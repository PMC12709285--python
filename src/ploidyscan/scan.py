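"""Window construction, outlier calling, gene annotation and set-level tests.

Windows form a fixed non-overlapping grid anchored at position 1 of each
scaffold (window w spans [w*size + 1, (w+1)*size] in 1-based coordinates);
windows with fewer SNPs than the informativeness threshold are discarded.
Outliers are the top quantile of the windowed statistic per population
pair, candidate genes are windows' >= 1 bp overlaps with gene models, and
parallelism requires outliers in population pairs of distinct lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Per-gene supporting evidence across pairs and methods."""

    genes: dict = field(default_factory=dict)  # gene_id -> {"pairs": set, "methods": set, "lineages": set}

    def gene_ids(self) -> set:
        return set(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                g,
                ",".join(sorted(v["pairs"])),
                ",".join(sorted(v["methods"])),
                ",".join(sorted(v["lineages"])),
            )
            for g, v in sorted(self.genes.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "pairs", "methods", "lineages"])


def build_windows(
    sites: pd.DataFrame, window_size: int = 1000, min_snps: int = 10
):
    """Assign sites to a fixed window grid and keep informative windows.

    Returns (windows, window_index) where ``windows`` has columns scaffold,
    start, end (1-based inclusive), n_snps, and ``window_index`` maps each
    site to its row in ``windows`` (-1 for sites in discarded windows).
    """
    scaf = sites["scaffold"].to_numpy()
    pos = sites["pos"].to_numpy()
    bin_id = (pos - 1) // window_size
    key = pd.DataFrame({"scaffold": scaf, "bin": bin_id})
    grouped = key.groupby(["scaffold", "bin"], sort=True).size().reset_index(name="n_snps")
    kept = grouped[grouped["n_snps"] >= min_snps].reset_index(drop=True)
    n_discarded = len(grouped) - len(kept)
    if n_discarded:
        logger.info("discarded %d windows with < %d SNPs", n_discarded, min_snps)
    windows = pd.DataFrame(
        {
            "scaffold": kept["scaffold"],
            "start": kept["bin"] * window_size + 1,
            "end": (kept["bin"] + 1) * window_size,
            "n_snps": kept["n_snps"],
        }
    )
    lookup = {
        (s, b): i for i, (s, b) in enumerate(zip(kept["scaffold"], kept["bin"]))
    }
    window_index = np.array(
        [lookup.get((s, b), -1) for s, b in zip(scaf, bin_id)], dtype=np.int64
    )
    return windows, window_index


def outlier_windows(
    windows: pd.DataFrame, stat_column: str = "fst", quantile: float = 0.01
) -> pd.DataFrame:
    """Top ``ceil(quantile * N)`` windows by the statistic, ties at the
    cutoff included.  Requires >= 100 windows for a stable quantile."""
    values = windows[stat_column].to_numpy(dtype=float)
    valid = np.isfinite(values)
    n = int(valid.sum())
    if n < 100:
        raise ValueError(f"only {n} windows with finite {stat_column}: quantile unstable")
    if np.nanmax(values) == np.nanmin(values):
        raise ValueError("all window statistics equal: no outliers definable")
    n_out = ceil(quantile * n)
    order = np.sort(values[valid])[::-1]
    cutoff = order[n_out - 1]
    out = windows[valid & (values >= cutoff)]
    if len(out) > n_out:
        logger.info("outlier cutoff ties: %d windows for nominal %d", len(out), n_out)
    return out.reset_index(drop=True)


def annotate_genes(intervals: pd.DataFrame, genes: pd.DataFrame) -> set:
    """Genes overlapped (>= 1 bp, 1-based inclusive coordinates) by any of
    the given windows/SNP intervals.  SNP tables may carry ``pos`` instead
    of start/end."""
    if "start" not in intervals.columns and "pos" in intervals.columns:
        intervals = intervals.assign(start=intervals["pos"], end=intervals["pos"])
    hit = set()
    known_scaffolds = set(genes["scaffold"])
    unmatched = set(intervals["scaffold"]) - known_scaffolds
    if unmatched:
        n = int(intervals["scaffold"].isin(unmatched).sum())
        logger.warning("%d intervals on scaffolds absent from annotation: %s", n, sorted(unmatched))
    for scaffold, sub in intervals.groupby("scaffold", sort=False):
        g = genes[genes["scaffold"] == scaffold]
        if g.empty:
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        ws = sub["start"].to_numpy()[:, None]
        we = sub["end"].to_numpy()[:, None]
        overlap = (ws <= ge[None, :]) & (we >= gs[None, :])
        hit.update(g["gene_id"].to_numpy()[overlap.any(axis=0)])
    return hit


def parallel_candidates(
    per_pair_genes: dict, pair_lineage: dict, min_pairs: int = 2
) -> CandidateSet:
    """Genes that are outliers in >= ``min_pairs`` population pairs covering
    at least two distinct lineages (within one ploidy)."""
    if len(per_pair_genes) < 2:
        raise ValueError("need >= 2 population pairs")
    if len(set(pair_lineage[p] for p in per_pair_genes)) < 2:
        logger.warning("all pairs from one lineage: no parallel candidates definable")
        return CandidateSet()
    support: dict = {}
    for pair, genes in per_pair_genes.items():
        for g in genes:
            support.setdefault(g, set()).add(pair)
    out = CandidateSet()
    for g, pairs in support.items():
        lineages = {pair_lineage[p] for p in pairs}
        if len(pairs) >= min_pairs and len(lineages) >= 2:
            out.genes[g] = {"pairs": set(pairs), "methods": {"fst_scan"}, "lineages": lineages}
    return out


def top_candidates(
    fst_parallel: CandidateSet, repeatability_genes: set, assoc_genes: set
) -> CandidateSet:
    """Intersection rule: F_ST parallel candidates backed by at least one of
    the repeatability or association methods."""
    out = CandidateSet()
    for g, v in fst_parallel.genes.items():
        methods = set(v["methods"])
        if g in repeatability_genes:
            methods.add("repeatability")
        if g in assoc_genes:
            methods.add("env_assoc")
        if methods - {"fst_scan"}:
            out.genes[g] = {"pairs": set(v["pairs"]), "methods": methods, "lineages": set(v["lineages"])}
    return out


def overlap_test(set_a: set, set_b: set, universe_size: int) -> float:
    """Hypergeometric upper-tail probability of the observed overlap,
    P(X >= |A & B|) drawing |B| from a universe containing |A| marked genes."""
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    overlap = len(a & b)
    return float(sps.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))


def recombination_permutation_test(
    candidate_genes: set,
    rates: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """One-sided permutation test: is the mean recombination rate of
    candidate genes greater than random same-size gene draws?

    ``rates`` has columns gene_id, rate.  p = (1 + #{null >= observed}) /
    (n_perm + 1)."""
    if not candidate_genes:
        raise ValueError("empty candidate set")
    table = rates.set_index("gene_id")["rate"]
    present = [g for g in candidate_genes if g in table.index]
    coverage = len(present) / len(candidate_genes)
    if coverage < 0.9:
        logger.warning("recombination rate available for only %.0f%% of candidates", 100 * coverage)
    observed = float(table.loc[present].mean())
    pool = table.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    k = len(present)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = pool[rng.choice(len(pool), size=k, replace=False)].mean()
    # tolerance so numerically-equal null means count as >= observed
    tol = 1e-9 * max(1.0, abs(observed))
    p = (1.0 + float((null >= observed - tol).sum())) / (n_perm + 1.0)
    return {"observed_mean": observed, "p": p, "n_candidates": k, "coverage": coverage}
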