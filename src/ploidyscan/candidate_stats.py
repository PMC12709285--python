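"""Fixation, allele-frequency and relative-differentiation comparisons of
candidate genes across ploidies.

Fixation is strict: a SNP counts as fixed for a pair when one population's
derived-allele frequency is exactly 0 and the other's exactly 1 (complete
allele frequency divergence), computed either on all sampled chromosomes or
after a standardized 12-chromosome subsample.  Gene-level averages include
a population pair only when the gene is a significant outlier in that pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def windows_overlapping_gene(gene, window_size: int = 1000):
    """1-based [start, end] span of the fixed window grid overlapping a gene."""
    w_first = (int(gene["start"]) - 1) // window_size
    w_last = (int(gene["end"]) - 1) // window_size
    return w_first * window_size + 1, (w_last + 1) * window_size


def fixed_snp_count(
    freqA: np.ndarray,
    freqB: np.ndarray,
    positions: np.ndarray,
    scaffolds: np.ndarray,
    gene,
    window_size: int = 1000,
) -> int:
    """Count SNPs with frequencies exactly 0 vs 1 inside the 1-kbp windows
    overlapping the gene."""
    lo, hi = windows_overlapping_gene(gene, window_size)
    sel = (scaffolds == gene["scaffold"]) & (positions >= lo) & (positions <= hi)
    if not sel.any():
        logger.info("gene %s: no windows overlap", gene.get("gene_id", "?"))
        return 0
    fa = np.asarray(freqA, dtype=float)[sel]
    fb = np.asarray(freqB, dtype=float)[sel]
    fixed = ((fa == 0.0) & (fb == 1.0)) | ((fa == 1.0) & (fb == 0.0))
    return int(fixed.sum())


def average_fixation(per_pair_counts: pd.DataFrame, outlier_map: set) -> dict:
    """Average fixed-SNP counts over qualifying pairs only.

    ``per_pair_counts`` has columns gene_id, pair_id, count; ``outlier_map``
    is the set of (gene_id, pair_id) where the gene is a significant
    outlier.  Returns per-gene means, their overall mean, and the fraction
    of genes with at least one fixed SNP in a qualifying pair."""
    qualifying = per_pair_counts[
        [
            (g, p) in outlier_map
            for g, p in zip(per_pair_counts["gene_id"], per_pair_counts["pair_id"])
        ]
    ]
    per_gene = qualifying.groupby("gene_id")["count"].mean()
    any_fixed = qualifying.groupby("gene_id")["count"].max() > 0
    return {
        "per_gene_mean": per_gene,
        "mean_over_genes": float(per_gene.mean()) if len(per_gene) else float("nan"),
        "fraction_genes_with_fixation": float(any_fixed.mean()) if len(any_fixed) else float("nan"),
    }


def af_distribution(
    freq_table,
    candidate_genes: pd.DataFrame,
    pop_soil_class: dict,
    qualifying_pops: dict | None = None,
    flank: int = 2000,
) -> pd.DataFrame:
    """Mean derived-allele frequency per candidate SNP by soil class,
    oriented so the siliceous class carries the higher mean (display
    polarity only; inputs are untouched).

    ``freq_table`` is an AlleleFreqTable; ``candidate_genes`` holds gene
    spans; ``qualifying_pops`` optionally restricts, per gene_id, the set of
    populations entering the means."""
    pos = freq_table.sites["pos"].to_numpy()
    scaf = freq_table.sites["scaffold"].to_numpy()
    rows = []
    for _, gene in candidate_genes.iterrows():
        sel = (
            (scaf == gene["scaffold"])
            & (pos >= int(gene["start"]) - flank)
            & (pos <= int(gene["end"]) + flank)
        )
        if not sel.any():
            continue
        pops = freq_table.populations
        allowed = (
            qualifying_pops.get(gene["gene_id"], set(pops)) if qualifying_pops else set(pops)
        )
        by_class = {"calcareous": [], "siliceous": []}
        for pi, pop in enumerate(pops):
            if pop not in allowed or pop not in pop_soil_class:
                continue
            by_class[pop_soil_class[pop]].append(freq_table.freq[pi][sel])
        if not by_class["calcareous"] or not by_class["siliceous"]:
            continue
        cal = np.nanmean(np.vstack(by_class["calcareous"]), axis=0)
        sil = np.nanmean(np.vstack(by_class["siliceous"]), axis=0)
        flip = cal > sil
        cal_o = np.where(flip, 1 - cal, cal)
        sil_o = np.where(flip, 1 - sil, sil)
        for j, snp_pos in enumerate(pos[sel]):
            rows.append((gene["gene_id"], gene["scaffold"], int(snp_pos), cal_o[j], sil_o[j]))
    return pd.DataFrame(
        rows, columns=["gene_id", "scaffold", "pos", "mean_freq_calcareous", "mean_freq_siliceous"]
    )


def relative_gene_differentiation(
    per_pair_gene_rho: pd.DataFrame, genomewide_rho: dict, outlier_map: set
) -> dict:
    """Candidate-gene Rho divided by the pair's genome-wide Rho, averaged
    over qualifying pairs.

    ``per_pair_gene_rho`` has columns gene_id, pair_id, rho (mean windowed
    Rho over the gene's windows); ``genomewide_rho`` maps pair_id to the
    genome-wide mean."""
    rows = []
    for _, r in per_pair_gene_rho.iterrows():
        if (r["gene_id"], r["pair_id"]) not in outlier_map:
            continue
        gw = genomewide_rho[r["pair_id"]]
        if not gw > 0:
            raise ValueError(f"genome-wide rho must be positive for pair {r['pair_id']}")
        rows.append((r["gene_id"], r["pair_id"], r["rho"] / gw))
    ratios = pd.DataFrame(rows, columns=["gene_id", "pair_id", "ratio"])
    per_gene = ratios.groupby("gene_id")["ratio"].mean()
    return {
        "per_gene_ratio": per_gene,
        "mean_ratio": float(per_gene.mean()) if len(per_gene) else float("nan"),
    }
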