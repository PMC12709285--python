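"""Latent-factor-corrected association of allele frequencies with soil PC1.

A deliberately explicit stand-in for ridge latent-factor mixed models:
population structure is captured by the top-k principal components of the
centred population x SNP frequency matrix, which then enter an ordinary
per-SNP linear regression of population allele frequency on the soil PC1
score.  Population-level frequencies (not individual genotypes) are
modelled, and missing frequencies are mean-imputed per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """Per-SNP association output (soil coefficient scale)."""

    table: pd.DataFrame  # columns: beta, p, q; indexed by SNP position in input
    k: int
    n_excluded_constant: int


def _impute(freqs: np.ndarray) -> np.ndarray:
    """Mean-impute missing population frequencies per SNP."""
    out = freqs.astype(float).copy()
    col_mean = np.nanmean(out, axis=0)
    holes = np.isnan(out)
    out[holes] = np.take(col_mean, np.nonzero(holes)[1])
    return out


def latent_factors(freqs: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal component scores of the centred population x SNP
    frequency matrix (k orthogonal structure covariates per population)."""
    n_pops = freqs.shape[0]
    if k == 0:
        return np.empty((n_pops, 0))
    if k >= n_pops - 1:
        raise ValueError(f"k={k} too large for {n_pops} populations")
    x = _impute(freqs)
    x = x - x.mean(axis=0, keepdims=True)
    u, s_vals, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :k] * s_vals[:k]


def association_scan(
    freqs: np.ndarray,
    soil_pc1: np.ndarray,
    factors: np.ndarray | None = None,
    k: int = 4,
    fdr_q: float = 0.1,
) -> AssociationResult:
    """Per-SNP linear model frequency ~ intercept + soil_pc1 + factors.

    ``freqs`` is populations x SNPs (NaN = missing, mean-imputed per SNP);
    ``soil_pc1`` must be available for every population.  Returns two-sided
    p-values for the soil coefficient with Benjamini-Hochberg q-values;
    SNPs constant across populations are excluded (logged) and carry NaN.
    """
    soil = np.asarray(soil_pc1, dtype=float)
    if np.any(~np.isfinite(soil)):
        raise ValueError("soil_pc1 must be finite for every population")
    if np.ptp(soil) == 0:
        raise ValueError("constant soil vector")
    if factors is None:
        factors = latent_factors(freqs, k)
    k = factors.shape[1]
    y = _impute(freqs)
    n_pops, n_snps = y.shape
    X = np.column_stack([np.ones(n_pops), soil, factors])
    p_params = X.shape[1]
    df = n_pops - p_params
    if df < 1:
        raise ValueError("more covariates than populations")

    constant = np.ptp(y, axis=0) == 0
    n_constant = int(constant.sum())
    if n_constant:
        logger.info("excluded %d SNPs constant across populations", n_constant)

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y  # (p_params, n_snps)
    resid = y - X @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / se
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    pvals[constant] = np.nan

    q = np.full(n_snps, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        q[ok] = multipletests(pvals[ok], alpha=fdr_q, method="fdr_bh")[1]
    table = pd.DataFrame({"beta": beta[1], "p": pvals, "q": q})
    table.loc[constant, "beta"] = np.nan
    return AssociationResult(table=table, k=k, n_excluded_constant=n_constant)


def assoc_candidate_genes(
    significant_snps: pd.DataFrame, genes: pd.DataFrame, min_snps: int = 3
) -> set:
    """Genes containing >= ``min_snps`` significant SNPs within their span
    (a SNP inside two overlapping genes counts for both)."""
    counts: dict = {}
    for scaffold, sub in significant_snps.groupby("scaffold", sort=False):
        g = genes[genes["scaffold"] == scaffold]
        if g.empty:
            continue
        pos = sub["pos"].to_numpy()[:, None]
        inside = (pos >= g["start"].to_numpy()[None, :]) & (
            pos <= g["end"].to_numpy()[None, :]
        )
        for gid, n in zip(g["gene_id"], inside.sum(axis=0)):
            counts[gid] = counts.get(gid, 0) + int(n)
    return {g for g, n in counts.items() if n >= min_snps}
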