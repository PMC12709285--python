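"""Ploidy-aware diversity and differentiation estimators.

Per-site statistics operate on derived-allele counts (``k`` out of ``n``
sampled chromosomes) or on individual dosages where the estimator needs the
within-individual stratum.  Windowed values of ratio statistics (F_ST, Rho)
are ratio-of-sums of the per-SNP variance components, which avoids the
upward bias of averaging per-SNP ratios; negative per-SNP components are
kept in the sums and only clamped at reporting.

Rho is an F_ST analogue that excludes the within-individual stratum --
identity probabilities are computed only over gene pairs drawn from
different individuals -- which removes the part of the genotype structure
where polysomic heterozygosity lives and makes the statistic comparable
between diploids and autotetraploids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variants_io import MISSING, AlleleFreqTable, GenotypeMatrix

__all__ = [
    "downsample_individuals",
    "downsample_chromosomes",
    "downsample",
    "site_heterozygosity",
    "nucleotide_diversity",
    "tajima_constants",
    "tajimas_d",
    "wc_fst_components",
    "wc_fst",
    "rho_components",
    "rho",
    "window_ratio_of_sums",
]


# ---------------------------------------------------------------------------
# downsampling

def downsample_individuals(
    gm: GenotypeMatrix, n_individuals: int, seed: int
) -> GenotypeMatrix:
    """Per population and per site, keep a uniform random subset of
    ``n_individuals`` non-missing genotypes (the rest set missing).  Sites
    where a population has fewer non-missing individuals are dropped for
    that population (all its genotypes set missing there)."""
    rng = np.random.default_rng(seed)
    dosage = gm.dosage.copy()
    pops = gm.samples["population"].to_numpy()
    for pop in pd.unique(pops):
        cols = np.flatnonzero(pops == pop)
        d = dosage[:, cols]
        ok = d != MISSING
        n_ok = ok.sum(axis=1)
        # rank non-missing genotypes by random keys; keep the first n per site
        keys = rng.random(d.shape)
        keys[~ok] = np.inf
        order = np.argsort(keys, axis=1)
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(d.shape[1])[None, :], axis=1)
        keep = ok & (ranks < n_individuals)
        keep[n_ok < n_individuals] = False
        d = np.where(keep, d, MISSING).astype(np.int16)
        dosage[:, cols] = d
    out = GenotypeMatrix(
        sites=gm.sites.copy(), dosage=dosage, depth=gm.depth, samples=gm.samples,
        log={**gm.log, "downsampled_individuals": n_individuals},
    )
    return out


def downsample_chromosomes(
    freqs: AlleleFreqTable, n_chromosomes: int = 12, seed: int = 0
) -> AlleleFreqTable:
    """Hypergeometric draw of ``n_chromosomes`` allele copies from each
    population's sampled chromosomes at each site (without replacement).
    Populations with fewer sampled chromosomes get NaN at that site."""
    rng = np.random.default_rng(seed)
    n = freqs.chroms
    k = np.rint(np.nan_to_num(freqs.freq) * n).astype(np.int64)
    enough = n >= n_chromosomes
    drawn = np.zeros_like(k)
    good = np.clip(k, 0, None)
    drawn[enough] = rng.hypergeometric(
        good[enough], (n - good)[enough], n_chromosomes
    )
    freq = np.where(enough, drawn / n_chromosomes, np.nan)
    chroms = np.where(enough, n_chromosomes, 0).astype(np.int32)
    return AlleleFreqTable(
        populations=list(freqs.populations), sites=freqs.sites.copy(),
        freq=freq, chroms=chroms,
    )


def downsample(gm=None, freqs=None, n_individuals=None, n_chromosomes=None, seed=0):
    """Dispatch between the two downsampling modes (exactly one allowed)."""
    if (n_individuals is None) == (n_chromosomes is None):
        raise ValueError("request exactly one of n_individuals or n_chromosomes")
    if n_individuals is not None:
        if gm is None:
            raise ValueError("individual-mode downsampling needs a GenotypeMatrix")
        return downsample_individuals(gm, n_individuals, seed)
    if freqs is None:
        raise ValueError("chromosome-mode downsampling needs an AlleleFreqTable")
    return downsample_chromosomes(freqs, n_chromosomes, seed)


# ---------------------------------------------------------------------------
# diversity

def site_heterozygosity(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-site expected heterozygosity 2k(n-k) / (n(n-1)).

    Sites with n < 2 yield NaN (skipped by callers)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * k * (n - k) / (n * (n - 1.0))
    return np.where(n >= 2, h, np.nan)


def nucleotide_diversity(k: np.ndarray, n: np.ndarray, window_length: int) -> float:
    """Window pi per bp: sum of per-site heterozygosities over window length.
    Monomorphic positions contribute zero implicitly."""
    h = site_heterozygosity(k, n)
    return float(np.nansum(h)) / float(window_length)


def tajima_constants(n: int) -> dict:
    """Tajima (1989) a1..e2 constants for n sampled chromosomes."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pairwise_pi_sum: float, n: int) -> float:
    """Tajima's D from segregating-site count S and the summed per-site
    pairwise diversity (theta-pi, not per bp) at n chromosomes.

    Returns NaN for S == 0 (undefined)."""
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((pairwise_pi_sum - S / c["a1"]) / np.sqrt(var))


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST (two populations, allele-count / haploid level)

def wc_fst_components(kA, nA, kB, nB):
    """Per-SNP Weir & Cockerham (1984) variance components ``a`` (among
    populations) and ``b`` (within), from derived-allele counts and sampled
    chromosome totals of two populations.  The haplotype-level estimator is
    used (sample units are allele copies), matching allele-frequency input.

    Returns (a, a + b); sites where either population has n == 0 give NaN.
    """
    kA, nA, kB, nB = (np.asarray(x, dtype=float) for x in (kA, nA, kB, nB))
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = kA / nA
        pB = kB / nB
        N = nA + nB
        pbar = (kA + kB) / N
        # one-way ANOVA mean squares on allele copies (0/1 observations)
        msa = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / (r - 1.0)
        msw = (nA * pA * (1.0 - pA) + nB * pB * (1.0 - pB)) / (N - r)
        nc = (N - (nA**2 + nB**2) / N) / (r - 1.0)
        a = (msa - msw) / nc
    valid = (nA > 0) & (nB > 0) & (N > r) & (nc > 0)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, msw, np.nan)
    return a, a + b


def wc_fst(kA, nA, kB, nB):
    """Windowed Weir-Cockerham F_ST: ratio of summed components.

    Returns (per-SNP a, per-SNP a+b, windowed F_ST).  Per-SNP ratios are
    clamped to [0, 1] only at reporting; the window uses raw sums."""
    num, den = wc_fst_components(kA, nA, kB, nB)
    total = np.nansum(den)
    fst = float(np.nansum(num) / total) if total > 0 else float("nan")
    return num, den, fst


# ---------------------------------------------------------------------------
# Rho (AMOVA components excluding the within-individual stratum)

def _between_individual_diversity(dos: np.ndarray, ploidy: int):
    """Per-site expected diversity over pairs of allele copies drawn from
    *different* individuals of one population, plus the individual-mean
    frequency and the non-missing individual count.

    For individual allele frequencies y_j = dosage_j / ploidy the unbiased
    pair average of y_j(1-y_k) + y_k(1-y_j) over j != k is
    2 [S1 (n-1) - S1^2 + S2] / (n (n-1)) with S1 = sum y, S2 = sum y^2.
    """
    dos = np.asarray(dos, dtype=float)
    ok = dos != MISSING
    y = np.where(ok, dos / ploidy, 0.0)
    n = ok.sum(axis=1).astype(float)
    s1 = y.sum(axis=1)
    s2 = (y**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_w = 2.0 * (s1 * (n - 1.0) - s1**2 + s2) / (n * (n - 1.0))
        p_hat = s1 / n
    return h_w, p_hat, n


def rho_components(dosA: np.ndarray, dosB: np.ndarray, ploidyA: int, ploidyB: int):
    """Per-SNP Rho numerator and denominator from individual dosages.

    ``dosA``/``dosB`` are (n_sites, n_individuals) integer dosage matrices
    (MISSING = -1) of two populations with constant within-population
    ploidy.  Returns (num, den) per site with Rho = num / den; sites where
    either population has < 2 non-missing individuals give NaN.

    Identity probabilities are built from gene pairs of *different*
    individuals only, so the within-individual stratum -- where polysomic
    heterozygosity lives -- never enters and the statistic is comparable
    between ploidies: with H_B the between-population diversity
    p_A(1-p_B) + p_B(1-p_A) and H_W the average within-population
    between-individual diversity, Rho = (H_B - H_W) / H_B.
    """
    h_wA, pA_hat, nA = _between_individual_diversity(dosA, ploidyA)
    h_wB, pB_hat, nB = _between_individual_diversity(dosB, ploidyB)
    valid = (nA >= 2) & (nB >= 2)
    h_b = pA_hat * (1.0 - pB_hat) + pB_hat * (1.0 - pA_hat)
    num = h_b - 0.5 * (h_wA + h_wB)
    num = np.where(valid, num, np.nan)
    den = np.where(valid, h_b, np.nan)
    return num, den


def rho(dosA, dosB, ploidyA: int, ploidyB: int):
    """Windowed Rho: ratio of summed per-SNP components (negative per-SNP
    estimates retained in sums, per-window value clamped at reporting)."""
    num, den = rho_components(dosA, dosB, ploidyA, ploidyB)
    total = np.nansum(den)
    value = float(np.nansum(num) / total) if total > 0 else float("nan")
    return num, den, value


# ---------------------------------------------------------------------------
# window aggregation

def window_ratio_of_sums(num, den, window_index, n_windows: int):
    """Sum per-SNP numerators/denominators into windows; NaN components are
    ignored.  Returns (n_windows,) ratio array, NaN where no data."""
    num = np.nan_to_num(np.asarray(num, dtype=float), nan=0.0)
    den_raw = np.asarray(den, dtype=float)
    den = np.nan_to_num(den_raw, nan=0.0)
    sums_n = np.bincount(window_index, weights=num, minlength=n_windows)
    sums_d = np.bincount(window_index, weights=den, minlength=n_windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums_d != 0, sums_n / sums_d, np.nan)
    return out
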