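"""Hard-sweep shape per candidate gene: magnitude and breadth from per-SNP
differentiation (Rho) tracks.

For a gene and population pair, the *curve region* is the 100-kbp stretch on
each side of the gene midpoint.  *Magnitude* is the highest raw per-SNP Rho
in the region minus the genome-wide mean Rho (smoother-independent by
design).  *Breadth* is measured on a locally fitted curve: local linear
regression with tricube weights whose span is selected by minimizing the
bias-corrected Akaike information criterion (AICC) over a fixed grid; the
breadth is the bp length of the contiguous above-threshold interval
containing the curve maximum, the threshold being twice the *background*
Rho (mean per-SNP Rho in the 200 kbp flanking the curve region on each
side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPAN_GRID = np.round(np.arange(0.10, 0.901, 0.05), 2)


@dataclass
class SweepProfile:
    gene_id: str
    pair_id: str
    region: tuple  # (lo, hi) bp
    magnitude: float
    breadth: float
    background_rho: float
    genomewide_rho: float
    span: float
    grid: np.ndarray = field(repr=False, default=None)
    curve: np.ndarray = field(repr=False, default=None)
    flags: set = field(default_factory=set)


def extract_region(
    track: pd.DataFrame,
    gene: pd.Series,
    flank: int = 100_000,
    scaffold_length: int | None = None,
):
    """SNPs of the per-SNP Rho track within gene midpoint +/- flank.

    ``track`` has columns scaffold, pos, rho.  Returns (region DataFrame,
    flags set); regions truncated at the scaffold edge get a flag.  Regions
    with < 20 SNPs are reported as None (profile skipped, logged)."""
    mid = (int(gene["start"]) + int(gene["end"])) // 2
    lo, hi = mid - flank, mid + flank
    flags = set()
    if lo < 1 or (scaffold_length is not None and hi > scaffold_length):
        flags.add("region_truncated")
        lo = max(lo, 1)
        if scaffold_length is not None:
            hi = min(hi, scaffold_length)
    sub = track[
        (track["scaffold"] == gene["scaffold"])
        & (track["pos"] >= lo)
        & (track["pos"] <= hi)
        & np.isfinite(track["rho"])
    ]
    if len(sub) < 20:
        logger.info("gene %s: %d SNPs in region, profile skipped", gene.get("gene_id", "?"), len(sub))
        return None, flags
    return sub.reset_index(drop=True), flags


def _loess_fit(x, y, span, x_out):
    """Local linear regression with tricube weights.

    Returns (fitted at x, trace of the smoother matrix, fitted at x_out).
    """
    n = len(x)
    k = max(2, int(np.ceil(span * n)))
    fitted = np.empty(n)
    trace = 0.0

    def local(x0, want_hat_index=None):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            raise ValueError("degenerate x: repeated positions exhaust the bandwidth")
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        dx = x - x0
        s0 = w.sum()
        s1 = (w * dx).sum()
        s2 = (w * dx**2).sum()
        denom = s0 * s2 - s1**2
        if denom <= 0:
            l_row = w / s0
        else:
            l_row = w * (s2 - dx * s1) / denom
        value = float(l_row @ y)
        hat = float(l_row[want_hat_index]) if want_hat_index is not None else 0.0
        return value, hat

    for i in range(n):
        fitted[i], hii = local(x[i], want_hat_index=i)
        trace += hii
    curve = np.array([local(x0)[0] for x0 in x_out])
    return fitted, trace, curve


def fit_profile(region: pd.DataFrame, grid_step: int = 1000, max_points: int = 1000):
    """AICC-selected loess curve over the region on a 1-kbp grid.

    AICC = log(sigma_hat^2) + (1 + tr(L)/n) / (1 - (tr(L) + 2)/n); the span
    minimizing it over SPAN_GRID is kept.  Dense regions are thinned to at
    most ``max_points`` evenly spaced SNPs before fitting (the raw points
    still drive magnitude elsewhere).

    Returns (grid positions, curve values, chosen span)."""
    x = region["pos"].to_numpy(dtype=float)
    y = region["rho"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all SNPs at one position")
    if len(x) > max_points:
        idx = np.linspace(0, len(x) - 1, max_points).astype(int)
        x, y = x[idx], y[idx]
    grid = np.arange(np.ceil(x.min() / grid_step) * grid_step, x.max() + 1, grid_step)
    if len(grid) == 0:
        grid = np.array([x.mean()])

    best = (np.inf, None, None)
    n = len(x)
    for span in SPAN_GRID:
        fitted, tr, curve = _loess_fit(x, y, span, grid)
        rss = float(((y - fitted) ** 2).sum())
        sigma2 = max(rss / n, 1e-300)
        if (tr + 2.0) >= n:
            continue
        aicc = np.log(sigma2) + (1.0 + tr / n) / (1.0 - (tr + 2.0) / n)
        if aicc < best[0]:
            best = (aicc, float(span), curve)
    if best[1] is None:
        raise ValueError("no admissible span on the candidate grid")
    return grid, best[2], best[1]


def sweep_magnitude(region: pd.DataFrame, genomewide_mean_rho: float) -> float:
    """Highest raw per-SNP Rho in the region minus the genome-wide mean
    (negative values allowed and flagged by callers)."""
    if region is None or len(region) == 0:
        raise ValueError("empty region")
    return float(np.nanmax(region["rho"].to_numpy(dtype=float)) - genomewide_mean_rho)


def sweep_breadth(grid: np.ndarray, curve: np.ndarray, background_rho: float):
    """Breadth in bp of the above-threshold interval containing the curve
    maximum, threshold = 2 x background Rho, with linear interpolation at
    the crossings.  Returns (breadth, flags)."""
    flags = set()
    thr = 2.0 * background_rho
    peak = int(np.nanargmax(curve))
    if curve[peak] < thr:
        flags.add("curve_never_crosses")
        return 0.0, flags

    # walk left from the peak to the crossing
    left = grid[0]
    crossed_left = False
    for i in range(peak, 0, -1):
        if curve[i - 1] < thr:
            frac = (curve[i] - thr) / (curve[i] - curve[i - 1])
            left = grid[i] - frac * (grid[i] - grid[i - 1])
            crossed_left = True
            break
    right = grid[-1]
    crossed_right = False
    for i in range(peak, len(curve) - 1):
        if curve[i + 1] < thr:
            frac = (curve[i] - thr) / (curve[i] - curve[i + 1])
            right = grid[i] + frac * (grid[i + 1] - grid[i])
            crossed_right = True
            break
    if not (crossed_left or crossed_right):
        flags.add("curve_all_above")
    return float(right - left), flags


def profile_gene(
    track: pd.DataFrame,
    gene: pd.Series,
    pair_id: str,
    genomewide_rho: float,
    flank: int = 100_000,
    background_flank: int = 200_000,
    scaffold_length: int | None = None,
    max_points: int = 1000,
) -> SweepProfile | None:
    """Full per-case profile: region, AICC loess, magnitude and breadth.

    Background Rho is the mean of per-SNP Rho in the ``background_flank``
    stretch beyond the curve region on each side; when no flanking SNPs
    exist the genome-wide mean is used instead (flagged)."""
    region, flags = extract_region(track, gene, flank, scaffold_length)
    if region is None:
        return None
    mid = (int(gene["start"]) + int(gene["end"])) // 2
    lo, hi = mid - flank, mid + flank
    flank_snps = track[
        (track["scaffold"] == gene["scaffold"])
        & (
            ((track["pos"] >= lo - background_flank) & (track["pos"] < lo))
            | ((track["pos"] > hi) & (track["pos"] <= hi + background_flank))
        )
    ]
    if np.isfinite(flank_snps["rho"]).sum() > 0:
        background = float(flank_snps["rho"].mean())
    else:
        background = genomewide_rho
        flags.add("background_from_genomewide")

    grid, curve, span = fit_profile(region, max_points=max_points)
    magnitude = sweep_magnitude(region, genomewide_rho)
    if magnitude < 0:
        flags.add("region_below_genomewide")
    breadth, bflags = sweep_breadth(grid, curve, background)
    flags |= bflags
    return SweepProfile(
        gene_id=str(gene.get("gene_id", "?")),
        pair_id=pair_id,
        region=(lo, hi),
        magnitude=magnitude,
        breadth=breadth,
        background_rho=background,
        genomewide_rho=genomewide_rho,
        span=span,
        grid=grid,
        curve=curve,
        flags=flags,
    )
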