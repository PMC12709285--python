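"""Mixed-ploidy VCF input, site/gene filters and ancestral polarization.

Genotypes are held as integer allele *dosages* (count of ALT alleles, or of
derived alleles after polarization) in a sites x samples matrix, with -1
marking missing calls.  Per-sample ploidy (2 or 4) comes from the sample
table; a tetraploid call ``0/0/0/1`` has dosage 1, a diploid ``0/1`` has
dosage 1.  Positions are 1-based as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MISSING = -1

SAMPLE_COLUMNS = ["sample_id", "population", "ploidy", "lineage"]


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample table invariants and return it unchanged.

    Required columns: sample_id, population, ploidy, lineage; optional
    soil_pc1.  Sample ids must be unique and each population must carry a
    single ploidy and a single lineage.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table lacks columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    if not samples["ploidy"].isin([2, 4]).all():
        raise ValueError("ploidy must be 2 or 4 for every sample")
    for col in ("ploidy", "lineage"):
        per_pop = samples.groupby("population")[col].nunique()
        bad = per_pop[per_pop > 1]
        if len(bad):
            raise ValueError(f"populations with mixed {col}: {bad.index.tolist()}")
    return samples


def read_sample_table(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    return validate_sample_table(samples)


@dataclass
class GenotypeMatrix:
    """Per-site, per-sample allele dosages with depth and missingness.

    Attributes
    ----------
    sites : DataFrame with columns scaffold, pos (1-based), ref, alt,
        ancestral (one of ``ref``/``alt``/``unknown``).
    dosage : (n_sites, n_samples) int16; ALT-allele count per genotype,
        -1 when missing.  After :func:`polarize` the count refers to the
        derived allele at sites with known ancestral state.
    depth : (n_sites, n_samples) int32 read depth (0 where absent).
    samples : sample table aligned with the dosage columns.
    """

    sites: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray
    samples: pd.DataFrame
    log: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def ploidies(self) -> np.ndarray:
        return self.samples["ploidy"].to_numpy()

    def take_sites(self, index) -> "GenotypeMatrix":
        return replace(
            self,
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[index],
            depth=self.depth[index],
        )

    def derived_dosage(self) -> np.ndarray:
        """Dosage of the derived allele; NaN where missing or unpolarized."""
        out = self.dosage.astype(float)
        out[self.dosage == MISSING] = np.nan
        unknown = (self.sites["ancestral"] == "unknown").to_numpy()
        out[unknown] = np.nan
        return out


@dataclass
class AlleleFreqTable:
    """Population x site derived/ALT-allele frequencies with chromosome counts."""

    populations: list
    sites: pd.DataFrame
    freq: np.ndarray  # (n_pops, n_sites), NaN where no data
    chroms: np.ndarray  # (n_pops, n_sites) int, chromosomes sampled

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)


def read_vcf(path, samples: pd.DataFrame) -> GenotypeMatrix:
    """Parse a (possibly mixed-ploidy) VCF into a GenotypeMatrix.

    GT fields must have arity equal to the sample's declared ploidy;
    half-missing calls (``./0/0/1``) are treated as fully missing.
    Multi-allelic records are dropped (count logged).
    """
    validate_sample_table(samples)
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    known = set(samples["sample_id"])
    unknown = [s for s in vcf_samples if s not in known]
    if unknown:
        raise ValueError(f"VCF samples without metadata: {unknown}")
    samples = (
        samples.set_index("sample_id").loc[vcf_samples].reset_index()
    )
    ploidies = samples["ploidy"].to_numpy()

    recs = []
    dosages = []
    depths = []
    n_multiallelic = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multiallelic += 1
            continue
        row_d = np.empty(len(vcf_samples), dtype=np.int16)
        row_dp = np.zeros(len(vcf_samples), dtype=np.int32)
        for i, name in enumerate(vcf_samples):
            call = rec.samples[i]
            gt = call.get("GT")
            if gt is None or len(gt) == 0 or all(a is None for a in gt):
                row_d[i] = MISSING
            elif any(a is None for a in gt):
                row_d[i] = MISSING  # half-called -> missing
            else:
                if len(gt) != ploidies[i]:
                    raise ValueError(
                        f"GT arity {len(gt)} != ploidy {ploidies[i]} for sample "
                        f"{name} at {rec.chrom}:{rec.pos}"
                    )
                row_d[i] = sum(gt)
            dp = call.get("DP")
            row_dp[i] = dp if dp is not None else 0
        recs.append((rec.chrom, rec.pos, rec.ref, rec.alts[0], "unknown"))
        dosages.append(row_d)
        depths.append(row_dp)
    vf.close()

    sites = pd.DataFrame(recs, columns=["scaffold", "pos", "ref", "alt", "ancestral"])
    gm = GenotypeMatrix(
        sites=sites,
        dosage=np.asarray(dosages, dtype=np.int16).reshape(len(sites), len(vcf_samples)),
        depth=np.asarray(depths, dtype=np.int32).reshape(len(sites), len(vcf_samples)),
        samples=samples,
        log={"multiallelic_dropped": n_multiallelic},
    )
    if n_multiallelic:
        logger.info("dropped %d multi-allelic records", n_multiallelic)
    return gm


def filter_sites(
    gm: GenotypeMatrix,
    min_depth: int = 8,
    max_missing_fraction: float = 0.5,
    maf: float = 0.0,
) -> GenotypeMatrix:
    """Depth-mask genotype cells, then drop sites by missingness and MAF.

    Cells with depth < ``min_depth`` are set missing first; sites whose
    missing fraction exceeds ``max_missing_fraction`` or whose minor-allele
    frequency (over all samples of the analysis set) falls below ``maf``
    are removed.  The filter log records counts per rule.
    """
    if not (0 <= max_missing_fraction <= 1 and 0 <= maf <= 0.5 and min_depth >= 0):
        raise ValueError("filter thresholds out of range")
    dosage = gm.dosage.copy()
    low = gm.depth < min_depth
    n_depth_masked = int((low & (dosage != MISSING)).sum())
    dosage[low] = MISSING

    miss_frac = (dosage == MISSING).mean(axis=1)
    keep_missing = miss_frac <= max_missing_fraction

    ok = dosage != MISSING
    alt = np.where(ok, dosage, 0).sum(axis=1).astype(float)
    tot = (ok * gm.ploidies[None, :]).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    site_maf = np.fmin(p, 1 - p)
    keep_maf = ~(site_maf < maf)  # NaN (all-missing) handled by missingness rule

    keep = keep_missing & keep_maf
    out = replace(
        gm,
        sites=gm.sites.loc[keep].reset_index(drop=True),
        dosage=dosage[keep],
        depth=gm.depth[keep],
        log={
            **gm.log,
            "cells_depth_masked": n_depth_masked,
            "sites_removed_missing": int((~keep_missing).sum()),
            "sites_removed_maf": int((keep_missing & ~keep_maf).sum()),
            "sites_kept": int(keep.sum()),
        },
    )
    return out


def mask_paralog_genes(
    gm: GenotypeMatrix,
    genes: pd.DataFrame,
    min_fixed_het: int = 5,
    min_pops: int = 2,
) -> np.ndarray:
    """Mask sites of genes with excess fixed heterozygosity (collapsed paralogs).

    A SNP is *fixed heterozygous* in a population when every non-missing
    sample has dosage == ploidy/2 (all diploids 0/1, all tetraploids with
    dosage 2).  Genes reaching >= ``min_fixed_het`` such SNPs in
    >= ``min_pops`` populations get all their sites masked (True in the
    returned boolean array).
    """
    if (gm.ploidies % 2).any():
        raise ValueError("odd ploidy: fixed heterozygosity undefined")
    half = (gm.ploidies // 2).astype(np.int16)
    pops = gm.samples["population"].to_numpy()
    fixed_het = {}
    for pop in pd.unique(pops):
        cols = np.flatnonzero(pops == pop)
        d = gm.dosage[:, cols]
        nonmiss = d != MISSING
        n_nonmiss = nonmiss.sum(axis=1)
        het = (d == half[cols][None, :]) | ~nonmiss
        fixed_het[pop] = het.all(axis=1) & (n_nonmiss > 0)

    mask = np.zeros(gm.n_sites, dtype=bool)
    pos = gm.sites["pos"].to_numpy()
    scaf = gm.sites["scaffold"].to_numpy()
    for _, g in genes.iterrows():
        in_gene = (scaf == g["scaffold"]) & (pos >= g["start"]) & (pos <= g["end"])
        if not in_gene.any():
            continue
        n_pops_hit = sum(
            int(fixed_het[pop][in_gene].sum()) >= min_fixed_het for pop in fixed_het
        )
        if n_pops_hit >= min_pops:
            mask |= in_gene
    return mask


def mask_excess_depth(
    gm: GenotypeMatrix, sd_multiplier: float = 2.0, min_individuals: int = 20
) -> np.ndarray:
    """Mask sites with excess coverage in many samples.

    Depth mean and SD are per sample over all sites; a sample "exceeds" at a
    site when depth > mean + sd_multiplier * SD (so a flat depth profile,
    SD = 0, never exceeds).  A site is masked when at least
    ``min_individuals`` samples exceed.
    """
    mean = gm.depth.mean(axis=0)
    sd = gm.depth.std(axis=0)
    exceed = gm.depth > (mean + sd_multiplier * sd)[None, :]
    return exceed.sum(axis=1) >= min_individuals


def polarize(gm: GenotypeMatrix, key: pd.DataFrame, threshold: float = 0.7) -> GenotypeMatrix:
    """Assign ancestral alleles from a polarization key and re-express dosages.

    ``key`` has columns scaffold, pos, p_anc_ref = P(REF allele ancestral).
    Sites with p >= threshold keep their ALT dosage (derived = ALT); sites
    with 1 - p >= threshold are flipped to ploidy - dosage (derived = REF);
    all others (and uncovered sites) are marked ``unknown`` and retained.
    """
    p = key["p_anc_ref"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("polarization probabilities outside [0, 1]")
    keyed = key.set_index(["scaffold", "pos"])["p_anc_ref"]
    idx = pd.MultiIndex.from_frame(gm.sites[["scaffold", "pos"]])
    probs = keyed.reindex(idx).to_numpy(dtype=float)

    ancestral = np.where(
        probs >= threshold, "ref", np.where((1 - probs) >= threshold, "alt", "unknown")
    )
    ancestral = np.where(pd.isna(probs), "unknown", ancestral)

    dosage = gm.dosage.copy()
    flip = ancestral == "alt"
    if flip.any():
        block = dosage[flip]
        miss = block == MISSING
        block = gm.ploidies[None, :].astype(np.int16) - block
        block[miss] = MISSING
        dosage[flip] = block
    sites = gm.sites.copy()
    sites["ancestral"] = ancestral
    return replace(gm, sites=sites, dosage=dosage)


def population_frequencies(gm: GenotypeMatrix, samples: pd.DataFrame | None = None) -> AlleleFreqTable:
    """Per-population allele frequencies: sum(dosage) / sum(ploidy) over
    non-missing samples.  All-missing yields NaN (absence, not zero)."""
    samples = gm.samples if samples is None else samples
    pops = samples["population"].to_numpy()
    ploidies = samples["ploidy"].to_numpy()
    pop_names = list(pd.unique(pops))
    freq = np.full((len(pop_names), gm.n_sites), np.nan)
    chroms = np.zeros((len(pop_names), gm.n_sites), dtype=np.int32)
    for pi, pop in enumerate(pop_names):
        cols = np.flatnonzero(pops == pop)
        d = gm.dosage[:, cols]
        ok = d != MISSING
        tot = (ok * ploidies[cols][None, :]).sum(axis=1)
        alt = np.where(ok, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        freq[pi] = f
        chroms[pi] = tot
    return AlleleFreqTable(populations=pop_names, sites=gm.sites.copy(), freq=freq, chroms=chroms)


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into a flat table.

    Returns columns gene_id, scaffold, start, end (1-based inclusive), strand.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", ""))
            rows.append((gene_id, parts[0], int(parts[3]), int(parts[4]), parts[6]))
    genes = pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in GFF3")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene with start > end")
    return genes
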