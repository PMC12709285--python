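"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: input loading and site filtering; per-pair
windowed F_ST scans with outlier calling and gene annotation; lineage-aware
parallel candidates; repeated-adaptation order-statistic scan; soil PCA and
environmental association; method intersection; per-case sweep profiling;
fixation/differentiation comparisons; adaptation-mode tallies and tests;
protein-interaction degree test.  A JSON manifest records parameters,
seeds, input checksums and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import candidate_stats, env_assoc, modes_stats, network
from . import popgen_stats as pg
from . import repeatability as rep
from . import scan, soil as soil_mod, sweep_profile, variants_io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; every threshold is echoed into the manifest."""

    input_dir: str = ""
    window_size: int = 1000
    min_snps: int = 10
    diversity_window_size: int = 50_000
    outlier_quantile: float = 0.01
    min_depth: int = 8
    max_missing_fraction: float = 0.5
    assoc_maf: float = 0.05
    assoc_max_missing: float = 0.1
    assoc_k: int = 2
    assoc_fdr_q: float = 0.1
    assoc_min_snps: int = 3
    repeatability_reps: int = 10_000
    repeatability_fdr_q: float = 0.05
    sweep_flank: int = 100_000
    background_flank: int = 200_000
    sweep_max_points: int = 600
    af_flank: int = 2000
    n_perm: int = 10_000
    downsample_individuals: int = 4
    downsample_chromosomes: int = 12
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.input_dir:
            raise ValueError("config missing required path: input_dir")
        for key in ("window_size", "min_snps", "n_perm", "repeatability_reps"):
            if getattr(self, key) < 1:
                raise ValueError(f"config value must be positive: {key}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pair_table(samples: pd.DataFrame) -> pd.DataFrame:
    s = samples.drop_duplicates("population")
    rows = []
    for pair_id, grp in s.groupby("pair_id", sort=False):
        cal = grp.loc[grp["soil_class"] == "calcareous", "population"].iloc[0]
        sil = grp.loc[grp["soil_class"] == "siliceous", "population"].iloc[0]
        rows.append((pair_id, int(grp["ploidy"].iloc[0]), grp["lineage"].iloc[0], cal, sil))
    return pd.DataFrame(rows, columns=["pair_id", "ploidy", "lineage", "calcareous", "siliceous"])


def pair_fst_windows(freqs, pair, windows, window_index):
    """Windowed Weir-Cockerham F_ST for one calcareous/siliceous pair."""
    ia = freqs.pop_index(pair["calcareous"])
    ib = freqs.pop_index(pair["siliceous"])
    ka = np.nan_to_num(freqs.freq[ia]) * freqs.chroms[ia]
    kb = np.nan_to_num(freqs.freq[ib]) * freqs.chroms[ib]
    num, den = pg.wc_fst_components(ka, freqs.chroms[ia], kb, freqs.chroms[ib])
    ok = window_index >= 0
    values = pg.window_ratio_of_sums(num[ok], den[ok], window_index[ok], len(windows))
    out = windows.copy()
    out["fst"] = np.clip(values, 0.0, 1.0)
    return out


def pair_rho(gm, samples, pair, windows, window_index):
    """Per-SNP and windowed Rho for one pair, plus the genome-wide mean."""
    pops = samples["population"].to_numpy()
    cols_a = np.flatnonzero(pops == pair["calcareous"])
    cols_b = np.flatnonzero(pops == pair["siliceous"])
    pl_a = int(samples["ploidy"].to_numpy()[cols_a[0]])
    pl_b = int(samples["ploidy"].to_numpy()[cols_b[0]])
    num, den = pg.rho_components(gm.dosage[:, cols_a], gm.dosage[:, cols_b], pl_a, pl_b)
    ok = window_index >= 0
    win_rho = pg.window_ratio_of_sums(num[ok], den[ok], window_index[ok], len(windows))
    total = np.nansum(den)
    genomewide = float(np.nansum(num) / total) if total > 0 else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(np.isfinite(den) & (den != 0), num / den, np.nan)
    track = gm.sites[["scaffold", "pos"]].copy()
    track["rho"] = np.clip(per_snp, 0.0, 1.0)
    wins = windows.copy()
    wins["rho"] = np.clip(win_rho, 0.0, 1.0)
    return track, wins, genomewide


def diversity_summary(gm, samples, config, seed) -> pd.DataFrame:
    """Per-population pi and Tajima's D on the 4-individual downsampled set,
    in 50-kbp windows with >= 10 SNPs."""
    down = pg.downsample_individuals(gm, config.downsample_individuals, seed)
    freqs = variants_io.population_frequencies(down)
    windows, widx = scan.build_windows(
        gm.sites, window_size=config.diversity_window_size, min_snps=config.min_snps
    )
    ok = widx >= 0
    rows = []
    for pi_idx, pop in enumerate(freqs.populations):
        f = freqs.freq[pi_idx][ok]
        n = freqs.chroms[pi_idx][ok]
        k = np.nan_to_num(f) * n
        h = pg.site_heterozygosity(k, n)
        pis, ds = [], []
        for w in range(len(windows)):
            sel = widx[ok] == w
            if not sel.any():
                continue
            hw = h[sel]
            valid = np.isfinite(hw)
            pi_val = float(np.nansum(hw)) / config.diversity_window_size
            seg = (k[sel] > 0) & (k[sel] < n[sel]) & valid
            S = int(seg.sum())
            n_mode = int(np.median(n[sel][valid])) if valid.any() else 0
            pis.append(pi_val)
            if S >= 1 and n_mode >= 4:
                ds.append(pg.tajimas_d(S, float(np.nansum(hw[seg])), n_mode))
        rows.append(
            (
                pop,
                float(np.mean(pis)) if pis else np.nan,
                float(np.nanmean(ds)) if ds else np.nan,
                len(pis),
            )
        )
    out = pd.DataFrame(rows, columns=["population", "pi", "tajimas_d", "n_windows"])
    meta = samples.drop_duplicates("population")[["population", "ploidy", "lineage"]]
    return out.merge(meta, on="population")


def run(config: RunConfig, outdir) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    indir = Path(config.input_dir)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
    }

    # ---- stage: load ------------------------------------------------------
    paths = {
        "vcf": indir / "synthetic.vcf",
        "samples": indir / "samples.tsv",
        "genes": indir / "genes.gff3",
        "soil": indir / "soil.tsv",
        "recombination": indir / "recombination.tsv",
        "edges": indir / "ppi_edges.tsv",
        "id_mapping": indir / "id_mapping.tsv",
        "modes": indir / "modes.tsv",
    }
    for k, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"stage load: missing input {k}: {p}")
        manifest["inputs"][k] = _checksum(p)
    samples = variants_io.read_sample_table(paths["samples"])
    gm = variants_io.read_vcf(paths["vcf"], samples)
    genes = variants_io.read_gff3_genes(paths["genes"])
    soil_table = pd.read_csv(paths["soil"], sep="\t")
    recomb = pd.read_csv(paths["recombination"], sep="\t")
    mapping = pd.read_csv(paths["id_mapping"], sep="\t")
    mode_cases = modes_stats.read_mode_cases(paths["modes"])
    manifest["stages"]["load"] = {"n_sites": gm.n_sites, "n_samples": gm.n_samples}

    # ---- stage: filter ----------------------------------------------------
    paralog_mask = variants_io.mask_paralog_genes(gm, genes)
    depth_mask = variants_io.mask_excess_depth(gm)
    keep = ~(paralog_mask | depth_mask)
    gm = gm.take_sites(np.flatnonzero(keep))
    gm = variants_io.filter_sites(
        gm, min_depth=config.min_depth, max_missing_fraction=config.max_missing_fraction
    )
    manifest["stages"]["filter"] = {
        "paralog_masked": int(paralog_mask.sum()),
        "depth_masked": int(depth_mask.sum()),
        **{k: v for k, v in gm.log.items() if isinstance(v, int)},
    }

    # ---- stage: soil ------------------------------------------------------
    soil_complete, _ = soil_mod.impute_soil(soil_table)
    pca = soil_mod.soil_pca(soil_complete)
    pc1 = pca["pc1"]
    pca["scores"].to_csv(outdir / "soil_scores.tsv", sep="\t", index=False)
    manifest["stages"]["soil"] = {
        "n_populations": len(pc1),
        "pc1_variance_fraction": float(pca["variance_fraction"][0]),
    }

    # ---- stage: windows + frequencies -------------------------------------
    freqs = variants_io.population_frequencies(gm)
    windows, widx = scan.build_windows(
        gm.sites, window_size=config.window_size, min_snps=config.min_snps
    )
    universe = sorted(scan.annotate_genes(windows, genes))
    manifest["stages"]["windows"] = {"n_windows": len(windows), "gene_universe": len(universe)}

    pairs = _pair_table(samples)
    soil_class = dict(
        samples.drop_duplicates("population")[["population", "soil_class"]].itertuples(
            index=False, name=None
        )
    )

    per_ploidy: dict = {}
    results_rows = []
    for ploidy in (2, 4):
        psub = pairs[pairs["ploidy"] == ploidy]
        pair_windows = {}
        pair_gene_sets = {}
        for _, pair in psub.iterrows():
            fst_w = pair_fst_windows(freqs, pair, windows, widx)
            pair_windows[pair["pair_id"]] = fst_w
            outliers = scan.outlier_windows(fst_w, "fst", config.outlier_quantile)
            pair_gene_sets[pair["pair_id"]] = scan.annotate_genes(outliers, genes)
        pair_lineage = dict(zip(psub["pair_id"], psub["lineage"]))
        fst_parallel = scan.parallel_candidates(pair_gene_sets, pair_lineage)

        # repeatability: one contrast per lineage
        lineage_first = psub.drop_duplicates("lineage")
        stat_matrix = pd.DataFrame(
            {
                row["pair_id"]: pair_windows[row["pair_id"]]["fst"]
                for _, row in lineage_first.iterrows()
            }
        )
        pmat = rep.empirical_pvalues(stat_matrix)
        rep_scan = rep.repeated_adaptation_scan(
            pmat,
            n_reps=config.repeatability_reps,
            seed=config.seed + ploidy,
            fdr_q=config.repeatability_fdr_q,
        )
        sig_windows = windows.loc[rep_scan.index[rep_scan["significant"]]]
        rep_genes = scan.annotate_genes(sig_windows, genes) if len(sig_windows) else set()

        # environmental association on the ploidy subset
        pcols = samples["ploidy"].to_numpy() == ploidy
        gm_p = variants_io.GenotypeMatrix(
            sites=gm.sites, dosage=gm.dosage[:, pcols], depth=gm.depth[:, pcols],
            samples=samples[pcols].reset_index(drop=True),
        )
        gm_p = variants_io.filter_sites(
            gm_p, min_depth=config.min_depth,
            max_missing_fraction=config.assoc_max_missing, maf=config.assoc_maf,
        )
        freqs_p = variants_io.population_frequencies(gm_p)
        soil_vec = np.array([pc1.get(p, np.nan) for p in freqs_p.populations])
        have_soil = np.isfinite(soil_vec)
        assoc = env_assoc.association_scan(
            freqs_p.freq[have_soil], soil_vec[have_soil],
            k=config.assoc_k, fdr_q=config.assoc_fdr_q,
        )
        sig = assoc.table["q"] < config.assoc_fdr_q
        sig_snps = gm_p.sites.loc[sig.to_numpy(), ["scaffold", "pos"]]
        assoc_genes = env_assoc.assoc_candidate_genes(sig_snps, genes, config.assoc_min_snps)

        top = scan.top_candidates(fst_parallel, rep_genes, assoc_genes)
        top.to_frame().to_csv(outdir / f"top_candidates_{ploidy}x.tsv", sep="\t", index=False)

        # Rho tracks, sweep profiles, fixation
        outlier_map = {
            (g, p) for p, gs in pair_gene_sets.items() for g in gs
        }
        tracks = {}
        genomewide_rho = {}
        rho_windows = {}
        for _, pair in psub.iterrows():
            track, wrho, gw = pair_rho(gm, samples, pair, windows, widx)
            tracks[pair["pair_id"]] = track
            rho_windows[pair["pair_id"]] = wrho
            genomewide_rho[pair["pair_id"]] = gw

        gix = genes.set_index("gene_id")
        profiles = []
        fix_rows = []
        fix12_rows = []
        gene_rho_rows = []
        freqs12 = pg.downsample_chromosomes(
            freqs, config.downsample_chromosomes, seed=config.seed + 100 + ploidy
        )
        for gene_id in sorted(top.gene_ids()):
            gene = gix.loc[gene_id]
            gene = pd.Series(
                {**gene.to_dict(), "gene_id": gene_id}
            )
            for _, pair in psub.iterrows():
                pid = pair["pair_id"]
                if (gene_id, pid) not in outlier_map:
                    continue
                prof = sweep_profile.profile_gene(
                    tracks[pid], gene, pid, genomewide_rho[pid],
                    flank=config.sweep_flank, background_flank=config.background_flank,
                    max_points=config.sweep_max_points,
                )
                if prof is not None:
                    profiles.append(prof)
                for freq_tab, sink in ((freqs, fix_rows), (freqs12, fix12_rows)):
                    fa = freq_tab.freq[freq_tab.pop_index(pair["calcareous"])]
                    fb = freq_tab.freq[freq_tab.pop_index(pair["siliceous"])]
                    sink.append(
                        (
                            gene_id,
                            pid,
                            candidate_stats.fixed_snp_count(
                                fa, fb,
                                freq_tab.sites["pos"].to_numpy(),
                                freq_tab.sites["scaffold"].to_numpy(),
                                gene, config.window_size,
                            ),
                        )
                    )
                wrho = rho_windows[pid]
                in_gene = (wrho["scaffold"] == gene["scaffold"]) & (
                    (wrho["start"] <= gene["end"]) & (wrho["end"] >= gene["start"])
                )
                if in_gene.any():
                    gene_rho_rows.append((gene_id, pid, float(wrho.loc[in_gene, "rho"].mean())))

        fix = candidate_stats.average_fixation(
            pd.DataFrame(fix_rows, columns=["gene_id", "pair_id", "count"]), outlier_map
        )
        fix12 = candidate_stats.average_fixation(
            pd.DataFrame(fix12_rows, columns=["gene_id", "pair_id", "count"]), outlier_map
        )
        reldiff = candidate_stats.relative_gene_differentiation(
            pd.DataFrame(gene_rho_rows, columns=["gene_id", "pair_id", "rho"]),
            genomewide_rho, outlier_map,
        )
        top_gene_frame = genes[genes["gene_id"].isin(top.gene_ids())]
        afd = candidate_stats.af_distribution(
            freqs, top_gene_frame, soil_class, flank=config.af_flank
        )
        afd.to_csv(outdir / f"af_distribution_{ploidy}x.tsv", sep="\t", index=False)
        prof_frame = pd.DataFrame(
            [
                (
                    p.gene_id, p.pair_id, p.magnitude, p.breadth,
                    p.background_rho, p.genomewide_rho, p.span, ",".join(sorted(p.flags)),
                )
                for p in profiles
            ],
            columns=[
                "gene_id", "pair_id", "magnitude", "breadth",
                "background_rho", "genomewide_rho", "span", "flags",
            ],
        )
        prof_frame.to_csv(outdir / f"sweep_profiles_{ploidy}x.tsv", sep="\t", index=False)

        per_ploidy[ploidy] = {
            "pair_gene_sets": pair_gene_sets,
            "fst_parallel": fst_parallel,
            "repeatability_genes": rep_genes,
            "assoc_genes": assoc_genes,
            "top": top,
            "profiles": prof_frame,
            "fixation": fix,
            "fixation_12chrom": fix12,
            "relative_differentiation": reldiff,
        }
        results_rows.append(
            {
                "ploidy": ploidy,
                "n_parallel": len(fst_parallel.gene_ids()),
                "n_repeatability_genes": len(rep_genes),
                "n_assoc_genes": len(assoc_genes),
                "n_top_candidates": len(top.gene_ids()),
                "mean_sweep_magnitude": float(prof_frame["magnitude"].mean())
                if len(prof_frame) else float("nan"),
                "mean_sweep_breadth": float(prof_frame["breadth"].mean())
                if len(prof_frame) else float("nan"),
                "mean_fixation": fix["mean_over_genes"],
                "mean_fixation_12chrom": fix12["mean_over_genes"],
                "fraction_genes_with_fixation": fix["fraction_genes_with_fixation"],
                "mean_relative_differentiation": reldiff["mean_ratio"],
            }
        )
        manifest["stages"][f"scan_{ploidy}x"] = {
            k: v for k, v in results_rows[-1].items() if isinstance(v, int)
        }

    # ---- stage: cross-ploidy comparisons ----------------------------------
    top2 = per_ploidy[2]["top"].gene_ids()
    top4 = per_ploidy[4]["top"].gene_ids()
    shared = top2 & top4
    overlap_p = scan.overlap_test(top2, top4, len(universe)) if top2 and top4 else float("nan")
    candidates_all = top2 | top4
    recomb_test = (
        scan.recombination_permutation_test(
            candidates_all, recomb, n_perm=config.n_perm, seed=config.seed + 7
        )
        if candidates_all
        else {"p": float("nan")}
    )

    tallies = modes_stats.tally_modes(mode_cases)
    mode_tests = modes_stats.mode_contingency_tests(mode_cases)
    bins = modes_stats.bin_selection_strength(mode_cases)
    tallies.to_csv(outdir / "mode_tallies.tsv", sep="\t", index=False)
    mode_tests.to_csv(outdir / "mode_tests.tsv", sep="\t", index=False)
    bins["proportions"].to_csv(outdir / "maxsel_bins.tsv", sep="\t", index=False)

    degrees = network.load_edges(paths["edges"])
    net_results = {}
    for ploidy, top_set in ((2, top2), (4, top4)):
        if not top_set:
            net_results[ploidy] = {"p": float("nan"), "observed_mean": float("nan")}
            continue
        cand_deg, unmapped = network.map_ids(top_set, mapping, degrees)
        if len(cand_deg) == 0:
            net_results[ploidy] = {"p": float("nan"), "observed_mean": float("nan")}
            continue
        net_results[ploidy] = network.degree_permutation_test(
            cand_deg, degrees, n_perm=config.n_perm, seed=config.seed + 11 + ploidy
        )
        net_results[ploidy]["unmapped"] = unmapped

    diversity = diversity_summary(gm, samples, config, seed=config.seed + 23)
    diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False)

    summary = pd.DataFrame(results_rows)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    manifest["stages"]["comparisons"] = {
        "shared_top_genes": len(shared),
        "overlap_p": overlap_p,
        "recombination_p": recomb_test["p"],
        "degree_test": {
            str(k): {kk: vv for kk, vv in v.items() if kk in ("p", "observed_mean")}
            for k, v in net_results.items()
        },
        "mean_degree": float(degrees.mean()),
    }
    manifest["seed"] = config.seed
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return {
        "manifest": manifest,
        "summary": summary,
        "per_ploidy": per_ploidy,
        "diversity": diversity,
        "shared_top_genes": shared,
        "overlap_p": overlap_p,
        "recombination_test": recomb_test,
        "mode_tallies": tallies,
        "mode_tests": mode_tests,
        "maxsel_bins": bins,
        "network": net_results,
    }
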