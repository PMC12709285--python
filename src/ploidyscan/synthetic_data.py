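"""Self-contained synthetic mixed-ploidy study generator with known truth.

Emulates a paired design: diploid and autotetraploid lineages, each holding
calcareous/siliceous population pairs, genotyped at biallelic SNPs.  Allele
frequencies follow a two-level Balding-Nichols hierarchy (ancestral ->
lineage -> population); selective sweeps are planted at chosen genes by
pushing the derived-allele frequency of siliceous populations toward
fixation with a triangular positional kernel, with a hard frequency cap
below 1 in tetraploids mimicking the slower approach to fixation of
(partially) dominant variants under polysomic inheritance.  SNPs are
unlinked except for this deterministic within-sweep track.

Everything downstream of variant calling is derivable from the bundle:
VCF, sample table, gene models (GFF3), soil chemistry, per-gene
recombination rates, a protein-interaction edge list with gene/protein ID
mapping, per-case adaptation-mode assignments, and a truth table of
planted sweeps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .variants_io import MISSING

MAXSEL_BINS = (0.0001, 0.001, 0.01, 0.05, 0.5)

#: half-maximum point of the push fraction gamma(s) = s / (s + S_HALF)
S_HALF = 0.01


@dataclass(frozen=True)
class SweepLocus:
    gene_id: str
    s: float  # selection coefficient; also sets the planted maxSel bin
    mode: str  # denovo | standing | migration
    ploidies: tuple = (2, 4)


def default_sweeps() -> list:
    """Planted sweeps used by the default configuration.

    A mix of sources and strengths: strong shared standing sweeps, a
    diploid-only de novo sweep, a tetraploid-only migration sweep, and two
    weaker shared sweeps, each centred on a mid-scaffold gene so the
    100-kbp profiling regions fit inside the scaffold.
    """
    return [
        SweepLocus("g0026", 0.5, "standing", (2, 4)),
        SweepLocus("g0076", 0.5, "denovo", (2,)),
        SweepLocus("g0126", 0.5, "migration", (4,)),
        SweepLocus("g0176", 0.05, "standing", (2, 4)),
        SweepLocus("g0226", 0.01, "denovo", (2, 4)),
        SweepLocus("g0276", 0.5, "standing", (2, 4)),
    ]


@dataclass
class SimConfig:
    """Synthetic-study configuration.

    ``pops_per_lineage`` counts populations (must be even): consecutive
    populations form calcareous/siliceous pairs, so the default of 2 gives
    one soil contrast per lineage, and with four lineages per ploidy the
    bundle carries four lineage-distinct contrasts per ploidy.
    """

    n_lineages_per_ploidy: int = 4
    pops_per_lineage: int = 2
    inds_per_pop: int = 6
    n_scaffolds: int = 6
    scaffold_len: int = 300_000
    snp_density: float = 0.02
    F_lineage: float = 0.15
    F_pop: float = 0.05
    sweep_loci: list = field(default_factory=default_sweeps)
    tetraploid_freq_cap: float = 0.85
    missing_rate: float = 0.05
    mean_depth: int = 25
    sweep_half_width: int = 20_000
    gene_length: int = 3_000
    gene_spacing: int = 6_000
    beta_shape: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        def check(name, cond):
            if not cond:
                raise ValueError(f"invalid SimConfig parameter: {name}")

        check("n_lineages_per_ploidy", self.n_lineages_per_ploidy >= 1)
        check("pops_per_lineage", self.pops_per_lineage >= 2 and self.pops_per_lineage % 2 == 0)
        check("inds_per_pop", self.inds_per_pop >= 1)
        check("n_scaffolds", self.n_scaffolds >= 1)
        check("scaffold_len", self.scaffold_len >= 10_000)
        check("snp_density", 0 < self.snp_density <= 1 and np.isfinite(self.snp_density))
        check("F_lineage", 0 <= self.F_lineage < 1)
        check("F_pop", 0 <= self.F_pop < 1)
        check("tetraploid_freq_cap", 0 < self.tetraploid_freq_cap <= 1)
        check("missing_rate", 0 <= self.missing_rate < 1)
        check("mean_depth", self.mean_depth >= 1)
        check("sweep_half_width", self.sweep_half_width >= 1)
        check("beta_shape", self.beta_shape > 0)
        for sw in self.sweep_loci:
            check("sweep_loci.s", 0 < sw.s <= 1 and np.isfinite(sw.s))
            check("sweep_loci.mode", sw.mode in ("denovo", "standing", "migration"))
            check("sweep_loci.ploidies", all(p in (2, 4) for p in sw.ploidies))


@dataclass
class SyntheticBundle:
    """In-memory synthetic study with ground truth."""

    config: SimConfig
    sites: pd.DataFrame  # scaffold, pos, ref, alt
    populations: list
    pop_freq: np.ndarray  # (n_pops, n_snps) true derived frequencies
    dosage: np.ndarray  # (n_snps, n_samples) int16, MISSING for missing
    depth: np.ndarray
    samples: pd.DataFrame
    genes: pd.DataFrame
    soil: pd.DataFrame
    recombination: pd.DataFrame
    edges: pd.DataFrame
    id_mapping: pd.DataFrame
    modes: pd.DataFrame
    truth: pd.DataFrame

    @property
    def pairs(self) -> pd.DataFrame:
        """One row per calcareous/siliceous contrast: pair_id, ploidy,
        lineage, calcareous population, siliceous population."""
        s = self.samples.drop_duplicates("population")
        rows = []
        for pair_id, grp in s.groupby("pair_id", sort=False):
            cal = grp.loc[grp["soil_class"] == "calcareous", "population"].iloc[0]
            sil = grp.loc[grp["soil_class"] == "siliceous", "population"].iloc[0]
            rows.append(
                (pair_id, int(grp["ploidy"].iloc[0]), grp["lineage"].iloc[0], cal, sil)
            )
        return pd.DataFrame(
            rows, columns=["pair_id", "ploidy", "lineage", "calcareous", "siliceous"]
        )


def _gene_models(config: SimConfig) -> pd.DataFrame:
    rows = []
    gid = 0
    for sc in range(config.n_scaffolds):
        start = 1
        while start + config.gene_length - 1 <= config.scaffold_len:
            gid += 1
            rows.append(
                (
                    f"g{gid:04d}",
                    f"scaffold_{sc + 1}",
                    start,
                    start + config.gene_length - 1,
                    "+" if gid % 2 else "-",
                )
            )
            start += config.gene_spacing
    return pd.DataFrame(rows, columns=["gene_id", "scaffold", "start", "end", "strand"])


def _population_layout(config: SimConfig) -> pd.DataFrame:
    rows = []
    for ploidy in (2, 4):
        for li in range(1, config.n_lineages_per_ploidy + 1):
            lineage = f"{ploidy}x_L{li}"
            for k in range(config.pops_per_lineage // 2):
                pair_id = f"pair_{ploidy}x_{li}_{k + 1}"
                for soil_class in ("calcareous", "siliceous"):
                    pop = f"{ploidy}x_L{li}_p{k + 1}_{soil_class[:3]}"
                    rows.append((pop, ploidy, lineage, pair_id, soil_class))
    return pd.DataFrame(
        rows, columns=["population", "ploidy", "lineage", "pair_id", "soil_class"]
    )


def _bn_draw(rng, p_anc: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols draw around ancestral frequencies p_anc."""
    if F <= 1e-12:
        return p_anc.copy()
    p = np.clip(p_anc, 1e-4, 1 - 1e-4)
    c = (1 - F) / F
    return rng.beta(p * c, (1 - p) * c)


def _apply_sweeps(config, layout, sites, genes, p0, lineage_freq, pop_freq):
    """Push siliceous-population derived frequencies toward fixation at
    sweep loci; returns a boolean (n_pops, n_snps) matrix of capped cells."""
    pop_idx = {p: i for i, p in enumerate(layout["population"])}
    genes_ix = genes.set_index("gene_id")
    scaf = sites["scaffold"].to_numpy()
    pos = sites["pos"].to_numpy()
    capped = np.zeros_like(pop_freq, dtype=bool)
    for sw in config.sweep_loci:
        g = genes_ix.loc[sw.gene_id]
        mid = (int(g["start"]) + int(g["end"])) // 2
        snp_mask = (scaf == g["scaffold"]) & (
            np.abs(pos - mid) <= config.sweep_half_width
        )
        if not snp_mask.any():
            continue
        tri = 1.0 - np.abs(pos[snp_mask] - mid) / config.sweep_half_width
        gamma = sw.s / (sw.s + S_HALF)
        for ploidy in sw.ploidies:
            target = 1.0 if ploidy == 2 else config.tetraploid_freq_cap
            sil = layout[(layout["ploidy"] == ploidy) & (layout["soil_class"] == "siliceous")]
            cols = [pop_idx[p] for p in sil["population"]]
            push = gamma * tri
            if sw.mode == "standing":
                shared = p0[snp_mask] + (target - p0[snp_mask]) * push
                for c in cols:
                    pop_freq[c, snp_mask] = shared
            elif sw.mode == "migration":
                first = pop_freq[cols[0], snp_mask]
                moved = first + (target - first) * push
                for c in cols:
                    pop_freq[c, snp_mask] = moved
            else:  # denovo: independent elevation per population
                for c in cols:
                    base = pop_freq[c, snp_mask]
                    pop_freq[c, snp_mask] = base + (target - base) * push
            if target < 1.0:
                for c in cols:
                    capped[c, snp_mask] = True
    return capped


def _enforce_cap(dosage_block: np.ndarray, ploidy: int, cap: float, site_rows: np.ndarray):
    """Hard-cap the realized derived frequency of a population at sweep
    sites: sampled dosages are reduced (from the largest genotypes down)
    until the population frequency is <= cap."""
    for r in site_rows:
        row = dosage_block[r]
        ok = row != MISSING
        total = int(ok.sum()) * ploidy
        if total == 0:
            continue
        allowed = int(np.floor(cap * total))
        excess = int(row[ok].sum()) - allowed
        while excess > 0:
            j = int(np.argmax(np.where(ok, row, -1)))
            if row[j] <= 0:
                break
            take = min(excess, int(row[j]))
            row[j] -= take
            excess -= take


def _soil_table(rng, layout: pd.DataFrame) -> pd.DataFrame:
    """Soil chemistry with class-separated pH/Ca/CEC so that PC1 of the
    standardized table captures the calcareous-siliceous gradient."""
    means = {
        # column: (calcareous mean, siliceous mean, sd)
        "pH_H2O": (7.8, 5.0, 0.25),
        "pH_KCl": (7.3, 4.4, 0.25),
        "bioavailable_Ca": (150.0, 25.0, 15.0),
        "total_Ca": (420.0, 60.0, 40.0),
        "total_Mg": (85.0, 40.0, 10.0),
        "total_K": (14.0, 26.0, 4.0),
        "total_Na": (8.0, 6.0, 1.5),
        "CEC": (185.0, 90.0, 20.0),
    }
    pops = layout.drop_duplicates("population")
    out = {"population": pops["population"].to_numpy()}
    is_cal = (pops["soil_class"] == "calcareous").to_numpy()
    for col, (mc, ms, sd) in means.items():
        base = np.where(is_cal, mc, ms)
        vals = rng.normal(base, sd)
        if col.startswith("pH"):
            vals = np.clip(vals, 0.5, 13.5)
        else:
            vals = np.clip(vals, 0.5, None)
        out[col] = vals
    soil = pd.DataFrame(out)
    # a few missing cells in imputable columns (predictors stay complete)
    n = len(soil)
    for col in ("total_Mg", "CEC"):
        holes = rng.random(n) < 0.1
        soil.loc[holes, col] = np.nan
    return soil


def _network_tables(rng, genes: pd.DataFrame):
    n_genes = len(genes)
    n_extra = 200
    g = nx.barabasi_albert_graph(n_genes + n_extra, 3, seed=int(rng.integers(2**31 - 1)))
    perm = rng.permutation(n_genes + n_extra)
    names = {}
    for node in g.nodes:
        k = perm[node]
        names[node] = (
            "P" + genes["gene_id"].iloc[k][1:] if k < n_genes else f"PX{k - n_genes:04d}"
        )
    edges = pd.DataFrame(
        [(names[a], names[b]) for a, b in g.edges], columns=["protein1", "protein2"]
    )
    edges["combined_score"] = rng.integers(150, 1000, size=len(edges))
    mapping = pd.DataFrame(
        {"gene_id": genes["gene_id"], "protein_id": "P" + genes["gene_id"].str[1:]}
    )
    mapping = mapping.iloc[2:].reset_index(drop=True)  # two genes left unmapped
    return edges, mapping


def _nearest_bin(s: float) -> float:
    bins = np.asarray(MAXSEL_BINS)
    return float(bins[np.argmin(np.abs(np.log10(bins) - np.log10(s)))])


def _mode_fixture(rng, config: SimConfig, layout: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-case adaptation-mode assignments for each planted sweep along
    each lineage-distinct quartet of its affected ploidies, plus a few
    neutral cases on non-sweep genes (excluded from tallies downstream)."""
    from .modes_stats import enumerate_quartets

    contrasts = layout.drop_duplicates("pair_id")[["pair_id", "lineage", "ploidy"]]
    rows = []
    for sw in config.sweep_loci:
        for ploidy in sw.ploidies:
            sub = contrasts[contrasts["ploidy"] == ploidy]
            quartets = enumerate_quartets(
                list(zip(sub["pair_id"], sub["lineage"]))
            )
            for qi, (c1, c2) in enumerate(quartets):
                rows.append(
                    (
                        sw.gene_id,
                        f"{ploidy}x_q{qi + 1}",
                        ploidy,
                        sw.mode,
                        _nearest_bin(sw.s),
                        float(rng.normal(-500, 50)),
                    )
                )
    sweep_ids = {sw.gene_id for sw in config.sweep_loci}
    neutral_pool = [g for g in genes["gene_id"] if g not in sweep_ids][:4]
    for g in neutral_pool:
        ploidy = int(rng.choice([2, 4]))
        rows.append((g, f"{ploidy}x_q1", ploidy, "neutral", 0.0001, float(rng.normal(-500, 50))))
    return pd.DataFrame(
        rows, columns=["gene_id", "quartet_id", "ploidy", "mode", "maxSel", "mcl"]
    )


def simulate_dataset(config: SimConfig) -> SyntheticBundle:
    """Generate the full synthetic study.  Same config + seed gives a
    byte-identical bundle when written."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_models(config)
    known = set(genes["gene_id"])
    for sw in config.sweep_loci:
        if sw.gene_id not in known:
            raise ValueError(f"invalid SimConfig parameter: sweep_loci gene {sw.gene_id}")
    layout = _population_layout(config)

    # -- sites ---------------------------------------------------------------
    site_frames = []
    for sc in range(config.n_scaffolds):
        n_snps = int(round(config.snp_density * config.scaffold_len))
        pos = np.sort(rng.choice(config.scaffold_len, size=n_snps, replace=False)) + 1
        site_frames.append(pd.DataFrame({"scaffold": f"scaffold_{sc + 1}", "pos": pos}))
    sites = pd.concat(site_frames, ignore_index=True)
    n_total = len(sites)
    base = rng.integers(0, 4, size=n_total)
    shift = rng.integers(1, 4, size=n_total)
    alphabet = np.array(list("ACGT"))
    sites["ref"] = alphabet[base]
    sites["alt"] = alphabet[(base + shift) % 4]

    # -- hierarchical frequencies -------------------------------------------
    p0 = np.clip(rng.beta(config.beta_shape, config.beta_shape, size=n_total), 0.01, 0.99)
    lineage_freq = {}
    for ploidy in (2, 4):
        for li in range(1, config.n_lineages_per_ploidy + 1):
            lineage_freq[f"{ploidy}x_L{li}"] = _bn_draw(rng, p0, config.F_lineage)
    pop_freq = np.empty((len(layout), n_total))
    for i, row in layout.iterrows():
        pop_freq[i] = np.clip(
            _bn_draw(rng, lineage_freq[row["lineage"]], config.F_pop), 0.0, 1.0
        )
    capped = _apply_sweeps(config, layout, sites, genes, p0, lineage_freq, pop_freq)
    pop_freq = np.clip(pop_freq, 0.0, 1.0)

    # -- genotypes -----------------------------------------------------------
    sample_rows = []
    dosage_cols = []
    for i, row in layout.iterrows():
        ploidy = int(row["ploidy"])
        block = rng.binomial(
            ploidy, pop_freq[i][:, None], size=(n_total, config.inds_per_pop)
        ).astype(np.int16)
        if capped[i].any():
            _enforce_cap(block, ploidy, config.tetraploid_freq_cap, np.flatnonzero(capped[i]))
        dosage_cols.append(block)
        for m in range(config.inds_per_pop):
            sample_rows.append(
                (
                    f"{row['population']}_i{m + 1}",
                    row["population"],
                    ploidy,
                    row["lineage"],
                    row["pair_id"],
                    row["soil_class"],
                )
            )
    dosage = np.concatenate(dosage_cols, axis=1)
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "population", "ploidy", "lineage", "pair_id", "soil_class"],
    )
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = MISSING
    depth = rng.poisson(config.mean_depth, size=dosage.shape).astype(np.int32)

    # -- side tables ---------------------------------------------------------
    soil = _soil_table(rng, layout)
    recomb = pd.DataFrame(
        {"gene_id": genes["gene_id"], "rate": rng.lognormal(0.0, 0.5, size=len(genes))}
    )
    edges, mapping = _network_tables(rng, genes)
    modes = _mode_fixture(rng, config, layout, genes)
    truth_rows = []
    gix = genes.set_index("gene_id")
    for sw in config.sweep_loci:
        g = gix.loc[sw.gene_id]
        truth_rows.append(
            (
                sw.gene_id,
                g["scaffold"],
                int(g["start"]),
                int(g["end"]),
                (int(g["start"]) + int(g["end"])) // 2,
                sw.s,
                sw.mode,
                ",".join(str(p) for p in sw.ploidies),
                config.sweep_half_width,
                config.tetraploid_freq_cap,
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_id", "scaffold", "start", "end", "mid",
            "s", "mode", "ploidies", "half_width", "tetraploid_freq_cap",
        ],
    )
    return SyntheticBundle(
        config=config,
        sites=sites,
        populations=list(layout["population"]),
        pop_freq=pop_freq,
        dosage=dosage,
        depth=depth,
        samples=samples,
        genes=genes,
        soil=soil,
        recombination=recomb,
        edges=edges,
        id_mapping=mapping,
        modes=modes,
        truth=truth,
    )


def _gt_string(dosage: int, ploidy: int) -> str:
    if dosage == MISSING:
        return "/".join(["."] * ploidy)
    return "/".join(["0"] * (ploidy - dosage) + ["1"] * dosage)


def write_vcf(bundle: SyntheticBundle, path) -> None:
    config = bundle.config
    ploidies = bundle.samples["ploidy"].to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ploidyscan-synthetic\n")
        for sc in range(config.n_scaffolds):
            fh.write(f"##contig=<ID=scaffold_{sc + 1},length={config.scaffold_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(bundle.samples["sample_id"])
            + "\n"
        )
        scaffolds = bundle.sites["scaffold"].to_numpy()
        positions = bundle.sites["pos"].to_numpy()
        refs = bundle.sites["ref"].to_numpy()
        alts = bundle.sites["alt"].to_numpy()
        for r in range(len(bundle.sites)):
            cells = [
                _gt_string(int(bundle.dosage[r, c]), int(ploidies[c]))
                + ":"
                + str(int(bundle.depth[r, c]))
                for c in range(bundle.dosage.shape[1])
            ]
            fh.write(
                f"{scaffolds[r]}\t{positions[r]}\t.\t{refs[r]}\t{alts[r]}\t.\tPASS\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['scaffold']}\tploidyscan\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundle(bundle: SyntheticBundle, directory, overwrite: bool = False) -> dict:
    """Write all bundle files plus a JSON manifest with checksums.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"directory {directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)

    paths = {
        "vcf": directory / "synthetic.vcf",
        "samples": directory / "samples.tsv",
        "genes": directory / "genes.gff3",
        "soil": directory / "soil.tsv",
        "recombination": directory / "recombination.tsv",
        "edges": directory / "ppi_edges.tsv",
        "id_mapping": directory / "id_mapping.tsv",
        "modes": directory / "modes.tsv",
        "truth": directory / "truth.tsv",
    }
    write_vcf(bundle, paths["vcf"])
    write_gff3(bundle.genes, paths["genes"])
    for key, df in (
        ("samples", bundle.samples),
        ("soil", bundle.soil),
        ("recombination", bundle.recombination),
        ("edges", bundle.edges),
        ("id_mapping", bundle.id_mapping),
        ("modes", bundle.modes),
        ("truth", bundle.truth),
    ):
        df.to_csv(paths[key], sep="\t", index=False)

    manifest = {
        "files": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in paths.items()},
        "seed": bundle.config.seed,
        "n_sites": int(len(bundle.sites)),
        "n_samples": int(len(bundle.samples)),
        "n_genes": int(len(bundle.genes)),
        "n_sweeps": int(len(bundle.truth)),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
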