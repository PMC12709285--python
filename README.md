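# ploidyscan

Ploidy-aware genome scans for repeated adaptation in mixed
diploid/autotetraploid populations.

Whole-genome duplication changes how natural selection plays out: extra
chromosome sets mask recessive variants, slow fixation, and enlarge the
pool of standing variation.  Testing those predictions requires comparing
footprints of selection between diploid and autotetraploid populations
facing the same environmental contrast — here, calcareous (high-pH,
calcium-rich) versus siliceous (low-pH) soils colonized repeatedly by
multiple genetic lineages of each ploidy.  `ploidyscan` implements that
comparison as a reusable, tested pipeline for population geneticists
working with mixed-ploidy resequencing data:

- mixed-ploidy VCF input (`0/1` and `0/0/0/1` genotypes) with the standard
  site filters, paralog and excess-depth masks, and ancestral polarization;
- diversity and differentiation statistics that remain comparable across
  ploidies: windowed pi, Tajima's D (with per-population downsampling),
  Weir–Cockerham F_ST, and Rho — an F_ST analogue whose identity
  probabilities exclude within-individual gene pairs, so polysomic
  heterozygosity cancels: `Rho = (H_B − H_W) / H_B` with `H_W` the
  between-individual within-population diversity;
- replicated top-1% outlier scans in 1-kbp windows, gene annotation, and
  lineage-aware parallel candidates;
- an order-statistic test of repeated adaptation across 3–12 lineages
  (Beta order-statistic tails `q_a = BetaCDF(p_(a); a, L−a+1)` with
  Dunn–Šidák combination, Monte-Carlo calibration and FDR);
- latent-factor-corrected association of population allele frequencies
  with the soil PC1 gradient;
- hard-sweep shape per candidate gene: *magnitude* (peak Rho above the
  genome-wide mean) and *breadth* (bp above twice the local background,
  from an AICC-tuned local regression);
- fixation counts (strict 0-vs-1 divergence, full and 12-chromosome
  standardized), adaptation-mode tallies with Yates-corrected chi-square
  and Fisher tests, and a protein-interaction degree permutation test;
- a self-contained synthetic study generator (Balding–Nichols hierarchy,
  planted sweeps with a tetraploid frequency cap, correlated soil
  chemistry, scale-free interaction network) with known ground truth.

## Worked example

Desk-scale statistics need no data files.  Comparing how often the two
ploidies adapt from each evolutionary source, using published per-quartet
case counts (44/81 standing-variation cases in diploids vs 28/47 in
tetraploids; 15/81 vs 1/47 de novo):

```python
from ploidyscan.modes_stats import yates_chisq, enumerate_quartets

res = yates_chisq([[44, 37], [28, 19]])
print(f"standing variation: chi2(1) = {res['statistic']:.2f}, p = {res['p']:.4f}")
res = yates_chisq([[15, 66], [1, 46]])
print(f"de novo:            chi2(1) = {res['statistic']:.2f}, p = {res['p']:.4f}")
quartets = enumerate_quartets([(f"pair{i}", f"L{i}") for i in range(6)])
print(f"quartets from 6 lineage-distinct contrasts: {len(quartets)}")
```

prints

```
standing variation: chi2(1) = 0.15, p = 0.6945
de novo:            chi2(1) = 5.88, p = 0.0153
quartets from 6 lineage-distinct contrasts: 15
```

— the standing-variation share does not differ between ploidies, while
adaptation from de novo mutation is almost absent in tetraploids.

The full pipeline runs from the command line.  Generate a small synthetic
study with planted sweeps and analyse it end to end:

```bash
ploidyscan simulate --outdir demo --seed 1 --tiny
ploidyscan run-all --input-dir demo --outdir demo_run --seed 1
```

which ends with the per-ploidy summary (also written to
`demo_run/summary.tsv`; columns for the repeatability/association gene
counts and breadth omitted here for width):

```
 ploidy  n_parallel  n_top_candidates  mean_sweep_magnitude  mean_fixation  fraction_genes_with_fixation
      2           2                 2              0.829478            9.5                           1.0
      4           1                 1              0.709700            0.0                           0.0
```

Both planted sweeps surface as diploid top candidates with fixed (0 vs 1)
differences, while the tetraploid frequency cap (0.85) leaves the same
sweeps detectable — similar magnitude — but without any fixed SNPs: the
fixation contrast between ploidies falls out of the dosage model, not from
separate code paths.  `demo_run/` also contains per-case sweep profiles,
candidate lists with per-method provenance, mode tallies and the run
manifest (parameters, seeds, input checksums), which is byte-identical
across reruns with the same seed.

The same stages are available as a library (`ploidyscan.popgen_stats`,
`.scan`, `.repeatability`, `.env_assoc`, `.soil`, `.sweep_profile`,
`.candidate_stats`, `.modes_stats`, `.network`, `.pipeline`).

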