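# cnpskit

Curation and statistical analysis of **carbon, nitrogen, phosphorus and
sulfur (CNPS) biogeochemical-cycling genes** from shotgun-metagenomic
annotation tables.

Microbial communities drive elemental cycling through functional genes
(methanogenesis, nitrification, denitrification, sulfate reduction, ...).
After standard upstream processing — assembly, gene prediction, KofamScan
KEGG-orthology (KO) annotation, DIAMOND-vs-NR taxonomy, and TPM gene
abundance estimation — a researcher is left with large flat tables and the
tedious job of curating the handful of ecologically meaningful cycle genes
out of them. `cnpskit` automates that downstream step for microbial
ecologists and biogeochemists: it ships a curated ontology of **42 cycling
processes represented by 119 KO entries** (7 carbon processes / 22 KOs, 18
nitrogen / 48, 2 phosphorus / 5, 15 sulfur / 47; the pmoABC/amoABC subunits
are shared between methane and ammonia oxidation) and turns the five
standard input tables into process-level profiles, statistics, host-taxon
breakdowns and publication-style figures.

## What it computes

Given the five tab-delimited inputs (KO×sample abundance with a trailing
`Description` column; `SampleID/Group`; `GeneID/KO`; `GeneID/Taxonomy`;
gene×sample abundance), per element:

- **Process abundance** — cumulative abundance of each process *p* in sample
  *s*: `A[p,s] = Σ_{k∈KOs(p)} ko[k,s]`, and presence calls (a process is
  detected iff some KO has non-zero abundance *and* annotates ≥1 gene).
- **Differential statistics** — Shapiro-Wilk normality gate; Welch *t* +
  Wilcoxon rank-sum (2 groups) or one-way ANOVA + Kruskal-Wallis (≥3 groups),
  both families always reported, Benjamini-Hochberg adjustment across the
  element's processes; pairwise fold changes of group means
  `log2((m_t+ε)/(m_r+ε))` with a scale-relative pseudocount ε.
- **Host taxa** — genes carrying each detected process's KOs joined to their
  NR lineages and summed per taxon at six ranks (phylum → species), with
  group-mean relative abundances.
- **β-diversity** — Bray-Curtis dissimilarity `Σ|x−y|/Σ(x+y)` on the
  element's KO submatrix; PCoA, PCA and NMDS (Kruskal stress-1) ordination;
  PERMANOVA (pseudo-F), ANOSIM (R) and MRPP (chance-corrected A) with seeded
  label permutations, `p = (1 + #{perm ≥ obs})/(1 + N_perm)`.
- **Figures & results tree** — fold-change heatmaps, host heatmaps,
  ordination plots, per-element cycle diagrams with abundance tiles, all
  written into a `Results/{Carbon,Nitrogen,Phosphorus,Sulfur}/` tree with a
  JSON manifest and run log; identical seeded runs are byte-identical.

A synthetic-data generator (`cnpskit.synth_bench`) produces the same five
tables with a known truth set (present KOs/processes, differential effects,
lognormal noise, dropout) and scores detection with FNR / FPR / accuracy.

## Worked example

```python
import cnpskit as ck

mapping = ck.load_mapping()                  # packaged 42-process ontology
bundle, truth = ck.example_bundle(seed=42)   # synthetic 2 groups x 3 samples

pam = ck.aggregate(bundle.ko, mapping, "C")
print(pam.values.round(2).iloc[:4, :3])
```
```
                           G1_S1  G1_S2  G1_S3
aerobic_carbon_fixation     7.21   5.33   6.16
anaerobic_carbon_fixation  12.89  11.23  12.02
aerobic_respiration        10.57  19.53  11.92
fermentation                7.78   7.88   9.02
```
Each cell is the cumulative abundance (input units, typically TPM) of the
process's KOs in that sample.

```python
fc = ck.fold_change(pam, bundle.group, "G1", "G2")
print(fc.table[["mean_ref", "mean_target", "log2fc"]].round(3).head(4))
```
```
                           mean_ref  mean_target  log2fc
aerobic_carbon_fixation       6.232        6.318   0.015
anaerobic_carbon_fixation    12.046       12.479   0.043
aerobic_respiration          14.006       14.995   0.086
fermentation                  8.225        7.468  -0.109
```
`log2fc ≈ 0` throughout — the example dataset has no differential effect, so
group means differ only by sampling noise.

```python
sub = ck.element_ko_matrix(bundle.ko, mapping, "C")
d = ck.bray_curtis(sub)
res = ck.multivariate_tests(d, bundle.group, method="PERMANOVA",
                            n_permutations=999, seed=1)
print(f"PERMANOVA pseudo-F = {res.statistic:.3f}, p = {res.p:.3f}")
```
```
PERMANOVA pseudo-F = 0.482, p = 1.000
```
As expected under exchangeable groups, the observed pseudo-F is unremarkable
among its permutations.

The full pipeline, from the shell:

```bash
cnpskit run --example --out Results --seed 1          # demo data
cnpskit run --ko ko.tsv --group group.tsv --gene gene.tsv \
            --tax tax.tsv --abundance abundance.tsv \
            --out Results --elements C,N --permutations 999 --seed 1
cnpskit synth --out fixtures/ --seed 7                # synthetic bundle + truth.json
cnpskit score --detected detected.txt --truth fixtures/truth.json
```

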