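# Methods

## The ontology

The unit of analysis is the *biogeochemical cycling process*: a curated
metabolic transformation (e.g. methanogenesis, anammox, dissimilatory
sulfite reduction) represented by a small set of KEGG orthology (KO)
entries. The packaged mapping (`src/cnpskit/data/cnps_mapping.tsv`) defines
42 processes over 119 distinct KOs: carbon 7 processes / 22 KOs, nitrogen
18 / 48, phosphorus 2 / 5, sulfur 15 / 47. The per-element KO counts sum to
122 because three KOs are deliberately shared across elements: the
particulate methane/ammonia monooxygenase subunits K10944–K10946
(pmoA-amoA/pmoB-amoB/pmoC-amoC) act in both methane oxidation (C) and
ammonia oxidation (N), and aggregation counts a shared KO in every process
it belongs to. The mapping is data, not code: it is a five-column TSV users
can replace, and the loader validates KO syntax (`K` + five digits), element
codes, process uniqueness and the rebuildability of the KO→process reverse
index. Cross-element duplicates are reported informationally, never
rejected.

The KO identities were curated for this package from standard KEGG
definitions in the style of the dedicated cycle databases (NCycDB, PCycDB,
SCycDB, DiTing's pathway tables); the count structure above is the
normative constraint, and users with their own curation can substitute it
freely.

## Input model and validation

Five tab-delimited tables: KO×sample abundance (trailing `Description`
column), SampleID→Group, GeneID→KO, GeneID→lineage, gene×sample abundance.
Abundances are consumed as produced upstream (typically TPM) — no
re-normalization. The KO table's column order is the canonical sample
order; group and gene-abundance tables are reordered to it. Validation
distinguishes errors (sample-set mismatches, duplicate IDs, non-numeric or
negative cells — empty cells are errors, not zeros, because silent
zero-filling hides upstream corruption) from warnings (annotated genes
without abundance rows, which are ignored downstream; groups with n < 3
replicates, below the recommended minimum for reliable testing). A gene may
carry several KO annotations (several rows); it then contributes to every
process any of its KOs belongs to, but at most once per process.

## Process profiles, presence, fold change

Process abundance is the plain cumulative sum of the process's KOs; all-zero
processes are kept as rows so outputs are structurally stable. Presence
requires both (i) non-zero abundance of ≥1 KO in ≥1 sample (strict > 0, no
threshold) and (ii) ≥1 gene annotated to a KO of the process. Fold change
compares *group means* of process abundance (matching the heatmap-of-group-
comparisons presentation, not per-sample ratios) with pseudocount
ε = ½·min(non-zero entries of the element's process matrix), ε = 1 for an
all-zero matrix. A scale-relative ε keeps ratios finite for processes absent
from one group without dominating real signal at the data's natural scale;
it is reported in every output, and swapping groups negates log2fc exactly.

## Univariate statistics

Per process: Shapiro-Wilk per group at α = 0.05 gates the *recommended*
branch — parametric only when every group has n ≥ 3, non-zero variance and
Shapiro p > α. Both families are computed regardless (Welch *t* and Wilcoxon
rank-sum for two groups; one-way ANOVA and tie-corrected Kruskal-Wallis for
three or more); the gate only selects which p-value is flagged and adjusted.
Welch's unequal-variance *t* is used because equal variances cannot be
assumed for abundance data. The Wilcoxon p is exact for small tie-free
samples and normal-approximated with tie correction otherwise. Degenerate
processes (all-zero everywhere) report "not computed" with p = 1, never NaN,
keeping downstream tables rectangular. Benjamini-Hochberg adjustment is
applied across an element's processes to the recommended p-values; raw
p-values are always reported alongside, since 42 simultaneous tests need
disclosure-grade correction but raw values preserve comparability.

## Multivariate statistics

PERMANOVA (pseudo-F from squared distances), ANOSIM (R on distance ranks,
divisor M/2 with M = n(n−1)/2) and MRPP share one seeded label-permutation
engine; p = (1 + #{permuted as-or-more extreme})/(1 + N_perm), default
N_perm = 999 with the seed recorded in every result. For MRPP "more
extreme" means a *smaller* weighted within-group mean distance δ
(w_g = n_g/N); the reported statistic is the chance-corrected agreement
A = 1 − δ/E(δ) with E(δ) the mean of the permuted δ. PERMANOVA and ANOSIM
statistics are cross-checked against scikit-bio in the test suite. Note the
permutation floor: with few samples per group, many random permutations
recreate the observed partition, so the minimum attainable p is above
1/(N_perm+1); this is a property of the design, not the implementation.

## Host-taxon linkage

Lineage strings are split on `;`, optional Greengenes/GTDB-style prefixes
(`d__`, `k__`, `p__`, ..., `s__`) are stripped, domain/kingdom fields are
discarded, and missing trailing ranks are padded with the reserved name
`Unclassified` (plain 7- or 8-field lineages are assumed to carry leading
domain/kingdom entries). For each *detected* process, genes carrying its KOs
are joined to lineage and gene abundance and summed by bare taxon name at
each of the six ranks — taxon identity is the rank-level name alone, so rare
cross-lineage name collisions merge; this matches how such heatmaps label
taxa, and is documented rather than disambiguated. Host tables use the gene
abundance table (taxonomy attaches to genes, not KOs). Group summaries are
means of per-sample relative abundances (all-zero samples stay zero). The
folder name `Host_relative_Group` reflects the group-mean default;
per-sample absolute tables are what the profile itself stores.

## β-diversity

Computed on the element's KO-level submatrix (raw upstream-normalized
abundances; deduplicated even when a KO sits in two processes). Bray-Curtis
pairs with zero total are reported as 0 with a warning. PCoA is classical
metric MDS: Gower double-centering of −d²/2, symmetric eigendecomposition,
axes ordered by eigenvalue; negative eigenvalues are reported untouched (no
Cailliez/Lingoes correction — the simplest honest treatment) and their axes
dropped; explained fractions are relative to the positive-eigenvalue sum.
PCA centers features without scaling. NMDS minimizes Kruskal stress-1 over
n_starts = 20 random initializations (k = 2, max_iter = 200, stress
tolerance 1e-7; all recorded in output metadata), best configuration kept,
coordinates centered.

## Synthetic data and benchmarking

The generator emulates the *end product* of an upstream read-simulation and
annotation pipeline at the table level; it does not simulate reads,
assembly or database search. Defaults mirror the demonstration conditions:
2 groups × 3 samples, 500 genes, and a truth set of 83 cycle KOs (a seeded
draw from the 119; the simulation design spikes a broad CNPS subset rather
than the full ontology), each truth KO carrying ≥1 gene, surplus genes
split between extra truth copies and non-cycle background KOs. Baseline
abundance is lognormal(0, σ) per gene and sample with σ = 0.5 — a simple
heavy-tailed stand-in for sequencing noise and abundance variation;
differential processes have their KOs multiplied by the configured factor
in the last group; dropout zeroes a truth KO's genes with the configured
probability. The KO table is the exact per-KO sum of its genes' rows, so
generation is internally conserved, and identical configs and seeds yield
byte-identical tables.

What passing tests on this generator do **not** show: robustness to
annotation errors (mis-assigned KOs), compositional effects, library-size
variation, chimeric lineages, or one gene mapping to conflicting taxa —
real data's failure modes live upstream of these tables. Detection scoring
(FNR = FN/(FN+TP), FPR = FP/(FP+TN), accuracy) uses the ontology's KO or
process set as the negative universe — the tool's detection scope — since
an unbounded universe would make FPR meaninglessly small.

The recovery experiment repeats generation with incremented seeds and
tabulates per-process rejection rates of the recommended test. At the
default n = 3/group the observed null rates sit slightly below the nominal
0.05 because the exact Wilcoxon branch cannot reject at that sample size
when the gate selects it — a real small-sample phenomenon, not an artifact.

## Pipeline and outputs

`run_all` analyzes each selected element: aggregate → detect → differential
+ fold changes → host linkage → KO submatrix → Bray-Curtis → PCoA/PCA/NMDS
→ PERMANOVA/ANOSIM/MRPP → plots → results tree. Detection gates only the
host analysis; β-diversity runs whenever the element's KOs carry abundance.
Validation errors abort before any output; warnings never abort. ASCII
folder names are used throughout (`beta_diversity` for β-diversity) for
filesystem portability. Plots fix the PDF creation date so identical runs
are byte-identical; heatmap rows keep mapping order (no clustering) for
reproducibility; fold-change heatmaps use a symmetric diverging scale
centered at log2fc = 0 and host heatmaps row-wise max normalization. Cycle
diagrams draw from editable per-element JSON layout templates (circular
node placement with qualitative redox-loop arrows); the topology is an
approximation users can edit, since no canonical coordinates exist for
these diagrams.

## Problem sizes used in the checks

The packaged checks run at desk scale: 500-gene bundles, 500-replicate null
calibrations with 199 permutations, 100-replicate power comparisons, and
50-bundle aggregation sweeps — sizes chosen so the entire suite re-runs in a
few minutes on a single CPU while leaving the binomial error of estimated
rates well inside the documented bands.

## Known limitations

- The KO→process curation is one defensible choice among several; counts
  are pinned, identities are editable data.
- No compositional (CLR-type) or zero-inflated modeling; abundances are
  analyzed on the scale provided.
- No post-hoc pairwise tests after ANOVA/Kruskal-Wallis; pairwise contrasts
  are routed through fold changes.
- Taxon names are not reconciled against a taxonomy database beyond prefix
  stripping; one lineage per gene is assumed.
- Fe/As cycles, MAG-level analysis and read-level simulation are out of
  scope.
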