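"""Synthetic input bundles with known truth, and FNR/FPR/accuracy scoring.

The generator emulates the *end product* of an upstream read-simulation +
assembly + annotation pipeline at the table level: it writes the same five
tables a real run produces, with a known set of cycle KOs present, known
gene -> (KO, lineage) assignments, lognormal multiplicative abundance noise,
optional per-KO dropout and optional per-process differential fold effects.
Detection quality against the known truth is scored with false-negative rate,
false-positive rate and accuracy over a stated universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ontology import CycleMapping, load_mapping
from .table_io import (
    GeneAbundanceTable,
    GeneFunctionTable,
    GeneTaxonomyTable,
    GroupTable,
    InputBundle,
    KOTable,
)

# Lineages typical of the compost/soil communities the workflow targets.
DEFAULT_TAXON_POOL = (
    "p__Actinobacteria;c__Actinomycetia;o__Streptomycetales;f__Streptomycetaceae;g__Streptomyces;s__Streptomyces griseus",
    "p__Actinobacteria;c__Actinomycetia;o__Micrococcales;f__Micrococcaceae;g__Arthrobacter;s__Arthrobacter globiformis",
    "p__Firmicutes;c__Bacilli;o__Bacillales;f__Bacillaceae;g__Bacillus;s__Bacillus subtilis",
    "p__Firmicutes;c__Clostridia;o__Eubacteriales;f__Clostridiaceae;g__Clostridium;s__Clostridium butyricum",
    "p__Proteobacteria;c__Gammaproteobacteria;o__Pseudomonadales;f__Pseudomonadaceae;g__Pseudomonas;s__Pseudomonas putida",
    "p__Proteobacteria;c__Alphaproteobacteria;o__Hyphomicrobiales;f__Nitrobacteraceae;g__Bradyrhizobium;s__Bradyrhizobium japonicum",
    "p__Bacteroidota;c__Bacteroidia;o__Flavobacteriales;f__Flavobacteriaceae;g__Flavobacterium;s__Flavobacterium johnsoniae",
    "p__Chloroflexi;c__Anaerolineae;o__Anaerolineales;f__Anaerolineaceae;g__Anaerolinea;s__Anaerolinea thermophila",
)

# Number of cycle KOs seeded into the default truth set (the simulation design
# spikes a broad CNPS subset, not the full ontology).
DEFAULT_N_TRUTH_KOS = 83


@dataclass
class SynthConfig:
    n_groups: int = 2
    samples_per_group: int = 3
    n_genes: int = 500
    truth_kos: Optional[Sequence[str]] = None  # None -> seeded draw of 83 mapping KOs
    differential: Mapping[str, float] = field(default_factory=dict)
    noise: float = 0.5  # lognormal sigma of multiplicative abundance noise
    taxon_pool: Sequence[str] = DEFAULT_TAXON_POOL
    dropout: float = 0.0  # probability a truth KO is zeroed out
    seed: int = 42

    def __post_init__(self) -> None:
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if any(m <= 0 for m in self.differential.values()):
            raise ValueError("differential multipliers must be > 0")
        if self.noise < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class TruthSet:
    present_kos: set[str]
    present_processes: set[str]
    differential_processes: dict[str, float]
    gene_assignments: pd.DataFrame  # GeneID, KO, Taxonomy


@dataclass
class BenchMetrics:
    level: str  # "KO" | "process"
    tp: int
    fn: int
    fp: int
    tn: int
    universe: str = ""

    @property
    def fnr(self) -> float:
        return self.fn / (self.fn + self.tp) if (self.fn + self.tp) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else 0.0


def _target_group_index(n_groups: int) -> int:
    """Differential multipliers are applied to the last group."""
    return n_groups - 1


def generate_dataset(
    config: SynthConfig, mapping: Optional[CycleMapping] = None
) -> tuple[InputBundle, TruthSet]:
    """Deterministically generate the five input tables plus their truth set.

    Genes are assigned KOs so that every (non-dropped) truth KO carries at
    least one gene; surplus genes split between extra truth-KO copies and
    background KOs outside the ontology.  Baseline abundance per gene and
    sample is lognormal(0, noise); KOs of each differential process are
    multiplied by the configured factor in the last group.  Same seed, same
    config -> identical tables.
    """
    mapping = mapping or load_mapping()
    rng = np.random.default_rng(config.seed)
    mapping_kos = sorted(mapping.all_kos)

    if config.truth_kos is None:
        k = min(DEFAULT_N_TRUTH_KOS, len(mapping_kos))
        truth_kos = sorted(rng.choice(mapping_kos, size=k, replace=False))
    else:
        truth_kos = sorted(dict.fromkeys(config.truth_kos))
        outside = set(truth_kos) - set(mapping_kos)
        if outside:
            raise ValueError(f"truth KOs outside the mapping: {sorted(outside)}")

    n_truth = len(truth_kos)
    if config.n_genes < n_truth:
        raise ValueError(f"n_genes must be >= number of truth KOs ({n_truth})")

    background_pool = [f"K9{i:04d}" for i in range(900, 940)]
    background_pool = [k for k in background_pool if k not in mapping.all_kos]

    gene_ids = [f"gene_{i + 1:05d}" for i in range(config.n_genes)]
    kos = list(truth_kos)  # one gene per truth KO first
    for _ in range(config.n_genes - n_truth):
        if rng.random() < 0.5:
            kos.append(str(rng.choice(truth_kos)))
        else:
            kos.append(str(rng.choice(background_pool)))
    lineages = [str(rng.choice(config.taxon_pool)) for _ in gene_ids]

    groups = [f"G{i + 1}" for i in range(config.n_groups)]
    samples = [f"{g}_S{r + 1}" for g in groups for r in range(config.samples_per_group)]
    sample_groups = [g for g in groups for _ in range(config.samples_per_group)]

    if config.noise > 0:
        abundance = rng.lognormal(mean=0.0, sigma=config.noise, size=(config.n_genes, len(samples)))
    else:
        abundance = np.ones((config.n_genes, len(samples)))

    # differential effects: multiply the target group's columns for genes whose
    # KO belongs to the affected process
    target_group = groups[_target_group_index(config.n_groups)]
    target_cols = [i for i, g in enumerate(sample_groups) if g == target_group]
    differential_processes: dict[str, float] = {}
    for process_id, mult in config.differential.items():
        proc = mapping.process(process_id)
        differential_processes[process_id] = float(mult)
        gene_rows = [i for i, k in enumerate(kos) if k in set(proc.ko_ids)]
        for i in gene_rows:
            abundance[i, target_cols] *= mult

    # dropout: zero all genes of a dropped truth KO
    dropped: set[str] = set()
    for k in truth_kos:
        if config.dropout > 0 and rng.random() < config.dropout:
            dropped.add(k)
    for i, k in enumerate(kos):
        if k in dropped:
            abundance[i, :] = 0.0

    abundance_df = pd.DataFrame(
        np.round(abundance, 6), index=pd.Index(gene_ids, name="GeneID"), columns=samples
    )

    # KO table: per-KO sums of assigned genes
    ko_df = abundance_df.groupby(pd.Index(kos, name="KO")).sum()
    gene_label = {
        ko: label
        for p in mapping.processes
        for ko, label in zip(p.ko_ids, p.gene_labels or ("",) * len(p.ko_ids))
    }
    descriptions = pd.Series(
        [gene_label.get(k, "simulated background function") for k in ko_df.index],
        index=ko_df.index,
        name="Description",
    )

    bundle = InputBundle(
        ko=KOTable(values=ko_df, descriptions=descriptions),
        group=GroupTable(
            assignments=pd.Series(sample_groups, index=samples, name="Group")
        ),
        gene=GeneFunctionTable(
            table=pd.DataFrame({"GeneID": gene_ids, "KO": kos})
        ),
        tax=GeneTaxonomyTable(
            assignments=pd.Series(lineages, index=gene_ids, name="Taxonomy")
        ),
        abundance=GeneAbundanceTable(values=abundance_df),
    )

    present_kos = {k for k in truth_kos if k not in dropped}
    assigned_kos = set(kos)
    present_processes = {
        p.process_id
        for p in mapping.processes
        if any(k in present_kos for k in p.ko_ids)
        and any(k in assigned_kos for k in p.ko_ids)
    }
    truth = TruthSet(
        present_kos=present_kos,
        present_processes=present_processes,
        differential_processes=differential_processes,
        gene_assignments=pd.DataFrame(
            {"GeneID": gene_ids, "KO": kos, "Taxonomy": lineages}
        ),
    )
    return bundle, truth


def example_bundle(seed: int = 42) -> tuple[InputBundle, TruthSet]:
    """The default demonstration dataset: 2 groups x 3 samples, 500 genes."""
    return generate_dataset(SynthConfig(seed=seed))


def score_detection(
    detected: set[str],
    truth: set[str],
    universe: set[str],
    level: str = "KO",
) -> BenchMetrics:
    """Confusion counts and FNR/FPR/accuracy of a detected set vs the truth.

    The universe fixes the negatives: by convention the ontology's full KO (or
    process) set, i.e. the tool's detection scope.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not detected <= universe:
        raise ValueError("detected items outside the universe")
    if not truth <= universe:
        raise ValueError("truth items outside the universe")
    tp = len(detected & truth)
    fn = len(truth - detected)
    fp = len(detected - truth)
    tn = len(universe - detected - truth)
    return BenchMetrics(
        level=level, tp=tp, fn=fn, fp=fp, tn=tn, universe=f"{len(universe)} items"
    )


def recovery_experiment(
    config: SynthConfig,
    mapping: Optional[CycleMapping] = None,
    element: str = "C",
    alpha: float = 0.05,
    n_reps: int = 100,
) -> pd.DataFrame:
    """Per-process rejection rates over repeated simulated datasets.

    Runs ``generate_dataset`` with seeds config.seed .. config.seed+n_reps-1,
    applies the differential table to the chosen element and tabulates the
    fraction of replicates in which each process's recommended-test raw p falls
    below alpha.  Under a global null this estimates the type-I error; for a
    truly differential process it estimates power.
    """
    from dataclasses import replace

    from .group_stats import differential_table
    from .process_abundance import aggregate

    mapping = mapping or load_mapping()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    counts: dict[str, int] = {}
    computed: dict[str, int] = {}
    for rep in range(n_reps):
        bundle, _ = generate_dataset(replace(config, seed=config.seed + rep), mapping)
        pam = aggregate(bundle.ko, mapping, element)
        for res in differential_table(pam, bundle.group, alpha=alpha):
            if "not computed" in res.note:
                continue
            computed[res.process_id] = computed.get(res.process_id, 0) + 1
            if res.p_raw < alpha:
                counts[res.process_id] = counts.get(res.process_id, 0) + 1
    rows = []
    for p in mapping.processes_for_element(element):
        n = computed.get(p.process_id, 0)
        rows.append(
            {
                "process_id": p.process_id,
                "n_reps_tested": n,
                "rejection_rate": counts.get(p.process_id, 0) / n if n else float("nan"),
                "true_multiplier": config.differential.get(p.process_id, 1.0),
            }
        )
    return pd.DataFrame(rows).set_index("process_id")
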