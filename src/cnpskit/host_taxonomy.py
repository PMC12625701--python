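"""Link cycle genes to their taxonomic origins ("hosts").

For each *detected* process, genes whose KO annotation belongs to the process
are joined with their NR-derived lineage and their per-sample abundance, then
summed by taxon name at each of six ranks (phylum, class, order, family,
genus, species).  Genes without taxonomy count under the reserved taxon
"Unclassified".  Host tables are computed from the gene abundance table, not
the KO table, because taxonomy attaches to genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .ontology import CycleMapping
from .process_abundance import PresenceVector
from .table_io import GroupTable, InputBundle

RANKS = ("phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "Unclassified"

# GTDB/Greengenes-style prefixes; d__/k__ fields are discarded (ranks above phylum)
_PREFIX_RANK = {
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
_DISCARD_PREFIXES = {"d", "k"}


@dataclass(frozen=True)
class Lineage:
    phylum: str = UNCLASSIFIED
    class_: str = UNCLASSIFIED
    order: str = UNCLASSIFIED
    family: str = UNCLASSIFIED
    genus: str = UNCLASSIFIED
    species: str = UNCLASSIFIED

    def at(self, rank: str) -> str:
        return getattr(self, "class_" if rank == "class" else rank)

    def as_dict(self) -> dict[str, str]:
        return {r: self.at(r) for r in RANKS}


def parse_lineage(raw: str) -> Lineage:
    """Parse a semicolon-separated lineage string into six ranks.

    Accepts both prefixed ("p__Firmicutes;c__Bacilli;...") and plain
    ("Firmicutes;Bacilli") dialects; domain/kingdom fields are discarded and
    missing trailing ranks are padded with "Unclassified".  An empty string
    yields an all-Unclassified lineage with a warning.
    """
    if not raw or not raw.strip():
        warnings.warn("empty lineage string: treating as fully Unclassified", stacklevel=2)
        return Lineage()
    fields = [f.strip() for f in raw.split(";")]
    prefixed = any(len(f) > 3 and f[1:3] == "__" for f in fields if f)
    values: dict[str, str] = {}
    if prefixed:
        for f in fields:
            if len(f) > 2 and f[1:3] == "__":
                prefix, name = f[0].lower(), f[3:].strip()
            else:
                continue
            if prefix in _DISCARD_PREFIXES:
                continue
            rank = _PREFIX_RANK.get(prefix)
            if rank and name:
                values[rank] = name
    else:
        names = [f for f in fields if f]
        # 7+ plain fields imply leading domain (and kingdom) entries
        if len(names) >= 8:
            names = names[2:]
        elif len(names) == 7:
            names = names[1:]
        for rank, name in zip(RANKS, names):
            values[rank] = name
    kwargs = {("class_" if r == "class" else r): values.get(r, UNCLASSIFIED) for r in RANKS}
    return Lineage(**kwargs)


@dataclass
class HostProfile:
    element: str
    process_id: str
    rank: str
    table: pd.DataFrame  # taxon x sample absolute abundance
    relative_by_group: Optional[pd.DataFrame] = None  # taxon x group


def link_hosts(
    bundle: InputBundle,
    mapping: CycleMapping,
    element: str,
    presence: PresenceVector,
) -> list[HostProfile]:
    """Per-process, per-rank taxon abundance tables for detected processes.

    A gene annotated to several KOs of the same process contributes once per
    process; genes absent from the abundance table are ignored; genes lacking
    a taxonomy entry count as "Unclassified" at every rank.
    """
    gene_table = bundle.gene.table
    tax = bundle.tax.assignments
    abundance = bundle.abundance.values
    samples = list(abundance.columns)
    lineage_cache: dict[str, Lineage] = {}

    profiles: list[HostProfile] = []
    for proc in mapping.processes_for_element(element):
        if not presence.presence.get(proc.process_id, False):
            continue
        ko_set = set(proc.ko_ids)
        genes = pd.unique(gene_table.loc[gene_table["KO"].isin(ko_set), "GeneID"])
        genes = [g for g in genes if g in abundance.index]
        if not genes:
            warnings.warn(
                f"process {proc.process_id!r} detected but no annotated genes have "
                "abundance rows: empty host table",
                stacklevel=2,
            )
        rows = abundance.loc[genes] if genes else pd.DataFrame(columns=samples)
        lineages = []
        for g in genes:
            raw = tax.get(g, "")
            if raw not in lineage_cache:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lineage_cache[raw] = parse_lineage(raw) if raw else Lineage()
            lineages.append(lineage_cache[raw])
        for rank in RANKS:
            if genes:
                taxa = [ln.at(rank) for ln in lineages]
                table = rows.groupby(pd.Index(taxa, name=rank)).sum()
            else:
                table = pd.DataFrame(columns=samples)
            profiles.append(
                HostProfile(
                    element=element,
                    process_id=proc.process_id,
                    rank=rank,
                    table=table,
                )
            )
    return profiles


def summarize_by_group(profile: HostProfile, group: GroupTable) -> HostProfile:
    """Fill relative_by_group: group means of per-sample relative abundances.

    Each sample column is normalized to sum to 1 (all-zero columns stay zero),
    then averaged within each group.
    """
    table = profile.table
    if table.empty:
        profile.relative_by_group = pd.DataFrame(columns=group.groups)
        return profile
    unknown = set(table.columns) - set(group.sample_ids)
    if unknown:
        raise ValueError(f"samples without group assignment: {sorted(unknown)}")
    totals = table.sum(axis=0)
    rel = table.div(totals.where(totals > 0, 1.0), axis=1)
    rel.loc[:, totals == 0] = 0.0
    by_group = pd.DataFrame(
        {g: rel[group.samples_in(g)].mean(axis=1) for g in group.groups}
    )
    profile.relative_by_group = by_group
    return profile
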