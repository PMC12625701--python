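"""Readers and validators for the five tab-delimited input tables.

The workflow consumes the end products of a standard shotgun-metagenomic
pipeline (assembly, gene prediction, KofamScan KO annotation, DIAMOND-vs-NR
taxonomy, TPM gene abundances):

* ``ko``        — KO x sample abundance matrix with a trailing Description column
* ``group``     — SampleID -> Group assignments
* ``gene``      — GeneID -> KO annotation
* ``tax``       — GeneID -> taxonomic lineage string
* ``abundance`` — GeneID x sample abundance matrix

All five must agree on one sample set; the KO table's column order is the
canonical sample order and the other tables are reordered to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .ontology import KO_PATTERN

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A required column or structural property of an input table is missing."""


@dataclass
class Finding:
    """One machine-readable validation finding."""

    code: str
    level: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.level == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.level == "warning"]

    def add(self, code: str, level: str, message: str) -> None:
        self.findings.append(Finding(code, level, message))


@dataclass
class KOTable:
    values: pd.DataFrame  # KO x sample, numeric >= 0
    descriptions: pd.Series  # aligned with values.index

    @property
    def ko_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GroupTable:
    assignments: pd.Series  # index SampleID, values group label

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments.index)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.assignments:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        return list(self.assignments.index[self.assignments == group])


@dataclass
class GeneFunctionTable:
    # one row per (GeneID, KO) pair; duplicates per gene preserved deliberately
    table: pd.DataFrame  # columns GeneID, KO

    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.table["GeneID"]))

    def kos_of(self, gene_id: str) -> list[str]:
        return list(self.table.loc[self.table["GeneID"] == gene_id, "KO"])


@dataclass
class GeneTaxonomyTable:
    assignments: pd.Series  # index GeneID, values raw lineage string


@dataclass
class GeneAbundanceTable:
    values: pd.DataFrame  # gene x sample, numeric >= 0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class InputBundle:
    ko: KOTable
    group: GroupTable
    gene: GeneFunctionTable
    tax: GeneTaxonomyTable
    abundance: GeneAbundanceTable

    @property
    def sample_ids(self) -> list[str]:
        return self.ko.sample_ids


# ---------------------------------------------------------------------------
# parsing helpers

def _read_tsv(path: PathLike, label: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise FileNotFoundError(f"{label} table not found: {path}") from None
    if df.empty or df.shape[1] == 0:
        raise SchemaError(f"{label} table {path} is empty")
    return df


def _numeric_matrix(df: pd.DataFrame, id_col: str, label: str) -> pd.DataFrame:
    """Coerce all non-ID columns to float, reporting the first offending cell.

    Empty cells are errors, not zeros: silent zero-filling would hide upstream
    corruption.  Scientific notation is accepted; the radix is '.'.
    """
    ids = df[id_col]
    dupes = ids[ids.duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"{label} table: duplicate row IDs {list(dupes)[:5]}")
    body = df.drop(columns=[id_col])
    out = {}
    for col in body.columns:
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = ids[bad].iloc[0]
            val = body[col][bad].iloc[0]
            raise SchemaError(
                f"{label} table: non-numeric abundance {val!r} at row "
                f"{row!r}, column {col!r}"
            )
        out[col] = converted.astype(float).to_numpy()
    matrix = pd.DataFrame(out, index=pd.Index(ids, name=id_col))
    if (matrix.to_numpy() < 0).any():
        raise SchemaError(f"{label} table: negative abundance values present")
    return matrix


def read_ko_table(path: PathLike) -> KOTable:
    df = _read_tsv(path, "KO")
    if "Description" not in df.columns:
        raise SchemaError(f"KO table {path}: missing required 'Description' column")
    id_col = df.columns[0]
    desc = pd.Series(df["Description"].values, index=df[id_col].values, name="Description")
    matrix = _numeric_matrix(df.drop(columns=["Description"]), id_col, "KO")
    return KOTable(values=matrix, descriptions=desc)


def read_group_table(path: PathLike) -> GroupTable:
    df = _read_tsv(path, "group")
    for col in ("SampleID", "Group"):
        if col not in df.columns:
            raise SchemaError(f"group table {path}: missing required column {col!r}")
    dupes = df["SampleID"][df["SampleID"].duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"group table {path}: duplicate SampleIDs {list(dupes)}")
    if (df["Group"].str.strip() == "").any():
        raise SchemaError(f"group table {path}: empty group labels present")
    return GroupTable(
        assignments=pd.Series(df["Group"].values, index=df["SampleID"].values, name="Group")
    )


def read_gene_table(path: PathLike) -> GeneFunctionTable:
    df = _read_tsv(path, "Gene")
    cols = {c: c for c in df.columns}
    if "Entry" in cols and "KO" not in cols:
        df = df.rename(columns={"Entry": "KO"})
    for col in ("GeneID", "KO"):
        if col not in df.columns:
            raise SchemaError(f"Gene table {path}: missing required column {col!r}")
    bad = df["KO"][~df["KO"].str.match(KO_PATTERN)]
    if len(bad):
        raise SchemaError(
            f"Gene table {path}: malformed KO identifiers {list(bad.unique())[:5]}"
        )
    return GeneFunctionTable(table=df[["GeneID", "KO"]].copy())


def read_tax_table(path: PathLike) -> GeneTaxonomyTable:
    df = _read_tsv(path, "tax")
    for col in ("GeneID", "Taxonomy"):
        if col not in df.columns:
            raise SchemaError(f"tax table {path}: missing required column {col!r}")
    dupes = df["GeneID"][df["GeneID"].duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"tax table {path}: duplicate GeneIDs {list(dupes)[:5]}")
    if (df["Taxonomy"].str.strip() == "").any():
        raise SchemaError(f"tax table {path}: empty Taxonomy strings present")
    return GeneTaxonomyTable(
        assignments=pd.Series(df["Taxonomy"].values, index=df["GeneID"].values, name="Taxonomy")
    )


def read_abundance_table(path: PathLike) -> GeneAbundanceTable:
    df = _read_tsv(path, "abundance")
    if "GeneID" not in df.columns:
        raise SchemaError(f"abundance table {path}: missing required column 'GeneID'")
    return GeneAbundanceTable(values=_numeric_matrix(df, "GeneID", "abundance"))


def read_inputs(
    ko: PathLike,
    group: PathLike,
    gene: PathLike,
    tax: PathLike,
    abundance: PathLike,
) -> InputBundle:
    """Read the five tables and align them on the KO table's sample order.

    Raises :class:`SchemaError` on structural problems; cross-table consistency
    beyond sample-set equality is reported by :func:`validate_bundle`.
    """
    ko_t = read_ko_table(ko)
    group_t = read_group_table(group)
    gene_t = read_gene_table(gene)
    tax_t = read_tax_table(tax)
    ab_t = read_abundance_table(abundance)

    order = ko_t.sample_ids
    if set(group_t.sample_ids) == set(order):
        group_t = GroupTable(assignments=group_t.assignments.reindex(order))
    if set(ab_t.sample_ids) == set(order):
        ab_t = GeneAbundanceTable(values=ab_t.values[order])
    return InputBundle(ko=ko_t, group=group_t, gene=gene_t, tax=tax_t, abundance=ab_t)


def validate_bundle(bundle: InputBundle) -> ValidationReport:
    """Cross-check the bundle; returns findings, never raises.

    Errors: sample-set mismatches between the KO, group and gene-abundance
    tables.  Warnings: annotated genes absent from the abundance table (they are
    ignored downstream), and groups below the recommended n >= 3 replicates.
    """
    report = ValidationReport()
    ko_samples = set(bundle.ko.sample_ids)
    for label, samples in (
        ("group", set(bundle.group.sample_ids)),
        ("abundance", set(bundle.abundance.sample_ids)),
    ):
        if samples != ko_samples:
            missing = sorted(ko_samples - samples)
            extra = sorted(samples - ko_samples)
            report.add(
                "sample_mismatch",
                "error",
                f"{label} table sample set differs from KO table "
                f"(missing {missing}, unexpected {extra})",
            )

    abundant = set(bundle.abundance.gene_ids)
    for label, genes in (
        ("Gene", set(bundle.gene.table["GeneID"])),
        ("tax", set(bundle.tax.assignments.index)),
    ):
        orphaned = genes - abundant
        if orphaned:
            report.add(
                "gene_without_abundance",
                "warning",
                f"{len(orphaned)} genes in the {label} table are absent from the "
                "abundance table and will be ignored",
            )

    for g in bundle.group.groups:
        n = len(bundle.group.samples_in(g))
        if n < 3:
            report.add(
                "small_group",
                "warning",
                f"group {g!r} has n={n} samples; n >= 3 biological replicates "
                "per group are recommended for reliable differential tests",
            )
    return report


# ---------------------------------------------------------------------------
# writers (fixture generation and round-tripping)

def write_bundle(bundle: InputBundle, directory: PathLike) -> dict[str, Path]:
    """Write the five TSVs in the input dialect; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ko": directory / "ko.tsv",
        "group": directory / "group.tsv",
        "gene": directory / "gene.tsv",
        "tax": directory / "tax.tsv",
        "abundance": directory / "abundance.tsv",
    }
    ko_out = bundle.ko.values.copy()
    ko_out["Description"] = bundle.ko.descriptions.reindex(ko_out.index).values
    ko_out.index.name = "KO"
    ko_out.to_csv(paths["ko"], sep="\t")

    pd.DataFrame(
        {"SampleID": bundle.group.sample_ids, "Group": bundle.group.assignments.values}
    ).to_csv(paths["group"], sep="\t", index=False)
    bundle.gene.table.to_csv(paths["gene"], sep="\t", index=False)
    pd.DataFrame(
        {
            "GeneID": bundle.tax.assignments.index,
            "Taxonomy": bundle.tax.assignments.values,
        }
    ).to_csv(paths["tax"], sep="\t", index=False)
    ab = bundle.abundance.values.copy()
    ab.index.name = "GeneID"
    ab.to_csv(paths["abundance"], sep="\t")
    return paths
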