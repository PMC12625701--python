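"""Curated mapping from KEGG orthology (KO) entries to biogeochemical cycling processes.

The package ships a curated ontology of 42 cycling processes spanning the four
major elements — carbon (7 processes), nitrogen (18), phosphorus (2) and sulfur
(15) — represented by 119 distinct KO entries.  A KO may legitimately belong to
more than one process: the particulate methane/ammonia monooxygenase subunits
(pmoABC/amoABC) act in both methane oxidation and ammonia oxidation, so they are
listed under both a carbon and a nitrogen process.  Users may substitute their
own mapping file with the same five-column tab-delimited layout.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

ELEMENTS = ("C", "N", "P", "S")
ELEMENT_NAMES = {"C": "Carbon", "N": "Nitrogen", "P": "Phosphorus", "S": "Sulfur"}
KO_PATTERN = re.compile(r"^K\d{5}$")

MAPPING_COLUMNS = ["element", "process_id", "display_name", "ko_id", "gene_label"]


class MappingError(ValueError):
    """Raised when a cycle-mapping file violates the ontology contract."""


@dataclass(frozen=True)
class ProcessDef:
    """One biogeochemical cycling process and the KOs that represent it."""

    process_id: str
    display_name: str
    element: str
    ko_ids: tuple[str, ...]
    gene_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise MappingError(
                f"process {self.process_id!r}: element {self.element!r} "
                f"not one of {ELEMENTS}"
            )
        if not self.ko_ids:
            raise MappingError(f"process {self.process_id!r} has no KO entries")
        for ko in self.ko_ids:
            if not KO_PATTERN.match(ko):
                raise MappingError(
                    f"process {self.process_id!r}: invalid KO identifier {ko!r} "
                    "(expected 'K' followed by five digits)"
                )


@dataclass
class CycleMapping:
    """Validated element -> process -> KO ontology with a reverse KO index."""

    processes: list[ProcessDef]
    ko_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.process_id for p in self.processes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise MappingError(f"duplicate process_ids: {sorted(dupes)}")
        rebuilt = self._build_ko_index(self.processes)
        if self.ko_index and self.ko_index != rebuilt:
            raise MappingError("ko_index inconsistent with process definitions")
        self.ko_index = rebuilt

    @staticmethod
    def _build_ko_index(processes: Iterable[ProcessDef]) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {}
        for proc in processes:
            for ko in proc.ko_ids:
                index.setdefault(ko, []).append(proc.process_id)
        return index

    # -- queries -----------------------------------------------------------

    def processes_for_element(self, element: str) -> list[ProcessDef]:
        _check_element(element)
        return [p for p in self.processes if p.element == element]

    def process(self, process_id: str) -> ProcessDef:
        for p in self.processes:
            if p.process_id == process_id:
                return p
        raise KeyError(process_id)

    @property
    def all_kos(self) -> set[str]:
        return set(self.ko_index)

    def cross_element_kos(self) -> dict[str, set[str]]:
        """KOs assigned to processes of more than one element (informational)."""
        out: dict[str, set[str]] = {}
        by_proc = {p.process_id: p.element for p in self.processes}
        for ko, procs in self.ko_index.items():
            elems = {by_proc[p] for p in procs}
            if len(elems) > 1:
                out[ko] = elems
        return out

    def summary(self) -> dict[str, dict[str, int]]:
        """Per-element process and distinct-KO counts plus overall totals."""
        out: dict[str, dict[str, int]] = {}
        for el in ELEMENTS:
            procs = self.processes_for_element(el)
            kos = set().union(*(p.ko_ids for p in procs)) if procs else set()
            out[el] = {"n_processes": len(procs), "n_kos": len(kos)}
        out["total"] = {
            "n_processes": len(self.processes),
            "n_kos": len(self.all_kos),
        }
        return out

    # -- serialization -----------------------------------------------------

    def to_table(self) -> "pd.DataFrame":  # noqa: F821 - late import
        import pandas as pd

        rows = []
        for p in self.processes:
            labels = p.gene_labels or ("",) * len(p.ko_ids)
            for ko, label in zip(p.ko_ids, labels):
                rows.append((p.element, p.process_id, p.display_name, ko, label))
        return pd.DataFrame(rows, columns=MAPPING_COLUMNS)

    def write(self, path: Union[str, Path]) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def _check_element(element: str) -> None:
    if element not in ELEMENTS:
        raise MappingError(f"unknown element code {element!r}; expected one of {ELEMENTS}")


def default_mapping_path() -> Path:
    return Path(importlib.resources.files("cnpskit.data") / "cnps_mapping.tsv")


def load_mapping(source: Union[str, Path] = "default") -> CycleMapping:
    """Load and validate a cycle mapping from a TSV file (or the packaged default).

    The file must be tab-delimited with header columns
    ``element  process_id  display_name  ko_id  gene_label`` and one KO per row;
    rows sharing a process_id are merged in declaration order.
    """
    import pandas as pd

    path = default_mapping_path() if source == "default" else Path(source)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MAPPING_COLUMNS if c not in table.columns]
    if missing:
        raise MappingError(f"{path}: missing mapping columns {missing}")
    if table.empty:
        raise MappingError(f"{path}: mapping file contains no rows")

    for i, row in table.iterrows():
        if not KO_PATTERN.match(row["ko_id"]):
            raise MappingError(
                f"{path} row {i + 2}: invalid KO identifier {row['ko_id']!r}"
            )
        if row["element"] not in ELEMENTS:
            raise MappingError(
                f"{path} row {i + 2}: unknown element code {row['element']!r}"
            )

    processes: list[ProcessDef] = []
    seen: dict[str, dict] = {}
    for _, row in table.iterrows():
        pid = row["process_id"]
        if pid not in seen:
            seen[pid] = {
                "element": row["element"],
                "display_name": row["display_name"],
                "kos": [],
                "labels": [],
            }
        entry = seen[pid]
        if row["element"] != entry["element"]:
            raise MappingError(
                f"{path}: process {pid!r} assigned to elements "
                f"{entry['element']!r} and {row['element']!r}"
            )
        if row["ko_id"] not in entry["kos"]:
            entry["kos"].append(row["ko_id"])
            entry["labels"].append(row["gene_label"])
    for pid, entry in seen.items():
        processes.append(
            ProcessDef(
                process_id=pid,
                display_name=entry["display_name"],
                element=entry["element"],
                ko_ids=tuple(entry["kos"]),
                gene_labels=tuple(entry["labels"]),
            )
        )
    return CycleMapping(processes=processes)


def kos_for_element(mapping: CycleMapping, element: str) -> set[str]:
    """Deduplicated union of KO ids over one element's processes."""
    _check_element(element)
    kos: set[str] = set()
    for p in mapping.processes_for_element(element):
        kos.update(p.ko_ids)
    return kos


def element_ko_order(mapping: CycleMapping, element: str) -> list[str]:
    """Element KOs in mapping declaration order, first occurrence wins."""
    _check_element(element)
    seen: list[str] = []
    for p in mapping.processes_for_element(element):
        for ko in p.ko_ids:
            if ko not in seen:
                seen.append(ko)
    return seen


def processes_for_ko(mapping: CycleMapping, ko: str) -> list[str]:
    """Process ids containing ``ko`` in declaration order ([] if absent)."""
    return list(mapping.ko_index.get(ko, []))
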