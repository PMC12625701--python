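"""Process-level abundance curation: aggregation, presence calls, fold change.

KO-level abundances (same units as the input, typically TPM) are summed into
cumulative per-process profiles.  A process is called *present* only when
(i) at least one of its KOs has non-zero abundance in at least one sample and
(ii) at least one of its KOs annotates at least one gene in the Gene table.
Pairwise group comparisons are expressed as fold changes of group means with a
scale-relative pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ontology import CycleMapping, _check_element
from .table_io import GroupTable, GeneFunctionTable, KOTable


@dataclass
class ProcessAbundanceMatrix:
    element: str
    values: pd.DataFrame  # process x sample

    @property
    def process_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PresenceVector:
    element: str
    presence: dict[str, bool]

    @property
    def present(self) -> list[str]:
        return [p for p, v in self.presence.items() if v]


@dataclass
class FoldChangeTable:
    element: str
    reference_group: str
    target_group: str
    table: pd.DataFrame  # index process_id; mean_ref, mean_target, ratio, log2fc
    pseudocount: float


def aggregate(ko: KOTable, mapping: CycleMapping, element: str) -> ProcessAbundanceMatrix:
    """Cumulative per-process abundance: value[p, s] = sum of ko[k, s] over k in p.

    KOs absent from the KO table contribute zero; a KO listed under several
    processes contributes to each independently.  All-zero processes are kept
    so output shape is stable across datasets.
    """
    _check_element(element)
    procs = mapping.processes_for_element(element)
    samples = ko.sample_ids
    rows = np.zeros((len(procs), len(samples)))
    for i, proc in enumerate(procs):
        hit = [k for k in proc.ko_ids if k in ko.values.index]
        if hit:
            rows[i] = ko.values.loc[hit].to_numpy().sum(axis=0)
    values = pd.DataFrame(rows, index=[p.process_id for p in procs], columns=samples)
    return ProcessAbundanceMatrix(element=element, values=values)


def detect_processes(
    ko: KOTable,
    gene: GeneFunctionTable,
    mapping: CycleMapping,
    element: str,
) -> PresenceVector:
    """Binary presence per process (abundance criterion AND gene-mapping criterion)."""
    _check_element(element)
    annotated_kos = set(gene.table["KO"])
    presence: dict[str, bool] = {}
    for proc in mapping.processes_for_element(element):
        hit = [k for k in proc.ko_ids if k in ko.values.index]
        has_abundance = bool(hit) and bool((ko.values.loc[hit].to_numpy() > 0).any())
        has_gene = any(k in annotated_kos for k in proc.ko_ids)
        presence[proc.process_id] = has_abundance and has_gene
    return PresenceVector(element=element, presence=presence)


def _pseudocount(values: pd.DataFrame) -> float:
    nz = values.to_numpy()
    nz = nz[nz > 0]
    return float(nz.min()) / 2.0 if nz.size else 1.0


def fold_change(
    pam: ProcessAbundanceMatrix,
    group: GroupTable,
    reference: str,
    target: str,
) -> FoldChangeTable:
    """Per-process fold change of group means, target vs reference.

    ratio = (mean_target + eps) / (mean_ref + eps) with eps = half the smallest
    non-zero entry of the process-abundance matrix (1.0 when all-zero), so
    ratios stay finite for processes absent from one group without the
    pseudocount dominating real signal.  Swapping reference and target negates
    log2fc exactly.
    """
    if reference == target:
        raise ValueError("reference and target groups must differ")
    groups = set(group.groups)
    for g in (reference, target):
        if g not in groups:
            raise ValueError(f"unknown group label {g!r}")
    eps = _pseudocount(pam.values)
    ref_samples = group.samples_in(reference)
    tgt_samples = group.samples_in(target)
    mean_ref = pam.values[ref_samples].mean(axis=1)
    mean_tgt = pam.values[tgt_samples].mean(axis=1)
    ratio = (mean_tgt + eps) / (mean_ref + eps)
    table = pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_target": mean_tgt,
            "ratio": ratio,
            "log2fc": np.log2(ratio),
            "pseudocount": eps,
        }
    )
    return FoldChangeTable(
        element=pam.element,
        reference_group=reference,
        target_group=target,
        table=table,
        pseudocount=eps,
    )


def pairwise_fold_changes(
    pam: ProcessAbundanceMatrix, group: GroupTable
) -> list[FoldChangeTable]:
    """Fold change for every ordered-free pair of groups, in group order."""
    gs = group.groups
    out = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            out.append(fold_change(pam, group, gs[i], gs[j]))
    return out
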