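"""One-command orchestration of the four-element workflow.

``run_all`` wires the modules in method order for each selected element:
aggregate -> detect -> differential tests + fold changes -> host linkage ->
element KO submatrix -> Bray-Curtis -> PCoA/PCA/NMDS -> PERMANOVA/ANOSIM/MRPP
-> plots -> results tree.  Detection gates only the host analysis; beta
diversity runs whenever the element's KOs carry abundance.  Every parameter,
the seed and all warnings are recorded in Results/run.log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from . import __version__
from .beta_diversity import bray_curtis, element_ko_matrix, nmds, pca, pcoa
from .group_stats import differential_table, multivariate_tests
from .host_taxonomy import link_hosts, summarize_by_group
from .ontology import ELEMENTS, CycleMapping, load_mapping
from .process_abundance import aggregate, detect_processes, pairwise_fold_changes
from .synth_bench import example_bundle
from .table_io import InputBundle, read_inputs, validate_bundle
from .viz import ElementResults, write_results_tree

PathLike = Union[str, Path]


@dataclass
class RunConfig:
    ko: Optional[PathLike] = None
    group: Optional[PathLike] = None
    gene: Optional[PathLike] = None
    tax: Optional[PathLike] = None
    abundance: Optional[PathLike] = None
    use_example: bool = False  # run on the packaged synthetic demonstration data
    out: PathLike = "Results"
    elements: tuple[str, ...] = ELEMENTS
    mapping: Union[str, Path] = "default"
    alpha: float = 0.05
    permutations: int = 999
    seed: int = 1
    nmds_starts: int = 20
    overwrite: bool = False

    def __post_init__(self) -> None:
        bad = set(self.elements) - set(ELEMENTS)
        if bad:
            raise ValueError(f"unknown elements {sorted(bad)}; allowed: {ELEMENTS}")


class ValidationFailure(RuntimeError):
    """Input bundle failed validation; no analysis output was produced."""


def _load_bundle(config: RunConfig) -> InputBundle:
    if config.use_example:
        bundle, _ = example_bundle(seed=42)
        return bundle
    paths = [config.ko, config.group, config.gene, config.tax, config.abundance]
    if any(p is None for p in paths):
        raise ValueError("all five input tables (or use_example) are required")
    return read_inputs(*paths)


def analyze_element(
    bundle: InputBundle,
    mapping: CycleMapping,
    element: str,
    alpha: float = 0.05,
    permutations: int = 999,
    seed: int = 1,
    nmds_starts: int = 20,
    log: Optional[list[str]] = None,
) -> ElementResults:
    """Run the full per-element analysis; beta diversity is skipped (with a
    logged note) only when none of the element's KOs appear in the KO table."""
    log = log if log is not None else []
    pam = aggregate(bundle.ko, mapping, element)
    presence = detect_processes(bundle.ko, bundle.gene, mapping, element)
    differential = differential_table(pam, bundle.group, alpha=alpha)
    fold_changes = pairwise_fold_changes(pam, bundle.group)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        hosts = [
            summarize_by_group(p, bundle.group)
            for p in link_hosts(bundle, mapping, element, presence)
        ]
    for w in caught:
        log.append(f"[{element}] warning: {w.message}")

    distance = None
    multivariate = []
    ordinations = []
    ko_sub = None
    try:
        ko_sub = element_ko_matrix(bundle.ko, mapping, element)
    except ValueError as exc:
        log.append(f"[{element}] beta diversity skipped: {exc}")
    if ko_sub is not None:
        distance = bray_curtis(ko_sub)
        n_samples = len(distance.sample_ids)
        group_sizes = [len(bundle.group.samples_in(g)) for g in bundle.group.groups]
        if len(group_sizes) >= 2 and min(group_sizes) >= 2:
            for method in ("PERMANOVA", "ANOSIM", "MRPP"):
                multivariate.append(
                    multivariate_tests(
                        distance,
                        bundle.group,
                        method=method,
                        n_permutations=permutations,
                        seed=seed,
                    )
                )
        else:
            log.append(f"[{element}] multivariate tests skipped: need >=2 groups with >=2 samples")
        ordinations.append(pcoa(distance))
        ordinations.append(pca(ko_sub))
        if n_samples >= 4:
            ordinations.append(nmds(distance, k=2, seed=seed, n_starts=nmds_starts))
        else:
            log.append(f"[{element}] NMDS skipped: needs >= 4 samples")
    return ElementResults(
        element=element,
        pam=pam,
        presence=presence,
        differential=differential,
        fold_changes=fold_changes,
        hosts=hosts,
        distance=distance,
        multivariate=multivariate,
        ordinations=ordinations,
        ko_submatrix=ko_sub,
    )


def run_all(config: RunConfig) -> dict[str, list[str]]:
    """Full workflow; returns the manifest. Raises ValidationFailure on bad input."""
    log: list[str] = [f"cnpskit {__version__}"]
    log.append(
        f"parameters: elements={','.join(config.elements)} alpha={config.alpha} "
        f"permutations={config.permutations} seed={config.seed} "
        f"nmds_starts={config.nmds_starts} mapping={config.mapping}"
    )
    mapping = load_mapping(config.mapping)
    bundle = _load_bundle(config)
    report = validate_bundle(bundle)
    for f in report.findings:
        log.append(f"validation {f.level} [{f.code}]: {f.message}")
    if report.errors:
        raise ValidationFailure(
            "input validation failed: "
            + "; ".join(f.message for f in report.errors)
        )

    results: dict[str, object] = {}
    for element in config.elements:
        results[element] = analyze_element(
            bundle,
            mapping,
            element,
            alpha=config.alpha,
            permutations=config.permutations,
            seed=config.seed,
            nmds_starts=config.nmds_starts,
            log=log,
        )

    manifest = write_results_tree(
        config.out, results, mapping, bundle.group, overwrite=config.overwrite
    )
    log_path = Path(config.out) / "run.log"
    log_path.write_text("\n".join(log) + "\n")
    manifest["log"] = ["run.log"]
    (Path(config.out) / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
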