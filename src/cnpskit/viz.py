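"""Publication-style outputs and the element-organized results tree.

Four plot families: fold-change heatmaps (symmetric diverging scale centred on
log2fc = 0), host-taxon heatmaps (row-wise max normalization), ordination
scatter plots annotated with explained variance or NMDS stress, and cycle
diagrams that tile per-process group-mean abundance onto an editable per-element
layout template (undetected processes greyed).  All plots are written as vector
PDFs with the embedded creation date omitted so identical inputs produce
identical files.

The results tree mirrors the workflow's published layout:

    Results/{Carbon,Nitrogen,Phosphorus,Sulfur}/
        beta_diversity/{Distance,PCoA,PCA,NMDS}/
        Gene/{Abundance,Cycle image,Heatmap}/
        Host_relative_Group/<process display name>/
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import importlib.resources

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .beta_diversity import DistanceMatrix, OrdinationResult
from .group_stats import MultivariateResult, UnivariateResult, differential_frame
from .host_taxonomy import HostProfile
from .ontology import ELEMENT_NAMES, CycleMapping
from .process_abundance import FoldChangeTable, PresenceVector, ProcessAbundanceMatrix
from .table_io import GroupTable

PDF_METADATA = {"CreationDate": None}  # omit timestamp: byte-stable output
PathLike = Union[str, Path]


@dataclass
class CycleDiagramTemplate:
    element: str
    nodes: dict[str, tuple[float, float]]  # process_id -> (x, y)
    arrows: list[tuple[str, str]]

    def validate_against(self, mapping: CycleMapping) -> None:
        expected = {p.process_id for p in mapping.processes_for_element(self.element)}
        if set(self.nodes) != expected:
            raise ValueError(
                f"template nodes do not match the {self.element} processes of the mapping"
            )
        for a, b in self.arrows:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"arrow ({a}, {b}) references unknown node")


def load_cycle_template(element: str, path: Optional[PathLike] = None) -> CycleDiagramTemplate:
    """Load the editable per-element diagram layout (packaged default or custom)."""
    if path is None:
        path = importlib.resources.files("cnpskit.data") / f"cycle_template_{element}.json"
    raw = json.loads(Path(path).read_text())
    return CycleDiagramTemplate(
        element=raw["element"],
        nodes={n["process_id"]: (n["x"], n["y"]) for n in raw["nodes"]},
        arrows=[tuple(a) for a in raw["arrows"]],
    )


@dataclass
class PlotSpec:
    kind: str  # heatmap | foldchange | ordination | cycle_diagram
    element: str
    data: object
    output_path: Path
    options: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# renderers

def _save(fig, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="pdf", metadata=PDF_METADATA, bbox_inches="tight")
    plt.close(fig)
    return path


def _heatmap(frame: pd.DataFrame, title: str, cmap: str, center: Optional[float] = None):
    fig, ax = plt.subplots(figsize=(max(3, 0.6 * frame.shape[1] + 2), max(2.5, 0.3 * frame.shape[0] + 1.5)))
    values = frame.to_numpy(dtype=float)
    if center is not None:
        limit = max(np.abs(values).max(), 1e-9)
        mesh = ax.pcolormesh(values, cmap=cmap, vmin=-limit, vmax=limit)
    else:
        mesh = ax.pcolormesh(values, cmap=cmap)
    ax.set_xticks(np.arange(frame.shape[1]) + 0.5, frame.columns, rotation=45, ha="right", fontsize=8)
    ax.set_yticks(np.arange(frame.shape[0]) + 0.5, frame.index, fontsize=8)
    ax.invert_yaxis()
    ax.set_title(title, fontsize=10)
    fig.colorbar(mesh, ax=ax, shrink=0.8)
    return fig


def render(spec: PlotSpec) -> Optional[Path]:
    """Render one PlotSpec to PDF; empty data is skipped with a warning."""
    kind = spec.kind
    if kind == "foldchange":
        frame = spec.data  # process x comparison log2fc matrix
        if frame.empty:
            warnings.warn(f"empty fold-change table: skipping {spec.output_path}", stacklevel=2)
            return None
        fig = _heatmap(
            frame,
            f"{ELEMENT_NAMES[spec.element]} cycle: log2 fold change",
            cmap="RdBu_r",
            center=0.0,
        )
        return _save(fig, spec.output_path)
    if kind == "heatmap":
        frame = spec.data  # taxon x group (or process x sample)
        if frame.empty:
            warnings.warn(f"empty table: skipping {spec.output_path}", stacklevel=2)
            return None
        # row-wise max normalization makes each taxon's profile comparable
        norm = frame.div(frame.max(axis=1).replace(0, 1.0), axis=0)
        fig = _heatmap(norm, spec.options.get("title", ""), cmap="viridis")
        return _save(fig, spec.output_path)
    if kind == "ordination":
        ordination: OrdinationResult = spec.data
        group: GroupTable = spec.options["group"]
        coords = ordination.coordinates
        if coords.shape[1] < 2:
            coords = coords.assign(_axis2=0.0)
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for g in group.groups:
            samples = [s for s in group.samples_in(g) if s in coords.index]
            ax.scatter(coords.iloc[:, 0].loc[samples], coords.iloc[:, 1].loc[samples], label=g, s=40)
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        labels = list(ordination.coordinates.columns)
        if ordination.method in ("PCoA", "PCA") and ordination.explained is not None:
            pct = ordination.explained * 100
            ax.set_xlabel(f"{labels[0]} ({pct[0]:.1f}%)")
            if len(pct) > 1 and len(labels) > 1:
                ax.set_ylabel(f"{labels[1]} ({pct[1]:.1f}%)")
        else:
            ax.set_xlabel(labels[0])
            if len(labels) > 1:
                ax.set_ylabel(labels[1])
        title = f"{ELEMENT_NAMES[spec.element]} cycle: {ordination.method}"
        if ordination.method == "NMDS" and ordination.stress is not None:
            title += f" (stress = {ordination.stress:.4f})"
        ax.set_title(title, fontsize=10)
        ax.legend(fontsize=8)
        return _save(fig, spec.output_path)
    if kind == "cycle_diagram":
        template: CycleDiagramTemplate = spec.options["template"]
        presence: PresenceVector = spec.options["presence"]
        by_group: pd.DataFrame = spec.data  # process x group mean abundance
        if by_group.empty:
            warnings.warn(f"empty abundance table: skipping {spec.output_path}", stacklevel=2)
            return None
        fig, ax = plt.subplots(figsize=(7, 7))
        for a, b in template.arrows:
            xa, ya = template.nodes[a]
            xb, yb = template.nodes[b]
            ax.annotate(
                "",
                xy=(xb, yb),
                xytext=(xa, ya),
                arrowprops=dict(arrowstyle="-|>", color="grey", lw=1.0, shrinkA=18, shrinkB=18),
            )
        vmax = max(by_group.to_numpy().max(), 1e-9)
        cmap = plt.get_cmap("YlOrRd")
        groups = list(by_group.columns)
        tile = 0.05
        for pid, (x, y) in template.nodes.items():
            detected = presence.presence.get(pid, False)
            ax.text(
                x,
                y + 0.09,
                pid.replace("_", " "),
                ha="center",
                fontsize=7,
                color="black" if detected else "lightgrey",
            )
            for gi, g in enumerate(groups):
                x0 = x + (gi - len(groups) / 2) * tile
                value = by_group.loc[pid, g] if pid in by_group.index else 0.0
                color = cmap(value / vmax) if detected else (0.9, 0.9, 0.9)
                ax.add_patch(plt.Rectangle((x0, y - tile / 2), tile, tile, facecolor=color, edgecolor="grey", lw=0.3))
        ax.set_xlim(-1.4, 1.4)
        ax.set_ylim(-1.4, 1.4)
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_title(f"{ELEMENT_NAMES[spec.element]} cycling processes", fontsize=11)
        return _save(fig, spec.output_path)
    raise ValueError(f"unknown plot kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# results tree

@dataclass
class ElementResults:
    """All computed artifacts for one element, ready to be written."""

    element: str
    pam: ProcessAbundanceMatrix
    presence: PresenceVector
    differential: list[UnivariateResult]
    fold_changes: list[FoldChangeTable]
    hosts: list[HostProfile]
    distance: Optional[DistanceMatrix]
    multivariate: list[MultivariateResult]
    ordinations: list[OrdinationResult]
    ko_submatrix: Optional[pd.DataFrame] = None


def write_results_tree(
    root: PathLike,
    results: dict[str, ElementResults],
    mapping: CycleMapping,
    group: GroupTable,
    overwrite: bool = False,
) -> dict[str, list[str]]:
    """Write the full Results tree and return a category -> paths manifest.

    Refuses to write into an existing non-empty root unless ``overwrite``.
    The manifest (Results/manifest.json) lists every file written, by category.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"output root {root} is not empty (use overwrite)")
    manifest: dict[str, list[str]] = {}

    def record(category: str, path: Path) -> None:
        manifest.setdefault(category, []).append(str(path.relative_to(root)))

    for element, res in results.items():
        el_dir = root / ELEMENT_NAMES[element]

        # --- beta diversity ------------------------------------------------
        dist_dir = el_dir / "beta_diversity" / "Distance"
        dist_dir.mkdir(parents=True, exist_ok=True)
        if res.distance is not None:
            p = dist_dir / "bray_curtis.tsv"
            res.distance.to_frame().to_csv(p, sep="\t")
            record("distance", p)
            if res.multivariate:
                rows = [
                    {
                        "method": m.method,
                        "statistic": m.statistic,
                        "p": m.p,
                        "n_permutations": m.n_permutations,
                        "seed": m.seed,
                    }
                    for m in res.multivariate
                ]
                p = dist_dir / "multivariate_tests.tsv"
                pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
                record("distance", p)
        for ordn in res.ordinations:
            sub = el_dir / "beta_diversity" / ordn.method
            sub.mkdir(parents=True, exist_ok=True)
            p = sub / "coordinates.tsv"
            ordn.coordinates.to_csv(p, sep="\t")
            record("ordination", p)
            meta = {"method": ordn.method}
            if ordn.explained is not None:
                meta["explained"] = [float(v) for v in ordn.explained]
            if ordn.stress is not None:
                meta["stress"] = ordn.stress
                meta["seed"] = ordn.seed
            if ordn.negative_eigenvalues is not None and len(ordn.negative_eigenvalues):
                meta["negative_eigenvalues"] = [float(v) for v in ordn.negative_eigenvalues]
            p = sub / "metadata.json"
            p.write_text(json.dumps(meta, indent=1))
            record("ordination", p)
            plot = render(
                PlotSpec(
                    kind="ordination",
                    element=element,
                    data=ordn,
                    output_path=sub / f"{ordn.method.lower()}.pdf",
                    options={"group": group},
                )
            )
            if plot:
                record("plot", plot)

        # --- gene-level outputs --------------------------------------------
        ab_dir = el_dir / "Gene" / "Abundance"
        ab_dir.mkdir(parents=True, exist_ok=True)
        p = ab_dir / "process_abundance.tsv"
        res.pam.values.to_csv(p, sep="\t")
        record("gene_abundance", p)
        p = ab_dir / "process_presence.tsv"
        pd.Series(res.presence.presence, name="present").to_csv(p, sep="\t")
        record("gene_abundance", p)
        if res.ko_submatrix is not None:
            p = ab_dir / "ko_abundance.tsv"
            res.ko_submatrix.to_csv(p, sep="\t")
            record("gene_abundance", p)

        cycle_dir = el_dir / "Gene" / "Cycle image"
        cycle_dir.mkdir(parents=True, exist_ok=True)
        for fc in res.fold_changes:
            p = cycle_dir / f"fold_change_{fc.reference_group}_vs_{fc.target_group}.tsv"
            fc.table.to_csv(p, sep="\t")
            record("fold_change", p)
        by_group = pd.DataFrame(
            {g: res.pam.values[group.samples_in(g)].mean(axis=1) for g in group.groups}
        )
        template = load_cycle_template(element)
        plot = render(
            PlotSpec(
                kind="cycle_diagram",
                element=element,
                data=by_group,
                output_path=cycle_dir / "cycle_diagram.pdf",
                options={"template": template, "presence": res.presence},
            )
        )
        if plot:
            record("plot", plot)

        heat_dir = el_dir / "Gene" / "Heatmap"
        heat_dir.mkdir(parents=True, exist_ok=True)
        p = heat_dir / "differential_tests.tsv"
        differential_frame(res.differential).to_csv(p, sep="\t")
        record("differential", p)
        if res.fold_changes:
            log2fc = pd.DataFrame(
                {
                    f"{fc.target_group}_vs_{fc.reference_group}": fc.table["log2fc"]
                    for fc in res.fold_changes
                }
            )
            plot = render(
                PlotSpec(
                    kind="foldchange",
                    element=element,
                    data=log2fc,
                    output_path=heat_dir / "fold_change_heatmap.pdf",
                )
            )
            if plot:
                record("plot", plot)

        # --- host taxonomy -------------------------------------------------
        host_root = el_dir / "Host_relative_Group"
        host_root.mkdir(parents=True, exist_ok=True)
        display = {pr.process_id: pr.display_name for pr in mapping.processes_for_element(element)}
        for profile in res.hosts:
            proc_dir = host_root / display.get(profile.process_id, profile.process_id)
            proc_dir.mkdir(parents=True, exist_ok=True)
            rel = profile.relative_by_group
            p = proc_dir / f"{profile.rank}.csv"
            (rel if rel is not None else pd.DataFrame()).to_csv(p)
            record("host", p)
            if rel is not None and not rel.empty:
                plot = render(
                    PlotSpec(
                        kind="heatmap",
                        element=element,
                        data=rel,
                        output_path=proc_dir / f"{profile.rank}.pdf",
                        options={
                            "title": f"{display.get(profile.process_id, profile.process_id)}: {profile.rank}"
                        },
                    )
                )
                if plot:
                    record("plot", plot)

    manifest_path = root / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
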