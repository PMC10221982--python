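"""End-to-end orchestration and machine-readable reports.

``run_pipeline`` chains rooting, cluster detection, reconciliation,
retention classification and WGD association over one gene family, and
emits a report validated against the :class:`Report` pydantic model
(a JSON Schema copy ships in ``schemas/``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from . import dfd as dfd_mod
from .dfd import ClusterAssignment, DFDConfig, WGDEvent, analyze_family, count_dual_retainers
from .reconcile import count_losses
from .treekit import GeneTree, SpeciesTree, root_with_outgroup

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "EventReport",
    "Report",
    "run_pipeline",
    "build_report",
    "render_summary",
    "read_wgd_table",
    "read_keyvalue_config",
]


class EventReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gene_clade: list[str]
    mapped_species: str
    age_lower: float
    age_upper: float
    child_species: list[list[str]]
    completeness: list[float] | None = None
    verdict: str | None = None
    wgd_matches: list[dict] = []


class Report(BaseModel):
    """Schema of the JSON report written by the ``dfd`` and ``run`` commands."""

    model_config = ConfigDict(extra="forbid")

    n_leaves: int
    outgroup: list[str]
    hybrids_excluded: list[str]
    clusters: dict[str, list[str]]
    subclusters: dict[str, list[str]]
    coverage: dict[str, dict[str, bool]]
    events: list[EventReport]
    n_duplications: int
    n_losses: int
    dual_retainers: int


@dataclass
class RunConfig:
    """Inputs of one pipeline run; every path must exist at run time."""

    gene_tree_path: Path | None = None
    species_tree_path: Path | None = None
    wgd_path: Path | None = None
    family_tag: str = "GUS"
    outgroup: frozenset[str] = frozenset()
    dfd: DFDConfig = field(default_factory=DFDConfig)
    resolve_polytomies: bool = False


def read_keyvalue_config(path) -> dict[str, str]:
    """Parse a plain ``key=value`` config file; ``#`` starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_wgd_table(path) -> list[WGDEvent]:
    """TSV with header ``name branch_node_label age_min age_max``."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    required = ["name", "branch_node_label", "age_min", "age_max"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"WGD table is missing columns: {missing}")
    return [
        WGDEvent(
            name=row.name_, species_node=row.branch_node_label,
            age_min=float(row.age_min), age_max=float(row.age_max),
        )
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def build_report(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    config: DFDConfig,
    wgd_table: list[WGDEvent] | None = None,
    outgroup: frozenset[str] = frozenset(),
) -> tuple[Report, ClusterAssignment]:
    """Run the full analysis in memory and return the validated report."""
    if outgroup:
        gene_tree = root_with_outgroup(gene_tree, outgroup)
    events, recon, removed, pruned = analyze_family(
        gene_tree, species_tree, config, wgd_table=wgd_table,
        outgroup_labels=outgroup,
    )
    assignment = dfd_mod.detect_clusters(pruned, config, outgroup_labels=outgroup)
    losses = count_losses(pruned, species_tree, recon)
    report = Report(
        n_leaves=len(gene_tree.leaves()),
        outgroup=sorted(outgroup),
        hybrids_excluded=sorted(removed),
        clusters={k: sorted(v) for k, v in assignment.clusters.items()},
        subclusters={k: sorted(v) for k, v in assignment.subclusters.items()},
        coverage=assignment.coverage,
        events=[EventReport(**e.to_dict()) for e in events],
        n_duplications=len(events),
        n_losses=losses,
        dual_retainers=count_dual_retainers(assignment),
    )
    # round-trip through the schema so every emitted report is validated
    Report.model_validate(report.model_dump())
    return report, assignment


def render_summary(report: Report, config: DFDConfig) -> str:
    """Plain-text narrative mirroring the structure of the tree analysis."""
    lines = []
    n_phyla = len(config.required_phyla)
    full = [
        name for name, row in report.coverage.items()
        if name in report.clusters and all(row.values())
    ]
    lines.append(
        f"Gene family with {report.n_leaves} copies; "
        f"{len(report.clusters)} main cluster(s), of which {len(full)} cover "
        f"all {n_phyla} required phyla."
    )
    for name in sorted(report.clusters):
        subs = sorted(s for s in report.subclusters if s.startswith(name + "."))
        subtxt = f"; sub-lineages: {', '.join(subs)}" if subs else ""
        lines.append(
            f"  cluster {name}: {len(report.clusters[name])} copies{subtxt}"
        )
    lines.append(
        f"{report.n_duplications} duplication event(s), {report.n_losses} "
        f"implied loss(es)."
    )
    for ev in report.events:
        wgds = ", ".join(
            m["name"] + ("" if m["age_consistent"] else " (age-inconsistent)")
            for m in ev.wgd_matches
        ) or "none"
        comp = (
            "/".join(f"{c:.2f}" for c in ev.completeness)
            if ev.completeness else "n/a"
        )
        lines.append(
            f"  {ev.verdict or 'UNCLASSIFIED'}: duplication at {ev.mapped_species} "
            f"({ev.age_lower:.0f}-{ev.age_upper:.0f} Mya), retention {comp}, "
            f"candidate WGDs: {wgds}"
        )
    lines.append(
        f"{report.dual_retainers} species retain copies in both cluster 1 and cluster 3."
    )
    if report.hybrids_excluded:
        lines.append(
            "Hybrid-taxon copies excluded from inference: "
            + ", ".join(report.hybrids_excluded)
        )
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: RunConfig,
    wgd_table: list[WGDEvent] | None = None,
    out_path: Path | None = None,
) -> Report:
    """Load inputs per ``config``, analyse, optionally write the JSON report."""
    if config.gene_tree_path is None or config.species_tree_path is None:
        raise FileNotFoundError("gene tree and species tree paths are required")
    for p in (config.gene_tree_path, config.species_tree_path, config.wgd_path):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input not found: {p}")
    species = SpeciesTree.from_newick(Path(config.species_tree_path).read_text())
    gene = GeneTree.from_newick(
        Path(config.gene_tree_path).read_text(), family_tag=config.family_tag
    )
    if config.resolve_polytomies:
        gene = gene.resolve_polytomies()
    if wgd_table is None and config.wgd_path is not None:
        wgd_table = read_wgd_table(config.wgd_path)
    report, _ = build_report(
        gene, species, config.dfd, wgd_table=wgd_table, outgroup=config.outgroup
    )
    if out_path is not None:
        Path(out_path).write_text(report.model_dump_json(indent=2) + "\n")
    return report
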