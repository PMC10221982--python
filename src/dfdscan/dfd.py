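"""Duplication-plus-functional-differentiation (DFD) analysis.

A duplication whose two daughter copies differentiated in expression or
function tends to be retained in *every* descendant species; in the gene
tree this shows up as a "double-gene phylum": two sister clades with
identical species composition hanging off the duplication node.  This
module detects the phylum-covering clusters of a gene family, measures per
-event retention completeness, applies the double-gene-phylum test, and
classifies each duplication:

* ``DFD_LIKELY`` — complete double-gene phylum and an ancient event (age
  lower bound at or above ``ancient_cutoff``);
* ``RETAINED_RECENT`` — complete, but too recent for retention alone to be
  informative (not enough time for losses to accrue);
* ``NON_DFD_LOSSY`` — incomplete, with losses spanning a whole family of
  taxa or a large fraction of descendants;
* ``AMBIGUOUS`` — anything else.

Classified events can then be associated with known whole-genome
duplications (WGDs) by species-tree branch and age-interval overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

from .reconcile import (
    DEFAULT_ROOT_AGE_CEILING,
    DuplicationEvent,
    ReconMap,
    Verdict,
    infer_duplications,
    lca_map,
)
from .treekit import GeneTree, SpeciesTree, TreeError

logger = logging.getLogger(__name__)

__all__ = [
    "DFDConfig",
    "ClusterAssignment",
    "WGDEvent",
    "detect_clusters",
    "assign_cluster_names",
    "retention_completeness",
    "is_double_gene_phylum",
    "classify_dfd",
    "map_to_wgd",
    "expected_genetic_distance",
    "count_dual_retainers",
    "prune_hybrid_leaves",
    "analyze_family",
    "FREE_RECOMBINATION_CM",
]

#: Genetic distance (cM) above which two loci assort essentially freely.
FREE_RECOMBINATION_CM = 50.0


@dataclass(frozen=True)
class DFDConfig:
    """Knobs of the retention analysis.

    ``tol`` is the fraction of descendant species allowed to be missing
    from each daughter clade while still counting as a double-gene phylum
    (0 = strict identical species composition).  ``ancient_cutoff`` (Mya)
    separates duplications old enough for complete retention to suggest
    functional differentiation from recent ones.  ``required_phyla`` maps
    phylum names to their member taxa and drives cluster detection.
    """

    tol: float = 0.0
    ancient_cutoff: float = 100.0
    required_phyla: dict[str, frozenset[str]] = field(default_factory=dict)
    root_age_ceiling: float = DEFAULT_ROOT_AGE_CEILING
    taxon_families: dict[str, str] = field(default_factory=dict)
    lossy_fraction: float = 0.5
    hybrid_taxa: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.tol < 1.0:
            raise ValueError("tol must lie in [0, 1)")
        if self.ancient_cutoff <= 0:
            raise ValueError("ancient_cutoff must be positive")
        if not 0.0 < self.lossy_fraction <= 1.0:
            raise ValueError("lossy_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class WGDEvent:
    """A known whole-genome duplication on a species-tree branch.

    ``species_node`` is the label (or tip taxon) of the node at the bottom
    of the branch on which the event occurred; the age interval is in Mya.
    """

    name: str
    species_node: str
    age_min: float
    age_max: float

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ValueError(f"WGD {self.name!r}: age_min exceeds age_max")


@dataclass
class ClusterAssignment:
    """Named clusters (disjoint clades) and their duplication-split subclusters."""

    tree: GeneTree
    clusters: dict[str, frozenset[str]] = field(default_factory=dict)
    subclusters: dict[str, frozenset[str]] = field(default_factory=dict)
    coverage: dict[str, dict[str, bool]] = field(default_factory=dict)
    cluster_nodes: dict[str, dendropy.Node] = field(default_factory=dict)

    def group_of(self, leaf_label: str) -> str | None:
        """Innermost group (subcluster if any, else cluster) of a leaf."""
        for name, members in self.subclusters.items():
            if leaf_label in members:
                return name
        for name, members in self.clusters.items():
            if leaf_label in members:
                return name
        return None


def _species_overlap_duplication(tree: GeneTree, node: dendropy.Node,
                                 ignore: frozenset[str]) -> bool:
    """Species-overlap test: a node is a duplication when two children share taxa."""
    kids = node.child_nodes()
    sets = [
        frozenset(t for t in tree.species_set(k) if t not in ignore) for k in kids
    ]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if sets[i] & sets[j]:
                return True
    return False


def detect_clusters(
    gene_tree: GeneTree,
    config: DFDConfig,
    outgroup_labels: frozenset[str] = frozenset(),
) -> ClusterAssignment:
    """Find the main phylum-covering clusters and their subclusters.

    Starting from the ingroup root, duplication nodes (species-overlap
    test) whose children all still cover every required phylum split the
    family into progressively smaller clusters; recursion stops at clades
    that either are speciation nodes or whose children lose phylum
    coverage, and those clades are the reported clusters.  Inside each
    cluster, the shallowest duplication nodes split off subclusters (the
    ``3.1``/``3.2`` pattern).  Cluster names here are provisional ordinals;
    :func:`assign_cluster_names` anchors them to reference labels.
    """
    if not config.required_phyla:
        raise ValueError("config.required_phyla must name at least one phylum")
    ignore_taxa = frozenset(config.hybrid_taxa)

    def species(node: dendropy.Node) -> frozenset[str]:
        return frozenset(
            gene_tree.taxon_of(lf)
            for lf in node.leaf_iter()
            if gene_tree.node_label(lf) not in outgroup_labels
            and gene_tree.taxon_of(lf) not in ignore_taxa
        )

    def covers(node: dendropy.Node) -> bool:
        sp = species(node)
        return all(sp & members for members in config.required_phyla.values())

    def coverage_row(node: dendropy.Node) -> dict[str, bool]:
        sp = species(node)
        return {ph: bool(sp & members) for ph, members in config.required_phyla.items()}

    ingroup_leaves = [
        lf for lf in gene_tree.leaves()
        if gene_tree.node_label(lf) not in outgroup_labels
    ]
    assignment = ClusterAssignment(tree=gene_tree)
    if not ingroup_leaves:
        logger.warning("no ingroup leaves; empty cluster assignment")
        return assignment
    if len(ingroup_leaves) == 1:
        node = ingroup_leaves[0]
        name = "1"
        assignment.clusters[name] = gene_tree.leaf_set(node)
        assignment.coverage[name] = coverage_row(node)
        assignment.cluster_nodes[name] = node
        return assignment

    root = gene_tree.mrca_of_leaves(
        gene_tree.node_label(lf) for lf in ingroup_leaves
    )
    if not covers(root):
        logger.warning(
            "no clade covers all required phyla; empty cluster assignment"
        )
        return assignment

    cluster_roots: list[dendropy.Node] = []

    def descend(node: dendropy.Node) -> None:
        if (
            not node.is_leaf()
            and _species_overlap_duplication(gene_tree, node, ignore_taxa)
            and all(covers(k) for k in node.child_nodes())
        ):
            for k in node.child_nodes():
                descend(k)
        else:
            cluster_roots.append(node)

    descend(root)

    for i, cnode in enumerate(cluster_roots, start=1):
        name = str(i)
        members = frozenset(
            gene_tree.node_label(lf)
            for lf in cnode.leaf_iter()
            if gene_tree.node_label(lf) not in outgroup_labels
        )
        assignment.clusters[name] = members
        assignment.coverage[name] = coverage_row(cnode)
        assignment.cluster_nodes[name] = cnode

        # shallowest duplication nodes inside the cluster spawn subclusters
        sub_children: list[dendropy.Node] = []

        def find_subs(node: dendropy.Node) -> None:
            if node.is_leaf():
                return
            if _species_overlap_duplication(gene_tree, node, ignore_taxa):
                sub_children.extend(node.child_nodes())
                return
            for k in node.child_nodes():
                find_subs(k)

        find_subs(cnode)
        j = 0
        for snode in sub_children:
            members_sub = frozenset(
                gene_tree.node_label(lf)
                for lf in snode.leaf_iter()
                if gene_tree.node_label(lf) not in outgroup_labels
            )
            if not members_sub:
                continue
            j += 1
            sname = f"{name}.{j}"
            assignment.subclusters[sname] = members_sub
            assignment.coverage[sname] = coverage_row(snode)
    return assignment


def assign_cluster_names(
    assignment: ClusterAssignment,
    reference_labels: dict[str, str],
    family_tag: str | None = None,
) -> GeneTree:
    """Rename clusters after reference anchors and relabel every leaf.

    ``reference_labels`` maps known leaf labels to conventional cluster
    names (e.g. the *Arabidopsis*-anchored ``1``/``3`` convention).  Each
    anchored cluster takes its anchor's name; unanchored clusters get the
    smallest unused ordinals in detection order.  Leaves are renamed
    ``<taxon><family_tag><group>``, where the group is the subcluster name
    when the leaf sits in one, with ``.a``, ``.b``... appended when a
    species keeps several copies in the same group.
    """
    tag = family_tag or assignment.tree.family_tag or "GUS"
    final: dict[str, str] = {}
    used_names: dict[str, str] = {}
    for prov, members in assignment.clusters.items():
        anchors = {reference_labels[l] for l in members if l in reference_labels}
        if len(anchors) > 1:
            raise TreeError(
                f"cluster {prov} holds reference labels from different clusters: "
                f"{sorted(anchors)}"
            )
        if anchors:
            name = anchors.pop()
            if name in used_names:
                raise TreeError(
                    f"reference cluster {name!r} is split across gene-tree clusters"
                )
            final[prov] = name
            used_names[name] = prov
    counter = 1
    for prov in assignment.clusters:
        if prov in final:
            continue
        while str(counter) in used_names:
            counter += 1
        final[prov] = str(counter)
        used_names[str(counter)] = prov
        counter += 1

    # group name (after renaming) per leaf
    group_of: dict[str, str] = {}
    for prov, members in assignment.clusters.items():
        for lf in members:
            group_of[lf] = final[prov]
    for sname, members in assignment.subclusters.items():
        prov, _, idx = sname.rpartition(".")
        renamed = f"{final[prov]}.{idx}"
        for lf in members:
            group_of[lf] = renamed

    # ordinal letters for same-taxon same-group copies, in tree order
    tree = assignment.tree
    per_group: dict[tuple[str, str], list[str]] = {}
    for lf in tree.leaves():
        label = tree.node_label(lf)
        if label in group_of:
            key = (tree.taxon_of(label), group_of[label])
            per_group.setdefault(key, []).append(label)

    mapping: dict[str, str] = {}
    for (taxon, group), labels in per_group.items():
        if len(labels) == 1:
            mapping[labels[0]] = f"{taxon}{tag}{group}"
        else:
            for k, label in enumerate(labels):
                letter = chr(ord("a") + k)
                mapping[label] = f"{taxon}{tag}{group}.{letter}"
    return tree.relabeled(mapping, family_tag=tag)


def retention_completeness(
    event: DuplicationEvent,
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    family_species: frozenset[str],
) -> tuple[float, float]:
    """Fraction of the event's descendant species present in each daughter.

    The denominator is the extant descendant set of the mapped species node
    restricted to ``family_species`` (taxa with at least one copy anywhere
    in the family), so unsampled genomes do not count as losses.  The
    result is stored on the event.
    """
    descendants = species_tree.descendant_taxa(event.species_node)
    denom = frozenset(descendants & family_species)
    if not denom:
        raise TreeError(
            "empty completeness denominator: reconciliation is inconsistent with "
            "the supplied family species set"
        )
    fractions = tuple(
        len(child & denom) / len(denom) for child in event.child_species_sets
    )
    event.completeness = fractions  # type: ignore[assignment]
    event.denominator_taxa = denom
    return fractions  # type: ignore[return-value]


def is_double_gene_phylum(
    event: DuplicationEvent,
    completeness: tuple[float, float],
    tol: float = 0.0,
) -> bool:
    """True when both daughter clades retain (almost) all descendant species."""
    return all(c >= 1.0 - tol for c in completeness)


def classify_dfd(
    event: DuplicationEvent,
    completeness: tuple[float, float],
    config: DFDConfig,
) -> Verdict:
    """Assign one verdict to the event (stored on it as well)."""
    if is_double_gene_phylum(event, completeness, config.tol):
        if event.age_lower >= config.ancient_cutoff:
            verdict = Verdict.DFD_LIKELY
        else:
            verdict = Verdict.RETAINED_RECENT
    else:
        denom = event.denominator_taxa or frozenset()
        lossy = False
        for child in event.child_species_sets:
            missing = denom - child
            if denom and len(missing) / len(denom) >= config.lossy_fraction:
                lossy = True
            if config.taxon_families:
                by_family: dict[str, set[str]] = {}
                for taxon in denom:
                    fam = config.taxon_families.get(taxon)
                    if fam is not None:
                        by_family.setdefault(fam, set()).add(taxon)
                for fam_taxa in by_family.values():
                    if len(fam_taxa) >= 2 and fam_taxa <= missing:
                        lossy = True
        low = min(completeness)
        verdict = Verdict.NON_DFD_LOSSY if (low < 1.0 - config.tol and lossy) else Verdict.AMBIGUOUS
    event.verdict = verdict
    return verdict


def map_to_wgd(
    event: DuplicationEvent,
    wgd_table: list[WGDEvent],
    species_tree: SpeciesTree,
) -> list[tuple[WGDEvent, bool]]:
    """Known WGDs on the event's branch, flagged by age-interval overlap.

    The duplication happened on the branch above its mapped species node,
    so only WGDs assigned to that same branch are candidates; the flag
    records whether the WGD's age interval intersects the event's
    ``[age_lower, age_upper]``.
    """
    node_by_id = {species_tree.node_id(n): n for n in species_tree.nodes()}
    matches = []
    for wgd in wgd_table:
        node = node_by_id.get(wgd.species_node)
        if node is None:
            raise TreeError(
                f"WGD {wgd.name!r}: species node {wgd.species_node!r} not found"
            )
        if node is not event.species_node:
            continue
        overlap = (
            max(event.age_lower, wgd.age_min) <= min(event.age_upper, wgd.age_max)
        )
        matches.append((wgd, overlap))
    return matches


def expected_genetic_distance(
    physical_mb: float, ratio_cm_per_mb: float = 2.0
) -> tuple[float, bool]:
    """Genetic distance implied by a physical distance and a cM/Mb ratio.

    Returns the distance in centimorgans and a flag marking effectively
    free recombination (>= 50 cM).
    """
    if physical_mb < 0 or ratio_cm_per_mb < 0:
        raise ValueError("physical distance and cM/Mb ratio must be non-negative")
    cm = physical_mb * ratio_cm_per_mb
    return cm, cm >= FREE_RECOMBINATION_CM


def count_dual_retainers(
    assignment: ClusterAssignment,
    cluster_a: str = "1",
    cluster_b: str = "3",
) -> int:
    """Number of species keeping at least one copy in each of two clusters."""
    tree = assignment.tree

    def taxa(cluster: str) -> frozenset[str]:
        members = assignment.clusters.get(cluster, frozenset())
        return frozenset(tree.taxon_of(l) for l in members)

    return len(taxa(cluster_a) & taxa(cluster_b))


def prune_hybrid_leaves(
    gene_tree: GeneTree, hybrid_taxa: frozenset[str]
) -> tuple[GeneTree, list[str]]:
    """Drop leaves of known hybrid/allopolyploid taxa before inference.

    Hybrids carry homoeologous copies that cluster with each parental
    lineage and would masquerade as duplications.  Returns the pruned tree
    and the removed leaf labels (reported separately downstream).
    """
    removed = [
        gene_tree.node_label(lf)
        for lf in gene_tree.leaves()
        if gene_tree.taxon_of(lf) in hybrid_taxa
    ]
    if not removed:
        return gene_tree, []
    keep = [l for l in gene_tree.leaf_labels() if l not in set(removed)]
    if not keep:
        raise TreeError("pruning hybrid taxa would remove every leaf")
    work = gene_tree.copy()
    dtree = work.dendropy_tree
    taxa = [lf.taxon for lf in dtree.leaf_node_iter() if lf.taxon.label in set(keep)]
    dtree.retain_taxa(taxa)
    dtree.suppress_unifurcations()
    pruned = GeneTree(
        dtree,
        family_tag=gene_tree.family_tag,
        taxon_map={l: gene_tree.taxon_of(l) for l in keep},
    )
    return pruned, removed


def analyze_family(
    gene_tree: GeneTree,
    species_tree: SpeciesTree,
    config: DFDConfig,
    wgd_table: list[WGDEvent] | None = None,
    outgroup_labels: frozenset[str] = frozenset(),
) -> tuple[list[DuplicationEvent], ReconMap, list[str], GeneTree]:
    """Reconcile, measure completeness and classify every duplication.

    Hybrid taxa from the config are pruned first; returns the classified
    events, the reconciliation map, the removed hybrid leaves, and the
    (possibly pruned) gene tree the map refers to.
    """
    pruned, removed = prune_hybrid_leaves(gene_tree, config.hybrid_taxa)
    recon = lca_map(pruned, species_tree)
    events = infer_duplications(
        pruned, species_tree, recon, root_age_ceiling=config.root_age_ceiling
    )
    family_species = frozenset(
        pruned.taxon_of(lf)
        for lf in pruned.leaves()
        if pruned.node_label(lf) not in outgroup_labels
    )
    for event in events:
        completeness = retention_completeness(
            event, pruned, species_tree, family_species
        )
        classify_dfd(event, completeness, config)
    if wgd_table:
        for event in events:
            event.wgd_matches = map_to_wgd(event, wgd_table, species_tree)
    return events, recon, removed, pruned
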