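"""Synthetic gene-family histories with known ground truth.

The generator emulates the processes the retention analysis is built to
detect: a gene family evolving down a dated species tree under

* lineage-specific duplication (rate ``lambda_dup`` per lineage per Myr) and
  loss (``lambda_loss``), with exponential waiting times along branches;
* episodic whole-genome duplications (WGDs) pinned to a species-tree branch
  at a fixed age, doubling every live lineage, the new copy surviving with
  a per-event retention probability;
* a *differentiation lock*: with probability ``p_dfd`` a duplication is
  "locked" — both daughter copies are functionally differentiated and their
  loss rate is multiplied by ``lock_loss_factor`` (0 by default, i.e. fully
  protected).  The lock is inherited by descendant copies.

Every simulated event is written to an :class:`EventLog`, so duplication
inference and DFD classification can be scored against the truth.  The
module also builds a small five-species demo family (one moss outgroup plus
four angiosperm lineages, 14 gene copies) used throughout the docs and
tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import CDSRecord
from .dfd import WGDEvent
from .treekit import GeneTree, SpeciesTree

__all__ = [
    "SimWGD",
    "SimParams",
    "SimEvent",
    "DetectableDuplication",
    "EventLog",
    "ConfusionSummary",
    "simulate_species_tree",
    "evolve_gene_family",
    "enumerate_rooted_topologies",
    "topology_newick",
    "random_dated_species_tree",
    "random_reconciliation_instance",
    "make_demo_fixture",
    "DemoFixture",
    "make_curation_table",
    "truth_vs_inferred",
]


@dataclass(frozen=True)
class SimWGD:
    """A whole-genome duplication placed on one species-tree branch.

    ``species_node`` names the node at the *bottom* of the branch carrying
    the event; ``age`` must lie strictly inside that branch's age interval.
    """

    name: str
    species_node: str
    age: float
    retention_prob: float = 1.0


@dataclass(frozen=True)
class SimParams:
    """Rates and probabilities of the gene-family process (per Myr)."""

    lambda_dup: float = 0.002
    lambda_loss: float = 0.001
    p_dfd: float = 0.0
    lock_loss_factor: float = 0.0
    wgd_events: tuple[SimWGD, ...] = ()
    lock_min_age: float | None = None
    family_tag: str = "GUS"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lambda_dup, self.lambda_loss, self.lock_loss_factor) < 0:
            raise ValueError("rates and factors must be non-negative")
        if not 0.0 <= self.p_dfd <= 1.0:
            raise ValueError("p_dfd must lie in [0, 1]")
        for w in self.wgd_events:
            if not 0.0 <= w.retention_prob <= 1.0:
                raise ValueError(f"WGD {w.name!r}: retention_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SimEvent:
    time: float  # age, Mya
    species_branch: str  # label of the node at the bottom of the branch
    kind: str  # DUP | LOSS | WGD_RETAIN | WGD_LOSE | LOCK
    lineage: int
    parent_lineage: int | None
    locked: bool


@dataclass(frozen=True)
class DetectableDuplication:
    """A logged duplication both of whose daughters left extant descendants."""

    event_index: int
    kind: str  # DUP or WGD_RETAIN
    time: float
    species_branch: str
    branch_bottom_age: float  # age of the species node below the carrying branch
    locked: bool
    child_leaf_sets: tuple[frozenset[str], frozenset[str]]


@dataclass
class EventLog:
    events: list[SimEvent] = field(default_factory=list)
    detectable: list[DetectableDuplication] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "time": e.time,
                    "species_branch": e.species_branch,
                    "kind": e.kind,
                    "lineage": e.lineage,
                    "parent_lineage": e.parent_lineage,
                    "locked": int(e.locked),
                }
                for e in self.events
            ],
            columns=["time", "species_branch", "kind", "lineage", "parent_lineage", "locked"],
        )


# -- species-tree simulation ----------------------------------------------------


def _taxon_code(i: int) -> str:
    letters = []
    for _ in range(4):
        letters.append(chr(ord("a") + i % 26))
        i //= 26
    return "Sp" + "".join(reversed(letters))


def simulate_species_tree(
    n_tips: int,
    birth_rate: float,
    death_rate: float = 0.0,
    seed: int = 0,
    root_age: float | None = None,
    retry_cap: int = 100,
) -> SpeciesTree:
    """Sample a dated species tree under a constant-rate birth-death process.

    The process starts from two lineages at the root and runs forward until
    ``n_tips`` lineages are alive; the present is drawn uniformly between
    that moment and the next event, so pendant edges have positive length.
    If ``root_age`` is given the tree is rescaled so the root sits at that
    age (Mya).  Full extinction triggers a resample, up to ``retry_cap``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    for _ in range(retry_cap):
        # alive: list of (node_dict); node_dict = {"t_birth": t, "children": []}
        root = {"t": 0.0, "children": []}
        a = {"t": None, "children": [], "parent": root}
        b = {"t": None, "children": [], "parent": root}
        root["children"] = [a, b]
        alive = [a, b]
        t = 0.0
        failed = False
        while len(alive) < n_tips:
            total = len(alive) * (birth_rate + death_rate)
            t += rng.exponential(1.0 / total)
            idx = rng.integers(len(alive))
            node = alive.pop(int(idx))
            if rng.random() < birth_rate / (birth_rate + death_rate):
                node["t"] = t
                c1 = {"t": None, "children": [], "parent": node}
                c2 = {"t": None, "children": [], "parent": node}
                node["children"] = [c1, c2]
                alive.extend([c1, c2])
            else:
                node["t"] = t
                node["dead"] = True
            if not alive:
                failed = True
                break
        if failed:
            continue
        total = len(alive) * (birth_rate + death_rate)
        present = t + rng.uniform() * rng.exponential(1.0 / total)
        for node in alive:
            node["t"] = present

        # prune extinct lineages, suppress unary nodes
        def prune(node):
            if not node["children"]:
                return None if node.get("dead") else node
            kept = [prune(c) for c in node["children"]]
            kept = [k for k in kept if k is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            node["children"] = kept
            return node

        pruned = prune(root)
        if pruned is None or not pruned["children"]:
            continue
        tips = [n for n in _iter_tree(pruned) if not n["children"]]
        if len(tips) != n_tips:
            continue

        scale = 1.0
        span = present - pruned["t"]
        if root_age is not None:
            scale = root_age / span
        for i, tip in enumerate(tips):
            tip["name"] = _taxon_code(i)

        def newick(node) -> str:
            if not node["children"]:
                length = (present - node["parent_t"]) * scale
                return f"{node['name']}:{length:.10g}"
            for c in node["children"]:
                c["parent_t"] = node["t"]
            inner = ",".join(newick(c) for c in node["children"])
            if node is pruned:
                return f"({inner})"
            length = (node["t"] - node["parent_t"]) * scale
            return f"({inner}):{length:.10g}"

        return SpeciesTree.from_newick(newick(pruned) + ";")

    raise RuntimeError(f"species-tree simulation failed {retry_cap} times (all lineages died)")


def _iter_tree(node):
    yield node
    for c in node["children"]:
        yield from _iter_tree(c)


# -- gene-family simulation -----------------------------------------------------


@dataclass
class _Lineage:
    lid: int
    locked: bool


@dataclass
class _GNode:
    """Gene-tree node under construction."""

    age: float
    children: list["_GNode"] = field(default_factory=list)
    leaf_lineage: int | None = None
    taxon: str | None = None
    event_index: int | None = None


def evolve_gene_family(
    species_tree: SpeciesTree,
    params: SimParams,
) -> tuple[GeneTree | None, EventLog]:
    """Evolve one gene family down ``species_tree``; returns tree + truth log.

    Extant copies become leaves named ``<taxon><family_tag><ordinal>``.  A
    family extinct in every species yields ``(None, log)``.
    """
    rng = np.random.default_rng(params.seed)
    log = EventLog()
    next_lid = [1]

    node_by_id = {species_tree.node_id(n): n for n in species_tree.nodes()}
    wgd_on: dict[int, list[SimWGD]] = {}
    for w in params.wgd_events:
        if w.species_node not in node_by_id:
            raise ValueError(f"WGD {w.name!r}: unknown species node {w.species_node!r}")
        node = node_by_id[w.species_node]
        parent = node.parent_node
        top = species_tree.age(parent) if parent is not None else float("inf")
        if not species_tree.age(node) <= w.age < top:
            raise ValueError(
                f"WGD {w.name!r}: age {w.age} outside branch interval "
                f"[{species_tree.age(node)}, {top})"
            )
        wgd_on.setdefault(id(node), []).append(w)
    for lst in wgd_on.values():
        lst.sort(key=lambda w: -w.age)

    def new_lineage(locked: bool) -> _Lineage:
        lin = _Lineage(next_lid[0], locked)
        next_lid[0] += 1
        return lin

    def lock_eligible(sp_node) -> bool:
        if params.lock_min_age is None:
            return True
        return species_tree.age(sp_node) >= params.lock_min_age

    def branch(sp_node, t_enter: float, lin: _Lineage) -> _GNode | None:
        bottom = species_tree.age(sp_node)
        branch_id = species_tree.node_id(sp_node)
        pending = [w for w in wgd_on.get(id(sp_node), []) if w.age < t_enter]
        next_wgd = pending[0] if pending else None

        loss_rate = params.lambda_loss * (params.lock_loss_factor if lin.locked else 1.0)
        rate = params.lambda_dup + loss_rate
        t_event = t_enter - (rng.exponential(1.0 / rate) if rate > 0 else np.inf)
        barrier = next_wgd.age if next_wgd is not None else bottom

        if t_event > barrier:
            if rng.random() < params.lambda_dup / rate:
                locked = lin.locked or (
                    lock_eligible(sp_node) and rng.random() < params.p_dfd
                )
                left = new_lineage(locked)
                right = new_lineage(locked)
                idx = len(log.events)
                log.events.append(
                    SimEvent(t_event, branch_id, "DUP", left.lid, lin.lid, locked)
                )
                if locked and not lin.locked:
                    log.events.append(
                        SimEvent(t_event, branch_id, "LOCK", left.lid, lin.lid, True)
                    )
                a = branch(sp_node, t_event, left)
                b = branch(sp_node, t_event, right)
                return _join(t_event, a, b, idx)
            log.events.append(SimEvent(t_event, branch_id, "LOSS", lin.lid, None, lin.locked))
            return None

        if next_wgd is not None:
            w = next_wgd
            if rng.random() < w.retention_prob:
                locked = lin.locked or (
                    lock_eligible(sp_node) and rng.random() < params.p_dfd
                )
                left = new_lineage(locked)
                right = new_lineage(locked)
                idx = len(log.events)
                log.events.append(
                    SimEvent(w.age, branch_id, "WGD_RETAIN", left.lid, lin.lid, locked)
                )
                a = branch(sp_node, w.age, left)
                b = branch(sp_node, w.age, right)
                return _join(w.age, a, b, idx)
            log.events.append(SimEvent(w.age, branch_id, "WGD_LOSE", lin.lid, None, lin.locked))
            return branch(sp_node, w.age, lin)

        # reached the bottom of the branch
        if sp_node.is_leaf():
            return _GNode(age=0.0, leaf_lineage=lin.lid,
                          taxon=species_tree.node_label(sp_node))
        kids = []
        for child in sp_node.child_nodes():
            kids.append(branch(child, bottom, replace_lineage(lin)))
        return _merge_speciation(bottom, kids)

    def replace_lineage(lin: _Lineage) -> _Lineage:
        # copies entering sibling species branches keep id lineage ancestry simple:
        # each species child continues the same gene lineage
        return _Lineage(lin.lid, lin.locked)

    def _join(age: float, a: _GNode | None, b: _GNode | None, event_index: int) -> _GNode | None:
        if a is not None and b is not None:
            return _GNode(age=age, children=[a, b], event_index=event_index)
        return a if a is not None else b

    def _merge_speciation(age: float, kids: list[_GNode | None]) -> _GNode | None:
        kept = [k for k in kids if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return _GNode(age=age, children=kept)

    root = species_tree.root
    root_age = species_tree.age(root)
    start = new_lineage(False)
    kids = [branch(c, root_age, _Lineage(start.lid, False)) for c in root.child_nodes()]
    gene_root = _merge_speciation(root_age, kids)

    if gene_root is None or not gene_root.children and gene_root.leaf_lineage is None:
        return None, log

    # name leaves per taxon in traversal order
    counter: dict[str, int] = {}

    def name_leaves(n: _GNode) -> None:
        if n.leaf_lineage is not None:
            counter[n.taxon] = counter.get(n.taxon, 0) + 1
            n.taxon = f"{n.taxon}{params.family_tag}{counter[n.taxon]}"
            return
        for c in n.children:
            name_leaves(c)

    name_leaves(gene_root)

    def leafset(n: _GNode) -> frozenset[str]:
        if n.leaf_lineage is not None:
            return frozenset([n.taxon])
        out: set[str] = set()
        for c in n.children:
            out |= leafset(c)
        return frozenset(out)

    def collect_detectable(n: _GNode) -> None:
        if n.leaf_lineage is not None:
            return
        if n.event_index is not None and len(n.children) == 2:
            ev = log.events[n.event_index]
            log.detectable.append(
                DetectableDuplication(
                    event_index=n.event_index,
                    kind=ev.kind,
                    time=ev.time,
                    species_branch=ev.species_branch,
                    branch_bottom_age=species_tree.age(node_by_id[ev.species_branch]),
                    locked=ev.locked,
                    child_leaf_sets=(leafset(n.children[0]), leafset(n.children[1])),
                )
            )
        for c in n.children:
            collect_detectable(c)

    collect_detectable(gene_root)

    def newick(n: _GNode, parent_age: float) -> str:
        if n.leaf_lineage is not None:
            return f"{n.taxon}:{parent_age:.10g}"
        inner = ",".join(newick(c, n.age) for c in n.children)
        return f"({inner}):{parent_age - n.age:.10g}"

    if gene_root.leaf_lineage is not None:
        text = f"{gene_root.taxon};"
    else:
        inner = ",".join(newick(c, gene_root.age) for c in gene_root.children)
        text = f"({inner});"
    gene_tree = GeneTree.from_newick(text, family_tag=params.family_tag)
    return gene_tree, log


# -- demo fixture ---------------------------------------------------------------

_DEMO_SPECIES_NEWICK = (
    "(Phypat:480,(Ambtri:180,(Anacom:160,(Aqucae:125,Nicsyl:125)"
    "eudicots:35)mesangiosperms:20)angiosperms:300)landplants;"
)

# Gene family with three main clusters (3, 1, 4), each holding all four
# angiosperm lineages, the eudicot sister pair 3.1/3.2 inside cluster 3,
# and the moss copy as outgroup.  Branch lengths are substitutions/site.
_DEMO_GENE_NEWICK = (
    "(PhypatGUS1.a:0.60,"
    "((AmbtriGUS3:0.20,(AnacomGUS3.a:0.18,(AqucaeGUS3:0.15,"
    "(NicsylGUS3.1:0.012,NicsylGUS3.2:0.011):0.14):0.05):0.04):0.10,"
    "((AmbtriGUS1:0.21,(AnacomGUS1.1:0.17,(AqucaeGUS1:0.14,NicsylGUS1.1:0.16)"
    ":0.05):0.04):0.09,"
    "(AmbtriGUS4:0.24,(AnacomGUS4:0.20,(AqucaeGUS4:0.17,NicsylGUS4:0.22)"
    ":0.06):0.05):0.11):0.05):0.30);"
)

_DEMO_METADATA = [
    # id, taxon, locus, chromosome, length, annotation
    ("PhypatGUS1.a", "Phypat", "Pp3c9_100", "chr9", 1602, "beta-glucuronidase"),
    ("AmbtriGUS1", "Ambtri", "AmTr_v1_01", "scaffold01", 1620, "heparanase-like protein"),
    ("AmbtriGUS3", "Ambtri", "AmTr_v1_02", "scaffold02", 1593, "heparanase-like protein"),
    ("AmbtriGUS4", "Ambtri", "AmTr_v1_03", "scaffold03", 1581, "beta-glucuronidase"),
    ("AnacomGUS1.1", "Anacom", "Aco003450", "LG05", 1608, "heparanase-like protein"),
    ("AnacomGUS3.a", "Anacom", "Aco011220", "LG11", 1600, "beta-glucuronidase"),
    ("AnacomGUS4", "Anacom", "Aco019870", "LG02", 1572, "heparanase-like protein"),
    ("AqucaeGUS1", "Aqucae", "Aqcoe5G117", "chr5", 1635, "heparanase-like protein"),
    ("AqucaeGUS3", "Aqucae", "Aqcoe1G332", "chr1", 1600, "beta-glucuronidase"),
    ("AqucaeGUS4", "Aqucae", "Aqcoe7G054", "chr7", 1566, "heparanase-like protein"),
    ("NicsylGUS1.1", "Nicsyl", "LOC104211", "chr3", 1647, "heparanase-like protein"),
    ("NicsylGUS3.1", "Nicsyl", "LOC104780", "chr7", 1600, "beta-glucuronidase"),
    ("NicsylGUS3.2", "Nicsyl", "LOC104912", "chr12", 1600, "heparanase-like protein"),
    ("NicsylGUS4", "Nicsyl", "LOC104355", "chr5", 650, "hypothetical heparanase fragment"),
]

#: Phylum membership of the demo taxa (one representative each).
DEMO_PHYLA = {
    "ancestral_angiosperms": frozenset({"Ambtri"}),
    "monocots": frozenset({"Anacom"}),
    "basal_eudicots": frozenset({"Aqucae"}),
    "eudicots": frozenset({"Nicsyl"}),
}

DEMO_WGD_EVENTS = (
    WGDEvent("seed-plant", "angiosperms", 300.0, 400.0),
    WGDEvent("angiosperm-ancestor", "angiosperms", 180.0, 220.0),
    WGDEvent("eudicot-hexaploidy", "Nicsyl", 70.0, 133.0),
    WGDEvent("solanaceae", "Nicsyl", 24.0, 70.0),
)


@dataclass
class DemoFixture:
    species_tree: SpeciesTree
    gene_tree: GeneTree
    metadata: pd.DataFrame
    wgd_events: tuple[WGDEvent, ...]
    phyla: dict[str, frozenset[str]]
    outgroup: frozenset[str]

    def metadata_tsv(self) -> str:
        buf = io.StringIO()
        self.metadata.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    def fasta(self, seed: int = 0) -> str:
        """Synthetic CDS sequences matching the metadata lengths."""
        rng = np.random.default_rng(seed)
        chunks = []
        for row in self.metadata.itertuples(index=False):
            seq = "".join(rng.choice(list("ACGT"), size=row.length))
            chunks.append(f">{row.id}\n{seq}\n")
        return "".join(chunks)

    def records(self) -> list[CDSRecord]:
        return [
            CDSRecord(
                id=row.id, taxon=row.taxon, locus=row.locus,
                chromosome=row.chromosome, length=int(row.length),
                annotation=row.annotation,
            )
            for row in self.metadata.itertuples(index=False)
        ]


def make_demo_fixture() -> DemoFixture:
    """Five-species, 14-copy gene family mirroring the documented example.

    A moss outgroup copy plus three angiosperm-wide clusters; reconciling the
    gene tree against the species tree yields two duplication nodes at the
    angiosperm crown and one recent within-species duplication (the eudicot
    3.1/3.2 pair).
    """
    species = SpeciesTree.from_newick(_DEMO_SPECIES_NEWICK)
    gene = GeneTree.from_newick(_DEMO_GENE_NEWICK, family_tag="GUS")
    meta = pd.DataFrame(
        _DEMO_METADATA,
        columns=["id", "taxon", "locus", "chromosome", "length", "annotation"],
    )
    return DemoFixture(
        species_tree=species,
        gene_tree=gene,
        metadata=meta,
        wgd_events=DEMO_WGD_EVENTS,
        phyla=dict(DEMO_PHYLA),
        outgroup=frozenset({"PhypatGUS1.a"}),
    )


def make_curation_table() -> list[CDSRecord]:
    """Twelve records exercising every filtering rule in a fixed order."""
    rows = [
        ("r01", "Aaaaaa", "L1", "chr1", 1620, "heparanase-like protein"),
        ("r02", "Aaaaaa", "L2", "chr1", 250, "heparanase"),  # hard length
        ("r03", "Bbbbbb", "L1", "chr2", 500, "hypothetical protein"),  # soft, unannotated
        ("r04", "Bbbbbb", "L2", "chr2", 500, "heparanase"),  # soft, rescued
        ("r05", "Cccccc", "L1", "chr3", 1600, "beta-glucuronidase"),
        ("r06", "Cccccc", "L1", "chr3", 1700, "beta-glucuronidase"),  # same locus dup
        ("r07", "Dddddd", "L1", "chr4", 299, "beta-glucuronidase"),  # hard length
        ("r08", "Dddddd", "L2", "chr4", 799, "unknown"),  # soft, unannotated
        ("r09", "Eeeeee", "L1", "chr5", 1580, "GUS family glycosyl hydrolase"),
        ("r10", "Eeeeee", "L1", "chr5", 900, "beta-glucuronidase"),  # same locus dup
        ("r11", "Ffffff", "L1", "chr6", 810, "unannotated transcript"),  # kept (>=800)
        ("r12", "Gggggg", "L1", "chr7", 1655, "heparanase 3"),
    ]
    return [
        CDSRecord(id=i, taxon=t, locus=l, chromosome=c, length=n, annotation=a)
        for (i, t, l, c, n, a) in rows
    ]


# -- small reconciliation instances for validation ------------------------------


def enumerate_rooted_topologies(leaves: list[str]):
    """All rooted binary topologies over the given labels, as nested tuples.

    Yields (2n-3)!! distinct shapes; each unordered split is produced once
    (the first label always stays in the left subtree).
    """
    if len(leaves) == 1:
        yield leaves[0]
        return
    head, rest = leaves[0], leaves[1:]
    n = len(rest)
    for mask in range(2 ** n):
        left = [head] + [rest[i] for i in range(n) if mask >> i & 1]
        right = [rest[i] for i in range(n) if not mask >> i & 1]
        if not right:
            continue
        for lt in enumerate_rooted_topologies(left):
            for rt in enumerate_rooted_topologies(right):
                yield (lt, rt)


def topology_newick(shape) -> str:
    def render(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(render(k) for k in node) + ")"

    return render(shape) + ";"


def random_dated_species_tree(n_species: int, rng: np.random.Generator) -> SpeciesTree:
    """Random ultrametric species tree by successive pair joins (ages Mya)."""
    if n_species < 1:
        raise ValueError("n_species must be positive")
    groups = [(_taxon_code(i), 0.0) for i in range(n_species)]
    age = 0.0
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        (a, age_a), (b, age_b) = groups[i], groups[j]
        age += float(rng.exponential(20.0)) + 1.0
        merged = (f"({a}:{age - age_a:.6f},{b}:{age - age_b:.6f})", age)
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
    return SpeciesTree.from_newick(groups[0][0] + ";")


def random_reconciliation_instance(
    n_species: int, n_gene_leaves: int, seed: int
) -> tuple[SpeciesTree, GeneTree]:
    """Random species tree plus a random gene tree over its taxa.

    Gene-tree topology is uniform over rooted labeled shapes; each leaf's
    taxon is drawn uniformly (every species gets at least one copy when
    ``n_gene_leaves >= n_species`` is not required).  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    species = random_dated_species_tree(n_species, rng)
    taxa = sorted(species.taxa)
    labels = [f"g{i}" for i in range(n_gene_leaves)]
    taxon_map = {lbl: taxa[int(rng.integers(len(taxa)))] for lbl in labels}

    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(f"({a},{b})")
    gene = GeneTree.from_newick(nodes[0] + ";", taxon_map=taxon_map)
    return species, gene


# -- truth vs inference ---------------------------------------------------------


@dataclass(frozen=True)
class ConfusionSummary:
    n_truth: int
    n_inferred: int
    n_matched: int
    recall: float
    precision: float
    dfd_truth: int
    dfd_predicted: int
    dfd_matched: int
    dfd_recall: float
    dfd_precision: float


def truth_vs_inferred(
    log: EventLog, events, ancient_cutoff: float | None = None
) -> ConfusionSummary:
    """Score inferred duplications against the simulation truth.

    A truth event is *detectable* when both daughter lineages left extant
    descendants; an inferred duplication matches it when the two child leaf
    sets coincide.  The DFD block compares locked truth events with events
    classified ``DFD_LIKELY`` (events must already carry verdicts); when
    ``ancient_cutoff`` is given, only locked events whose carrying branch
    bottoms out at or above that age count as DFD truth — younger locked
    duplications are indistinguishable from ordinary recent retention by
    design.
    """
    from .reconcile import Verdict

    truth_keys = {
        frozenset(d.child_leaf_sets): d for d in log.detectable
    }

    def is_dfd_truth(d: DetectableDuplication) -> bool:
        if not d.locked:
            return False
        return ancient_cutoff is None or d.branch_bottom_age >= ancient_cutoff
    matched = []
    matched_inferred = set()
    for i, ev in enumerate(events):
        key = frozenset(ev.child_leaf_sets)
        if key in truth_keys:
            matched.append((truth_keys[key], ev))
            matched_inferred.add(i)
    n_truth = len(truth_keys)
    n_inferred = len(events)
    n_matched = len(matched)
    recall = n_matched / n_truth if n_truth else 1.0
    precision = n_matched / n_inferred if n_inferred else 1.0

    dfd_truth = [d for d in truth_keys.values() if is_dfd_truth(d)]
    dfd_predicted = [e for e in events if e.verdict is Verdict.DFD_LIKELY]
    dfd_matched = [
        (d, e) for (d, e) in matched if is_dfd_truth(d) and e.verdict is Verdict.DFD_LIKELY
    ]
    return ConfusionSummary(
        n_truth=n_truth,
        n_inferred=n_inferred,
        n_matched=n_matched,
        recall=recall,
        precision=precision,
        dfd_truth=len(dfd_truth),
        dfd_predicted=len(dfd_predicted),
        dfd_matched=len(dfd_matched),
        dfd_recall=len(dfd_matched) / len(dfd_truth) if dfd_truth else 1.0,
        dfd_precision=len(dfd_matched) / len(dfd_predicted) if dfd_predicted else 1.0,
    )
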