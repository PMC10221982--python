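"""Tree primitives shared by the whole pipeline.

Two thin wrappers around :class:`dendropy.Tree` are provided:

* :class:`SpeciesTree` — a rooted, dated (ultrametric) tree of taxa whose
  node ages (in Mya) are recovered from branch lengths.  Tip ages are zero
  and every internal node is strictly older than its children.
* :class:`GeneTree` — a rooted tree of gene copies whose leaf labels follow
  the ``<TaxonCode><FamilyTag><ClusterSuffix>`` convention (for example
  ``NicsylGUS3.1``: taxon ``Nicsyl``, family ``GUS``, cluster ``3.1``).

Leaf labels that do not follow the convention (handy in tests and toy
examples, e.g. ``a1``) are handled by a permissive fallback that strips a
trailing run of digits and dots to obtain the taxon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "LabelError",
    "GeneLabel",
    "SpeciesTree",
    "GeneTree",
    "parse_leaf_label",
    "read_newick",
    "write_newick",
    "root_with_outgroup",
    "leaf_species_set",
]


class TreeError(ValueError):
    """Invalid tree structure or tree-level precondition violation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class LabelError(TreeError):
    """A leaf label does not follow the naming convention."""


_TAXON_RE = re.compile(r"^[A-Za-z]{6}$")
_SUFFIX_RE = re.compile(r"^$|^[0-9]+(\.[0-9A-Za-z]+)*$")
# permissive fallback: taxon = label minus a trailing run of digits/dots
_TRAILING_ORDINAL_RE = re.compile(r"[\d.]+$")


@dataclass(frozen=True)
class GeneLabel:
    """Structured form of a gene-copy leaf label."""

    taxon: str
    family_tag: str
    cluster_suffix: str
    raw: str

    def __post_init__(self) -> None:
        if not _TAXON_RE.match(self.taxon):
            raise LabelError(
                f"taxon code {self.taxon!r} must be exactly 6 alphabetic characters"
            )
        if self.raw != self.taxon + self.family_tag + self.cluster_suffix:
            raise LabelError(
                f"label {self.raw!r} does not decompose into "
                f"{self.taxon!r} + {self.family_tag!r} + {self.cluster_suffix!r}"
            )


def parse_leaf_label(raw: str, family_tag: str) -> GeneLabel:
    """Split ``raw`` into taxon code, family tag and cluster suffix.

    The taxon code is the first six characters; the family tag must follow
    immediately; whatever remains is the cluster suffix (``"3"``, ``"3.1"``,
    ``"1.a"`` or empty).
    """
    if len(raw) < 6 + len(family_tag):
        raise LabelError(f"label {raw!r} too short for a 6-char taxon + {family_tag!r}")
    taxon, rest = raw[:6], raw[6:]
    if not _TAXON_RE.match(taxon):
        raise LabelError(f"label {raw!r}: first 6 characters are not alphabetic")
    if not rest.startswith(family_tag):
        raise LabelError(f"label {raw!r}: family tag {family_tag!r} not found after taxon code")
    suffix = rest[len(family_tag):]
    if not _SUFFIX_RE.match(suffix):
        raise LabelError(f"label {raw!r}: cluster suffix {suffix!r} is malformed")
    return GeneLabel(taxon=taxon, family_tag=family_tag, cluster_suffix=suffix, raw=raw)


def _default_taxon(label: str) -> str:
    """Permissive taxon extraction for labels outside the strict convention."""
    if len(label) > 6 and _TAXON_RE.match(label[:6]):
        return label[:6]
    stripped = _TRAILING_ORDINAL_RE.sub("", label)
    if not stripped:
        raise LabelError(f"cannot extract a taxon from leaf label {label!r}")
    return stripped


def _parse_dendropy(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error subclasses
        raise NewickParseError(f"malformed Newick input: {exc}") from exc
    # all trees in this package are rooted; prevents dendropy from collapsing
    # the basal bifurcation when bipartitions are computed
    tree.is_rooted = True
    return tree


class _TreeBase:
    """Shared read-only accessors over the underlying dendropy tree."""

    def __init__(self, dtree: dendropy.Tree):
        self._t = dtree

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    @property
    def root(self) -> dendropy.Node:
        return self._t.seed_node

    def nodes(self) -> list[dendropy.Node]:
        return list(self._t.preorder_node_iter())

    def leaves(self) -> list[dendropy.Node]:
        return list(self._t.leaf_node_iter())

    def children(self, node: dendropy.Node) -> list[dendropy.Node]:
        return node.child_nodes()

    def parent(self, node: dendropy.Node) -> dendropy.Node | None:
        return node.parent_node

    @staticmethod
    def node_label(node: dendropy.Node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def leaf_labels(self) -> list[str]:
        return [self.node_label(lf) for lf in self.leaves()]

    def newick(self) -> str:
        s = self._t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s


class SpeciesTree(_TreeBase):
    """Rooted dated species tree; node ages in Mya derived from branch lengths.

    The input must be ultrametric (all root-to-tip path lengths equal within
    a relative tolerance of 1e-6); tips sit at age 0 and each internal node
    is strictly older than all of its children.  Polytomies are allowed.
    """

    ULTRAMETRIC_RTOL = 1e-6

    def __init__(self, dtree: dendropy.Tree):
        super().__init__(dtree)
        self._validate_labels()
        self._ages = self._compute_ages()
        self._tip_by_taxon = {self.node_label(lf): lf for lf in self.leaves()}

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls(_parse_dendropy(text))

    def _validate_labels(self) -> None:
        labels = self.leaf_labels()
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("species tree has unlabeled tips")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate species tip labels: {sorted(dupes)}")

    def _compute_ages(self) -> dict[int, float]:
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self._t.preorder_node_iter():
            if node is self.root:
                continue
            if node.edge.length is None:
                raise TreeError(
                    "species tree needs branch lengths on every edge to carry node ages"
                )
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
        tip_depths = [depth[id(lf)] for lf in self.leaves()]
        height = max(tip_depths)
        tol = self.ULTRAMETRIC_RTOL * max(height, 1.0)
        if height - min(tip_depths) > tol:
            raise TreeError(
                "species tree is not ultrametric: root-to-tip lengths range "
                f"from {min(tip_depths):g} to {height:g}"
            )
        ages: dict[int, float] = {}
        for node in self._t.preorder_node_iter():
            age = height - depth[id(node)]
            if node.is_leaf():
                age = 0.0
            ages[id(node)] = age
        for node in self._t.preorder_node_iter():
            for child in node.child_nodes():
                if ages[id(node)] - ages[id(child)] <= tol:
                    raise TreeError(
                        "species tree ages are not strictly decreasing toward the "
                        "tips (zero-length or negative edge)"
                    )
        return ages

    # -- age / topology queries -------------------------------------------------

    def age(self, node: dendropy.Node) -> float:
        return self._ages[id(node)]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self._tip_by_taxon)

    def tip(self, taxon: str) -> dendropy.Node:
        try:
            return self._tip_by_taxon[taxon]
        except KeyError:
            raise TreeError(f"taxon {taxon!r} is not a tip of the species tree") from None

    def descendant_taxa(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(self.node_label(lf) for lf in node.leaf_iter())

    def mrca_of_taxa(self, taxa: Iterable[str]) -> dendropy.Node:
        nodes = [self.tip(t) for t in taxa]
        if not nodes:
            raise TreeError("mrca of an empty taxon set is undefined")
        node = nodes[0]
        for other in nodes[1:]:
            node = self.mrca(node, other)
        return node

    def mrca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        ancestors = set()
        n = a
        while n is not None:
            ancestors.add(id(n))
            n = n.parent_node
        n = b
        while n is not None:
            if id(n) in ancestors:
                return n
            n = n.parent_node
        raise TreeError("nodes do not share an ancestor (disjoint trees?)")

    def is_ancestor_or_self(self, anc: dendropy.Node, node: dendropy.Node) -> bool:
        n = node
        while n is not None:
            if n is anc:
                return True
            n = n.parent_node
        return False

    def edge_steps(self, anc: dendropy.Node, desc: dendropy.Node) -> int:
        """Number of edges on the path from ``anc`` down to ``desc``."""
        steps = 0
        n = desc
        while n is not anc:
            if n is None:
                raise TreeError("edge_steps: first argument is not an ancestor of the second")
            n = n.parent_node
            steps += 1
        return steps

    def node_id(self, node: dendropy.Node) -> str:
        label = self.node_label(node)
        if label:
            return label
        return "mrca(" + "|".join(sorted(self.descendant_taxa(node))) + ")"


class GeneTree(_TreeBase):
    """Rooted gene-copy tree; each leaf carries a taxon assignment.

    ``family_tag`` enables strict label parsing (``NicsylGUS3.1`` style);
    alternatively an explicit ``taxon_map`` (dict or callable from raw leaf
    label to taxon code) may be supplied for unconventional labels.
    """

    def __init__(
        self,
        dtree: dendropy.Tree,
        family_tag: str | None = None,
        taxon_map: Mapping[str, str] | Callable[[str], str] | None = None,
    ):
        super().__init__(dtree)
        self.family_tag = family_tag
        labels = self.leaf_labels()
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("gene tree has unlabeled leaves")
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise TreeError(f"duplicate gene leaf labels: {dupes}")
        for node in self._t.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) < 2:
                raise TreeError("gene tree has an internal node with fewer than 2 children")
        self._taxon_of: dict[str, str] = {}
        self._gene_labels: dict[str, GeneLabel] = {}
        for lbl in labels:
            if callable(taxon_map):
                self._taxon_of[lbl] = taxon_map(lbl)
            elif taxon_map is not None:
                try:
                    self._taxon_of[lbl] = taxon_map[lbl]
                except KeyError:
                    raise LabelError(f"leaf {lbl!r} missing from the supplied taxon map") from None
            elif family_tag is not None:
                gl = parse_leaf_label(lbl, family_tag)
                self._gene_labels[lbl] = gl
                self._taxon_of[lbl] = gl.taxon
            else:
                self._taxon_of[lbl] = _default_taxon(lbl)

    @classmethod
    def from_newick(
        cls,
        text: str,
        family_tag: str | None = None,
        taxon_map: Mapping[str, str] | Callable[[str], str] | None = None,
    ) -> "GeneTree":
        return cls(_parse_dendropy(text), family_tag=family_tag, taxon_map=taxon_map)

    def taxon_of(self, leaf: dendropy.Node | str) -> str:
        label = leaf if isinstance(leaf, str) else self.node_label(leaf)
        return self._taxon_of[label]

    def gene_label(self, leaf: dendropy.Node | str) -> GeneLabel | None:
        label = leaf if isinstance(leaf, str) else self.node_label(leaf)
        return self._gene_labels.get(label)

    def leaf_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(self.node_label(lf) for lf in node.leaf_iter())

    def species_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(self._taxon_of[self.node_label(lf)] for lf in node.leaf_iter())

    def mrca_of_leaves(self, labels: Iterable[str]) -> dendropy.Node:
        """Smallest clade containing all the given leaf labels."""
        wanted = frozenset(labels)
        if not wanted:
            raise TreeError("mrca of an empty leaf set is undefined")
        missing = wanted - frozenset(self.leaf_labels())
        if missing:
            raise TreeError(f"labels absent from the gene tree: {sorted(missing)}")
        start = next(lf for lf in self.leaves() if self.node_label(lf) in wanted)
        node = start
        while not wanted <= self.leaf_set(node):
            node = node.parent_node
        return node

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._t.preorder_node_iter()
            if not n.is_leaf()
        )

    def resolve_polytomies(self) -> "GeneTree":
        """Deterministically resolve polytomies in input (child list) order."""
        if self.is_binary():
            return self
        out = self.copy()
        for node in list(out._t.preorder_node_iter()):
            while len(node.child_nodes()) > 2:
                kids = node.child_nodes()
                a, b = kids[0], kids[1]
                node.remove_child(a)
                node.remove_child(b)
                merged = dendropy.Node()
                merged.edge.length = 0.0
                merged.add_child(a)
                merged.add_child(b)
                node.insert_child(0, merged)
        return GeneTree(out._t, family_tag=self.family_tag, taxon_map=dict(self._taxon_of))

    def copy(self) -> "GeneTree":
        return GeneTree.from_newick(
            self.newick(), family_tag=self.family_tag, taxon_map=dict(self._taxon_of)
        )

    def relabeled(self, mapping: Mapping[str, str], family_tag: str | None = None) -> "GeneTree":
        """Return a copy with leaf labels replaced according to ``mapping``.

        Labels absent from the mapping are kept.  The taxon assignment of a
        renamed leaf is preserved.
        """
        clone = _parse_dendropy(self.newick())
        taxon_map: dict[str, str] = {}
        for lf in clone.leaf_node_iter():
            old = lf.taxon.label
            new = mapping.get(old, old)
            lf.taxon.label = new
            taxon_map[new] = self._taxon_of[old]
        return GeneTree(clone, family_tag=family_tag, taxon_map=taxon_map)


# -- module-level operations ----------------------------------------------------


def read_newick(text: str, kind: str = "gene", **kwargs) -> SpeciesTree | GeneTree:
    """Parse a Newick string into a :class:`SpeciesTree` or :class:`GeneTree`."""
    if kind == "species":
        return SpeciesTree.from_newick(text)
    if kind == "gene":
        return GeneTree.from_newick(text, **kwargs)
    raise ValueError(f"kind must be 'species' or 'gene', got {kind!r}")


def write_newick(tree: SpeciesTree | GeneTree) -> str:
    return tree.newick()


def leaf_species_set(node: dendropy.Node, tree: GeneTree) -> frozenset[str]:
    """Set of taxon codes over the leaves descending from ``node``."""
    return tree.species_set(node)


def root_with_outgroup(tree: GeneTree, outgroup_labels: Iterable[str]) -> GeneTree:
    """Reroot so that the outgroup clade is one child of the root.

    The outgroup must be a clade of the unrooted topology.  Rerooting a tree
    already rooted on the outgroup returns an identical topology.
    """
    outgroup = frozenset(
        lbl.raw if isinstance(lbl, GeneLabel) else lbl for lbl in outgroup_labels
    )
    all_leaves = frozenset(tree.leaf_labels())
    missing = sorted(outgroup - all_leaves)
    if missing:
        raise TreeError(f"outgroup labels absent from the gene tree: {missing}")
    if not outgroup:
        raise TreeError("empty outgroup")
    if outgroup == all_leaves:
        raise TreeError("outgroup cannot contain every leaf")

    work = tree.copy()
    root_kids = work.root.child_nodes()
    if len(root_kids) == 2 and any(work.leaf_set(k) == outgroup for k in root_kids):
        return work

    # locate the edge splitting outgroup from the rest (unrooted monophyly)
    target = None
    for node in work._t.preorder_node_iter():
        if node is work.root:
            continue
        ls = work.leaf_set(node)
        if ls == outgroup or ls == all_leaves - outgroup:
            target = node
            break
    if target is None:
        extras = sorted(work.leaf_set(work.mrca_of_leaves(outgroup)) - outgroup)
        raise TreeError(
            f"outgroup is not monophyletic; its smallest containing clade also holds {extras}"
        )

    dtree = work._t
    edge = target.edge
    if edge.length is not None:
        half = edge.length / 2.0
        dtree.reroot_at_edge(edge, length1=half, length2=half,
                             update_bipartitions=False)
    else:
        dtree.reroot_at_edge(edge, update_bipartitions=False)
    dtree.suppress_unifurcations()
    return GeneTree(dtree, family_tag=tree.family_tag,
                    taxon_map={lbl: tree.taxon_of(lbl) for lbl in all_leaves})
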