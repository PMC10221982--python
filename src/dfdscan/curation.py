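"""Coding-sequence curation: filters, dedup, collapse and summaries.

Rules are applied to each record in a fixed order and every record gets
exactly one decision:

1. ``LEN_LT_300`` — CDS shorter than a hard minimum (default 300 nt);
2. ``LEN_LT_800_UNANNOTATED`` — shorter than a soft minimum (default
   800 nt) and not annotated with any family keyword (database
   classifications are operationalised as a case-insensitive keyword match
   on the annotation text);
3. ``DUP_LOCUS`` — a later record from the same species and locus as an
   already-kept one (the first-listed record is kept);
4. ``KEPT`` otherwise.

Same-species copies that sit very close together on a guide tree (small
patristic distance) are collapsed to a single representative, mirroring the
practice of dropping tightly clustered within-family paralogs before
building a genus-level tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .treekit import GeneTree

__all__ = [
    "CDSRecord",
    "FilterRule",
    "FilterDecision",
    "CollapseDecision",
    "LengthSummary",
    "DEFAULT_KEYWORDS",
    "read_records",
    "apply_filters",
    "kept_records",
    "summarize_lengths",
    "collapse_tight_paralogs",
    "flag_pseudogenization_candidates",
]

DEFAULT_KEYWORDS = frozenset({"heparanase", "glucuronidase", "gus"})
DEFAULT_MIN_LEN_HARD = 300
DEFAULT_MIN_LEN_SOFT = 800
DEFAULT_PATRISTIC_THRESHOLD = 0.05


@dataclass(frozen=True)
class CDSRecord:
    """One coding sequence plus the metadata used for curation."""

    id: str
    taxon: str
    locus: str
    chromosome: str
    length: int
    annotation: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"record {self.id!r}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"record {self.id!r}: sequence length {len(self.sequence)} "
                f"does not match declared length {self.length}"
            )


class FilterRule(Enum):
    LEN_LT_300 = "LEN_LT_300"
    LEN_LT_800_UNANNOTATED = "LEN_LT_800_UNANNOTATED"
    DUP_LOCUS = "DUP_LOCUS"
    KEPT = "KEPT"


@dataclass(frozen=True)
class FilterDecision:
    record_id: str
    kept: bool
    rule: FilterRule


@dataclass(frozen=True)
class CollapseDecision:
    record_id: str
    group: int
    representative: bool


@dataclass(frozen=True)
class LengthSummary:
    n: int
    median: float
    min: int
    max: int


def read_records(fasta_path, metadata_path) -> list[CDSRecord]:
    """Join a FASTA file with its metadata TSV into :class:`CDSRecord` rows.

    The TSV must have columns ``id taxon locus chromosome length annotation``;
    ids must match the FASTA one-to-one and sequence lengths must agree with
    the declared lengths.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"length": int})
    required = ["id", "taxon", "locus", "chromosome", "length", "annotation"]
    missing_cols = [c for c in required if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing columns: {missing_cols}")

    meta_ids = list(meta["id"])
    orphans_fasta = sorted(set(seqs) - set(meta_ids))
    orphans_meta = sorted(set(meta_ids) - set(seqs))
    if orphans_fasta or orphans_meta:
        raise ValueError(
            "FASTA/metadata id mismatch: "
            f"in FASTA only {orphans_fasta}; in metadata only {orphans_meta}"
        )

    records = []
    for row in meta.itertuples(index=False):
        seq = seqs[row.id]
        if len(seq) != int(row.length):
            raise ValueError(
                f"record {row.id!r}: FASTA sequence length {len(seq)} "
                f"!= metadata length {row.length}"
            )
        records.append(
            CDSRecord(
                id=row.id, taxon=row.taxon, locus=row.locus,
                chromosome=row.chromosome, length=int(row.length),
                annotation=str(row.annotation), sequence=seq,
            )
        )
    return records


def _annotated(record: CDSRecord, keywords: frozenset[str]) -> bool:
    text = record.annotation.lower()
    return any(kw.lower() in text for kw in keywords)


def apply_filters(
    records: Sequence[CDSRecord],
    annotation_keywords: Iterable[str] = DEFAULT_KEYWORDS,
    min_len_hard: int = DEFAULT_MIN_LEN_HARD,
    min_len_soft: int = DEFAULT_MIN_LEN_SOFT,
) -> list[FilterDecision]:
    """One decision per record, applying the rules in their fixed order."""
    if min_len_hard > min_len_soft:
        raise ValueError("min_len_hard must not exceed min_len_soft")
    keywords = frozenset(annotation_keywords)
    seen_loci: set[tuple[str, str]] = set()
    decisions = []
    for rec in records:
        if rec.length < min_len_hard:
            decisions.append(FilterDecision(rec.id, False, FilterRule.LEN_LT_300))
            continue
        if rec.length < min_len_soft and not _annotated(rec, keywords):
            decisions.append(
                FilterDecision(rec.id, False, FilterRule.LEN_LT_800_UNANNOTATED)
            )
            continue
        key = (rec.taxon, rec.locus)
        if key in seen_loci:
            decisions.append(FilterDecision(rec.id, False, FilterRule.DUP_LOCUS))
            continue
        seen_loci.add(key)
        decisions.append(FilterDecision(rec.id, True, FilterRule.KEPT))
    return decisions


def kept_records(
    records: Sequence[CDSRecord], decisions: Sequence[FilterDecision]
) -> list[CDSRecord]:
    kept_ids = {d.record_id for d in decisions if d.kept}
    return [r for r in records if r.id in kept_ids]


def summarize_lengths(records: Sequence[CDSRecord]) -> LengthSummary:
    if not records:
        raise ValueError("cannot summarise an empty record set")
    lengths = np.array([r.length for r in records])
    return LengthSummary(
        n=len(lengths),
        median=float(np.median(lengths)),
        min=int(lengths.min()),
        max=int(lengths.max()),
    )


def collapse_tight_paralogs(
    records: Sequence[CDSRecord],
    guide_tree: GeneTree,
    patristic_threshold: float = DEFAULT_PATRISTIC_THRESHOLD,
) -> list[CollapseDecision]:
    """Collapse same-species copies closer than ``patristic_threshold``.

    Grouping is single-linkage on the patristic distance within each
    species; the representative of a group is its longest CDS (ties broken
    by lexicographic id).  Distances come from the guide tree's branch
    lengths, so the threshold is in the guide tree's units (typically
    substitutions/site).
    """
    if patristic_threshold <= 0:
        raise ValueError("patristic_threshold must be positive")
    leaf_labels = set(guide_tree.leaf_labels())
    missing = sorted(r.id for r in records if r.id not in leaf_labels)
    if missing:
        raise ValueError(f"records absent from the guide tree: {missing}")

    dtree = guide_tree.dendropy_tree
    pdm = dtree.phylogenetic_distance_matrix()
    taxon_by_label = {lf.taxon.label: lf.taxon for lf in dtree.leaf_node_iter()}

    # union-find over records of the same species
    parent = {r.id: r.id for r in records}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_species: dict[str, list[CDSRecord]] = {}
    for r in records:
        by_species.setdefault(r.taxon, []).append(r)
    for same in by_species.values():
        for i in range(len(same)):
            for j in range(i + 1, len(same)):
                d = pdm.patristic_distance(
                    taxon_by_label[same[i].id], taxon_by_label[same[j].id]
                )
                if d < patristic_threshold:
                    union(same[i].id, same[j].id)

    groups: dict[str, list[CDSRecord]] = {}
    for r in records:
        groups.setdefault(find(r.id), []).append(r)
    decisions = []
    group_index = {root: k for k, root in enumerate(sorted(groups))}
    for root, members in groups.items():
        rep = min(members, key=lambda r: (-r.length, r.id))
        for r in members:
            decisions.append(
                CollapseDecision(r.id, group_index[root], representative=(r is rep))
            )
    decisions.sort(key=lambda d: d.record_id)
    return decisions


def flag_pseudogenization_candidates(
    records: Sequence[CDSRecord],
    cluster_of: dict[str, str],
    soft_len: int = DEFAULT_MIN_LEN_SOFT,
    lossy_clusters: Iterable[str] = (),
) -> list[str]:
    """Advisory flags: short copies sitting in loss-prone clusters.

    ``cluster_of`` maps record/leaf id to cluster name (innermost group);
    a record is flagged when its length is below ``soft_len`` and its
    cluster is one of ``lossy_clusters``.
    """
    lossy = set(lossy_clusters)
    flagged = []
    for r in records:
        cluster = cluster_of.get(r.id)
        if cluster is not None and cluster in lossy and r.length < soft_len:
            flagged.append(r.id)
    return flagged
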