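# dfdscan

Tools for asking a simple evolutionary question of a gene family: *which
duplications left both copies behind in every descendant species?*

When a gene duplicates and the two copies diverge in expression or function
("duplication plus functional differentiation", DFD), neither copy can be
lost without cost, so both are retained in all species that descend from
the duplication. In the gene tree this leaves a distinctive footprint — a
**double-gene phylum**: two sister clades with identical species
composition hanging off the duplication node. Conversely, a duplication
whose copies stayed redundant bleeds copies by pseudogenization, and the
two clades end up with ragged, unequal species sets. The signal is only
meaningful for *old* duplications: a recent event looks perfectly retained
simply because there has been no time to lose anything.

`dfdscan` implements this analysis end to end for plant gene families (its
built-in example is the β-glucuronidase / GUS family, but nothing is
GUS-specific):

- **treekit** — Newick I/O over dendropy; dated (ultrametric) species trees
  with node ages in Mya; gene-copy leaf labels of the form
  `<TaxonCode><FamilyTag><Cluster>` (e.g. `NicsylGUS3.1`); outgroup
  rerooting.
- **reconcile** — LCA (last-common-ancestor) mapping of gene-tree nodes
  onto the species tree. A gene node *g* is a duplication iff its image
  equals a child's image; each event gets the age interval
  `[age(M(g)), age(parent(M(g)))]`. Implied losses are counted under the
  standard parsimony embedding, and an exhaustive oracle
  (`oracle_reconcile`) independently scores every valid embedding on small
  instances.
- **dfd** — detects the main clusters (maximal clades covering every
  required phylum, split recursively at duplication nodes), computes per-
  event **retention completeness** (fraction of the event's descendant
  species present in each daughter clade, with species sampled anywhere in
  the family as the denominator), and classifies each duplication:
  `DFD_LIKELY` (complete + older than `ancient_cutoff`, default 100 Mya),
  `RETAINED_RECENT`, `NON_DFD_LOSSY` (losses spanning whole families or a
  large fraction of taxa), or `AMBIGUOUS`. Events are associated with known
  whole-genome duplications (WGDs) by branch and age-interval overlap.
- **curation** — the CDS filtering rules used to assemble such families:
  discard sequences < 300 nt; discard sequences < 800 nt unless annotated
  with a family keyword; drop same-species/same-locus duplicates; collapse
  tightly clustered same-species paralogs by patristic distance; flag
  short copies in loss-prone clusters as pseudogenization candidates.
- **synthetic_data** — a gene-family simulator on dated species trees
  (birth–death duplication/loss, episodic WGD doubling with partial
  retention, and a heritable "differentiation lock" that protects both
  daughters of a DFD event), logging every event so inference can be scored
  against ground truth.
- **cli** — `dfdscan demo | simulate | curate | reconcile | dfd | run`.

## Worked example

The package ships a five-species demo family — a moss outgroup copy
(`PhypatGUS1.a`) plus 14 copies total across *Amborella*, *Ananas*,
*Aquilegia* and *Nicotiana*, one representative for each major angiosperm
lineage:

```bash
dfdscan run --out demo_out
cat demo_out/summary.txt
```

```
Gene family with 14 copies; 3 main cluster(s), of which 3 cover all 4 required phyla.
  cluster 1: 5 copies; sub-lineages: 1.1, 1.2
  cluster 2: 4 copies
  cluster 3: 4 copies
3 duplication event(s), 0 implied loss(es).
  DFD_LIKELY: duplication at angiosperms (180-480 Mya), retention 1.00/1.00, candidate WGDs: seed-plant, angiosperm-ancestor
  DFD_LIKELY: duplication at angiosperms (180-480 Mya), retention 1.00/1.00, candidate WGDs: seed-plant, angiosperm-ancestor
  RETAINED_RECENT: duplication at Nicsyl (0-125 Mya), retention 1.00/1.00, candidate WGDs: eudicot-hexaploidy, solanaceae
4 species retain copies in both cluster 1 and cluster 3.
```

Reading this: the family falls into three clusters, each containing all
four angiosperm lineages, which requires two duplication nodes at the
angiosperm crown (180–480 Mya). Both are fully retained in every
descendant species and old enough that functional differentiation is the
likely explanation — they are the events worth following up with
expression assays. The third duplication (the eudicot `3.1`/`3.2` pair) is
also fully retained but too recent for retention to mean much on its own.
The machine-readable version of the same analysis is in
`demo_out/report.json` (schema: `src/dfdscan/schemas/report_schema.json`).

The same analysis is available as library calls:

```python
from dfdscan import DFDConfig, analyze_family, make_demo_fixture

fx = make_demo_fixture()
events, recon, hybrids, tree = analyze_family(
    fx.gene_tree, fx.species_tree,
    DFDConfig(required_phyla=fx.phyla),
    wgd_table=list(fx.wgd_events),
    outgroup_labels=fx.outgroup,
)
for e in events:
    print(e.mapped_species, e.age_lower, e.completeness, e.verdict)
```

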