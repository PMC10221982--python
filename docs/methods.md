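# Methods

## The retention signature

The working model: after a gene duplication, the default fate of one copy
is pseudogenization and loss; both copies persist long-term only when they
acquire distinct, individually necessary roles (sub-/neo-functionalization
or escape from adaptive conflict). A duplication followed by such
functional differentiation (DFD) therefore produces two gene-tree clades
whose species compositions are *identical* over all descendants — a
"double-gene phylum" — whereas a redundant duplication produces clades with
unequal, eroded species sets. Retention alone cannot distinguish a DFD
event from a recent duplication that simply has not had time to lose a
copy, so the classification is age-qualified.

## Reconciliation

Gene trees are mapped onto a rooted, dated species tree by LCA
reconciliation: each leaf maps to its species' tip, each internal node to
the MRCA of its children's images; a node is a duplication iff its image
equals the image of at least one child. This mapping provably minimizes
both duplications and losses under the duplication–loss parsimony model.
Losses are counted per gene edge (u, v): d(M(u), M(v)) species-tree edges
are crossed silently, costing d losses when u is a duplication and d − 1
when u is a speciation.

Correctness is checked against `oracle_reconcile`, an exhaustive search
over all valid embeddings (every assignment of internal gene nodes to
ancestors of their clades' MRCAs, consistent along edges), scored by
mutation cost. The suite verifies equality on *all* gene-tree shapes and
labelings up to 4 leaves over a 3-species tree (1 305 instances) plus a
seeded randomized sweep up to 5 species and 7 gene leaves. A truly
exhaustive sweep at the larger sizes is combinatorially impossible
(10 395 shapes × 5⁸ labelings at 8 leaves alone), which is why the larger
sizes are sampled.

Each duplication's age interval is `[age(M(g)), age(parent(M(g)))]` — the
branch on which the event must have occurred. Events mapped to the species
root use a configurable ceiling (default 350 Mya, the age of the oldest
WGD commonly attributed to seed plants) as the upper bound so every event
has a finite, interpretable interval.

## Cluster detection and naming

Clusters are the "main groups" a reader sees in a family tree: starting at
the ingroup root, duplication nodes (species-overlap test: two children
sharing a taxon) whose children all still cover every required phylum
split the family; recursion stops at clades that are speciation nodes or
whose children lose coverage, and those clades are the clusters. Within a
cluster, the shallowest duplication nodes split off subclusters (the
`3.1`/`3.2` pattern). Cluster names are provisional ordinals until
anchored: `assign_cluster_names` takes reference labels (e.g. the
*Arabidopsis* convention that fixes clusters 1 and 3) and renames every
leaf `<taxon><tag><group>`, appending `.a`, `.b`… when one species keeps
several copies in the same group. A species' *single* copy in a cluster
gets the bare cluster name; published figures sometimes carry an extra
ordinal inherited from a wider tree, so renamed labels may be shorter than
their database names.

## Retention completeness and classification

For a duplication mapped to species node S with daughters L and R:

    completeness_i = |species(child_i) ∩ D| / |D|,
    D = descendants(S) ∩ family_species

where `family_species` is the set of taxa with ≥ 1 copy anywhere in the
family — an unsequenced or unsampled genome is not evidence of loss. At
tolerance 0 (the default) "double-gene phylum" means both fractions are
exactly 1, i.e. both child species sets equal D; the `tol` knob exists
because real assemblies have gaps.

Verdicts:

- `DFD_LIKELY`: double-gene phylum and `age_lower ≥ ancient_cutoff`
  (default 100 Mya, chosen to sit between the pre-angiosperm events
  (~200 Mya) and the family-level WGDs (24–70 Mya));
- `RETAINED_RECENT`: double-gene phylum but younger than the cutoff;
- `NON_DFD_LOSSY`: incomplete, and the missing taxa cover ≥ 1 whole
  configured family (with ≥ 2 sampled members) or ≥ `lossy_fraction`
  (default 0.5) of D — the threshold is a stand-in, since "lost in many
  species" is not quantified anywhere authoritative;
- `AMBIGUOUS`: everything else.

Known hybrids/allopolyploids (e.g. *N. tabacum*, *B. napus*) carry
homoeologous copies that pair with each parental lineage and masquerade as
duplications; taxa listed in `DFDConfig.hybrid_taxa` are pruned before
inference and reported separately.

WGD association: the duplication occurred on the branch above its mapped
node, so only WGDs placed on that branch are candidates, flagged by
age-interval overlap. The pre-angiosperm "two duplications or one
hexaploidization" ambiguity is deliberately left to this stage: the
reconciliation reports binary nodes, and a hexaploidy is simply two events
matching the same WGD.

## Curation rules

Applied in fixed order, one decision per record: length < 300 nt →
discard; length < 800 nt without a family keyword in the annotation text
(case-insensitive; default keywords *heparanase*, *glucuronidase*, *GUS* —
database classifier outputs are not reproducible, annotation text is) →
discard; same species + same locus as an already-kept record → discard
(first listed wins; deterministic, since no authoritative tiebreak
exists); otherwise keep. Same-species copies within patristic distance
0.05 substitutions/site on a guide tree (single linkage) collapse to their
longest representative (ties by id). Short (< 800 nt) copies in clusters
designated loss-prone are flagged as pseudogenization candidates —
advisory only.

## Simulator

Gene families evolve top-down along the dated species tree. Per lineage
and branch: duplication at rate λ_dup and loss at rate λ_loss (events per
lineage per Myr, exponential waiting times). WGDs are pinned to a branch
at a fixed age; every live lineage doubles and each *new* copy survives
with the event's retention probability. A duplication is "locked" with
probability `p_dfd` (eligibility optionally restricted by `lock_min_age`,
compared against the age of the node below the carrying branch — the same
quantity the classifier thresholds); locked lineages multiply their loss
rate by `lock_loss_factor` (default 0 — full protection) and pass the lock
to descendants, mirroring the idea that differentiation is a property of
the gene, not a branch.

Default rates (λ_dup = 0.002, λ_loss = 0.001 per lineage per Myr) are
order-of-magnitude plant gene-family values; the validation studies
override them per scenario (see below). The species-tree sampler is a
forward birth–death process conditioned on the tip count, with the present
drawn uniformly between the moment the count is reached and the next
event so that pendant edges are positive; trees can be rescaled to a
target root age.

What the simulator does *not* emulate: sequence evolution (no alignments,
no branch-length noise, no gene-tree estimation error), incomplete lineage
sorting, horizontal transfer, hybridization, or sampling failure. Passing
the recovery tests therefore shows the inference chain is correct when the
input gene tree is correct; it says nothing about robustness to tree
estimation artifacts such as long-branch attraction.

## Validation studies (sizes and seeds)

Run by `scripts/acceptance.py` and mirrored in `tests/test_acceptance.py`;
sizes were fixed once as a balance of statistical resolution and desk-scale
runtime (the full script completes in a few seconds):

- demo family: 14 copies, 5 species — 3 phylum-complete clusters, 2
  angiosperm-crown duplications, 2 eudicot sub-lineages, 4 dual-retaining
  species;
- oracle sweep: 1 305 exhaustive + 400 random instances, 100% agreement
  required;
- calibration: single 100-Myr branch, λ = 0.01, μ = 0.005, 2 000
  replicates; mean copy number within 3 SE of e^0.5 ≈ 1.6487;
- DFD recovery: 200 families on a 16-tip tree (root 300 Mya); with
  p_dfd = 1, lock_loss_factor = 0 and locks restricted to ancient events,
  DFD_LIKELY recall must equal 1 exactly at tol 0; with p_dfd = 0 the
  DFD_LIKELY fraction must be non-increasing over μ ∈ {0.002, 0.01, 0.05}
  (at the highest rate most families go extinct and the fraction hits 0);
- curation: a 12-record table exercising every rule, plus idempotence and
  order-invariance of the kept set.

## Numerical and degenerate-input choices

Species trees must be ultrametric within a relative tolerance of 1e-6 and
strictly decreasing in age toward the tips; trees without branch lengths
are rejected since ages are the time axis. Gene trees must be binary for
duplication inference; polytomies can be resolved deterministically in
input order. Ties in the tight-paralog collapse go to the
lexicographically smallest id; event ordering in reports is oldest-first,
then by clade size. An extinct simulated family returns an empty result
with a warning rather than an error. All randomness flows through numpy
generators seeded from a single integer; identical seeds give
byte-identical trees, logs and reports.

## Known limitations

- The double-gene phylum test is purely descriptive: no null model, no
  p-values; `NON_DFD_LOSSY` thresholds are conventions, not estimates.
- LCA reconciliation attributes all incongruence to duplication and loss;
  a wrong or poorly rooted input gene tree propagates directly into the
  event list.
- WGD matching requires the event branch to carry the WGD; losses that
  displace a duplication's mapped node defeat the association.
- The full published census of species retaining both main clusters
  (96 species) depends on supplementary tables not shipped here; the
  counting operation is exercised on the demo family only.
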