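# Methods

## Molecular graphs and atom typing

Compounds are heavy-atom graphs: hydrogens are implicit (explicit hydrogens
in molfiles are stripped), coordinates, stereochemistry, charges and isotopes
are ignored. Ring membership is perceived structurally — an atom is flagged
`rg` iff it lies on some cycle (equivalently, is incident to a non-bridge
edge); aromaticity is taken from the input bond annotation only (aromatic
bond type in molfiles / RDKit aromatic perception for SMILES input), never
re-perceived from geometry or electron counting. This keeps typing fully
deterministic across sources.

Every atom carries an environment code `ELEMENT.hyb.ring.het`:

- `hyb` ∈ {`sp3`, `sp2`, `ar`, `sp`}: `ar` for any incident aromatic bond,
  `sp` for a triple bond or two incident double bonds, `sp2` for a double
  bond, else `sp3`;
- `ring` ∈ {`rg`, `ac`};
- `het` ∈ {`h0`, `h1`, `h2+`}: number of non-carbon heavy neighbors.

The vocabulary is element-complete (any element accepted) and versioned
(`envcode-1`); similarity scores are refused across vocabulary versions.
The granularity — element × hybridization × ring × hetero-neighbor class —
is the same class of resolution as the KEGG atom types used by
reaction-classification systems, but is fully specified here.

## Atom mapping

The substrate→product correspondence is a maximum common **connected**
induced subgraph under element compatibility. Bond orders are deliberately
not a constraint: the bond whose order changes *is* the reaction center, and
an order-strict MCS would push it out of the mapping.

Exact search is a seeded branch-and-bound enumeration of connected common
induced subgraphs (each search tree requires its seed to be the smallest
mapped substrate atom, making enumeration duplicate-free), with an
optimistic reachability bound. Ties between equal-size mappings are broken
by the lexicographically smallest sorted pair sequence, which gives
bit-reproducible mappings and, when substrate and product share their atom
numbering, prefers the identity-like mapping. Beyond a size cap (default 30
heavy atoms per graph, configurable) a greedy seed-and-extend heuristic is
used instead and the mapping is labeled `greedy-fallback`.

## RDM patterns and similarity

A mapped atom is a reaction center iff its type code changes, it is adjacent
to an unmapped atom on either side, or an incident bond inside the mapped
set changes order. Each center yields one triple:
R = (type before, type after); D = multiset of types of unmapped neighbors
(substrate-side types for lost atoms, product-side for gained);
M = multiset of (before, after) type pairs of mapped neighbors.

Triple similarity is `w_R·[R_a=R_b] + w_D·J(D) + w_M·J(M)` with multiset
Jaccard `J` and `J(∅,∅) = 1` — absence agreeing with absence is evidence,
and two pure bond-order-change centers with no difference region must be
able to score 1. Default weights (0.5, 0.25, 0.25) make the center change
dominate, reflecting the primacy of the R atom in reaction-center
classification; they are configurable and must sum to 1. Pattern similarity
is the maximum-weight bipartite matching over triples (solved by the
Hungarian algorithm) divided by the larger triple count; two empty patterns
score 1, exactly one empty scores 0. The score is symmetric, lies in [0, 1],
and equals 1 iff the triple multisets are equal. No published definition of
the similarity score returned by hosted reaction-similarity services exists,
so this scorer is this package's own documented definition; absolute score
values are not comparable to any external service, though thresholding and
ranking behave analogously.

## Taxon specificity

A reaction is *specific* to a group iff the organisms of all its ortholog
clusters' genes lie in that group (strictest reading; a
`min_group_fraction` knob relaxes it, default off at 1.0). Reactions with
no clusters are orphans: they are *orphan-specific* only on explicit
pathway evidence (`pathway_taxa == {group}`), never inferred from missing
data, and *unassigned* otherwise. Every clustered reaction is exactly one
of specific/shared; every orphan exactly one of orphan-specific/unassigned.

## The screen

Queries are the taxon-specific reactions (orphans included by default);
the target pool is every reaction with ≥ 1 gene in the target group; every
(query, target) pair is scored on the main substrate/product pair, with RDM
patterns cached per compound-pair content hash. Self-hits are excluded;
candidates at or above the threshold keep the hit reaction's target-taxon
genes only. Ranking is by descending score, ties by hit reaction id. The
default threshold 0.4 is the conventional operating point for this kind of
screen, with tier counts reported up to 0.9. An optional pre-filter
(default off) skips pairs whose patterns share no reaction-center element
whenever the resulting upper bound `w_D + w_M` is below the threshold; it
never changes the candidate set, but sub-threshold scores of skipped pairs
are recorded as 0.

Multi-substrate reactions are reduced to one main pair per reaction (TSV:
one pair per row; KEGG-style flat files: first compound on each side, rest
kept as context). This convention is recorded in output metadata.

## Sequence-independence check

Smith–Waterman local alignment with BLOSUM62 and BLAST-style affine gaps
(a gap of length L costs 11 + L). Identity is matches over aligned columns
(gap columns included) and coverage is the aligned query span over query
length — the conventions used by BLAST tabular reports. Among co-optimal
alignments a canonical one is chosen: the end cell with the smallest
(query, target) index, traceback preferring substitution over a
query-consuming gap over a target-consuming gap, shortest gaps first.
A pair with no positive-scoring window is reported `N.A.` (not aligned),
a deterministic, tool-free analog of a BLAST no-hit. E-values are out of
scope (no Karlin–Altschul statistics), as is multiple alignment.

## Synthetic data

The generator emulates the statistical shape of a cross-taxon screen:
plant-specific reactions (default 20, of which 10 carry planted bacterial
analogs), background bacterial reactions (30), mixed-taxon shared reactions
(5), orphan plant reactions with pathway evidence only (5), over 5 plant and
8 bacterial organisms. Compounds are random trees of 4–12 heavy atoms over
{C, N, O} plus up to two ring-closing edges — small enough for the exact
MCS path, rich enough to exercise ring/acyclic and hetero-class type
distinctions. One global seed feeds per-component substreams
(`SeedSequence(seed, spawn_key=(component,))`), so changing one count does
not perturb the other components; identical configs are byte-identical on
disk.

Planted analogs must score exactly 1.0 at perturbation 0 and be
unambiguously recoverable, and this is arranged structurally rather than by
rejection sampling:

- each planted pair draws a distinct *signature* from a 36-entry pool
  (hetero flank element N/O/S × new bond order 2/3 × center degree shape ×
  direction) defining a bond-order change at a center carbon whose
  first- and second-shell environment is fixed by the signature, with the
  random scaffold attached strictly outside it;
- query and analog realise the same signature on different scaffolds, so
  their RDM patterns coincide triple for triple;
- background reactions are single-bond atom additions/removals, whose
  triples never contain a hybridization-changing R, so no background
  reaction can tie (or even approach) a planted analog on a planted query.

The perturbation ladder (levels 0–3) attaches pendant oxygens to the
center's neighbors in a fixed order, changing one matched-region entry per
level and, at level 3, the second center's own code — mean planted scores
along the ladder are strictly decreasing (≈ 1.0 / 0.95 / 0.91 / 0.58 under
default weights).

Protein fixtures are random 300-residue sequences with candidates derived
by point substitution at controlled rates (expected identity 100·(1−rate))
or unrelated random sequences.

What passing on this generator does **not** show: real metabolite graphs
are larger, aromatic-ring-rich and stereochemically constrained; real
ortholog clusters are noisy and incomplete; real analog reactions are
rarely exact. The generator validates the machinery (mapping, extraction,
scoring, filtering, reporting), not biological recall on KEGG-scale data.

## Numerical and scale choices

- Exhaustive-oracle checks run on graphs ≤ 8 atoms (subset enumeration is
  exponential), screens on databases of ~70 reactions, alignments on
  sequences ≤ 60 for the cubic oracle — sizes at which the independent
  oracles are feasible while every code path is exercised.
- Scores are plain float arithmetic; the 1.0-iff-equal property holds
  exactly because equal patterns produce component scores of exactly 1.0.
- Jaccard of empty multisets is 1 by convention (see above); degenerate
  inputs (empty mapping, empty patterns, single-atom compounds) follow the
  documented conventions rather than erroring.

## Known limitations

- Heavy-atom chemistry only: stereochemistry, charges, tautomers and
  reaction balancing are out of scope, as is EC-number prediction.
- The headline counts of KEGG-scale screens (hundreds of taxon-specific
  reactions) are not reproducible here: they depend on licensed database
  releases and a hosted scoring service; this package reproduces the
  *method* at desk scale.
- Exact MCS is exponential in the worst case; the size cap plus greedy
  fallback bounds runtime at the cost of optimality guarantees on very
  large compounds.
- Whether hosted tools score per hit reaction or per orthologue group is
  unknown; this package scores per hit reaction and attaches all its
  target-taxon genes.
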