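# Methods

## The model

A single protein chain is modelled as a three-tier vertex-weighted
hierarchical graph.

**Bottom tier.** Each of the 20 canonical amino acids is a fixed rooted
graph: vertices are heavy atoms (hydrogen-suppressed), edges are covalent
bonds, the root is the backbone Cα.  Vertex weights are standard atomic
masses (u, 3 decimals, bundled in `data/atomic_masses.csv`).  Residue graphs
are independent — the peptide bond is not an edge — and use the generic
in-chain form without the terminal OXT, so all residues are treated
uniformly.  Aromatic rings are plain cycles; protonation states are
irrelevant because hydrogens are suppressed.  The topology table
(`data/residue_topology.json`) is editable: residue code → atom list (name,
element) and bond list.

**Mid tier.** A substructure table assigns each secondary-structure element
*Dᵢ* a 1-based inclusive residue interval.  Adjacent intervals may share
their boundary residue; the shared residue is a vertex of *both* mid graphs.
Within an interval, residues are vertices and an edge joins two residues
whose distance under the chosen metric is at most the threshold.  Distance
metrics: `calpha` (Cα–Cα, default threshold 7 Å), `centroid` (unweighted
heavy-atom centroid, 8 Å offered), `center_of_mass`, and `all_atom`
(minimum heavy-atom pair distance).  Edges carry the number of atom-level
contacts within the threshold, counted over all heavy atoms or side-chain
atoms only (`count_metric="side_chain"`, backbone N/Cα/C/O excluded;
glycine then contributes no atoms).  A residue-level pair with no witnessing
atom contact under the count metric is not stored — with the default
settings the Cα pair itself is always a witness, so storage coincides with
the metric rule.  An optional `min_contacts_mid` raises the per-edge contact
requirement at the mid level (default 1; the ≥2 rule below applies to the
top level only).

**Top tier.** One vertex per substructure.  *Dᵢ* and *Dⱼ* are adjacent when
at least `min_pairs_top` (default 2) residue pairs spanning the two
intervals are in contact; pairs involving a shared boundary residue never
count toward the edge between the two substructures that share it (a residue
cannot contact itself).  The edge weight is the total spanning contact
count.

## Weighted invariants

For a graph with vertex weights *w*:

* weighted degree of *v*: Σ of *w* over the neighbors of *v*; maximum and
  average weighted degree follow.
* weighted domination: lower = minimum total weight over dominating sets;
  upper = maximum total weight over *minimal* dominating sets.  The
  restriction to minimal sets mirrors the classical upper domination number;
  without it the full vertex set would always be the maximum and the
  invariant would be vacuous.
* weighted path length: sum of vertex weights along the path *excluding the
  start vertex*, so unit weights recover the edge count.  This makes the
  induced distance directed; eccentricity, diameter (over ordered pairs) and
  periphery (vertices attaining the diameter, compared with absolute
  tolerance 1e-9) follow.
* circumference: vertex count of a longest simple cycle, 0 if acyclic —
  kept unweighted.

With all weights 1 every invariant reduces to its classical counterpart;
scaling all weights by λ > 0 scales the degree, domination and distance
invariants by λ.  Neighbor and dominating-set sums use `math.fsum`, so
values are exact and invariant under vertex relabeling.

All algorithms are exact.  Minimal dominating sets are enumerated by
branching on the closed neighborhood of the first undominated vertex with
exclusion of already-tried branches; the enumeration depends only on
topology and is cached per mid graph so many descriptor weightings reuse
one enumeration.  Longest cycles use an anchored depth-first search.  Both
are exponential in the worst case; the graphs they meet here are small
(≤ 14 atoms at the bottom, a few dozen residues per substructure).
A separate brute-force oracle (all subsets / all simple paths / all simple
cycles, refusing graphs above 14 vertices) validates the optimized routines
on hundreds of seeded random graphs in the test suite.

Weighted domination and weighted distances require non-negative weights
(negative weights would make "shortest" ill-defined in cyclic graphs and
break the minimal-set argument for domination).  During weight propagation,
descriptors containing negative values (hydropathy, charge, consensus
hydrophobicity) are therefore skipped for those invariants, with a warning;
degree-based invariants are computed for every descriptor.  The spanning-
tree analyses use degree-based weights and are unaffected.

## Descriptors and propagation

Every mid vertex carries its residue's descriptor vector.  The bundled
table combines:

* six graph-derived descriptors of the mass-weighted residue atom graphs —
  weighted lower/upper domination, weighted diameter, circumference, average
  weighted degree, and the cardinality of the weighted periphery (the
  periphery is a vertex set; its size is the numeric descriptor).  These are
  recomputed from the atom graphs at load time, so they are bit-identical
  to recomputation by construction.
* fifteen physicochemical indices compiled from widely used amino-acid
  scales: Kyte–Doolittle hydropathy (`Hydpthy`), Grantham polarity (`Plr`),
  net side-chain charge at pH 7 (`Chrg`, His 0.1), normalized van der Waals
  volume (`vanderWaal`), isoelectric point (`IsoElectric`), Veljković
  electron–ion interaction potential (`EIIP`), Eisenberg consensus
  hydrophobicity (`averhydrophocitiy`), Pace–Scholtz helix propensity
  (`ss-stability`), Balaban's J of the residue heavy-atom graph
  (`Balaban index`), and companion scales for side-chain stability
  contribution, charge-transfer capability and donation, coil propensity,
  side-chain radius of gyration, and shape (`stablty`, `chargetransf`,
  `chargedonar`, `coilConformation`, `RofGyr`, `ShapeIndex`).

Propagation writes, for each top vertex, one entry per
(invariant, descriptor) pair named `"invariant:descriptor"` — e.g.
`max_weighted_degree:Hydpthy` is the largest hydropathy-weighted degree of
the substructure's mid graph.  `circumference` is topology-only and stored
once.  Propagation is idempotent.  Mid graphs are normally connected
(consecutive residues are always within any sensible threshold); if a gap
disconnects one, the weighted diameter is taken as the maximum over
components and the periphery counts vertices attaining it.

## Mutations

Compact notation: `V51R` (substitution), `F508del` (deletion), `508insG`
(insertion *after* position 508 — the compact form does not specify an
anchor, so "after" is fixed here and documented).  Positions refer to the
original numbering; batches are applied right-to-left.

Substitutions preserve all topology, so the weight-only mutant
(`reweight_mutant`) just swaps descriptor vectors and re-propagates; the
affected top vertices are exactly the substructures containing the mutated
positions (two, when the position is a shared boundary residue).  Indels
change the mid-level vertex set, so `reweight_mutant` rejects them and the
hierarchy is instead rebuilt from a user-supplied structure
(`rebuild_mutant_from_structure`) — typically the output of an external
structure-prediction service; no such service is called here.  After
indels, substructure intervals are shifted by the cumulative offset of
indels strictly before each boundary.  The rebuild checks the structure
against the declared substitutions and reports the first mismatch position.

Graph diffs report exact edge set differences, per-vertex weight deltas,
and simple cycles present on one side only, enumerated up to 8 vertices by
default (long enough for the cycle lengths of interest in substructure
graphs while keeping enumeration cheap).

## Spanning-tree analysis

Edge weights derive from vertex weights: `w(Dᵢ)+w(Dⱼ)` (default, `sum`) or
the average.  The two differ by the constant factor 2, so every weight
comparison — hence the MST edge set and its uniqueness — is identical under
both; this equivalence is asserted in the tests.  The MST is computed by
Kruskal's algorithm with edges ordered by (weight, endpoint labels), making
results reproducible across platforms.  Minimization is the default; a
`maximize` flag is exposed for exploration.  Uniqueness is exact: a minimum
spanning tree is unique iff every non-tree edge is strictly heavier (beyond
a 1e-12 tie tolerance) than the heaviest tree edge on the path between its
endpoints; exhaustive enumeration over all spanning trees backs this for
small instances in the tests.

Mutation resampling draws `sample_size` mutations uniformly *without*
replacement per resample (a mutation set, not a multiset), computes the
weight-only mutant MST, and records vertex degrees.  The report gives the
per-vertex mean and population standard deviation (ddof = 0, so a
single-sample report has sd exactly 0).  The design is summarized by the
expected occurrences of each mutation, samples × sample_size / mutations;
`suggest_resampling_design` picks the sample count for a stated expectation
(default 2.5) at a given sample size.  Vertices with sd ≤ tolerance
(default 0) are classified stable, the rest sensitive.

## Synthetic structures

The generator emulates a single-chain PDB file with controllable geometry:

* `colinear` — Cα atoms on a line at a fixed spacing (default 3.8 Å, the
  canonical Cα–Cα virtual bond length).  With 3.8 Å spacing, a 7 Å
  threshold forces a path contact graph (3.8 ≤ 7 < 7.6) and an 8 Å
  threshold adds exactly the second neighbors — analytically known
  topologies used throughout the tests.
* `helix` — ideal α-helix (radius 2.3 Å, rise 1.5 Å per residue,
  100° per turn).
* `coil` — seeded persistent random walk with 3.8 Å steps.

Optionally a Cβ-like side-chain atom is placed 1.5 Å from each non-glycine
Cα.  Output is byte-deterministic given the seed.  These fixtures capture
inter-residue geometry, not chemistry: they carry no full side chains, no
backbone atoms beyond Cα(/Cβ), and the coil mode is not self-avoiding.
Tests passing on them therefore validate contact-map, hierarchy, mutation
and spanning-tree *logic* under controlled geometry; they say nothing about
descriptor choices or contact statistics of real structures, which require
a real PDB file (any single-chain PDB file can be supplied).

## Reference inputs

The bundled 19-row substructure table for yeast triosephosphate isomerase
is kept verbatim as printed in its source, including one known misprint:
row D10 declares the interval 12–130 with an 11-residue sequence (120–130
would be self-consistent).  The parser accepts the row, flags it via
`audit_definitions`, and never repairs it silently; analyses that need a
consistent D10 should edit the table deliberately.  Residues outside every
interval are dropped from the hierarchy with a warning.

## Problem sizes and determinism

The test and acceptance workloads use small instances chosen to keep
exhaustive oracles exact and fast: random graphs up to 10 vertices for the
invariant oracles (200 instances), up to 8 vertices for spanning-tree
enumeration (100 instances), 12–250-residue synthetic chains for geometry
and pipeline checks.  All randomness flows through seeded
`numpy.random.Generator` instances; every reported quantity is reproducible
from the seed.

## Known limitations

* Multi-chain assemblies are out of scope: one chain is selected; NMR
  ensembles use the first model only.
* Nonstandard residues (selenomethionine, PTMs, D-amino acids) need a
  user-supplied topology entry; there is no bond-order or charge model.
* Upper-domination enumeration and longest-cycle search are exponential in
  the worst case; they are intended for substructure-scale graphs, not
  whole-protein contact graphs (a mis-specified interval spanning half the
  chain will be slow).
* The physicochemical descriptor columns are representative published-scale
  values; swap in your own CSV (`load_descriptor_table`) for
  application-grade analyses.
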