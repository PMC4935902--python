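# Methods

## Model

A rooted phylogenetic network on a taxon set X is a DAG with a single
indegree-0 node (the root), sinks bijectively labeled by X, and no *tree
node* (indegree ≤ 1) of outdegree exactly 1. Reticulate nodes (indegree ≥ 2)
may have outdegree 1. `PhyloNetwork` enforces all of this at construction;
mid-reduction intermediates use a relaxed variant that waives only the
outdegree-1 condition. Nodes are stratified by *height* (longest path to a
leaf) and *depth* (longest path from the root); both are longest-path
lengths, computed in two topological sweeps.

A note on leaves: we classify a node as a leaf purely by outdegree 0. A sink
with indegree ≥ 2 (a "hybrid leaf", written `x#H1` in eNewick) is therefore
a labeled leaf that is also reticulate. The stricter reading under which
leaves must be tree nodes would exclude standard hybrid-species encodings.

## Semiequivalence, equivalence, and d_e

Semiequivalence (≜) is the coarsest bottom-up congruence: leaves match by
taxon, internal nodes match when their children pair into semiequivalent
pairs. Equivalence (≡) further requires parents to pair into equivalent
pairs, with the roots as base case. The definitions index children
u1…uk against v1…vk, but networks carry no child order, so we match by
multiset — any fixed ordering would make ≜ depend on serialization and break
the equivalence-relation property.

Both relations are computed by partition refinement with interned
fingerprints: a node's semiequivalence class id is the interned pair
(taxon) or (multiset of child class ids); its equivalence class id is the
interned pair (semieq id, multiset of parent eq ids), the root contributing
the empty parent multiset. The intern table is shared across a network pair,
so cross-network semi/equivalence is plain id equality and the h and g
mappings are table lookups. Two linear sweeps replace the O(n^5) pairwise
dynamic program; a definition-literal recursive oracle that tries every
child/parent bijection (exponential in degree, memoized) guards the
refinement in the tests.

d_e is half the symmetric difference of the class-multiplicity multisets
{eq class → class size} of the two networks. We compute it per the clipped
two-sided sum over unique-node representatives and cross-check it in tests
against a direct `Counter` symmetric difference. Arithmetic is exact: an
integer total halved into a `Fraction`, so the d_e = 0 test is never subject
to floating-point noise. Representatives of L(N) are chosen deterministically
as the (depth, height, name)-smallest class member.

`is_isomorphic_partly_reduced` refuses inputs containing a superconvergent
set unless forced, because d_e = 0 guarantees isomorphism only on the partly
reduced space; the shipped `fig4_N1`/`fig4_N2` pair (d_e = 0, not
isomorphic) is the canonical reason. The independent isomorphism oracle is
VF2 (`networkx.DiGraphMatcher`) over the directed graphs with taxon-matched
nodes — an exhaustive, d_e-independent search, size-guarded because it is
exponential in the worst case.

## Reduction procedures

Full pipeline (`reduce_network`):

1. **Pendant collapse.** Every maximal reticulation-free clade is replaced
   by a placeholder leaf whose taxon is the clade's canonical newick
   serialization (children sorted lexicographically); a registry allows
   exact re-expansion. A network with no reticulate node at all passes
   through unchanged — collapsing the whole tree would leave a parentless
   placeholder, which the procedure does not define.
2. **Set removal + unary suppression, to a fixpoint.** In full mode the
   targets are maximal convergent sets (classes of internal nodes with
   identical reachable-leaf sets, size ≥ 2); in partial mode, superconvergent
   sets (grouped by (cluster, parent set), a group qualifying when its shared
   parent set has ≤ 1 element or is cluster-homogeneous). Removal deletes
   every node on a path from a set member down to a parent of an affected
   leaf — members included, those leaf parents excluded — and replaces each
   surviving boundary edge (p, v) by edges from p to every surviving leaf
   parent, merging duplicates. Unary suppression then repeatedly splices out
   indegree-1/outdegree-1 nodes. Sets are recomputed from scratch after
   every round (removals change clusters; stale sets would be unsound) and
   processed in a fixed order (sorted leaf set, then members).
3. **Re-expansion** of surviving placeholders.

Conventions adopted where the procedure is ambiguous or silent:

* A set member that is itself the parent of an affected leaf is *kept*
  (exclusion wins over inclusion); otherwise the reconnection target set
  could be empty and the taxon would be lost.
* Sets containing the root are never removed: every ancestor of the
  reconnection frontier would die with it, leaving the leaf parents as
  multiple roots. Such sets can only arise in full mode (the root's parent
  set is empty and unique, so no superconvergent set contains it).
* A root left unary (indegree 0, outdegree 1) by removal is suppressed, its
  child becoming the new root, so reduced outputs are always strict-valid.
* Whether the fixpoint is independent of the processing order is not
  established in general; the implementation fixes a deterministic order and
  the suite additionally checks order-independence on the fixture where two
  maximal sets coexist.

Reduction preserves the taxon set, is idempotent up to isomorphism in both
modes, and full-mode outputs are fixpoints of partial-mode reduction (the
reduced space sits inside the partly reduced space) — all asserted in tests.

## Fixture reconstructions

The catalog networks (`fig1_*`, `fig2_*`, `fig3_reduced`, `fig4_*`) are
reconstructions: topologies chosen to satisfy, simultaneously, the published
structural facts about these examples — which maximal convergent and
superconvergent sets exist, which nodes are semi/equivalent within and
across the pair, the h/g memberships, the reduction stages, the d_e values,
and the (non-)isomorphism verdicts. The fixture self-test asserts every one
of those facts, so the reconstructions are checked rather than trusted.
Two facts are worth spelling out because they are forced:

* In the refinement pair, H1 ≜ H2 requires the two reticulations to share
  their child set (every other class is a singleton), so their common child
  G necessarily has indegree 2.
* In the separation-failure pair, a counting argument shows that if {H, J}
  were the *only* nontrivial equivalence class, d_e = 0 would force
  isomorphism. A d_e = 0 non-isomorphic pair therefore needs equivalent
  nodes with equivalent-but-distinct parents; the reconstruction uses the
  cascade H/J → D1/D2 → C1/C2 merging into shared reticulations, with the
  two networks differing only in the D→C wiring (one has directed
  triangles, the other none). Only {H, J} is superconvergent — the deeper
  pairs have distinct parent sets — which also makes the pair a
  counterexample to the folklore claim that any two equivalent nodes lie in
  a common superconvergent set.

## Synthetic data generator

`random_network` grows a uniform random rooted binary tree on the requested
taxa (repeatedly joining two random roots), then adds each reticulation by
subdividing two edges and joining the subdivision points, rejecting choices
that would create a cycle (bounded retries, then `InfeasibleConfigError`).
This yields binary, strict-valid networks with exactly the requested number
of reticulations. In `partly_reduced` mode the partial reduction is applied
before returning. Defaults used throughout the suite — 4–5 leaves, 0–2
reticulations, networks ≤ 12 nodes — keep the exhaustive oracles exact while
exercising every code path; they emulate topology and reticulation
placement only, not branch lengths, hybridization rates or coalescent noise,
so passing tests speak to combinatorial correctness, not to biological
realism of any particular inference.

All randomness flows through one `random.Random(seed)` per call; identical
configurations reproduce identical edge lists. `perturb_network` provides
label swaps, leaf regrafts and added reticulations to manufacture
nonzero-distance partners for metric-axiom tests.

## Known limitations

* Branch lengths, edge weights and time-consistency are out of scope, as are
  other comparison measures (m-distance, μ-distance, tripartitions).
* The VF2 oracle and the literal ≜/≡ oracles are exponential and guarded to
  small inputs; they exist to referee the polynomial implementations.
* eNewick support covers the single-statement `#H`-tag dialect (quoted
  labels included); Nexus/PhyloXML/NeXML and multi-network files are not
  handled.
* d_e on networks that are not partly reduced is a measure, not a metric:
  the package computes it (default `pre_reduce="none"`), but callers wanting
  metric guarantees should pass `pre_reduce="partial"` or check
  `superconvergent_sets` first (the CLI warns).
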