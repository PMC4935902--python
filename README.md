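# phylonetdist

Comparing rooted **phylogenetic networks** — DAGs whose leaves are labeled by
taxa and whose reticulate nodes (indegree ≥ 2) model hybridization,
recombination and horizontal gene transfer — is harder than comparing trees:
deciding isomorphism of general rooted networks is graph-isomorphism-complete,
so no polynomial-time metric can cover the whole space (unless GI ∈ P).
`phylonetdist` implements the **d_e distance**, a polynomial-time computable
dissimilarity that is a true metric on the space of *partly reduced* networks,
together with the reduction procedures that define that space. It is aimed at
researchers in phylogenetics who need to compare reticulate evolutionary
histories reconstructed by different methods or from different loci.

## The distance

Two nodes u, v are **semiequivalent** (u ≜ v) when they are leaves carrying
the same taxon, or their children can be paired into semiequivalent pairs;
they are **equivalent** (u ≡ v) when additionally their parents pair into
equivalent pairs, the roots being the base case. Writing L(N) for one
representative per equivalence class of N and e_N(v) for the class size, with
classes matched across the two networks by cross-equivalence (e(∅) = 0):

```
d_e(N1, N2) = 1/2 [ Σ_{v ∈ L(N1)} max(0, e(v) − e(v′))
                  + Σ_{u ∈ L(N2)} max(0, e(u) − e(u′)) ]
```

— half the symmetric difference of the two class-multiplicity multisets.
d_e is symmetric, satisfies the triangle inequality, and on partly reduced
networks d_e(N1, N2) = 0 holds exactly when N1 ≅ N2. A network is *partly
reduced* when it contains no **superconvergent set**: a set of ≥ 2 internal
nodes that reach the same leaves and share an identical parent set (itself
convergent when it has ≥ 2 members). `reduce_network(net, "partial")` maps
any network into that space; `"full"` mode removes all maximal convergent
sets, giving the classical reduced version. Everything runs in low-order
polynomial time via interned bottom-up/top-down partition refinement.

## Worked example

The package ships reconstructions of the classic counterexample pair: two
non-isomorphic networks on {1, 2, 3, 4, x} that earlier cluster-based
distances cannot tell apart.

```python
>>> import phylonetdist as pnd
>>> n1, n2 = pnd.load_fixture("fig1_N1"), pnd.load_fixture("fig1_N2")
>>> [sorted(s.members) for s in pnd.maximal_convergent_sets(n1)]
[['G', 'H1', 'H2']]
>>> cm = pnd.cross_mapping(n1, n2)
>>> sorted(cm.h["H1"]), sorted(cm.g["H1"])
(['h1', 'h2'], [])
>>> pnd.de_distance(n1, n2).as_decimal()
'4'
>>> r1, _ = pnd.reduce_network(n1, "full"); r2, _ = pnd.reduce_network(n2, "full")
>>> pnd.oracle_isomorphic(r1, r2)
True
```

The two reticulations H1 ≜ H2 map onto {h1, h2} under the semiequivalence
mapping h, but no node of {H1, H2, G, x} has an equivalent partner (g = ∅
there), and symmetrically — eight unmatched singleton classes, hence
d_e = 8/2 = 4, even though both networks *reduce* to the same network. The
converse failure mode also ships: `fig4_N1`/`fig4_N2` are non-isomorphic yet
d_e = 0 — they contain the superconvergent set {H, J}, i.e. they are not
partly reduced, which is exactly why the metric guarantee is restricted to
that space.

The same computations are available from the shell:

```sh
phylonetdist fixtures show fig1_N1 --format nel > N1.nel
phylonetdist fixtures show fig1_N2 --format nel > N2.nel
phylonetdist dist --a N1.nel --b N2.nel          # prints: 4
phylonetdist check-iso --a N1.nel --b N1.nel     # exit 0 (isomorphic)
phylonetdist reduce --mode full --in N1.nel --out reduced.nel
```

Both the eNewick dialect (`.enwk`, reticulate nodes under shared `#H<k>`
tags) and a tab-separated edge-list format (`.nel`) are read and written
deterministically.

## Layout

| module | contents |
| --- | --- |
| `phylonetdist.network` | `PhyloNetwork` model, validation, height/depth stratification |
| `phylonetdist.io` | eNewick and edge-list parsing/writing |
| `phylonetdist.reduction` | clusters, (super)convergent sets, full/partial reduction |
| `phylonetdist.equivalence` | ≜ / ≡ classes, cross mappings h and g, L(N), literal oracles |
| `phylonetdist.metric` | `de_distance`, partly-reduced isomorphism decision, VF2 oracle |
| `phylonetdist.fixtures` / `.generator` | fixture catalog, seeded random networks, perturbations |
| `phylonetdist.cli` | `dist`, `reduce`, `classes`, `check-iso`, `fixtures` subcommands |

See `docs/methods.md` for the procedure definitions, the conventions adopted
where the underlying constructions are ambiguous, and known limitations.
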