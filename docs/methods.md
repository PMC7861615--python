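# Methods

## The producibility model

comscope models metabolism qualitatively. A genome-scale metabolic
network is a bipartite graph of reaction and metabolite nodes; each
reaction is a directed hyperedge from its reactant set to its product
set. Producibility from a nutrient set S is defined by network
expansion: starting from M₀ = S, a reaction is *activated* once every
reactant is reachable, its products become reachable, and the process
iterates to a least fixed point. Two consequences of this semantics are
worth keeping in mind:

- **cycles cannot self-activate** — a loop A→B→A contributes nothing
  unless some external route reaches A or B first. This is conservative
  with respect to internal cofactor cycling;
- **no stoichiometry, no yield** — activation is boolean, so the model
  answers "can this compound be synthesised at all from these
  nutrients", never "at what rate". That is precisely what makes it
  robust on automatically reconstructed, incomplete networks, where
  stoichiometric inaccuracies would cripple flux-based analysis.

Reversible reactions are split at load time into two irreversible
directed reactions (`_fwd`/`_rev`): expansion is defined on directed
edges only. A reaction with an empty reactant set is unconditionally
activatable and effectively injects its products as hidden seeds; such
reactions are legal but trigger a load-time warning.

### Reachable vs produced

The fixed point (`reachable`) contains the seeds by definition. The
*produced* set — products of at least one activated reaction — is what
all reports expose by default, with `--include-seed-compounds` to
switch. The distinction matters whenever a compound of interest is also
part of the growth medium: an organism should only be called a producer
of such a compound if it actually carries an activated reaction making
it, not merely because the compound was supplied. Both sets are carried
on `ScopeResult`.

### Community semantics

The community scope is the scope of the meta-network formed by the
set-union of all members' reactions, metabolites and edges — i.e.
unconstrained sharing of every intermediate between all members. This
is an optimistic bound on cooperation: no transport, compartment or
cost model stands between organisms. Reactions are merged across
organisms by their (reactants, products) pair after directional
expansion; identifiers differ freely between files, but two reactions
with the same qualitative chemistry become one meta-reaction (gene sets
unioned). How duplicate reactions should be merged across organisms is
a genuinely open design point; the (reactants, products) key is the
choice made here because it is the exact granularity at which expansion
distinguishes reactions.

Metabolite identity across networks is exact id-string equality. No
fuzzy matching is attempted — silently unifying `glc_c` with `glc[e]`
would manufacture complementarity out of nothing. An opt-in normalizer
(`strip_compartment`) strips a single trailing compartment token for
users who know their collection mixes suffix conventions.

The *cooperation potential* is the set difference between the community
produced set and the union of the individual produced sets: metabolites
no member can make alone but the community can. By construction it is
disjoint from every individual scope (asserted as a property test).

### Target-producer classification

For a target t, an organism is an *individual producer* if t is in its
own produced set, and a *community-only producer* if it is not, but it
carries a reaction producing t whose reactants are all reachable by the
full community — the organism can perform the final step once partners
supply the precursors. Targets no organism can produce even
collectively are flagged unproducible rather than rejected, since
screening workflows pass large speculative target lists.

## Minimal communities and key species

Community selection minimises the number of members whose collective
produced set covers the target set. Producibility is monotone in the
reaction set, which gives the solver two useful facts:

1. scanning subset sizes k = 1, 2, … and stopping at the first feasible
   size is exact (iterative deepening, the default `"bnb"` solver);
2. every feasible subset of the optimal size L is automatically a
   *minimal* community — no proper subset can be feasible — so
   enumeration reduces to scanning the size-L layer.

A reference `"bruteforce"` solver scans the full powerset and is kept
as the independently-coded correctness oracle (used in tests up to ~12
organisms; the test suite additionally carries a third, naive-closure
powerset oracle in `tests/conftest.py`).

Key species are computed without enumeration by 2n optimisation calls
("projection"): organism G is *key* iff the minimum size with G forced
into the community equals L; among key species, G is *essential* iff
excluding G makes the problem infeasible or pushes the optimum above L,
*alternative* otherwise. The enumeration route (union/intersection over
all optima) is provided as `strategy="enumeration"` and the two are
asserted equal in tests.

Determinism: among equally-sized optima the reported community is the
lexicographically smallest sorted org-id tuple; collections are always
ordered lexicographically by org id. Targets outside the full
community's produced set are dropped from the constraint with a warning
(they are still listed in the result); an entirely unproducible
objective raises `InfeasibleObjective` (CLI exit code 3). Enumeration
is capped at 10⁶ by default with an explicit `complete` flag — real
datasets can harbour millions of equivalent optima, and an unbounded
enumeration must be a deliberate user choice.

## Synthetic communities

`planted_collection` builds communities whose ground truth is known in
closed form. Each planted function is a linear pathway
seed → intermediates → target of `chain_length` reactions; essential
organisms carry the sole pathway to their target, each member of an
alternative group carries a byte-identical pathway to the group's
target, decoys carry pathways to non-target metabolites. Hence L =
n_essential + n_groups, the essential/alternative sets are the planted
ones, and the number of minimal communities is the product of the group
sizes. Every reaction carries `genes_per_reaction` (default 2) gene ids
drawn from a cyclic organism-wide pool, so adjacent reactions share
genes — the redundancy in gene→reaction assignment that real
annotations exhibit and that the degradation model exercises.

What the generator does *not* emulate: branched or interlocking
pathways, shared intermediates between functions, cofactor coupling,
partial pathway overlap between group members, or realistic network
sizes (real GSMNs carry ~10³ reactions). Passing the planted-recovery
tests therefore demonstrates the correctness of the combinatorial
machinery on communities with crisp ground truth, not predictive
performance on real microbiomes, where targets are typically producible
through many partially overlapping routes.

`random_collection` draws unstructured reactions (1–3 reactants and
products uniformly from a shared metabolite pool) purely as a
property-test input source; it makes no biological claim.

## Degradation model

`degrade_collection` emulates metagenome-assembled-genome
incompleteness at the network level: a uniformly random ⌈q·N⌉-subset of
networks is affected; within each, a uniformly random ⌈p·|genes|⌉
subset of its gene ids is deleted; a reaction is removed iff it loses
*all* of its genes and is not spontaneous; reactions with no gene
annotation are never removed. Ceiling rounding guarantees p > 0 always
deletes at least one gene, so small fixtures cannot silently no-op.
The RNG stream is split per network (in lexicographic org order), so a
network's fate is independent of how many others are degraded. Genes
are sampled uniformly, an assumption rather than a measured property
of assembly loss.

This operates on the gene associations of already-built networks; it
deliberately does not re-annotate or re-reconstruct a truncated genome,
so it captures the direct gene→reaction consequence of missing genes,
not annotation-pipeline artefacts. The qualitative expectations it
supports — reaction loss below gene loss under redundant assignment,
community-scope similarity non-increasing with the degraded fraction —
are asserted over 50 seeded replicates at p ∈ {0.02, 0.05, 0.10},
mirroring the completeness range usually accepted for draft genomes.

## Numerical and implementation choices

- Scope computation propagates unmet-reactant counts through a
  worklist: O(Σ|reactants(r)| + |products(r)|), independent of
  iteration order; the fixed point is reached in ≤ |R| + 1 synchronous
  rounds. The tests additionally check it against a naive quadratic
  fire-until-fixpoint closure under shuffled reaction orders.
- Problem sizes in tests and the acceptance script (random collections
  of 4–9 organisms with 4 reactions each, 200 random networks of ≤ 40
  reactions, 50 degradation replicates) are chosen so the full
  powerset oracles stay exact while the whole suite runs in seconds.
- SBML: Level 2 (notes-based `GENE_ASSOCIATION`) and Level 3 + fbc
  (v2 `geneProductAssociation`) are read; boolean gene logic is
  flattened to the referenced gene set, because qualitative
  producibility only asks whether *any* annotated route survived.
  Writing emits Level 3 + fbc v2. `boundaryCondition` is ignored:
  seeds alone define the expansion boundary. Duplicate reaction ids in
  a file and org-id collisions after filename sanitization are hard
  errors, never last-wins.
- Pipeline outputs are deterministic JSON (sorted keys, no embedded
  timestamps), so the all-in-one `metacom` command and the four stage
  commands produce byte-identical files; timestamps live only in the
  log.

## Known limitations

- No flux, yield, thermodynamics or exchange minimisation: a producible
  compound may still be kinetically or energetically out of reach.
- The meta-network assumes every intermediate is shareable; predicted
  cooperation potential is an upper bound on realisable cross-feeding.
- The exact solver's iterative deepening is exponential in the optimum
  size; it is built for collections up to tens of organisms (and
  exactness-checked up to 12). Microbiota-scale instances (hundreds to
  thousands of networks) need a dedicated combinatorial backend such as
  an ASP or ILP encoding, for which the solver interface leaves room.
- Gene-level degradation cannot capture annotation artefacts of real
  MAG pipelines (chimeric contigs, frameshifts), only gene loss.
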