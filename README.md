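# comscope

Metabolic complementarity screening and minimal-community selection for
collections of genome-scale metabolic networks (GSMNs).

Metagenomic studies routinely yield hundreds to thousands of (draft)
genomes per environment. Turning those into statements about *who feeds
whom* and *which organisms matter for a metabolic function* requires
scaling metabolic modelling far beyond what flux-based methods tolerate,
on models too incomplete for stoichiometric analysis. comscope targets
that regime with a qualitative formalism: **network expansion**. Given a
network G = (R ∪ M, E) and a set of seed nutrients S, the producible
metabolites are the least fixed point

    Scope(G, S) = ⋃ᵢ Mᵢ,  M₀ = S,  Mᵢ₊₁ = Mᵢ ∪ products({r ∈ R | reactants(r) ⊆ Mᵢ})

a reaction fires once all of its reactants are reachable, and cycles
cannot self-activate. On top of this primitive the package computes, for
a collection {G₁ … Gₙ}:

- **individual scopes** — what each organism can synthesise alone;
- **community scope** — the scope of the meta-network (⋃Rᵢ, ⋃Mᵢ, ⋃Eᵢ),
  i.e. unconstrained metabolite sharing across the community;
- **cooperation potential** — collectiveScope ∖ ⋃ scope(Gᵢ, S): the
  metabolites only cross-feeding can unlock;
- **minimal communities** — minimum-cardinality sub-collections whose
  collective scope covers a target set T (exact combinatorial
  optimisation, all equivalent optima enumerable);
- **key species** — organisms in at least one minimal community, split
  into **essential symbionts** (in every optimum) and **alternative
  symbionts** (in only some);
- **association graphs** and taxonomy-stratified role tables over the
  enumerated optima;
- a **degradation utility** that emulates draft-genome incompleteness by
  deleting random gene associations, for robustness studies.

It is aimed at microbiome researchers who have SBML metabolic networks
(reconstructed with any pipeline) plus a growth-medium description, and
who want community-level producibility screens and candidate keystone
organisms without flux balance analysis.

## Worked example

The packaged eight-organism community (`comscope test` runs it end to
end) plants a known structure: organism `Y` carries the only pathway to
target `t1`; pairs `A1`/`A2` and `B1`/`B2` carry interchangeable
pathways to `t2` and `t3`; `D1`–`D3` are decoys. From Python:

```python
import comscope as cs

coll, seeds, targets = cs.demo_community()
res  = cs.minimal_community(coll, seeds, targets)
enum = cs.enumerate_minimal_communities(coll, seeds, targets)
ks   = cs.key_species(coll, seeds, targets)
print(res.min_size, res.community)
print(len(enum), enum.communities)
print(ks.to_dict())
```

prints

```
3 ('A1', 'B1', 'Y')
4 (('A1', 'B1', 'Y'), ('A1', 'B2', 'Y'), ('A2', 'B1', 'Y'), ('A2', 'B2', 'Y'))
{'key_species': ['A1', 'A2', 'B1', 'B2', 'Y'], 'essential_symbionts': ['Y'],
 'alternative_symbionts': ['A1', 'A2', 'B1', 'B2']}
```

Three organisms suffice to cover all three targets; there are exactly
four equivalent optima (2 × 2 choices of pair members); `Y` occurs in
every optimum (essential), the four pair members are interchangeable
(alternative), and the decoys appear nowhere.

The same run from the shell, via the SBML file interface:

```sh
comscope metacom -n networks/ -s seeds.sbml -t targets.sbml -o out/
cat out/mincom.json
```

```json
{
  "bacteria": ["A1", "B1", "Y"],
  "min_size": 3,
  "key_species": ["A1", "A2", "B1", "B2", "Y"],
  "essential_symbionts": ["Y"],
  "alternative_symbionts": ["A1", "A2", "B1", "B2"],
  "producible": ["t1", "t2", "t3"],
  "still_unprod": []
}
```

`metacom` chains the four stages — `iscope`, `cscope`, `addedvalue`,
`mincom` — each of which can also be run on its own; when no targets
are given, the cooperation potential becomes the selection objective.
`comscope analysis` additionally enumerates all optima and writes the
co-occurrence association graph (GML + TSV) and a per-taxon role table.

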