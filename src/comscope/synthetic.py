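"""Synthetic communities with planted ground truth, and degradation.

Three generators support testing and benchmarking:

* :func:`planted_collection` builds a community whose minimal-community
  structure is known in closed form — organisms carrying unique
  pathways are essential symbionts by construction, interchangeable
  group members are alternative symbionts, and the number of minimal
  communities is the product of the group sizes;
* :func:`random_collection` draws unstructured random networks for
  property tests;
* :func:`degrade_collection` emulates the incompleteness of
  metagenome-assembled genomes by deleting a fraction of gene
  identifiers from a fraction of the networks, then dropping the
  reactions that lost *all* their gene support.  Because several genes
  can back the same reaction, reaction loss lags gene loss — the
  redundancy that makes qualitative producibility robust to draft
  genomes.

Degradation operates on the gene associations of already-built
networks.  It does not re-run annotation or reconstruction on a
truncated genome, so it captures the direct gene→reaction effect of
incompleteness, not annotation-pipeline artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, prod

import numpy as np

from .model import (
    CompoundSet,
    MetabolicNetwork,
    NetworkCollection,
    Reaction,
)
from .selection import KeySpeciesResult


@dataclass(frozen=True)
class PlantedSpec:
    """Blueprint of a community with known key-species structure.

    ``n_essential`` organisms each carry the only pathway to one
    target; each entry of ``alt_groups`` is the size of a group of
    interchangeable organisms sharing an identical pathway to that
    group's target; ``n_decoys`` organisms contribute pathways to
    non-target metabolites only.  ``chain_length`` is the number of
    reactions in every pathway.  Construction is fully deterministic;
    ``rng_seed`` is carried for provenance and future randomised
    variants.
    """

    n_essential: int = 1
    alt_groups: tuple[int, ...] = (2, 2)
    n_decoys: int = 3
    chain_length: int = 1
    genes_per_reaction: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alt_groups", tuple(self.alt_groups))
        if self.n_essential < 0 or self.n_decoys < 0 or min(
            self.alt_groups, default=1
        ) < 1:
            raise ValueError("counts must be non-negative, group sizes >= 1")
        if self.n_essential == 0 and not self.alt_groups:
            raise ValueError("spec plants zero targets")
        if self.chain_length < 1 or self.genes_per_reaction < 1:
            raise ValueError("chain_length and genes_per_reaction must be >= 1")

    @property
    def n_targets(self) -> int:
        return self.n_essential + len(self.alt_groups)

    @property
    def expected_min_size(self) -> int:
        return self.n_essential + len(self.alt_groups)

    @property
    def expected_n_communities(self) -> int:
        return prod(self.alt_groups) if self.alt_groups else 1


SEED_ID = "seed"


def _pathway(
    org: str, fn: str, target: str, spec: PlantedSpec
) -> list[Reaction]:
    """A linear chain seed → ... → target of ``chain_length`` reactions.

    Intermediate metabolite ids are keyed by *fn* (the planted
    function), so every member of an alternative group carries
    byte-identical reaction topology while genes stay organism-specific
    (reaction i draws genes g_i .. g_{i+k-1} from a cyclic
    organism-wide pool — adjacent reactions share genes, the redundancy
    the degradation model exercises).
    """
    c = spec.chain_length
    n_genes = max(c, spec.genes_per_reaction)
    mets = [SEED_ID] + [f"{fn}_i{j}" for j in range(1, c)] + [target]
    rxns = []
    for j in range(c):
        genes = frozenset(
            f"{org}_g{(j + k) % n_genes}" for k in range(spec.genes_per_reaction)
        )
        rxns.append(
            Reaction(
                id=f"{org}_r{j}",
                reactants=frozenset({mets[j]}),
                products=frozenset({mets[j + 1]}),
                genes=genes,
            )
        )
    return rxns


def planted_collection(
    spec: PlantedSpec,
) -> tuple[NetworkCollection, CompoundSet, CompoundSet, KeySpeciesResult, int]:
    """Build the planted community.

    Returns ``(collection, seeds, targets, ground_truth, L)`` where the
    ground truth is exact by construction: the minimal community size L
    equals ``n_essential + len(alt_groups)``, the essential symbionts
    are the uniquely-capable organisms, the alternative symbionts are
    all group members, and the number of minimal communities is the
    product of the group sizes.
    """
    networks: list[MetabolicNetwork] = []
    targets: list[str] = [f"t{i}" for i in range(1, spec.n_targets + 1)]
    t_iter = iter(targets)
    essential: list[str] = []
    alternative: list[str] = []
    for i in range(1, spec.n_essential + 1):
        org = f"E{i}"
        essential.append(org)
        fn = f"fE{i}"
        networks.append(MetabolicNetwork(org, _pathway(org, fn, next(t_iter), spec)))
    for g, size in enumerate(spec.alt_groups, start=1):
        target = next(t_iter)
        fn = f"fG{g}"
        for m in range(1, size + 1):
            org = f"G{g}M{m}"
            alternative.append(org)
            networks.append(MetabolicNetwork(org, _pathway(org, fn, target, spec)))
    for d in range(1, spec.n_decoys + 1):
        org = f"D{d}"
        networks.append(
            MetabolicNetwork(org, _pathway(org, f"fD{d}", f"decoy{d}", spec))
        )
    coll = NetworkCollection(networks)
    seeds = CompoundSet("seeds", frozenset({SEED_ID}))
    target_set = CompoundSet("targets", frozenset(targets))
    truth = KeySpeciesResult(
        key_species=frozenset(essential) | frozenset(alternative),
        essential_symbionts=frozenset(essential),
        alternative_symbionts=frozenset(alternative),
    )
    return coll, seeds, target_set, truth, spec.expected_min_size


FIG_DEMO_SPEC = PlantedSpec(n_essential=1, alt_groups=(2, 2), n_decoys=3,
                            chain_length=1)

_DEMO_RENAME = {"E1": "Y", "G1M1": "A1", "G1M2": "A2", "G2M1": "B1",
                "G2M2": "B2"}


def demo_community() -> tuple[NetworkCollection, CompoundSet, CompoundSet]:
    """The eight-organism worked example.

    One organism (Y) holds the only route to target t1; two
    interchangeable pairs (A1/A2 and B1/B2) each cover t2 and t3; three
    decoys (D1–D3) produce nothing targeted.  There are exactly four
    minimal communities, each of size three, Y being a member of every
    one: Y is the sole essential symbiont and the four pair members are
    the alternative symbionts.
    """
    coll, seeds, targets, _, _ = planted_collection(FIG_DEMO_SPEC)
    renamed = []
    for net in coll:
        org = _DEMO_RENAME.get(net.org_id, net.org_id)
        renamed.append(
            MetabolicNetwork(
                org, list(net), metabolites=net.metabolites.values(), expand=False
            )
        )
    return NetworkCollection(renamed), seeds, targets


def random_collection(
    n_networks: int,
    n_metabolites: int,
    n_reactions: int,
    rng_seed: int,
) -> NetworkCollection:
    """Unstructured random networks for property testing.

    Each network draws ``n_reactions`` reactions whose reactant and
    product sets are 1–3 metabolites sampled uniformly (without
    replacement within a side) from a shared pool ``M1..Mk``.  Fully
    reproducible for a given ``rng_seed``.
    """
    if n_networks < 1 or n_metabolites < 1 or n_reactions < 0:
        raise ValueError("sizes must be >= 1 (n_reactions >= 0)")
    rng = np.random.default_rng(rng_seed)
    pool = np.array([f"M{i}" for i in range(1, n_metabolites + 1)])
    networks = []
    for i in range(1, n_networks + 1):
        rxns = []
        for j in range(n_reactions):
            n_sub = int(rng.integers(1, 4))
            n_prod = int(rng.integers(1, 4))
            sub = rng.choice(pool, size=min(n_sub, len(pool)), replace=False)
            prod_ = rng.choice(pool, size=min(n_prod, len(pool)), replace=False)
            rxns.append(
                Reaction(
                    id=f"N{i}_r{j}",
                    reactants=frozenset(map(str, sub)),
                    products=frozenset(map(str, prod_)),
                    genes=frozenset({f"N{i}_g{j}"}),
                )
            )
        networks.append(MetabolicNetwork(f"N{i:03d}", rxns))
    return NetworkCollection(networks)


@dataclass(frozen=True)
class DegradationSpec:
    """Parameters of the draft-genome degradation model.

    ``p_genes``: fraction of gene identifiers deleted in each affected
    network; ``q_networks``: fraction of networks affected.  Fractions
    are rounded with a ceiling, so any p > 0 deletes at least one gene
    in every affected network — small fixtures cannot silently no-op.
    """

    p_genes: float
    q_networks: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_genes <= 1.0 and 0.0 <= self.q_networks <= 1.0):
            raise ValueError("p_genes and q_networks must lie in [0, 1]")


def degrade_collection(
    coll: NetworkCollection, spec: DegradationSpec
) -> NetworkCollection:
    """Delete random genes and drop the reactions left with no support.

    A uniformly random ⌈q·N⌉-subset of the networks is degraded; within
    each, a uniformly random ⌈p·|genes|⌉-subset of its gene identifiers
    is deleted.  A reaction is removed iff *all* of its genes were
    deleted and it is not spontaneous; orphan reactions (no genes)
    are never touched.  Surviving reactions keep only their surviving
    genes.

    The RNG stream is split per network (in lexicographic org order),
    so which genes a given network loses does not depend on how many
    other networks are degraded.
    """
    n = len(coll)
    root = np.random.SeedSequence(spec.rng_seed)
    children = root.spawn(n + 1)
    select_rng = np.random.default_rng(children[0])
    n_affected = ceil(spec.q_networks * n)
    affected = set(
        select_rng.choice(n, size=n_affected, replace=False).tolist()
    )
    out = []
    for idx, net in enumerate(coll):
        if idx not in affected:
            out.append(net)
            continue
        genes = sorted({g for r in net for g in r.genes})
        n_del = ceil(spec.p_genes * len(genes))
        if n_del == 0 or not genes:
            out.append(net)
            continue
        rng = np.random.default_rng(children[idx + 1])
        deleted = set(
            np.array(genes)[
                rng.choice(len(genes), size=n_del, replace=False)
            ].tolist()
        )
        kept = []
        for rxn in net:
            if rxn.genes and rxn.genes <= deleted and not rxn.spontaneous:
                continue
            surviving = rxn.genes - frozenset(deleted)
            kept.append(
                Reaction(
                    id=rxn.id,
                    reactants=rxn.reactants,
                    products=rxn.products,
                    reversible=rxn.reversible,
                    genes=surviving if rxn.genes else rxn.genes,
                    spontaneous=rxn.spontaneous,
                )
            )
        out.append(
            MetabolicNetwork(
                net.org_id, kept, metabolites=net.metabolites.values(), expand=False
            )
        )
    return NetworkCollection(out)
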