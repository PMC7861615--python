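"""Network expansion: scopes, community scope, cooperation potential.

The scope of a network G under seed nutrients S is the least fixed
point of

    M0 = S,   M_{i+1} = M_i ∪ products({r ∈ R | reactants(r) ⊆ M_i})

i.e. a reaction fires once all its reactants are reachable, and cycles
cannot self-activate.  This boolean abstraction deliberately ignores
stoichiometry, which makes it robust to the inaccuracies of
automatically reconstructed networks.

Two sets are distinguished per network:

* ``reachable`` — the fixed point itself (seeds included);
* ``produced`` — metabolites that are products of at least one
  activated reaction.

Reports expose ``produced`` by default: a seed counts as *producible*
only if some activated reaction actually produces it.  Screens of
fermentation end-products need this distinction — an end-product may
well be supplied in the growth medium and still be of interest as a
biosynthetic capability.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .model import CompoundSet, MetabolicNetwork, NetworkCollection, union_network


@dataclass(frozen=True)
class ScopeResult:
    """Fixed point of network expansion for one network.

    ``n_iterations`` counts synchronous expansion rounds; it is at most
    ``len(reactions) + 1`` since every round before the last activates
    at least one new reaction.
    """

    org_id: str
    reachable: frozenset[str]
    produced: frozenset[str]
    n_iterations: int

    @property
    def activated_fraction(self) -> float:  # pragma: no cover - convenience
        return len(self.produced)


@dataclass(frozen=True)
class CommunityScopeResult:
    """Scope of the meta-network merging a whole collection."""

    reachable: frozenset[str]
    produced: frozenset[str]
    n_iterations: int


@dataclass(frozen=True)
class ScopeSummary:
    """Descriptive statistics over the per-network produced sets."""

    union: frozenset[str]
    intersection: frozenset[str]
    min_size: int
    max_size: int
    mean_size: float


def scope(net: MetabolicNetwork, seeds: CompoundSet) -> ScopeResult:
    """Compute the expansion fixed point of *net* from *seeds*.

    Seed identifiers need not occur in the network.  The result is
    deterministic whatever the internal iteration order; the
    implementation propagates reactant counts through a worklist, which
    is O(total reaction degree) rather than quadratic in |R|.
    """
    reachable: set[str] = set(seeds.ids)
    produced: set[str] = set()
    # unmet[r] = number of reactants of r not yet reachable
    unmet: dict[str, int] = {}
    by_reactant: dict[str, list[str]] = {}
    rxns = net.reactions
    queue: deque[str] = deque()
    for rid, rxn in rxns.items():
        missing = [m for m in rxn.reactants if m not in reachable]
        unmet[rid] = len(missing)
        if not missing:
            queue.append(rid)
        for m in missing:
            by_reactant.setdefault(m, []).append(rid)
    fired: set[str] = set()
    rounds = 1 if rxns else 0
    frontier_sizes: list[int] = []
    while queue:
        frontier_sizes.append(len(queue))
        next_queue: deque[str] = deque()
        for rid in queue:
            if rid in fired:
                continue
            fired.add(rid)
            for m in rxns[rid].products:
                produced.add(m)
                if m not in reachable:
                    reachable.add(m)
                    for dep in by_reactant.get(m, ()):
                        unmet[dep] -= 1
                        if unmet[dep] == 0:
                            next_queue.append(dep)
        queue = next_queue
    n_iter = len(frontier_sizes) + rounds if frontier_sizes else rounds
    return ScopeResult(
        org_id=net.org_id,
        reachable=frozenset(reachable),
        produced=frozenset(produced),
        n_iterations=min(n_iter, len(rxns) + 1),
    )


def individual_scopes(
    coll: NetworkCollection, seeds: CompoundSet
) -> dict[str, ScopeResult]:
    """Per-organism scopes, keyed by org_id."""
    return {net.org_id: scope(net, seeds) for net in coll}


def scope_summary(coll: NetworkCollection, seeds: CompoundSet) -> ScopeSummary:
    """Union/intersection/size statistics of the individual produced sets."""
    if len(coll) == 0:
        raise ValueError("empty collection")
    produced_sets = [scope(net, seeds).produced for net in coll]
    union: frozenset[str] = frozenset().union(*produced_sets)
    inter = frozenset(produced_sets[0]).intersection(*produced_sets[1:])
    sizes = [len(p) for p in produced_sets]
    return ScopeSummary(
        union=union,
        intersection=frozenset(inter),
        min_size=min(sizes),
        max_size=max(sizes),
        mean_size=sum(sizes) / len(sizes),
    )


def community_scope(
    coll: NetworkCollection, seeds: CompoundSet
) -> CommunityScopeResult:
    """Scope of the meta-organism pooling every member's reactions.

    Models unconstrained sharing of metabolites across the community:
    the collective scope is the expansion of the union network, so it
    always contains every individual scope.
    """
    res = scope(union_network(coll), seeds)
    return CommunityScopeResult(
        reachable=res.reachable, produced=res.produced, n_iterations=res.n_iterations
    )


def cooperation_potential(
    coll: NetworkCollection, seeds: CompoundSet
) -> CompoundSet:
    """Metabolites producible by the community but by no member alone.

    The set difference between the community produced set and the union
    of individual produced sets: the "added value" of cross-feeding, and
    the default objective of community selection.
    """
    com = community_scope(coll, seeds).produced
    indiv: set[str] = set()
    for net in coll:
        indiv |= scope(net, seeds).produced
    return CompoundSet("cooperation_potential", frozenset(com - indiv))


@dataclass(frozen=True)
class TargetProducers:
    """Classification of every organism with respect to one target."""

    target: str
    individual_producers: tuple[str, ...]
    com_only_producers: tuple[str, ...]
    unproducible: bool


@dataclass(frozen=True)
class ProducerReport:
    """Per-target producer classification over the whole collection."""

    targets: dict[str, TargetProducers]

    def to_dict(self) -> dict:
        """JSON-ready form, mirroring the producibility_targets contract."""
        return {
            t: {
                "individual_producers": list(tp.individual_producers),
                "com_only_producers": list(tp.com_only_producers),
                "unproducible": tp.unproducible,
            }
            for t, tp in sorted(self.targets.items())
        }


def classify_target_producers(
    coll: NetworkCollection, seeds: CompoundSet, targets: CompoundSet
) -> ProducerReport:
    """Classify each organism as individual / community-only producer per target.

    Organism Gi is an *individual producer* of target t when t is in
    Gi's own produced set.  It is a *community-only producer* when it is
    not an individual producer but carries a reaction producing t whose
    reactants are all reachable by the full community — i.e. Gi can make
    t once its partners feed it the precursors.  A target no organism
    can produce even collectively is flagged unproducible.

    Targets absent from every network are reported unproducible rather
    than rejected: screening workflows routinely pass large target
    lists.
    """
    if not targets.ids:
        raise ValueError("targets must be non-empty")
    indiv = individual_scopes(coll, seeds)
    com = community_scope(coll, seeds)
    report: dict[str, TargetProducers] = {}
    for t in sorted(targets.ids):
        ind: list[str] = []
        com_only: list[str] = []
        for net in coll:
            if t in indiv[net.org_id].produced:
                ind.append(net.org_id)
            else:
                can = any(
                    t in rxn.products and rxn.reactants <= com.reachable
                    for rxn in net
                )
                if can:
                    com_only.append(net.org_id)
        report[t] = TargetProducers(
            target=t,
            individual_producers=tuple(ind),
            com_only_producers=tuple(com_only),
            unproducible=t not in com.produced,
        )
    return ProducerReport(report)
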