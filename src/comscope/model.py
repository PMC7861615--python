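"""Qualitative data model for genome-scale metabolic networks (GSMNs).

A GSMN is represented as a bipartite graph of reaction and metabolite
nodes: each reaction links a set of reactant metabolites to a set of
product metabolites.  The model is deliberately qualitative — no
stoichiometric coefficients, no flux bounds — because every downstream
computation (network expansion, community selection) only needs the
directed reactant→product topology and the gene associations.

Reversible reactions are split into two irreversible directed reactions
at construction time (``_fwd``/``_rev`` suffixes): network expansion is
defined on directed edges only, and carrying a reversibility flag through
the reachability computation would just duplicate that logic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

#: role labels accepted by :class:`CompoundSet`
COMPOUND_ROLES = ("seeds", "targets", "scope", "cooperation_potential")


@dataclass(frozen=True)
class Metabolite:
    """A metabolite node, identified by a string in a shared namespace.

    Cross-network identity is exact id-string equality; see
    :func:`strip_compartment` for the optional compartment normalizer.
    """

    id: str
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A directed reaction: reactants → products.

    ``genes`` holds the flattened set of gene identifiers associated with
    the reaction (boolean AND/OR logic is collapsed: producibility is
    qualitative, so any gene evidence counts).  A reaction with no genes
    that is not flagged ``spontaneous`` is an *orphan*.
    """

    id: str
    reactants: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
    genes: frozenset[str] = frozenset()
    spontaneous: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        object.__setattr__(self, "reactants", frozenset(self.reactants))
        object.__setattr__(self, "products", frozenset(self.products))
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def is_orphan(self) -> bool:
        return not self.genes and not self.spontaneous


class MetabolicNetwork:
    """One organism's metabolic network.

    Parameters
    ----------
    org_id
        Organism identifier (unique within a collection).
    reactions
        Reactions; reversible ones are split into ``<id>_fwd`` /
        ``<id>_rev`` irreversible pairs unless ``expand=False``.
    metabolites
        Optional explicit metabolite list.  Metabolites referenced by
        reactions are always added, so this is only needed to carry
        species that participate in no reaction (or display names).
    """

    def __init__(
        self,
        org_id: str,
        reactions: Iterable[Reaction] = (),
        metabolites: Iterable[Metabolite] = (),
        expand: bool = True,
    ) -> None:
        if not org_id:
            raise ValueError("org_id must be non-empty")
        self.org_id = org_id
        self._reactions: dict[str, Reaction] = {}
        self._metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            self._metabolites[met.id] = met
        for rxn in reactions:
            if expand and rxn.reversible:
                self._add(replace(rxn, id=rxn.id + "_fwd", reversible=False))
                self._add(
                    replace(
                        rxn,
                        id=rxn.id + "_rev",
                        reactants=rxn.products,
                        products=rxn.reactants,
                        reversible=False,
                    )
                )
            else:
                self._add(rxn)
        empty_lhs = sorted(r.id for r in self._reactions.values() if not r.reactants)
        if empty_lhs:
            # such reactions fire at the first expansion step whatever the
            # seeds are: the user must know they act as hidden seeds
            warnings.warn(
                f"network {org_id!r}: reactions with empty reactant set are "
                f"unconditionally activatable: {empty_lhs}",
                stacklevel=2,
            )

    def _add(self, rxn: Reaction) -> None:
        if rxn.id in self._reactions:
            raise ValueError(
                f"duplicate reaction id {rxn.id!r} in network {self.org_id!r}"
            )
        self._reactions[rxn.id] = rxn
        for mid in rxn.reactants | rxn.products:
            self._metabolites.setdefault(mid, Metabolite(mid))

    # -- mapping-ish accessors -------------------------------------------------
    @property
    def reactions(self) -> Mapping[str, Reaction]:
        return self._reactions

    @property
    def metabolites(self) -> Mapping[str, Metabolite]:
        return self._metabolites

    def __len__(self) -> int:
        return len(self._reactions)

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self._reactions.values())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicNetwork {self.org_id}: {len(self._reactions)} reactions, "
            f"{len(self._metabolites)} metabolites>"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.org_id == other.org_id
            and self._reactions == other._reactions
            and set(self._metabolites) == set(other._metabolites)
        )

    __hash__ = None  # type: ignore[assignment]


def remove_orphan_reactions(net: MetabolicNetwork) -> MetabolicNetwork:
    """Return a copy of *net* without orphan reactions.

    An orphan is a reaction with no gene association that is not
    annotated as spontaneous — typically gap-filled reactions added by
    automatic reconstruction.  Spontaneous reactions are exempt.
    Metabolites are kept even if they become unreferenced, so the
    operation never invents missing species downstream.
    """
    kept = [r for r in net if not r.is_orphan]
    return MetabolicNetwork(
        net.org_id,
        kept,
        metabolites=net.metabolites.values(),
        expand=False,
    )


class NetworkCollection:
    """An ordered collection of metabolic networks with distinct org_ids.

    Order is deterministic: lexicographic by ``org_id``.
    """

    def __init__(self, networks: Iterable[MetabolicNetwork]) -> None:
        nets = sorted(networks, key=lambda n: n.org_id)
        ids = [n.org_id for n in nets]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate org_ids in collection: {sorted(dupes)}")
        self._networks: dict[str, MetabolicNetwork] = {n.org_id: n for n in nets}

    @property
    def org_ids(self) -> list[str]:
        return list(self._networks)

    def __getitem__(self, org_id: str) -> MetabolicNetwork:
        return self._networks[org_id]

    def __contains__(self, org_id: str) -> bool:
        return org_id in self._networks

    def __len__(self) -> int:
        return len(self._networks)

    def __iter__(self) -> Iterator[MetabolicNetwork]:
        return iter(self._networks.values())

    def subset(self, org_ids: Iterable[str]) -> "NetworkCollection":
        wanted = set(org_ids)
        unknown = wanted - set(self._networks)
        if unknown:
            raise KeyError(f"unknown org_ids: {sorted(unknown)}")
        return NetworkCollection(self._networks[i] for i in wanted)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<NetworkCollection of {len(self)} networks>"


def union_network(coll: NetworkCollection) -> MetabolicNetwork:
    """Merge a collection into one meta-network ("community").

    The meta-network is the union of all member reaction, metabolite and
    edge sets.  Reactions are merged by their (reactants, products) pair
    after directional expansion: two reactions with identical reactant
    and product sets — however each organism named them — become a
    single meta-reaction.  Gene sets of merged reactions are unioned;
    the merged reaction is spontaneous if any contributor was.
    """
    if len(coll) == 0:
        raise ValueError("cannot merge an empty collection")
    merged: dict[tuple[frozenset[str], frozenset[str]], Reaction] = {}
    mets: dict[str, Metabolite] = {}
    for net in coll:
        for met in net.metabolites.values():
            mets.setdefault(met.id, met)
        for rxn in net:
            key = (rxn.reactants, rxn.products)
            if key in merged:
                prev = merged[key]
                merged[key] = replace(
                    prev,
                    genes=prev.genes | rxn.genes,
                    spontaneous=prev.spontaneous or rxn.spontaneous,
                )
            else:
                # deterministic meta-reaction id from sorted member sets
                merged[key] = replace(rxn, id=_meta_reaction_id(key))
    return MetabolicNetwork(
        "community", merged.values(), metabolites=mets.values(), expand=False
    )


def _meta_reaction_id(key: tuple[frozenset[str], frozenset[str]]) -> str:
    lhs = "+".join(sorted(key[0])) or "0"
    rhs = "+".join(sorted(key[1])) or "0"
    return f"rxn[{lhs}-->{rhs}]"


@dataclass(frozen=True)
class CompoundSet:
    """A named set of metabolite identifiers.

    ``label`` records the role the set plays (seeds, targets, scope,
    cooperation_potential).  Seed sets must be non-empty.
    """

    label: str
    ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(self.ids))
        if self.label == "seeds" and not self.ids:
            raise ValueError("seeds must be non-empty")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.ids))

    def __contains__(self, mid: str) -> bool:
        return mid in self.ids


def strip_compartment(mid: str, tags: Sequence[str] = ("c", "e", "p")) -> str:
    """Strip one trailing compartment token, ``_<tag>`` or ``[<tag>]``.

    Off by default everywhere: identifier matching across networks is
    exact string equality, and silent fuzzy matching would corrupt
    complementarity results.  This helper is for users who know their
    collection mixes compartment suffixes.
    """
    for tag in tags:
        if mid.endswith(f"_{tag}"):
            return mid[: -len(tag) - 1]
        if mid.endswith(f"[{tag}]"):
            return mid[: -len(tag) - 2]
    return mid
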