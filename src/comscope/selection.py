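"""Minimal-community selection and key-species identification.

Given a collection of networks, seed nutrients S and a target compound
set T, a *minimal community* is a minimum-cardinality sub-collection
whose collective produced set covers T.  Because producibility is
monotone in the reaction set (adding an organism never removes a
producible metabolite), every feasible sub-collection of the globally
minimal size L is automatically minimal: no proper subset can be
feasible.

Many optima typically coexist.  Rather than forcing users through a
full (possibly astronomical) enumeration, the roles of organisms across
the whole optimum set are summarised by three sets:

* *key species* — organisms in at least one minimal community (union);
* *essential symbionts* — organisms in every minimal community
  (intersection);
* *alternative symbionts* — key species that are not essential.

Two solver routes are provided.  ``"bnb"`` (default) is an
iterative-deepening search over community sizes — the first feasible
size is optimal, so only subsets up to size L are ever examined; key
species are then computed by 2n forced-inclusion/exclusion solves,
without enumeration.  ``"bruteforce"`` checks every subset size by
size and exists as the independently-coded reference for tests; it is
practical up to ~20 organisms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .model import CompoundSet, NetworkCollection, Reaction
from .expansion import community_scope, scope
from .model import union_network

logger = logging.getLogger(__name__)

DEFAULT_ENUMERATION_CAP = 10**6


class InfeasibleObjective(ValueError):
    """No requested target is producible even by the full community."""


@dataclass(frozen=True)
class MinComResult:
    """One optimal community and the feasibility split of the targets."""

    min_size: int
    community: tuple[str, ...]
    targets_requested: frozenset[str]
    targets_feasible: frozenset[str]
    targets_unproducible: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "bacteria": list(self.community),
            "min_size": self.min_size,
            "still_unprod": sorted(self.targets_unproducible),
            "producible": sorted(self.targets_feasible),
        }


@dataclass(frozen=True)
class KeySpeciesResult:
    """Union / intersection structure of all minimal communities."""

    key_species: frozenset[str]
    essential_symbionts: frozenset[str]
    alternative_symbionts: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "key_species": sorted(self.key_species),
            "essential_symbionts": sorted(self.essential_symbionts),
            "alternative_symbionts": sorted(self.alternative_symbionts),
        }


@dataclass(frozen=True)
class Enumeration:
    """All minimal communities (or a capped prefix of them)."""

    communities: tuple[tuple[str, ...], ...]
    complete: bool

    def __len__(self) -> int:
        return len(self.communities)


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------


class _Instance:
    """Preprocessed instance: per-organism reaction lists + fast feasibility."""

    def __init__(
        self,
        coll: NetworkCollection,
        seeds: CompoundSet,
        targets: CompoundSet,
    ) -> None:
        if len(coll) == 0:
            raise ValueError("empty collection")
        if not targets.ids:
            raise ValueError("targets must be non-empty")
        self.coll = coll
        self.seeds = seeds
        self.org_ids: list[str] = coll.org_ids  # lexicographic
        self.reactions: dict[str, list[Reaction]] = {
            net.org_id: list(net) for net in coll
        }
        full = community_scope(coll, seeds)
        self.feasible_targets = frozenset(targets.ids & full.produced)
        self.unproducible = frozenset(targets.ids - full.produced)

    def produced(self, members: Iterable[str]) -> frozenset[str]:
        members = sorted(set(members))
        if not members:
            return frozenset()
        sub = union_network(self.coll.subset(members))
        return scope(sub, self.seeds).produced

    def covers(self, members: Iterable[str]) -> bool:
        return self.feasible_targets <= self.produced(members)


def _prepare(
    coll: NetworkCollection, seeds: CompoundSet, targets: CompoundSet
) -> _Instance:
    inst = _Instance(coll, seeds, targets)
    if not inst.feasible_targets:
        raise InfeasibleObjective(
            "no producible target: none of the requested targets is in the "
            "community scope of the full collection"
        )
    if inst.unproducible:
        warnings.warn(
            f"{len(inst.unproducible)} target(s) not producible by the full "
            f"community were dropped from the objective: "
            f"{sorted(inst.unproducible)}",
            stacklevel=3,
        )
    return inst


def _search_size_k(
    inst: _Instance,
    k: int,
    candidates: Sequence[str],
    required: Sequence[str] = (),
    cap: int | None = 1,
) -> list[tuple[str, ...]]:
    """All (or up to *cap*) feasible communities of exactly size k.

    ``required`` organisms are forced into every community; the k -
    len(required) free slots are filled from *candidates* in
    lexicographic order, so the first solution found is the
    lexicographically smallest tuple.
    """
    required = sorted(required)
    free = [o for o in candidates if o not in set(required)]
    n_free = k - len(required)
    if n_free < 0:
        return []
    found: list[tuple[str, ...]] = []
    for combo in combinations(free, n_free):
        members = tuple(sorted(required + list(combo)))
        if inst.covers(members):
            found.append(members)
            if cap is not None and len(found) >= cap:
                break
    return found


def _min_size(
    inst: _Instance,
    candidates: Sequence[str] | None = None,
    required: Sequence[str] = (),
) -> tuple[int, tuple[str, ...]] | None:
    """Smallest feasible community (size, lexicographically-first members).

    Iterative deepening: sizes are tried in increasing order, so the
    first hit is optimal.  Returns None when even the full candidate
    set is infeasible (used by the exclusion tests of key_species).
    """
    candidates = list(inst.org_ids if candidates is None else candidates)
    pool = sorted(set(candidates) | set(required))
    if not inst.covers(pool):
        return None
    for k in range(max(1, len(required)), len(pool) + 1):
        hits = _search_size_k(inst, k, candidates, required, cap=1)
        if hits:
            return k, hits[0]
    return None  # pragma: no cover - unreachable, full pool is feasible


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def minimal_community(
    coll: NetworkCollection,
    seeds: CompoundSet,
    targets: CompoundSet,
    solver: str = "bnb",
) -> MinComResult:
    """Select one minimum-size community covering the producible targets.

    Targets outside the full community's produced set are dropped from
    the constraint with a warning and listed in
    ``targets_unproducible``; if nothing remains the objective is
    infeasible and :class:`InfeasibleObjective` is raised.  Among
    equally-sized optima the reported community is the one with the
    lexicographically smallest sorted org_id tuple, so repeated runs and
    different solvers agree.
    """
    inst = _prepare(coll, seeds, targets)
    if solver == "bruteforce":
        best = _bruteforce_optima(inst)
        size, community = len(best[0]), best[0]
    elif solver == "bnb":
        res = _min_size(inst)
        assert res is not None  # feasible targets guarantee a solution
        size, community = res
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return MinComResult(
        min_size=size,
        community=community,
        targets_requested=inst.feasible_targets | inst.unproducible,
        targets_feasible=inst.feasible_targets,
        targets_unproducible=inst.unproducible,
    )


def _bruteforce_optima(inst: _Instance) -> list[tuple[str, ...]]:
    """Every feasible subset of the globally minimal size, by exhaustion.

    Checks all subsets size by size.  Independent of the
    iterative-deepening path on purpose: this is the reference
    implementation used to validate the default solver.
    """
    orgs = inst.org_ids
    for k in range(1, len(orgs) + 1):
        optima = [
            tuple(c) for c in combinations(orgs, k) if inst.covers(c)
        ]
        if optima:
            return sorted(optima)
    raise InfeasibleObjective("no feasible community")  # pragma: no cover


def enumerate_minimal_communities(
    coll: NetworkCollection,
    seeds: CompoundSet,
    targets: CompoundSet,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> Enumeration:
    """Enumerate all minimal communities, up to *cap* of them.

    Since all optima share the minimal size L, enumeration scans the
    size-L subsets; communities come out deduplicated and sorted.  When
    the cap truncates the scan the ``complete`` flag is False and a
    warning is emitted — association graphs built from a truncated
    enumeration are only a lower bound on co-occurrence.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    inst = _prepare(coll, seeds, targets)
    res = _min_size(inst)
    assert res is not None
    size = res[0]
    hits = _search_size_k(inst, size, inst.org_ids, cap=cap + 1)
    complete = len(hits) <= cap
    if not complete:
        warnings.warn(
            f"enumeration truncated at cap={cap}; result is incomplete",
            stacklevel=2,
        )
        hits = hits[:cap]
    return Enumeration(communities=tuple(sorted(hits)), complete=complete)


def key_species(
    coll: NetworkCollection,
    seeds: CompoundSet,
    targets: CompoundSet,
    strategy: str = "projection",
) -> KeySpeciesResult:
    """Key species, essential and alternative symbionts.

    ``strategy="projection"`` (default) avoids enumeration: with L the
    minimal community size,

    * organism G is a *key species* iff some minimal community contains
      it, i.e. the minimum size with G forced included is still L;
    * G is *essential* iff every minimal community contains it, i.e.
      excluding G makes the problem infeasible or pushes the minimum
      above L.

    ``strategy="enumeration"`` derives the same sets as union and
    intersection over the full enumeration (reference route).
    """
    if strategy == "enumeration":
        enum = enumerate_minimal_communities(coll, seeds, targets)
        return key_species_from_enumeration(enum)
    if strategy != "projection":
        raise ValueError(f"unknown strategy {strategy!r}")
    inst = _prepare(coll, seeds, targets)
    res = _min_size(inst)
    assert res is not None
    min_size = res[0]
    key: set[str] = set()
    essential: set[str] = set()
    for org in inst.org_ids:
        with_org = _min_size(inst, required=[org])
        if with_org is not None and with_org[0] == min_size:
            key.add(org)
            without = _min_size(
                inst, candidates=[o for o in inst.org_ids if o != org]
            )
            if without is None or without[0] > min_size:
                essential.add(org)
    return KeySpeciesResult(
        key_species=frozenset(key),
        essential_symbionts=frozenset(essential),
        alternative_symbionts=frozenset(key - essential),
    )


def key_species_from_enumeration(enum: Enumeration) -> KeySpeciesResult:
    """Union/intersection role sets from an explicit enumeration."""
    if not enum.communities:
        raise ValueError("empty enumeration")
    sets = [set(c) for c in enum.communities]
    key = set().union(*sets)
    essential = set(sets[0]).intersection(*sets[1:])
    return KeySpeciesResult(
        key_species=frozenset(key),
        essential_symbionts=frozenset(essential),
        alternative_symbionts=frozenset(key - essential),
    )


@dataclass(frozen=True)
class CommunityVerdict:
    feasible: bool
    minimal: bool


def verify_community(
    coll: NetworkCollection,
    members: Iterable[str],
    seeds: CompoundSet,
    targets: CompoundSet,
) -> CommunityVerdict:
    """Check a candidate community: does it cover the targets, minimally?

    *Feasible*: the requested targets are all in the members' collective
    produced set.  *Minimal*: feasible, and every subset obtained by
    dropping one member is infeasible (by monotonicity this is
    equivalent to no proper subset being feasible).  Unknown org_ids
    raise KeyError.
    """
    members = sorted(set(members))
    sub = coll.subset(members)  # raises on unknown ids
    if not targets.ids:
        raise ValueError("targets must be non-empty")
    want = frozenset(targets.ids)

    def covered(orgs: Sequence[str]) -> bool:
        if not orgs:
            return False
        produced = scope(union_network(coll.subset(orgs)), seeds).produced
        return want <= produced

    feasible = covered(members)
    minimal = feasible and all(
        not covered([o for o in members if o != drop]) for drop in members
    )
    return CommunityVerdict(feasible=feasible, minimal=minimal)
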